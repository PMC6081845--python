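"""Annotation quality categories and PPI orthology mapping."""

import pandas as pd
import pytest

from atlasforge import BlastHit, categorize_hits, intersect_ppi_clusters, map_ppi
from atlasforge.annotation import hits_from_table, normalize_description
from atlasforge.network import ClusterSet


def hit(**kw):
    base = dict(
        subject_id="S1",
        description="solute carrier family 2 member 1",
        genus="Mus",
        percent_identity=95.0,
        alignment_length=190,
        gap_count=0,
        e_value=1e-80,
        is_human=False,
        subject_protein_length=None,
    )
    base.update(kw)
    return BlastHit(**base)


DESC = "solute carrier family 2 member 1"
HGNC = {DESC: "SLC2A1"}


def full_hit_set(subject_len=200):
    """One human hit plus four genera, all high quality, shared description."""
    hits = [hit(subject_id="H1", genus="Homo", is_human=True, subject_protein_length=subject_len)]
    for j, genus in enumerate(("Mus", "Rattus", "Canis", "Sus")):
        hits.append(hit(subject_id=f"O{j}", genus=genus, e_value=1e-70))
    return hits


class TestCategorize:
    def test_top_category_rule_cascade(self):
        res = categorize_hits("g", full_hit_set(subject_len=200), 200, HGNC)
        assert res.category == 1  # human coverage 190/200 = 95%
        assert res.assigned_name == "SLC2A1"

    @pytest.mark.parametrize("subject_len,cat", [(200, 1), (240, 2), (350, 3), (520, 4)])
    def test_human_coverage_grades(self, subject_len, cat):
        res = categorize_hits("g", full_hit_set(subject_len), 200, HGNC)
        assert res.category == cat

    def test_unknown_human_protein_length_stays_five(self):
        res = categorize_hits("g", full_hit_set(subject_len=None), 200, HGNC)
        assert res.category == 5

    def test_three_genera_capped_at_six(self):
        hits = [hit(subject_id="H1", genus="Homo", is_human=True, subject_protein_length=200)]
        hits += [hit(subject_id=f"O{j}", genus=g, e_value=1e-60) for j, g in enumerate(("Mus", "Rattus"))]
        res = categorize_hits("g", hits, 200, HGNC)
        assert res.category == 6

    def test_gallus_does_not_count_toward_genera(self):
        hits = [hit(subject_id="H1", genus="Homo", is_human=True, subject_protein_length=200)]
        hits += [hit(subject_id=f"O{j}", genus=g, e_value=1e-60)
                 for j, g in enumerate(("Mus", "Rattus", "Gallus", "Gallus"))]
        res = categorize_hits("g", hits, 200, HGNC)
        assert res.category == 6

    def test_no_human_hit_is_seven(self):
        hits = [hit(subject_id=f"O{j}", genus=g) for j, g in enumerate(("Mus", "Rattus"))]
        assert categorize_hits("g", hits, 200, HGNC).category == 7

    def test_hypothetical_only_falls_to_eight(self):
        res = categorize_hits("g", [hit(description="hypothetical protein LOC1", e_value=1e-60)], 200)
        assert res.category == 8
        assert res.description == "hypothetical protein LOC1"
        assert res.assigned_name is None

    def test_excluded_descriptions_ignored_above_eight(self):
        hits = [
            hit(subject_id="BAD", description="hypothetical protein", e_value=1e-99),
            hit(subject_id="OK", description="ferritin heavy chain", genus="Mus", e_value=1e-50),
        ]
        res = categorize_hits("g", hits, 200)
        assert res.category == 7
        assert res.description == "ferritin heavy chain"

    def test_evalue_cutoff_gives_unannotated(self):
        res = categorize_hits("g", [hit(e_value=1e-10)], 200)
        assert res.category is None and res.label == "unannotated"

    def test_no_hits_unannotated(self):
        assert categorize_hits("g", [], 200).category is None

    @pytest.mark.parametrize(
        "degrade",
        [
            dict(percent_identity=80.0),
            dict(alignment_length=100),
            dict(gap_count=2),
            dict(alignment_length=40),
        ],
    )
    def test_any_failed_quality_criterion_drops_to_eight(self, degrade):
        res = categorize_hits("g", [hit(**degrade)], 200)
        assert res.category == 8

    def test_category_monotone_under_relaxation(self):
        """Adding evidence (a 4th genus) can only improve the category."""
        hits = [hit(subject_id="H1", genus="Homo", is_human=True, subject_protein_length=200)]
        hits += [hit(subject_id=f"O{j}", genus=g, e_value=1e-60)
                 for j, g in enumerate(("Mus", "Rattus", "Canis"))]
        before = categorize_hits("g", hits, 200, HGNC).category
        hits.append(hit(subject_id="O9", genus="Sus", e_value=1e-60))
        after = categorize_hits("g", hits, 200, HGNC).category
        assert after <= before

    def test_name_requires_description_agreement(self):
        hits = full_hit_set(200)
        # replace 2 of 5 descriptions: agreement 60% < 75%
        hits[3] = hit(subject_id="O2", genus="Canis", description="other protein A", e_value=1e-70)
        hits[4] = hit(subject_id="O3", genus="Sus", description="other protein B", e_value=1e-70)
        res = categorize_hits("g", hits, 200, HGNC)
        assert res.assigned_name is None

    def test_description_normalizer(self):
        assert normalize_description("  Solute  Carrier ISOFORM X1") == "solute carrier"
        assert normalize_description("ferritin heavy chain") == "ferritin heavy chain"


class TestFixtureCascade:
    def test_all_categories_match_hand_tabulated_truth(self, fixtures):
        per_gene = hits_from_table(fixtures.hit_table)
        qlens = fixtures.hit_table.drop_duplicates("gene").set_index("gene")["query_protein_length"]
        for row in fixtures.annotation_truth.itertuples(index=False):
            res = categorize_hits(row.gene, per_gene[row.gene], int(qlens[row.gene]), fixtures.hgnc_map)
            assert res.category == (None if pd.isna(row.expected_category) else int(row.expected_category)), row.gene
            expected_name = None if row.expected_name in (None, "") or pd.isna(row.expected_name) else row.expected_name
            assert res.assigned_name == expected_name, row.gene

    def test_fixture_contains_disqualified_description(self, fixtures):
        descs = fixtures.hit_table["description"].str.lower()
        assert descs.str.contains("hypothetical").any()

    def test_fixture_orthology_spans_gene_order_boundary(self, fixtures):
        goc = fixtures.orthology_table["goc_score"]
        assert (goc == 60.0).any() and (goc >= 75.0).any()


class TestMapPpi:
    def test_labelled_fixture_decisions_match(self, fixtures):
        ppi_in = fixtures.ppi_table[["uniprot_a", "uniprot_b", "evidence"]]
        kept, rejected = map_ppi(ppi_in, fixtures.orthology_table, fixtures.uniprot_map)
        expected_kept = fixtures.ppi_table[fixtures.ppi_table["expected_keep"]]
        got_pairs = set(map(tuple, kept[["uniprot_a", "uniprot_b"]].values))
        exp_pairs = set(map(tuple, expected_kept[["uniprot_a", "uniprot_b"]].values))
        assert got_pairs == exp_pairs
        reasons = rejected.set_index(["uniprot_a", "uniprot_b"])["reason"]
        for row in fixtures.ppi_table.itertuples(index=False):
            if not row.expected_keep and row.reject_reason != "duplicate_pair":
                assert reasons.loc[(row.uniprot_a, row.uniprot_b)] == row.reject_reason

    def test_ortho_evidence_dropped(self, fixtures):
        ppi = pd.DataFrame([("UP00001", "UP00004", "ortho")],
                           columns=["uniprot_a", "uniprot_b", "evidence"])
        kept, rejected = map_ppi(ppi, fixtures.orthology_table, fixtures.uniprot_map)
        assert kept.empty
        assert rejected.iloc[0]["reason"] == "evidence_not_exp_or_pred"

    def test_zero_confidence_orthologue_dropped(self, fixtures):
        ppi = pd.DataFrame([("UP00005", "UP00001", "exp")],
                           columns=["uniprot_a", "uniprot_b", "evidence"])
        kept, rejected = map_ppi(ppi, fixtures.orthology_table, fixtures.uniprot_map)
        assert kept.empty and rejected.iloc[0]["reason"] == "no_qualifying_orthologue"

    def test_unordered_pairs_deduplicated(self, fixtures):
        ppi = pd.DataFrame(
            [("UP00001", "UP00004", "exp"), ("UP00004", "UP00001", "pred")],
            columns=["uniprot_a", "uniprot_b", "evidence"],
        )
        kept, _ = map_ppi(ppi, fixtures.orthology_table, fixtures.uniprot_map)
        assert len(kept) == 1

    def test_output_stable_under_remapping(self, fixtures):
        ppi_in = fixtures.ppi_table[["uniprot_a", "uniprot_b", "evidence"]]
        kept, _ = map_ppi(ppi_in, fixtures.orthology_table, fixtures.uniprot_map)
        again, _ = map_ppi(kept[["uniprot_a", "uniprot_b", "evidence"]],
                           fixtures.orthology_table, fixtures.uniprot_map)
        pd.testing.assert_frame_equal(kept, again)


class TestIntersectPpiClusters:
    def _clusters(self):
        return ClusterSet({1: ["A", "B", "C"], 2: ["D", "E"]}, 2.2)

    def _edges(self, pairs):
        return pd.DataFrame(
            [(f"u{a}", f"u{b}", "exp", a, b) for a, b in pairs],
            columns=["uniprot_a", "uniprot_b", "evidence", "gene_a", "gene_b"],
        )

    def test_spanning_edge_absent(self):
        out = intersect_ppi_clusters(self._edges([("A", "D")]), self._clusters())
        assert out.empty

    def test_clique_cluster_reports_all_pairs(self):
        pairs = [("A", "B"), ("A", "C"), ("B", "C")]
        out = intersect_ppi_clusters(self._edges(pairs), self._clusters())
        assert len(out) == 3 and (out["cluster_id"] == 1).all()

    def test_matches_brute_force_double_loop(self, fixtures):
        from atlasforge._rng import stream

        rng = stream(12, "ppix")
        genes = [f"G{i}" for i in range(30)]
        clusters = ClusterSet({1: genes[:10], 2: genes[10:18], 3: genes[18:]}, 2.2)
        pairs = [tuple(sorted(rng.choice(genes, 2, replace=False))) for _ in range(60)]
        edges = self._edges(pairs)
        out = intersect_ppi_clusters(edges, clusters)
        member = {g: cid for cid, mem in clusters.clusters.items() for g in mem}
        brute = sum(1 for a, b in pairs if member[a] == member[b])
        assert len(out) == brute
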