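"""Reference construction: ORF trimming, source merging, revision."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atlasforge import TranscriptRecord, dedupe_union, revise_transcriptome, trim_utrs
from atlasforge.quant import ExpressionTable
import pandas as pd

STOPS = ("TAA", "TAG", "TGA")


def orf_brute_force(seq):
    """Enumerate every ATG..stop ORF in all forward frames; longest wins,
    ties to the 5'-most start."""
    best = ""
    best_start = len(seq)
    for start in range(len(seq) - 2):
        if seq[start : start + 3] != "ATG":
            continue
        for end in range(start + 3, len(seq) - 2, 3):
            if seq[end : end + 3] in STOPS:
                orf = seq[start : end + 3]
                if len(orf) > len(best) or (len(orf) == len(best) and start < best_start):
                    best, best_start = orf, start
                break
    return best


class TestTrimUtrs:
    def test_hand_readable_single_orf(self):
        assert trim_utrs("AAATGAAATAG") == "ATGAAATAG"

    def test_complete_orf_unchanged(self):
        orf = "ATG" + "GCT" * 10 + "TAA"
        assert trim_utrs(orf) == orf

    def test_longest_of_two_orfs_wins(self):
        short = "ATGAAATAG"            # 9 nt
        long = "ATG" + "GCA" * 5 + "TGA"  # 21 nt
        seq = "CC" + short + "CC" + long + "CC"
        assert trim_utrs(seq) == long
        assert trim_utrs("CC" + long + "CC" + short) == long

    def test_no_orf_returns_empty(self):
        assert trim_utrs("CCCTTTCCC") == ""

    def test_rejects_non_nucleotide_characters(self):
        with pytest.raises(ValueError):
            trim_utrs("ATGXXXTAA")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=60))
    def test_matches_brute_force_enumeration(self, seq):
        assert trim_utrs(seq) == orf_brute_force(seq)


def _rec(tid, seq, source="ensembl", gene=None):
    return TranscriptRecord(tid, seq, source, gene)


def make_mhc_style_fixture():
    """A gene with curated transcripts plus mRNAs that variously duplicate,
    encapsulate, or extend them — the hard merge cases."""
    cds_long = "ATG" + "GAA" * 118 + "TAA"   # 360 nt
    cds_short = "ATG" + "CCA" * 118 + "TGA"
    cds_novel = "ATG" + "GGA" * 118 + "TAG"
    utr5, utr3 = "CT" * 9, "TC" * 73
    ens = [
        _rec("ENST0001", cds_long, "ensembl", "BF1"),
        _rec("ENST0002", cds_short, "ensembl", "BF1"),
    ]
    refseq = [
        # validated mRNA = curated CDS + UTRs: trims to an exact duplicate
        _rec("NM_0001", utr5 + cds_long + utr3, "refseq_nm", "BF1"),
        # predicted mRNA encapsulating a curated CDS of the same gene
        _rec("XM_0002", utr5 + cds_short + utr3, "refseq_xm", "BF1"),
        # predicted mRNA with a CDS absent from the curated set
        _rec("XM_0003", utr5 + cds_novel + utr3, "refseq_xm", "BF1"),
    ]
    return ens, refseq, cds_novel


class TestDedupeUnion:
    def test_encapsulating_xm_is_dropped(self):
        ens, refseq, _ = make_mhc_style_fixture()
        ref = dedupe_union(ens, refseq)
        log = ref.exclusion_table().set_index("transcript_id")
        assert log.loc["XM_0002", "reason"] == "incorporates_ensembl_cds"
        assert "XM_0002" not in ref.ids()

    def test_duplicate_nm_retained_under_curated_identifier(self):
        ens, refseq, _ = make_mhc_style_fixture()
        ref = dedupe_union(ens, refseq)
        log = ref.exclusion_table().set_index("transcript_id")
        assert log.loc["NM_0001", "reason"] == "duplicate_sequence"
        assert log.loc["NM_0001", "detail"] == "ENST0001"
        assert "ENST0001" in ref.ids() and "NM_0001" not in ref.ids()

    def test_novel_xm_kept_and_trimmed(self):
        ens, refseq, cds_novel = make_mhc_style_fixture()
        ref = dedupe_union(ens, refseq)
        rec = {r.transcript_id: r for r in ref.records}["XM_0003"]
        assert rec.sequence == cds_novel  # UTRs removed

    def test_short_cds_excluded(self):
        short = _rec("ENST0250", "ATG" + "GCA" * 81 + "TAA", "ensembl", "G1")  # 249 nt
        ref = dedupe_union([short], [])
        assert ref.records == []
        assert ref.exclusions[0].reason == "short_cds"

    def test_every_drop_logged_exactly_once(self):
        ens, refseq, _ = make_mhc_style_fixture()
        ref = dedupe_union(ens, refseq)
        log = ref.exclusion_table()
        dropped = {r.transcript_id for r in ens + refseq} - set(ref.ids())
        assert sorted(log["transcript_id"]) == sorted(dropped)

    def test_idempotent_on_own_output(self):
        ens, refseq, _ = make_mhc_style_fixture()
        ref = dedupe_union(ens, refseq)
        kept_ens = [r for r in ref.records if r.source == "ensembl"]
        kept_rs = [r for r in ref.records if r.source != "ensembl"]
        again = dedupe_union(kept_ens, kept_rs)
        assert {r.transcript_id: r.sequence for r in again.records} == {
            r.transcript_id: r.sequence for r in ref.records
        }
        assert again.exclusions == []


def _expr(values, meta):
    return ExpressionTable(pd.DataFrame(values), "transcript", pd.DataFrame(meta))


def make_expression_fixture():
    """3 transcripts x 4 samples over 2 tissues (+1 QC-failed sample)."""
    cds = "ATG" + "GCA" * 118 + "TAA"
    records = [
        _rec("T_ZERO", cds, "ensembl", "G0"),
        _rec("T_ONETISSUE", "ATG" + "GGA" * 118 + "TAA", "ensembl", "G1"),
        _rec("T_FAILONLY", "ATG" + "CCA" * 118 + "TAA", "ensembl", "G2"),
        _rec("T_BROAD", "ATG" + "CAA" * 118 + "TAA", "ensembl", "G3"),
    ]
    ref = dedupe_union(records, [])
    values = {
        "s_liver": {"T_ZERO": 0.0, "T_ONETISSUE": 5.0, "T_FAILONLY": 0.0, "T_BROAD": 50.0},
        "s_brain": {"T_ZERO": 0.0, "T_ONETISSUE": 0.0, "T_FAILONLY": 0.0, "T_BROAD": 40.0},
        "s_bad": {"T_ZERO": 0.0, "T_ONETISSUE": 0.0, "T_FAILONLY": 9.0, "T_BROAD": 30.0},
    }
    meta = {
        "bioproject": {"s_liver": "BP1", "s_brain": "BP1", "s_bad": "BP1"},
        "tissue": {"s_liver": "liver", "s_brain": "brain", "s_bad": "spleen"},
    }
    return ref, _expr(values, meta)


class TestReviseTranscriptome:
    def test_undetectable_transcript_dropped(self):
        ref, table = make_expression_fixture()
        ref2 = revise_transcriptome(ref, table, ["s_bad"], single_tissue_filter=False)
        reasons = ref2.exclusion_table().set_index("transcript_id")["reason"]
        assert reasons.loc["T_ZERO"] == "low_expression"

    def test_single_tissue_filter_toggle(self):
        ref, table = make_expression_fixture()
        on = revise_transcriptome(ref, table, ["s_bad"], single_tissue_filter=True)
        off = revise_transcriptome(ref, table, ["s_bad"], single_tissue_filter=False)
        assert "T_ONETISSUE" not in on.ids()
        assert on.exclusion_table().set_index("transcript_id").loc["T_ONETISSUE", "reason"] == "single_tissue"
        assert "T_ONETISSUE" in off.ids()

    def test_transcript_only_in_failed_sample_dropped(self):
        ref, table = make_expression_fixture()
        ref2 = revise_transcriptome(ref, table, ["s_bad"], single_tissue_filter=False)
        reasons = ref2.exclusion_table().set_index("transcript_id")["reason"]
        assert reasons.loc["T_FAILONLY"] == "only_in_failed_samples"
        assert "T_BROAD" in ref2.ids()
        assert ref2.iteration == 2

    def test_output_is_subset_of_input(self):
        ref, table = make_expression_fixture()
        ref2 = revise_transcriptome(ref, table, [], single_tissue_filter=True)
        assert set(ref2.ids()) <= set(ref.ids())

    def test_unknown_failed_sample_rejected(self):
        ref, table = make_expression_fixture()
        with pytest.raises(KeyError):
            revise_transcriptome(ref, table, ["nonexistent"])
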