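"""Down-sampling, k choice, quantification and gene summarisation."""

import numpy as np
import pandas as pd
import pytest

from atlasforge import (
    InsufficientDepthError,
    ReadLibrary,
    SampleSpec,
    TranscriptRecord,
    build_index,
    choose_k,
    downsample,
    gene_summarize,
    make_truth,
    quantify,
    simulate_library,
)
from atlasforge._rng import stream
from atlasforge.quant import ExpressionTable, TPM_TOTAL


def seq_lib(reads, sample_id="s"):
    return ReadLibrary(sample_id=sample_id, reads=list(reads), read_length=max(map(len, reads)))


class TestDownsample:
    def test_exact_cardinality_and_subset(self):
        reads = ["ACGTAC"] * 6 + ["TTGGCC"] * 6
        lib = seq_lib(reads)
        out = downsample(lib, 5, seed=100)
        assert len(out.reads) == 5
        assert all(r in reads for r in out.reads)

    def test_full_depth_is_identity(self):
        lib = seq_lib(["ACGTAC"] * 7)
        assert downsample(lib, 7, seed=1).reads == lib.reads

    def test_same_seed_same_selection(self):
        lib = seq_lib([f"{'ACGT'[i % 4] * 6}" for i in range(50)])
        a = downsample(lib, 10, seed=7)
        b = downsample(lib, 10, seed=7)
        assert a.reads == b.reads

    def test_order_preserved(self):
        reads = ["AAAAAA", "CCCCCC", "GGGGGG", "TTTTTT"] * 5
        lib = seq_lib(reads)
        out = downsample(lib, 8, seed=3)
        positions = []
        cursor = 0
        for r in out.reads:
            cursor = reads.index(r, cursor)
            positions.append(cursor)
        assert positions == sorted(positions)

    def test_abstract_counts_conserved_across_seeds(self):
        counts = pd.Series(
            stream(0, "c").integers(0, 2000, size=500),
            index=[f"t{i}" for i in range(500)],
        )
        lib = ReadLibrary(sample_id="s", counts=counts)
        n = 100_000
        for seed in (1, 2):
            out = downsample(lib, n, seed=seed)
            assert int(out.counts.sum()) == n
            assert (out.counts <= counts).all()

    def test_insufficient_depth_rejected(self):
        lib = seq_lib(["ACGTAC"] * 3)
        with pytest.raises(InsufficientDepthError):
            downsample(lib, 4, seed=1)
        assert InsufficientDepthError.reason == "insufficient_depth"

    def test_unbiasedness_over_repeated_draws(self):
        """Mean sampled proportion stays within 3 standard errors of source."""
        src = pd.Series([5000, 2500, 1500, 800, 200], index=list("abcde"))
        lib = ReadLibrary(sample_id="s", counts=src)
        n, reps = 2000, 200
        draws = np.stack([downsample(lib, n, seed=s).counts.to_numpy() for s in range(reps)])
        props = draws / n
        mean = props.mean(axis=0)
        se = props.std(axis=0, ddof=1) / np.sqrt(reps)
        target = src.to_numpy() / src.sum()
        assert (np.abs(mean - target) <= 3 * np.maximum(se, 1e-12)).all()


class TestChooseK:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [
            (42, 63, 21),    # interval [21, 21]
            (40, 120, 21),   # empty interval -> default
            (60, 90, 29),    # midpoint 30: tie between 29 and 31 broken down
            (100, 100, 41),  # interval [33.3, 50], midpoint ~41.7
        ],
    )
    def test_rule_arithmetic(self, lo, hi, expected):
        assert choose_k(lo, hi) == expected

    def test_invalid_lengths(self):
        with pytest.raises(ValueError):
            choose_k(0, 50)
        with pytest.raises(ValueError):
            choose_k(80, 50)


def _random_tx(rng, tid, gene, n=600):
    seq = "ATG" + "".join(rng.choice(list("ACGT"), size=n - 6)) + "TAA"
    return TranscriptRecord(tid, seq, "ensembl", gene)


class TestQuantify:
    def test_two_equal_transcripts_split_symmetrically(self):
        rng = stream(5, "tx")
        t1 = _random_tx(rng, "T1", "G1")
        t2 = _random_tx(rng, "T2", "G2")
        index = build_index([t1, t2], k=21)
        reads = [t1.sequence[i : i + 50] for i in range(0, 250, 5)] + [
            t2.sequence[i : i + 50] for i in range(0, 250, 5)
        ]
        table = quantify(seq_lib(reads), index)
        assert table.values.loc["T1", "s"] == pytest.approx(500_000, rel=1e-6)
        assert table.values.loc["T2", "s"] == pytest.approx(500_000, rel=1e-6)

    def test_single_transcript_closure(self):
        rng = stream(6, "tx")
        t1 = _random_tx(rng, "T1", "G1")
        index = build_index([t1], k=21)
        table = quantify(seq_lib([t1.sequence[:60]] * 9), index)
        assert table.values.loc["T1", "s"] == pytest.approx(TPM_TOTAL)

    def test_abstract_mode_closed_form(self):
        rng = stream(7, "tx")
        txs = [_random_tx(rng, f"T{i}", f"G{i}") for i in range(3)]
        index = build_index(txs, k=21, with_kmers=False)
        counts = pd.Series([100, 200, 700], index=["T0", "T1", "T2"])
        table = quantify(ReadLibrary(sample_id="s", counts=counts), index)
        expected = [1e5, 2e5, 7e5]  # equal lengths: TPM proportional to counts
        assert np.allclose(table.values["s"].loc[["T0", "T1", "T2"]], expected)

    def test_sequence_mode_recovers_true_proportions(self):
        """Error-free reads from unique-k-mer transcripts: TPM within 1%."""
        rng = stream(8, "tx")
        txs = [_random_tx(rng, f"T{i:02d}", f"G{i:02d}", n=900) for i in range(10)]
        index = build_index(txs, k=21)
        weights = np.arange(1, 11, dtype=float)
        probs = weights / weights.sum()
        reads = []
        n_reads = 4000
        picks = stream(9, "reads").choice(10, size=n_reads, p=probs)
        starts = stream(10, "starts").integers(0, 900 - 75 + 1, size=n_reads)
        for t, s in zip(picks, starts):
            reads.append(txs[t].sequence[s : s + 75])
        table = quantify(seq_lib(reads), index)
        counts = pd.Series(picks).value_counts().sort_index()
        true_tpm = counts / counts.sum() * TPM_TOTAL  # equal (effective) lengths
        got = table.values["s"].to_numpy()
        assert np.allclose(got, true_tpm.to_numpy(), rtol=0.01)

    def test_reads_shorter_than_k_are_skipped_and_counted(self):
        rng = stream(11, "tx")
        t1 = _random_tx(rng, "T1", "G1")
        index = build_index([t1], k=21)
        table = quantify(seq_lib([t1.sequence[:60], "ACGT"]), index)
        assert int(table.meta.loc["s", "n_too_short"]) == 1

    def test_empty_index_rejected(self):
        with pytest.raises(ValueError):
            build_index([], k=21)


class TestGeneSummarize:
    def _table(self, tpm, tx2gene):
        values = pd.DataFrame({"s": pd.Series(tpm)})
        return ExpressionTable(values, "transcript"), tx2gene

    def test_singleton_gene_identity(self):
        table, m = self._table({"T1": 1e6}, {"T1": "G1"})
        out = gene_summarize(table, m)
        assert out.values.loc["G1", "s"] == 1e6 and out.level == "gene"

    def test_additivity_and_column_sum_preserved(self):
        table, m = self._table(
            {"T1": 1e5, "T2": 1e5, "T3": 8e5}, {"T1": "G1", "T2": "G1", "T3": "G2"}
        )
        out = gene_summarize(table, m)
        assert out.values.loc["G1", "s"] == pytest.approx(2e5)
        assert out.values["s"].sum() == pytest.approx(TPM_TOTAL)

    def test_unmapped_transcript_rejected(self):
        table, _ = self._table({"T1": 1e6}, {"T1": "G1"})
        with pytest.raises(KeyError):
            gene_summarize(table, {})


def test_downsampling_spread_concentrates_with_expression(small_truth):
    """Repeated down-samples perturb lowly expressed genes the most: the
    relative TPM spread (max-min over mean) falls monotonically across
    expression deciles."""
    lib = simulate_library(small_truth, SampleSpec("deep", "tissue00", "BP0"), 4_000_000, seed=2)
    tpms = []
    for s in range(10):
        d = downsample(lib, 1_000_000, seed=s)
        tpm = d.counts / d.counts.sum() * TPM_TOTAL
        tpms.append(tpm)
    mat = pd.concat(tpms, axis=1)
    mean = mat.mean(axis=1)
    keep = mean > 0
    rel_spread = (mat.max(axis=1) - mat.min(axis=1))[keep] / mean[keep]
    deciles = pd.qcut(mean[keep].rank(method="first"), 10, labels=False)
    medians = rel_spread.groupby(deciles).median()
    assert (medians.diff().dropna() < 0).mean() >= 0.8  # near-monotone decrease
    assert medians.iloc[0] > medians.iloc[-1]
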