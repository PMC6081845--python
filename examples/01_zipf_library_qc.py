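"""Zipf's-law library QC.

Simulates five RNA-seq libraries from a Zipf-ranked abundance model —
four healthy, one corrupted to a rank^-2 profile — quantifies them and
fits each sample's reverse-cumulative TPM curve on log-log axes.
Healthy libraries fit a slope near -1; the corrupted one falls outside
the acceptance band [-1.2, -0.8] and is excluded.
"""

from atlasforge import SampleSpec, build_index, make_truth, quantify, simulate_library
from atlasforge.reference import TranscriptRecord
from atlasforge.zipf import filter_samples, fit_sample

truth = make_truth(2000, seed=3, n_clusters=0, cluster_size=0)
records = [TranscriptRecord(g, "A" * 1000, "ensembl", g) for g in truth.gene_ids]
index = build_index(records, 21, with_kmers=False)

specs = [SampleSpec(f"lib{i}", "tissue00", "BP0") for i in range(4)]
specs.append(SampleSpec("lib_bad", "tissue00", "BP0", zipf_alpha=2.0))

fits = []
for spec in specs:
    lib = simulate_library(truth, spec, 1_000_000, seed=11)
    table = quantify(lib, index)
    fits.append(fit_sample(table.values.iloc[:, 0].to_numpy(), spec.sample_id))

passed, failed = filter_samples(fits)
for fit in fits:
    verdict = "pass" if fit.passed else "FAIL"
    print(f"{fit.sample_id:8s} exponent={fit.exponent:+.3f} r2={fit.r_squared:.4f} {verdict}")
print(f"\n{len(passed)} libraries pass; {len(failed)} excluded from the atlas.")
print("The exponent is the log-log slope of 'genes with TPM >= level' vs level;")
print("-1 means a minority of genes account for the majority of reads, as expected.")
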