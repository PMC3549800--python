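"""Subsample benchmark: does moderation improve gene ranking?

Simulates a 10-vs-10 pool with known truth, then scores T, Tshrink and
Tshrink+ on repeated random 4-vs-4 subsamples by normalized partial AUC
(FPR <= 0.01; 1 = perfect ranking) and TP/FP at the Bonferroni 0.05 cutoff.
"""

import tshrinkplus as tp

pool = tp.simulate_counts(tp.SimulationConfig(genes=3000, n1=10, n2=10, seed=8))
track = tp.simulate_external_track(pool, rho=0.8, m_replicates=4, seed=9)
cov = tp.standardize_external(track, pool.cm.gene_ids)

report = tp.subsample_benchmark(
    pool.cm,
    pool.truth,
    methods=tp.METHODS,
    n=4,
    replicates=30,
    seed=10,
    covariate=cov,
)

print(f"{'method':9s} {'pAUC':>7s} {'TP':>7s} {'FP':>6s} {'lambda':>7s}")
for m in tp.METHODS:
    print(f"{m:9s} {report.pauc[m]:7.3f} {report.tp[m]:7.1f} "
          f"{report.fp[m]:6.1f} {report.lambdas[m]:7.3f}")

# expected ordering: pAUC(Tshrink+) > pAUC(Tshrink) > pAUC(T).  Moderation
# (Tshrink) improves the ranking by stabilising small-sample variances; the
# external covariate (Tshrink+) adds gene-level variance information the
# mean alone cannot provide, and typically also calls more true positives
# at the same cutoff.
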