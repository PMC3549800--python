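# tshrinkplus

Moderated differential-expression testing for RNA-Seq count data that
borrows variance information from **other experiments**.

## The problem

RNA-Seq experiments with two, three or four biological replicates per
condition are still common, and per-gene variance estimates on
ν = n₁+n₂−2 degrees of freedom are too unstable to rank or call
differentially expressed (DE) genes well. The standard remedy is
*moderation*: shrink each gene's pooled sample variance s² toward a
*common variance* — a smooth curve describing how variance depends on mean
expression. This package implements a moderation scheme whose common
variance is a **surface**, not a curve: local regression of log s² on log
mean expression *plus* one standardized external covariate, either

* gene-wise sample variances computed from an independent RNA-Seq or
  microarray experiment (even of a different tissue), or
* gene length.

The moderated variance is σ̂²_shrink = λ·σ̂²_common + (1−λ)·s², with the
shrinkage weight

λ = min(1, (2K/ν) / Σₖ (s²ₖ/σ̂²_common,k − 1)²)

— the ratio of the expected to the observed squared error of the
common-variance fit (λ = 1: the surface explains gene variances fully).
Each gene is tested with the Wald statistic
(ȳ₁−ȳ₂)/√(σ̂²_shrink(1/n₁+1/n₂)) on pooled Welch–Satterthwaite degrees of
freedom. Three variants are exposed: **T** (plain pooled t-test),
**Tshrink** (mean-only surface) and **Tshrink+** (surface with one
external covariate). The package also ships the GC-content and
cyclic-loess count normalization the tests assume, a seeded NB2 count
simulator with tunable covariate informativeness, and ROC/partial-AUC
benchmarking utilities. See `docs/methods.md` for the full model.

## Worked example

```python
import tshrinkplus as tp

config = tp.SimulationConfig(genes=2000, n1=4, n2=4, de_fraction=0.1, seed=1)
ds = tp.simulate_counts(config)
track = tp.simulate_external_track(ds, rho=0.8, m_replicates=4, seed=2)
covariate = tp.standardize_external(track, ds.cm.gene_ids)

for method in tp.METHODS:
    kwargs = {"covariate": covariate} if method == "Tshrink+" else {}
    res = tp.run_method(ds.cm, method, **kwargs)
```

Running `python examples/01_simulate_and_test.py` (the script above plus
printing) gives:

```
simulated 2000 genes, 4+4 samples, 200 truly DE

method     lambda  nu_shrink  hits  true hits
T           0.000        6.0     9          9
Tshrink     0.495       50.8    73         73
Tshrink+    0.586       89.8    79         79
```

Reading the numbers: the plain t-test on 6 df finds only 9 of the 200 DE
genes at Bonferroni 0.05. Moderation (λ ≈ 0.5 — the mean-only surface
explains about half the squared error of the raw variances) raises the
effective degrees of freedom to ~51 and the discoveries to 73, all of them
true. The external variance track (informativeness ρ = 0.8, 4 external
replicates) lifts λ further, to ν_shrink ≈ 90 and 79 true discoveries —
external variance information buys sensitivity that mean expression alone
cannot.

Other capabilities are demonstrated one per script in `examples/`:
normalization (`02`), covariate standardization (`03`), subsample
benchmarking (`04`).

## Command line

```sh
tshrinkplus simulate --genes 2000 --seed 1 --out-prefix sim/
tshrinkplus normalize --counts raw.tsv --groups "A:s1,s2 B:s3,s4" \
    --annotation ann.tsv --out norm.tsv
tshrinkplus test --counts norm.tsv --conditions cond.tsv \
    --method tshrink+ --external track.tsv --out results.tsv
tshrinkplus evaluate --counts norm.tsv --conditions cond.tsv \
    --truth truth.tsv --n 4 --replicates 100 --seed 1 --out report.json
tshrinkplus run --config run.yaml
```

Tables are TSV (`gene_id mean_g1 mean_g2 statistic df_used p_value
p_adjusted`); run summaries are JSON and record λ, ν_shrink, gene counts
and warnings.

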