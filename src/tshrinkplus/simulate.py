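"""Synthetic count data with the statistical structure the method assumes.

Counts follow the NB2 law: gene i has mean mu_i and variance

    sigma2_i = mu_i + b_i * mu_i^2,

with b_i the squared coefficient of biological variation.  Sampling uses
the gamma-Poisson mixture equivalent to the negative binomial with
r = mu^2 / (sigma2 - mu) and p = mu / sigma2, which keeps non-integer r
exact; b_i = 0 genes are Poisson.  Gene means are log-normal, dispersions
scatter log-normally around a common b, a configurable fraction of genes
is differentially expressed with log2 fold changes drawn from a symmetric
law, and optional library-size and GC-content biases multiply the means.

A Gaussian observation family is also provided: gene values are drawn
Normal(mu, sigma2) with the same NB2 mean-variance relation and clipped at
zero.  It exists for calibration experiments where the chi-square sampling
law of the pooled variance must hold exactly.

External variance tracks are simulated with a tunable informativeness rho:
the external dataset's log-dispersion scatter is Gaussian-copula-correlated
(correlation rho) with the analysis dataset's, so rho = 1 reproduces the
analysis dispersions exactly and rho = 0 is independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, VarianceTrack
from .io import track_from_counts

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_counts",
    "simulate_moments",
    "simulate_external_track",
]


@dataclass
class SimulationConfig:
    """Generative settings for a two-group count experiment.

    Defaults echo a bulk RNA-Seq tissue comparison: 5000 genes, log-normal
    mean counts (median ~55), NB2 dispersion b = 0.05 with log-normal
    gene-level scatter (sd 0.5 on the log scale), 10% DE genes with |log2
    fold changes| uniform on [0.5, 2].
    """

    genes: int = 5000
    n1: int = 4
    n2: int = 4
    mean_log: float = 4.0
    mean_sdlog: float = 1.5
    dispersion: float = 0.05  # NB2 coefficient b
    dispersion_sdlog: float = 0.5  # gene-level scatter of log b; 0 = common b
    de_fraction: float = 0.1
    lfc_min: float = 0.5
    lfc_max: float = 2.0
    library_sdlog: float = 0.0  # log-normal library size factors
    gc_bias: tuple | None = None  # (a, b): per-sample 2^(a + b*gc) factors
    family: str = "nb"  # "nb" or "gaussian"
    inflate_fraction: float = 0.0  # fraction of genes with inflated variance
    inflate_factor: float = 1.0  # multiplier on sigma2 for those genes
    seed: int = 0

    def validate(self) -> None:
        if self.genes < 1 or self.n1 < 1 or self.n2 < 1:
            raise ValueError("genes, n1, n2 must be positive")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ValueError("de_fraction must be in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion b must be >= 0 (sigma2 >= mu)")
        if self.family not in ("nb", "gaussian"):
            raise ValueError(f"unknown observation family {self.family!r}")
        if not (0.0 <= self.inflate_fraction <= 1.0):
            raise ValueError("inflate_fraction must be in [0, 1]")
        if self.inflate_factor < 1.0:
            raise ValueError("inflate_factor must be >= 1 (sigma2 >= mu)")


@dataclass
class SimulatedDataset:
    """A simulated experiment with its generative ground truth."""

    cm: CountMatrix
    mu: pd.DataFrame  # true per-group means, columns g1/g2
    sigma2: pd.DataFrame  # true per-group variances
    dispersion: pd.Series  # true per-gene b_i
    lfc: pd.Series  # true log2 fold change (0 for non-DE)
    truth: pd.Series  # "DE" / "notDE"
    annotation: pd.DataFrame  # length, gc_fraction
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def de_genes(self) -> pd.Index:
        return self.truth.index[self.truth == "DE"]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, sigma2: np.ndarray) -> np.ndarray:
    """Gamma-Poisson draw with mean mu and variance sigma2 elementwise.

    Uses r = mu^2 / (sigma2 - mu), p = mu / sigma2; genes with sigma2 == mu
    are Poisson.  sigma2 < mu is outside the count model's domain.
    """
    mu = np.asarray(mu, float)
    sigma2 = np.asarray(sigma2, float)
    if (sigma2 < mu).any():
        raise ValueError("sigma2 < mu requested; counts cannot be under-dispersed")
    out = np.empty(mu.shape)
    over = sigma2 > mu
    pois = ~over
    if over.any():
        r = mu[over] ** 2 / (sigma2[over] - mu[over])
        lam = rng.gamma(r, (sigma2[over] - mu[over]) / mu[over])
        out[over] = rng.poisson(lam)
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    return out


def simulate_counts(config: SimulationConfig) -> SimulatedDataset:
    """Draw one experiment according to ``config`` (seeded, deterministic)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    g = config.genes
    genes = pd.Index([f"g{i:05d}" for i in range(g)], name="gene_id")
    samples = [f"A{j}" for j in range(config.n1)] + [f"B{j}" for j in range(config.n2)]
    conditions = pd.Series(["1"] * config.n1 + ["2"] * config.n2, index=samples)

    mu_base = rng.lognormal(config.mean_log, config.mean_sdlog, g)
    if config.dispersion_sdlog > 0 and config.dispersion > 0:
        b = config.dispersion * rng.lognormal(0.0, config.dispersion_sdlog, g)
    else:
        b = np.full(g, config.dispersion)

    lfc = np.zeros(g)
    n_de = int(round(config.de_fraction * g))
    if n_de:
        de_idx = rng.choice(g, size=n_de, replace=False)
        mag = rng.uniform(config.lfc_min, config.lfc_max, n_de)
        sign = rng.choice([-1.0, 1.0], n_de)
        lfc[de_idx] = mag * sign

    inflate = np.ones(g)
    if config.inflate_fraction > 0 and config.inflate_factor > 1:
        n_inf = int(round(config.inflate_fraction * g))
        inflate[rng.choice(g, size=n_inf, replace=False)] = config.inflate_factor

    mu1 = mu_base
    mu2 = mu_base * 2.0**lfc
    var1 = inflate * (mu1 + b * mu1**2)
    var2 = inflate * (mu2 + b * mu2**2)

    lib = (
        rng.lognormal(0.0, config.library_sdlog, len(samples))
        if config.library_sdlog > 0
        else np.ones(len(samples))
    )
    gc = rng.uniform(0.3, 0.7, g)
    length = np.maximum(rng.lognormal(7.3, 0.7, g), 100).round().astype(int)

    counts = np.empty((g, len(samples)))
    for j, sample in enumerate(samples):
        mu_j = (mu1 if j < config.n1 else mu2) * lib[j]
        if config.gc_bias is not None:
            a_gc, b_gc = config.gc_bias
            # bias every sample except the first, which acts as reference
            if j > 0:
                mu_j = mu_j * 2.0 ** (a_gc + b_gc * gc)
        sigma2_j = inflate * (mu_j + b * mu_j**2)
        if config.family == "nb":
            counts[:, j] = _nb_draw(rng, mu_j, sigma2_j)
        else:
            counts[:, j] = np.maximum(rng.normal(mu_j, np.sqrt(sigma2_j)), 0.0)

    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=samples), conditions)
    return SimulatedDataset(
        cm=cm,
        mu=pd.DataFrame({"g1": mu1, "g2": mu2}, index=genes),
        sigma2=pd.DataFrame({"g1": var1, "g2": var2}, index=genes),
        dispersion=pd.Series(b, index=genes, name="b"),
        lfc=pd.Series(lfc, index=genes, name="lfc"),
        truth=pd.Series(np.where(lfc != 0, "DE", "notDE"), index=genes, name="label"),
        annotation=pd.DataFrame({"length": length, "gc_fraction": gc}, index=genes),
        config=config,
    )


def simulate_moments(
    genes: int,
    nu: int,
    dispersion: float = 0.05,
    mean_log: float = 5.0,
    mean_sdlog: float = 1.0,
    inflate_fraction: float = 0.0,
    inflate_factor: float = 1.0,
    seed: int = 0,
) -> tuple:
    """Draw gene moments with the mean-variance surface as exact truth.

    Gene means are known (no sampling noise) and pooled variances are drawn
    from their exact chi-square law, s2 = sigma2(mu) * chi2_nu / nu with
    sigma2 = mu + b * mu^2 — the calibration setting in which the shrinkage
    coefficient's working assumptions hold exactly.  Optionally a random
    fraction of genes has its true variance inflated, mis-specifying any
    surface that is a function of the mean alone.

    Returns ``(GeneMoments, true_sigma2)`` with nu split as an n/2-vs-n/2
    design.
    """
    from .datatypes import GeneMoments

    if nu < 2 or nu % 2:
        raise ValueError("nu must be an even integer >= 2 (n1 = n2 = nu/2 + 1)")
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(mean_log, mean_sdlog, genes)
    sigma2 = mu + dispersion * mu**2
    if inflate_fraction > 0 and inflate_factor > 1:
        n_inf = int(round(inflate_fraction * genes))
        idx = rng.choice(genes, size=n_inf, replace=False)
        sigma2[idx] *= inflate_factor
    s2 = sigma2 * rng.chisquare(nu, genes) / nu
    index = pd.Index([f"g{i:05d}" for i in range(genes)], name="gene_id")
    table = pd.DataFrame({"mu_hat": mu, "s2": s2}, index=index)
    half = nu // 2 + 1
    moments = GeneMoments(table, nu_gene=nu, n1=half, n2=half)
    return moments, pd.Series(sigma2, index=index, name="sigma2_true")


def simulate_external_track(
    dataset: SimulatedDataset,
    rho: float,
    m_replicates: int,
    seed: int,
    source_label: str = "simulated-external",
    return_counts: bool = False,
) -> VarianceTrack:
    """Simulate an external experiment whose variance structure is
    correlated with the analysis dataset's.

    The external gene dispersions share the analysis dataset's common b
    and scatter sd, with the Gaussian log-scatter correlated at ``rho``;
    ``m_replicates`` samples are then drawn at the analysis (group-1)
    means and summarised into a variance track.  With ``return_counts``
    the raw external matrix is returned alongside the track, so nested
    designs (first m columns of a larger external experiment) can be
    summarised with :func:`tshrinkplus.io.track_from_counts`.
    """
    if not (0.0 <= rho <= 1.0):
        raise ValueError("rho must be in [0, 1]")
    if m_replicates < 2:
        raise ValueError("m_replicates must be >= 2")
    config = dataset.config
    rng = np.random.default_rng(seed)
    g = len(dataset.cm.gene_ids)

    b = dataset.dispersion.to_numpy(float)
    sdlog = config.dispersion_sdlog
    if config.dispersion > 0 and sdlog > 0:
        z_data = np.log(b / config.dispersion) / sdlog
        z_ext = rho * z_data + np.sqrt(1.0 - rho**2) * rng.standard_normal(g)
        b_ext = config.dispersion * np.exp(sdlog * z_ext)
    else:
        b_ext = b.copy()

    mu = dataset.mu["g1"].to_numpy(float)
    sigma2_ext = mu + b_ext * mu**2
    draws = np.column_stack(
        [_nb_draw(rng, mu, sigma2_ext) for _ in range(m_replicates)]
    )
    df = pd.DataFrame(draws, index=dataset.cm.gene_ids)
    track = track_from_counts(df, source_label=source_label)
    return (track, df) if return_counts else track
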