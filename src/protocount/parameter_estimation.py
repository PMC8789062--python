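"""Estimation of simulation parameters from a reference count matrix.

Gene means: each cell is rescaled to a common transcript budget (default
300 000, roughly the total transcripts of a human cell) and the per-gene mean
of the rescaled values is the latent mean mu_g.

Heterogeneity: the ratio of total counts is computed for a random sample of
cell pairs; the 5th and 95th percentiles of those ratios become the bounds of
the Uniform distribution of per-cell scalings.  The ratio is taken
first/second as drawn, so the sampled distribution is symmetric around one
and the percentiles bracket one.

Capture efficiency: the mean mu_lambda is chosen so that the model-implied
probability of detecting a gene, P(X_g > 0) with
X_g ~ Binomial(round(mu_lambda * m), p_g) and p_g = mu_g / m, matches the
observed mean cell detection rate (UMI data use P(X_g > 1), reflecting
single-copy captures that are read as zeros).  The probability is averaged
over a random probe subset of genes and the objective is minimized by
bounded scalar search.  The SD sigma_lambda is the median absolute deviation
of the per-cell detection rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import binom

from . import protocol_model as pm
from .io import CountMatrix

DEFAULT_TOTAL_TRANSCRIPTS = 300_000


@dataclass
class EstimationConfig:
    total_transcripts: int = DEFAULT_TOTAL_TRANSCRIPTS
    n_pairs: int = 100
    n_probe_genes: int = 100
    umi_mode: bool = False
    rng_seed: int = 0
    mad_scaled: bool = False   # multiply the MAD by the 1.4826 Normal-consistency factor

    def __post_init__(self):
        if self.total_transcripts < 1 or self.n_pairs < 1 or self.n_probe_genes < 1:
            raise ValueError("config sizes must be positive")


@dataclass
class EstimatedParameters:
    mu: np.ndarray
    w_lo: float
    w_hi: float
    mu_lambda: float
    sigma_lambda: float
    total_reads: int

    def __post_init__(self):
        if np.any(self.mu < 0):
            raise ValueError("gene means must be non-negative")
        if not (0 < self.w_lo <= self.w_hi):
            raise ValueError("require 0 < w_lo <= w_hi")
        if not (0 < self.mu_lambda < 1):
            raise ValueError("mu_lambda must be in (0, 1)")
        if self.sigma_lambda < 0:
            raise ValueError("sigma_lambda must be >= 0")


def estimate_gene_means(counts: CountMatrix,
                        total_transcripts: int = DEFAULT_TOTAL_TRANSCRIPTS) -> np.ndarray:
    """Per-gene latent mean after rescaling every cell to a common total."""
    values = counts.values.astype(float)
    depths = values.sum(axis=0)
    keep = depths > 0
    if not np.any(keep):
        raise ValueError("no cells with nonzero depth")
    if not np.all(keep):
        warnings.warn(f"excluding {int(np.sum(~keep))} zero-depth cells from mean estimation")
    scaled = values[:, keep] / depths[keep][None, :] * total_transcripts
    return scaled.mean(axis=1)


def estimate_heterogeneity(counts: CountMatrix, n_pairs: int = 100,
                           rng_seed: int = 0) -> tuple[float, float]:
    """5th/95th percentiles of total-count ratios over random cell pairs."""
    depths = counts.depths().astype(float)
    n = depths.size
    if n < 2:
        raise ValueError("need at least 2 cells")
    rng = np.random.default_rng(rng_seed)
    ratios = np.empty(n_pairs)
    for k in range(n_pairs):
        i, j = rng.choice(n, size=2, replace=False)
        ratios[k] = depths[i] / depths[j] if depths[j] > 0 else np.nan
    ratios = ratios[np.isfinite(ratios)]
    w_lo, w_hi = np.percentile(ratios, [5, 95])
    w_lo = max(float(w_lo), 1e-6)
    return w_lo, max(float(w_hi), w_lo)


def detection_probability(mu_lambda: float, mu: np.ndarray, umi_mode: bool = False) -> np.ndarray:
    """Model-implied per-gene detection probability at capture efficiency mu_lambda.

    p_g = mu_g / m is a per-gene Binomial success probability (not a
    distribution over genes) and is clipped into [0, 1]; n = round(mu_lambda * m).
    """
    m = mu.size
    p_g = np.clip(mu / m, 0.0, 1.0)
    n = max(int(np.rint(mu_lambda * m)), 1)
    if umi_mode:
        return 1.0 - binom.cdf(1, n, p_g)   # P(X_g > 1)
    return 1.0 - binom.pmf(0, n, p_g)       # P(X_g > 0)


def estimate_capture_mean(mu: np.ndarray, observed_mean_detection: float,
                          umi_mode: bool = False, n_probe_genes: int = 100,
                          rng_seed: int = 0) -> float:
    """Capture-efficiency mean matching the observed mean cell detection rate."""
    if not (0 < observed_mean_detection < 1):
        raise ValueError("observed_mean_detection must be in (0, 1)")
    mu = np.asarray(mu, dtype=float)
    rng = np.random.default_rng(rng_seed)
    n_probe = min(n_probe_genes, mu.size)
    probe = mu[rng.choice(mu.size, size=n_probe, replace=False)]

    def objective(mu_lambda):
        implied = float(np.mean(_probe_detection(mu_lambda, probe, mu.size, umi_mode)))
        return abs(implied - observed_mean_detection)

    res = minimize_scalar(objective, bounds=(1e-4, 1.0 - 1e-9), method="bounded",
                          options={"xatol": 1e-4})
    est = float(res.x)
    if est <= 2e-4 or est >= 1.0 - 2e-4:
        warnings.warn("capture-efficiency optimum at search boundary")
    return est


def _probe_detection(mu_lambda: float, probe_mu: np.ndarray, m: int,
                     umi_mode: bool) -> np.ndarray:
    p_g = np.clip(probe_mu / m, 0.0, 1.0)
    n = max(int(np.rint(mu_lambda * m)), 1)
    if umi_mode:
        return 1.0 - binom.cdf(1, n, p_g)
    return 1.0 - binom.pmf(0, n, p_g)


def estimate_capture_sd(counts: CountMatrix, scaled: bool = False) -> float:
    """MAD of per-cell detection rates (optionally x1.4826 for Normal consistency)."""
    values = counts.values
    if values.shape[1] < 2:
        raise ValueError("need at least 2 cells")
    rates = np.count_nonzero(values, axis=0) / values.shape[0]
    mad = float(np.median(np.abs(rates - np.median(rates))))
    return mad * 1.4826 if scaled else mad


def estimate_parameters(counts: CountMatrix,
                        config: Optional[EstimationConfig] = None,
                        **overrides) -> EstimatedParameters:
    """Compose all estimators; keyword overrides replace any estimated field."""
    config = config or EstimationConfig()
    mu = estimate_gene_means(counts, config.total_transcripts)
    w_lo, w_hi = estimate_heterogeneity(counts, config.n_pairs, config.rng_seed)
    values = counts.values
    mean_detection = float(np.mean(np.count_nonzero(values, axis=0) / values.shape[0]))
    mu_lambda = estimate_capture_mean(mu, mean_detection, config.umi_mode,
                                      config.n_probe_genes, config.rng_seed)
    sigma_lambda = estimate_capture_sd(counts, scaled=config.mad_scaled)
    est = EstimatedParameters(mu=mu, w_lo=w_lo, w_hi=w_hi, mu_lambda=mu_lambda,
                              sigma_lambda=sigma_lambda,
                              total_reads=int(values.sum()))
    if overrides:
        est = replace(est, **overrides)
    return est


def to_protocol_parameters(est: EstimatedParameters, counts: CountMatrix,
                           protocol: str = pm.FULL_LENGTH,
                           equalization: Optional[pm.EqualizationSpec] = None) -> pm.ProtocolParameters:
    """Build full simulation parameters from estimates + protocol defaults.

    PCR (18/12 cycles) and tagmentation efficiencies default to
    Normal(0.95, 0.02); the read budget is the reference's grand total.
    """
    profile = pm.GeneExpressionProfile(gene_ids=list(counts.gene_ids), mu=est.mu)
    return pm.ProtocolParameters(
        profile=profile,
        n_cells=counts.n_cells,
        heterogeneity=pm.HeterogeneityModel(w_lo=est.w_lo, w_hi=est.w_hi),
        capture=pm.EfficiencyModel(mean=est.mu_lambda, sd=est.sigma_lambda, role="capture"),
        equalization=equalization or pm.EqualizationSpec(enabled=False),
        sequencing=pm.SequencingSpec(total_reads=est.total_reads, protocol=protocol),
    )
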