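"""Paired-simulation experiments quantifying the effect of cDNA equalization.

Each experiment estimates simulation parameters from the default synthetic
reference, then simulates matched pairs of unequalized/equalized datasets
that share every random stream except the equalization stage, and summarizes
the differences:

* ``paired_equalization_experiment`` — per-cell depth SD, mean gene-specific
  variance, mean cell detection rate and the count-depth-rate MAD statistic
  for each pair.
* ``silhouette_experiment`` — two-population simulations scored by the
  median silhouette width of a 2-D PCA embedding (the embedding is an input
  to the silhouette summary; any external embedding can be substituted).
* ``dynamic_experiment`` — trajectory simulations scored by the AUC of a
  quadratic polynomial test for dynamic genes along the true pseudotime.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np
from sklearn.decomposition import PCA

from . import diagnostics as dg
from . import parameter_estimation as pe
from . import population_structure as ps
from . import protocol_model as pm
from .fixtures import FixtureSpec, generate_fixture

DESK_GENES = 2000
DESK_CELLS = 80


def reference_parameters(seed: int, n_cells: int = DESK_CELLS,
                         fixture_spec: Optional[FixtureSpec] = None):
    """Estimate protocol parameters from the default synthetic reference.

    The read budget is rescaled to the simulated cell count so per-cell depth
    matches the reference's.
    """
    spec = fixture_spec or FixtureSpec(rng_seed=seed)
    matrix, truth = generate_fixture(spec)
    est = pe.estimate_parameters(matrix, pe.EstimationConfig(rng_seed=seed))
    params = pe.to_protocol_parameters(est, matrix)
    reads = int(round(est.total_reads * n_cells / matrix.n_cells))
    params = replace(params, n_cells=n_cells,
                     sequencing=pm.SequencingSpec(reads, pm.FULL_LENGTH))
    return params, est, matrix, truth


def paired_equalization_experiment(n_pairs: int = 20, seed: int = 0,
                                   n_cells: int = DESK_CELLS,
                                   compute_mad: bool = True) -> dict:
    """Simulate matched unEQ/EQ pairs and summarize equalization's effect.

    Returns per-pair arrays: 'depth_sd_pct_change', 'gene_variance_pct_change'
    (both B=EQ relative to A=unEQ), 'detection_gain' (EQ - unEQ mean cell
    detection rate) and, when compute_mad, 'mad_uneq'/'mad_eq'.
    """
    params, _, _, _ = reference_parameters(seed, n_cells=n_cells)
    p_un = replace(params, equalization=pm.EqualizationSpec(enabled=False))
    p_eq = replace(params, equalization=pm.EqualizationSpec(enabled=True))
    out = {"depth_sd_pct_change": [], "gene_variance_pct_change": [],
           "detection_gain": [], "mad_uneq": [], "mad_eq": []}
    for k in range(n_pairs):
        pair_seed = seed * 10_000 + k
        r_un = pm.simulate_experiment(p_un, pair_seed)
        r_eq = pm.simulate_experiment(p_eq, pair_seed)
        change = dg.paired_change_summary(r_un.counts, r_eq.counts)
        out["depth_sd_pct_change"].append(change["depth_sd_pct_change"])
        out["gene_variance_pct_change"].append(change["gene_variance_pct_change"])
        out["detection_gain"].append(
            float(dg.cell_detection_rates(r_eq.counts).mean()
                  - dg.cell_detection_rates(r_un.counts).mean()))
        if compute_mad:
            out["mad_uneq"].append(dg.count_depth_profile(r_un.counts).mad)
            out["mad_eq"].append(dg.count_depth_profile(r_eq.counts).mad)
    return {k: np.asarray(v) for k, v in out.items() if v}


def _pca_embedding(counts: np.ndarray, seed: int) -> np.ndarray:
    """Externally-supplied 2-D coordinates for silhouette scoring: PCA of
    depth-normalized log counts."""
    depths = counts.sum(axis=0).astype(float)
    depths[depths == 0] = 1.0
    x = np.log1p(counts / depths[None, :] * depths.mean())
    return PCA(n_components=2, random_state=seed).fit_transform(x.T)


def silhouette_experiment(n_pairs: int = 10, seed: int = 0) -> dict:
    """Two-population (50 + 40 cells, 10% DE, fold changes Normal(1.5, 0.5))
    paired simulations scored by median silhouette width of a PCA embedding."""
    params, _, _, _ = reference_parameters(seed, n_cells=90)
    p_un = replace(params, equalization=pm.EqualizationSpec(enabled=False))
    p_eq = replace(params, equalization=pm.EqualizationSpec(enabled=True))
    sil_un, sil_eq = [], []
    for k in range(n_pairs):
        pair_seed = seed * 10_000 + k
        spec = ps.PopulationSpec([50, 40], prop_de=0.1, fc_mean=1.5, fc_sd=0.5,
                                 rng_seed=pair_seed)
        r_un, truth = ps.simulate_structured(p_un, spec, pair_seed)
        r_eq, _ = ps.simulate_structured(p_eq, spec, pair_seed)
        labels = truth["population"]
        _, m_un = dg.silhouette_summary(_pca_embedding(r_un.counts, pair_seed), labels)
        _, m_eq = dg.silhouette_summary(_pca_embedding(r_eq.counts, pair_seed), labels)
        sil_un.append(m_un)
        sil_eq.append(m_eq)
    sil_un, sil_eq = np.asarray(sil_un), np.asarray(sil_eq)
    return {"silhouette_uneq": sil_un, "silhouette_eq": sil_eq,
            "frac_eq_larger": float(np.mean(sil_eq > sil_un)),
            "median_difference": float(np.median(sil_eq - sil_un))}


def dynamic_experiment(n_pairs: int = 3, seed: int = 0) -> dict:
    """Trajectory simulations: AUC of the quadratic dynamic-gene test along
    the true pseudotime, equalized vs unequalized."""
    params, _, _, _ = reference_parameters(seed, n_cells=DESK_CELLS)
    p_un = replace(params, equalization=pm.EqualizationSpec(enabled=False))
    p_eq = replace(params, equalization=pm.EqualizationSpec(enabled=True))
    auc_un, auc_eq = [], []
    for k in range(n_pairs):
        pair_seed = seed * 10_000 + k
        spec = ps.DynamicSpec(prop_dynamic=0.1, rng_seed=pair_seed)
        r_un, truth = ps.simulate_structured(p_un, spec, pair_seed)
        r_eq, _ = ps.simulate_structured(p_eq, spec, pair_seed)
        t = truth["pseudotime"]
        is_dyn = truth["is_dynamic"]
        x_un = np.log1p(r_un.counts.astype(float))
        x_eq = np.log1p(r_eq.counts.astype(float))
        auc_un.append(dg.dynamic_gene_auc(x_un, t, is_dyn)["auc"])
        auc_eq.append(dg.dynamic_gene_auc(x_eq, t, is_dyn)["auc"])
    return {"auc_uneq": np.asarray(auc_un), "auc_eq": np.asarray(auc_eq)}
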