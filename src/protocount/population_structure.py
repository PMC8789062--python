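"""Latent expression structure: discrete populations and continuous dynamics.

Discrete populations: the first population is the reference; every other
population changes a random fraction of genes by a fold change drawn from
Normal(fc_mean, fc_sd) (truncated at a small positive floor), applied as
multiplication or division with equal probability so differential expression
goes both directions.

Dynamic (trajectory) populations: cells sit on an evenly spaced pseudotime
grid in [0, 1]; each dynamic gene's latent mean is a quadratic B-spline with
two interior knots (at 1/3 and 2/3) whose coefficients are drawn
Normal(coef_mean, coef_sd), clamped at zero.  Non-dynamic genes keep their
static mean for every cell.

Both generators return ground-truth labels so downstream evaluations
(clustering separation, dynamic-gene detection) can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.interpolate import BSpline

from . import protocol_model as pm

_FC_FLOOR = 0.05


@dataclass
class PopulationSpec:
    cells_per_pop: list
    prop_de: float = 0.1
    fc_mean: float = 1.5
    fc_sd: float = 0.5
    rng_seed: int = 0
    direction: str = "random"   # 'random', 'up' or 'down' (forced direction)

    def __post_init__(self):
        if any(int(c) < 1 for c in self.cells_per_pop):
            raise ValueError("all population sizes must be >= 1")
        if not (0 <= self.prop_de <= 1):
            raise ValueError("prop_de must be in [0, 1]")
        if self.fc_sd < 0:
            raise ValueError("fc_sd must be >= 0")
        if self.direction not in ("random", "up", "down"):
            raise ValueError("direction must be 'random', 'up' or 'down'")


@dataclass
class DynamicSpec:
    prop_dynamic: float = 0.1
    spline_degree: int = 2
    n_knots: int = 2
    coef_mean: float = 5.0
    coef_sd: float = 5.0
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 <= self.prop_dynamic <= 1):
            raise ValueError("prop_dynamic must be in [0, 1]")
        if self.spline_degree < 1:
            raise ValueError("spline_degree must be >= 1")
        if self.n_knots < 0:
            raise ValueError("n_knots must be >= 0")


def apply_population_differences(profile: pm.GeneExpressionProfile,
                                 spec: PopulationSpec):
    """Per-population latent profiles plus ground-truth DE labels.

    Returns (profiles, de_labels): profiles[0] is the reference; de_labels is
    a boolean (n_pops, G) matrix (all False for the reference row).  DE gene
    sets and fold changes are drawn independently per non-reference
    population.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n_pops = len(spec.cells_per_pop)
    g = profile.n_genes
    n_de = int(np.rint(spec.prop_de * g))
    profiles = [profile]
    de_labels = np.zeros((n_pops, g), dtype=bool)
    for p in range(1, n_pops):
        mu = profile.mu.copy()
        idx = rng.choice(g, size=n_de, replace=False)
        fc = np.maximum(rng.normal(spec.fc_mean, spec.fc_sd, size=n_de), _FC_FLOOR)
        if spec.direction == "random":
            up = rng.random(n_de) < 0.5
        else:
            up = np.full(n_de, spec.direction == "up")
        mu[idx] = np.where(up, mu[idx] * fc, mu[idx] / fc)
        profiles.append(pm.GeneExpressionProfile(gene_ids=list(profile.gene_ids), mu=mu))
        de_labels[p, idx] = True
    return profiles, de_labels


def generate_dynamic_means(profile: pm.GeneExpressionProfile, spec: DynamicSpec,
                           n_cells: int):
    """G x N latent-mean matrix along pseudotime plus dynamic-gene labels.

    Returns (means, dynamic_labels, pseudotime).
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells for a trajectory")
    rng = np.random.default_rng(spec.rng_seed)
    g = profile.n_genes
    t = np.linspace(0.0, 1.0, n_cells)
    n_dyn = int(np.rint(spec.prop_dynamic * g))
    dynamic = np.zeros(g, dtype=bool)
    dynamic[rng.choice(g, size=n_dyn, replace=False)] = True

    means = np.tile(profile.mu[:, None], (1, n_cells)).astype(float)
    deg = spec.spline_degree
    interior = np.linspace(0, 1, spec.n_knots + 2)[1:-1]
    knots = np.concatenate([np.zeros(deg + 1), interior, np.ones(deg + 1)])
    n_coef = len(knots) - deg - 1
    for gi in np.nonzero(dynamic)[0]:
        coefs = rng.normal(spec.coef_mean, spec.coef_sd, size=n_coef)
        spline = BSpline(knots, coefs, deg, extrapolate=False)
        means[gi] = np.clip(spline(t), 0.0, None)
    return means, dynamic, t


def simulate_structured(params: pm.ProtocolParameters,
                        structure: Union[PopulationSpec, DynamicSpec],
                        rng_seed: int, keep_stages: bool = False):
    """Run the protocol simulation on top of a structured latent profile.

    Returns (SimulationResult, ground_truth); ground_truth carries
    'population' labels or ('pseudotime', 'is_dynamic') depending on the
    structure type, plus per-gene DE/dynamic flags.
    """
    if isinstance(structure, PopulationSpec):
        n_total = int(sum(structure.cells_per_pop))
        if n_total != params.n_cells:
            raise ValueError(f"cells_per_pop sums to {n_total} but params.n_cells is {params.n_cells}")
        profiles, de_labels = apply_population_differences(params.profile, structure)
        cols = []
        pop_of_cell = []
        for p, (prof, n_c) in enumerate(zip(profiles, structure.cells_per_pop)):
            cols.append(np.tile(prof.mu[:, None], (1, int(n_c))))
            pop_of_cell.extend([p] * int(n_c))
        latent = np.hstack(cols)
        truth = {"population": np.asarray(pop_of_cell),
                 "de_labels": de_labels,
                 "is_de": de_labels.any(axis=0)}
    elif isinstance(structure, DynamicSpec):
        latent, dynamic, t = generate_dynamic_means(params.profile, structure,
                                                    params.n_cells)
        truth = {"pseudotime": t, "is_dynamic": dynamic}
    else:
        raise TypeError(f"unsupported structure type {type(structure).__name__}")

    result = pm.simulate_experiment(params, rng_seed, keep_stages=keep_stages,
                                    latent_means=latent)
    return result, truth
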