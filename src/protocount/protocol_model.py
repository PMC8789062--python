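"""Forward simulation of an scRNA-seq experiment, one protocol stage at a time.

The generative model tracks a genes x cells molecule-count matrix through the
stages of a plate-based full-length protocol (Smart-seq-like):

    latent mRNA  ->  capture/RT  ->  preamplification PCR  ->
    (optional cDNA equalization)  ->  tagmentation  ->  second PCR  ->
    pooled sequencing

Latent mRNA for gene g in cell j is Poisson(omega_j * mu_g), where mu_g is the
gene's latent mean and omega_j ~ Uniform(w_lo, w_hi) captures cell-to-cell
heterogeneity in total mRNA content.  Capture, equalization and tagmentation
are multinomial thinnings of each cell's column: a per-cell efficiency sets
the retained total and molecules are allocated proportionally to current
abundances.  PCR multiplies every count by (1 + rho_j)^cycles.  Sequencing
allocates a fixed read budget R over all gene-cell entries of the pooled
library by a single multinomial, so cells compete for reads in proportion to
their amplified cDNA.

Equalization dilutes concentrated cDNA libraries toward a common target q*
before pooling: cells above q* are diluted to it (dilution factor q*/l_j),
cells within range keep ~95% of material (liquid-transfer loss).  Realized
dilution factors get small Normal noise.

UMI protocols additionally track the number of distinct captured molecules
through every stage and report, per gene-cell entry, the number of distinct
molecules hit by at least one read.  Droplet protocols pool immediately after
capture, have no per-cell preamplification and no equalization, and use a
single global tagmentation/PCR efficiency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from ._rng import stage_rngs

_EFF_FLOOR = 1e-6

FULL_LENGTH = "full_length"
UMI_PLATE = "umi_plate"
DROPLET = "droplet"
PROTOCOLS = (FULL_LENGTH, UMI_PLATE, DROPLET)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class GeneExpressionProfile:
    """Latent per-gene mean mRNA counts mu_g."""

    gene_ids: list
    mu: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        if len(self.gene_ids) != self.mu.shape[0]:
            raise ValueError("gene_ids and mu must have equal length")
        if np.any(self.mu < 0):
            raise ValueError("gene means must be non-negative")
        if not np.any(self.mu > 0):
            raise ValueError("at least one gene mean must be positive")

    @property
    def n_genes(self) -> int:
        return self.mu.shape[0]


@dataclass
class HeterogeneityModel:
    """Bounds of the Uniform distribution of per-cell mRNA-content scalings."""

    w_lo: float = 0.8
    w_hi: float = 1.2

    def __post_init__(self):
        if not (0 < self.w_lo <= self.w_hi):
            raise ValueError("require 0 < w_lo <= w_hi")


@dataclass
class EfficiencyModel:
    """Normal distribution of a per-cell efficiency, clamped to (0, 1].

    role is one of 'capture', 'tagmentation', 'pcr1', 'pcr2'; it only labels
    the knob for reporting.
    """

    mean: float
    sd: float
    role: str = ""

    def __post_init__(self):
        if not (0 < self.mean <= 1):
            raise ValueError(f"efficiency mean must be in (0, 1], got {self.mean}")
        if self.sd < 0:
            raise ValueError("efficiency sd must be >= 0")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        vals = rng.normal(self.mean, self.sd, size=n)
        return np.clip(vals, _EFF_FLOOR, 1.0)


@dataclass
class PCRSpec:
    cycles1: int = 18
    cycles2: int = 12
    eff1: EfficiencyModel = field(default_factory=lambda: EfficiencyModel(0.95, 0.02, "pcr1"))
    eff2: EfficiencyModel = field(default_factory=lambda: EfficiencyModel(0.95, 0.02, "pcr2"))

    def __post_init__(self):
        if self.cycles1 < 0 or self.cycles2 < 0:
            raise ValueError("cycle counts must be >= 0")


DILUTE_TO_MIN = "dilute_to_min"
QUANTILE_RANGE = "quantile_range"


@dataclass
class EqualizationSpec:
    enabled: bool = False
    mode: str = DILUTE_TO_MIN
    quantile: float = 0.8
    retained_fraction: float = 0.95
    noise_sd: float = 0.01

    def __post_init__(self):
        if self.mode not in (DILUTE_TO_MIN, QUANTILE_RANGE):
            raise ValueError(f"unknown equalization mode {self.mode!r}")
        if not (0 < self.retained_fraction <= 1):
            raise ValueError("retained_fraction must be in (0, 1]")
        if not (0 < self.quantile <= 1):
            raise ValueError("quantile must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SequencingSpec:
    total_reads: int
    protocol: str = FULL_LENGTH

    def __post_init__(self):
        self.total_reads = int(self.total_reads)
        if self.total_reads < 1:
            raise ValueError("total_reads must be >= 1")
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")


@dataclass
class ProtocolParameters:
    """Everything needed to run one simulated experiment."""

    profile: GeneExpressionProfile
    n_cells: int
    heterogeneity: HeterogeneityModel = field(default_factory=HeterogeneityModel)
    capture: EfficiencyModel = field(default_factory=lambda: EfficiencyModel(0.1, 0.005, "capture"))
    pcr: PCRSpec = field(default_factory=PCRSpec)
    tagmentation: EfficiencyModel = field(default_factory=lambda: EfficiencyModel(0.95, 0.02, "tagmentation"))
    equalization: EqualizationSpec = field(default_factory=EqualizationSpec)
    sequencing: SequencingSpec = field(default_factory=lambda: SequencingSpec(1_000_000))
    # EQ-Vary style variable pooling: per-cell scaling in (0, 1] applied as an
    # extra thinning after equalization; None disables it.
    post_equalization_scaling: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.post_equalization_scaling is not None:
            s = np.asarray(self.post_equalization_scaling, dtype=float)
            if s.shape != (self.n_cells,) or np.any(s <= 0) or np.any(s > 1):
                raise ValueError("post_equalization_scaling must be length n_cells with values in (0, 1]")
            self.post_equalization_scaling = s
        if self.equalization.enabled and self.sequencing.protocol == DROPLET:
            raise ValueError("equalization is not possible in droplet protocols (cDNA is pooled at capture)")


@dataclass
class CellDraws:
    """Per-cell realized parameters for one simulated experiment."""

    omega: np.ndarray
    lam: np.ndarray
    rho1: np.ndarray
    gamma: np.ndarray
    rho2: np.ndarray
    dilution: Optional[np.ndarray] = None


STAGES = ("initial", "captured", "preamplified", "equalized", "tagmented", "amplified2", "sequenced")


@dataclass
class StageState:
    """Snapshot of the molecule-count matrix after one protocol stage."""

    counts: np.ndarray
    stage: str
    unique_molecules: Optional[np.ndarray] = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("stage counts must be non-negative")


@dataclass
class SimulationResult:
    counts: np.ndarray               # final G x N observed counts (reads or UMIs)
    draws: CellDraws
    seed: int
    params: ProtocolParameters
    stages: Optional[list] = None    # list[StageState] when keep_stages
    gene_ids: list = field(default_factory=list)
    cell_ids: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# stage operations
# ---------------------------------------------------------------------------

def draw_cell_parameters(params: ProtocolParameters, rng_seed: int) -> CellDraws:
    """Realize every per-cell parameter from its distribution.

    Draw order (omega, lambda, rho1, gamma, rho2) is fixed; efficiencies are
    clamped to (1e-6, 1].
    """
    rng = stage_rngs(rng_seed)["draws"]
    return _draw_cell_parameters(params, rng)


def _draw_cell_parameters(params: ProtocolParameters, rng: np.random.Generator) -> CellDraws:
    n = params.n_cells
    h = params.heterogeneity
    omega = rng.uniform(h.w_lo, h.w_hi, size=n)
    lam = params.capture.draw(n, rng)
    rho1 = params.pcr.eff1.draw(n, rng)
    gamma = params.tagmentation.draw(n, rng)
    rho2 = params.pcr.eff2.draw(n, rng)
    return CellDraws(omega=omega, lam=lam, rho1=rho1, gamma=gamma, rho2=rho2)


def generate_initial_mrna(
    profile: GeneExpressionProfile,
    omega: np.ndarray,
    rng_seed: Optional[int] = None,
    *,
    rng: Optional[np.random.Generator] = None,
    latent_means: Optional[np.ndarray] = None,
) -> StageState:
    """Draw the latent mRNA matrix M with M[g, j] ~ Poisson(omega_j * mu_g).

    latent_means may supply a full G x N matrix of cell-specific means (used
    for multi-population and dynamic simulations); otherwise profile.mu is
    broadcast across cells.
    """
    if rng is None:
        rng = stage_rngs(rng_seed)["initial"]
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("omega must be positive")
    mu = profile.mu[:, None] if latent_means is None else np.asarray(latent_means, dtype=float)
    if mu.ndim == 1:
        mu = mu[:, None]
    if np.any(mu < 0):
        raise ValueError("latent means must be non-negative")
    lam = mu * omega[None, :]
    counts = rng.poisson(lam).astype(np.int64)
    return StageState(counts=counts, stage="initial")


def _thin_columns(counts: np.ndarray, fractions: np.ndarray, rng: np.random.Generator,
                  stage: str) -> np.ndarray:
    """Multinomial thinning of each column to round(f_j * colsum) molecules."""
    counts = np.asarray(counts)
    fractions = np.asarray(fractions, dtype=float)
    out = np.zeros_like(counts, dtype=np.int64)
    totals = counts.sum(axis=0)
    for j in range(counts.shape[1]):
        tot = totals[j]
        if tot == 0:
            warnings.warn(f"cell {j} has zero molecules entering stage {stage!r}; column left empty")
            continue
        target = int(np.rint(fractions[j] * tot))  # banker's rounding
        if target == 0:
            continue
        p = counts[:, j] / tot
        out[:, j] = rng.multinomial(target, p)
    return out


def _thin_unique(unique: np.ndarray, copies_before: np.ndarray, copies_after: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Thin distinct-molecule counts consistently with a thinning of copies.

    Each of u distinct molecules in an entry is assumed to hold an equal share
    c = T/u of the T copies present; after K of T copies are kept, a molecule
    survives with probability 1 - (1 - K/T)^c (with-replacement approximation
    of the without-replacement draw).  Survivor counts are drawn Binomial(u, p)
    independently per entry, floored at 1 wherever copies remain.
    """
    u = np.asarray(unique, dtype=np.int64)
    T = np.asarray(copies_before, dtype=float)
    K = np.asarray(copies_after, dtype=float)
    out = np.zeros_like(u)
    mask = (u > 0) & (T > 0)
    if not np.any(mask):
        return out
    c = T[mask] / u[mask]
    frac_lost = np.clip(1.0 - K[mask] / T[mask], 0.0, 1.0)
    p_survive = 1.0 - frac_lost ** c
    surv = rng.binomial(u[mask], p_survive)
    # copies remaining implies at least one physical molecule remains
    surv = np.where(K[mask] > 0, np.maximum(surv, 1), surv)
    surv = np.minimum(surv, np.minimum(u[mask], np.maximum(K[mask], 0)).astype(np.int64))
    out[mask] = surv
    return out


def capture_molecules(state: StageState, lam: np.ndarray,
                      rng_seed: Optional[int] = None, *,
                      rng: Optional[np.random.Generator] = None,
                      track_unique: bool = False) -> StageState:
    """Capture/RT: thin each cell's mRNA to round(lambda_j * total) molecules."""
    if rng is None:
        rng = stage_rngs(rng_seed)["capture"]
    z = _thin_columns(state.counts, lam, rng, "captured")
    return StageState(counts=z, stage="captured",
                      unique_molecules=z.copy() if track_unique else None)


def amplify(state: StageState, rho: np.ndarray | float, cycles: int,
            stage: str = "preamplified") -> StageState:
    """PCR: multiply every count by (1 + rho_j)^cycles, rounded to integer.

    Deterministic; amplification creates copies, never new distinct
    molecules, so unique_molecules passes through unchanged.  Computation is
    in float64, exact for counts below 2**53.
    """
    if cycles < 0:
        raise ValueError("cycles must be >= 0")
    rho = np.asarray(rho, dtype=float)
    factor = (1.0 + rho) ** cycles
    scaled = state.counts * (factor if factor.ndim == 0 else factor[None, :])
    out = np.rint(scaled)
    if np.any(out >= 2.0 ** 53):
        raise OverflowError("amplified counts exceed exact float64 integer range")
    return StageState(counts=out.astype(np.int64), stage=stage,
                      unique_molecules=state.unique_molecules)


def cdna_concentrations(state: StageState) -> np.ndarray:
    """Per-cell cDNA 'concentration' l_j = total amplified molecules in cell j.

    Concentration is proportional to molecule number at fixed reaction volume.
    """
    return state.counts.sum(axis=0).astype(float)


def compute_dilution_factors(l: np.ndarray, spec: EqualizationSpec,
                             rng_seed: Optional[int] = None, *,
                             rng: Optional[np.random.Generator] = None):
    """Dilution factors S_j ~ Normal(tau_j, noise_sd) toward the target q*.

    tau_j = retained_fraction for cells already below q* (in-range cells lose
    only transfer material), q*/l_j otherwise.  dilute_to_min sets q* to the
    smallest positive concentration; quantile_range sets it to the midpoint of
    the smallest concentration and the concentration at the requested
    quantile.  A cell exactly at q* falls in the 'otherwise' branch (tau = 1).

    Returns (S, qstar).
    """
    if rng is None:
        rng = stage_rngs(rng_seed)["equalize"]
    l = np.asarray(l, dtype=float)
    pos = l[l > 0]
    if pos.size == 0:
        raise ValueError("equalization undefined: all cells have zero cDNA")
    if spec.mode == DILUTE_TO_MIN:
        qstar = pos.min()
    else:
        qstar = 0.5 * (pos.min() + np.quantile(l, spec.quantile))
    tau = np.where(l < qstar, spec.retained_fraction, np.divide(qstar, l, out=np.ones_like(l), where=l > 0))
    s = rng.normal(tau, spec.noise_sd)
    return np.clip(s, _EFF_FLOOR, 1.0), float(qstar)


def equalize(state: StageState, s: np.ndarray,
             rng_seed: Optional[int] = None, *,
             rng: Optional[np.random.Generator] = None) -> StageState:
    """Dilute each cell's cDNA to round(S_j * total) molecules (multinomial)."""
    if rng is None:
        rng = stage_rngs(rng_seed)["equalize"]
    out = _thin_columns(state.counts, s, rng, "equalized")
    uniq = state.unique_molecules
    if uniq is not None:
        uniq = _thin_unique(uniq, state.counts, out, rng)
    return StageState(counts=out, stage="equalized", unique_molecules=uniq)


def tagment(state: StageState, gamma: np.ndarray,
            rng_seed: Optional[int] = None, *,
            rng: Optional[np.random.Generator] = None) -> StageState:
    """Tagmentation: per-cell multinomial thinning with efficiency gamma_j."""
    if rng is None:
        rng = stage_rngs(rng_seed)["tagment"]
    out = _thin_columns(state.counts, gamma, rng, "tagmented")
    uniq = state.unique_molecules
    if uniq is not None:
        uniq = _thin_unique(uniq, state.counts, out, rng)
    return StageState(counts=out, stage="tagmented", unique_molecules=uniq)


def _thin_pooled(state: StageState, fraction: float, rng: np.random.Generator,
                 stage: str) -> StageState:
    """Thin the whole pooled matrix at once (droplet tagmentation)."""
    counts = state.counts
    total = int(counts.sum())
    if total == 0:
        raise ValueError(f"no molecules entering pooled stage {stage!r}")
    target = int(np.rint(fraction * total))
    flat = counts.ravel().astype(float)
    out = rng.multinomial(target, flat / total).reshape(counts.shape).astype(np.int64)
    uniq = state.unique_molecules
    if uniq is not None:
        uniq = _thin_unique(uniq, counts, out, rng)
    return StageState(counts=out, stage=stage, unique_molecules=uniq)


def sequence_reads(state: StageState, total_reads: int,
                   rng_seed: Optional[int] = None, *,
                   rng: Optional[np.random.Generator] = None) -> StageState:
    """Allocate the read budget R over all gene-cell entries of the pool.

    Y ~ Multinomial(R, pi) with pi proportional to the amplified library B;
    the grand total of Y is exactly R.
    """
    if rng is None:
        rng = stage_rngs(rng_seed)["sequence"]
    b = state.counts
    grand = b.sum()
    if grand == 0:
        raise ValueError("cannot sequence an empty library")
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    pi = b.ravel().astype(float) / grand
    y = rng.multinomial(int(total_reads), pi).reshape(b.shape).astype(np.int64)
    return StageState(counts=y, stage="sequenced", unique_molecules=state.unique_molecules)


def collapse_umi(state: StageState, unique_molecules: Optional[np.ndarray] = None,
                 rng_seed: Optional[int] = None, *,
                 rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Collapse reads to distinct-molecule (UMI) counts.

    For an entry with u surviving distinct molecules receiving r reads, the
    UMI count is the number of distinct molecules hit when the r reads are
    allocated uniformly at random among the u molecules (classic occupancy
    draw); it never exceeds min(u, r).
    """
    if rng is None:
        rng = stage_rngs(rng_seed)["collapse"]
    if unique_molecules is None:
        unique_molecules = state.unique_molecules
    if unique_molecules is None:
        raise ValueError("collapse_umi requires tracked unique molecules")
    reads = state.counts
    u = np.asarray(unique_molecules, dtype=np.int64)
    out = np.zeros_like(reads, dtype=np.int64)
    rows, cols = np.nonzero(reads)
    for g, j in zip(rows, cols):
        r = int(reads[g, j])
        n_mol = int(u[g, j])
        if n_mol <= 0:
            continue  # reads from an entry with no tracked molecules: drop
        if n_mol == 1:
            out[g, j] = 1
        else:
            hits = rng.multinomial(r, np.full(n_mol, 1.0 / n_mol))
            out[g, j] = int(np.count_nonzero(hits))
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def simulate_experiment(params: ProtocolParameters, rng_seed: int,
                        keep_stages: bool = False,
                        latent_means: Optional[np.ndarray] = None,
                        gene_ids: Optional[Sequence] = None,
                        cell_ids: Optional[Sequence] = None) -> SimulationResult:
    """Run the full protocol simulation for one experiment.

    Reproducible: the master seed is split into per-stage streams in a fixed
    order, so two runs differing only in `equalization.enabled` share all
    other stages' randomness (the basis of paired unEQ/EQ comparisons).
    """
    protocol = params.sequencing.protocol
    rngs = stage_rngs(rng_seed)
    track_unique = protocol in (UMI_PLATE, DROPLET)

    draws = _draw_cell_parameters(params, rngs["draws"])
    initial = generate_initial_mrna(params.profile, draws.omega,
                                    rng=rngs["initial"], latent_means=latent_means)
    captured = capture_molecules(initial, draws.lam, rng=rngs["capture"],
                                 track_unique=track_unique)
    stages = [initial, captured]

    if protocol == DROPLET:
        # pooled immediately after capture; global (scalar) efficiencies
        gamma = float(params.tagmentation.draw(1, rngs["draws"])[0])
        rho2 = float(params.pcr.eff2.draw(1, rngs["draws"])[0])
        draws = replace(draws, gamma=np.full(params.n_cells, gamma),
                        rho2=np.full(params.n_cells, rho2))
        tagged = _thin_pooled(captured, gamma, rngs["tagment"], "tagmented")
        amplified2 = amplify(tagged, rho2, params.pcr.cycles2, stage="amplified2")
        sequenced = sequence_reads(amplified2, params.sequencing.total_reads,
                                   rng=rngs["sequence"])
        stages += [tagged, amplified2, sequenced]
        counts = collapse_umi(sequenced, rng=rngs["collapse"])
    else:
        pre = amplify(captured, draws.rho1, params.pcr.cycles1, stage="preamplified")
        stages.append(pre)
        current = pre
        if params.equalization.enabled:
            l = cdna_concentrations(pre)
            s, _ = compute_dilution_factors(l, params.equalization, rng=rngs["equalize"])
            draws.dilution = s
            current = equalize(pre, s, rng=rngs["equalize"])
            stages.append(current)
        if params.post_equalization_scaling is not None:
            scaled = _thin_columns(current.counts, params.post_equalization_scaling,
                                   rngs["equalize"], "pooled_scaled")
            uniq = current.unique_molecules
            if uniq is not None:
                uniq = _thin_unique(uniq, current.counts, scaled, rngs["equalize"])
            current = StageState(counts=scaled, stage="pooled_scaled", unique_molecules=uniq)
            stages.append(current)
        tagged = tagment(current, draws.gamma, rng=rngs["tagment"])
        amplified2 = amplify(tagged, draws.rho2, params.pcr.cycles2, stage="amplified2")
        sequenced = sequence_reads(amplified2, params.sequencing.total_reads,
                                   rng=rngs["sequence"])
        stages += [tagged, amplified2, sequenced]
        if protocol == UMI_PLATE:
            counts = collapse_umi(sequenced, rng=rngs["collapse"])
        else:
            counts = sequenced.counts

    g, n = counts.shape
    gene_ids = list(gene_ids) if gene_ids is not None else list(params.profile.gene_ids)
    cell_ids = list(cell_ids) if cell_ids is not None else [f"cell_{j}" for j in range(n)]
    return SimulationResult(counts=counts, draws=draws, seed=int(rng_seed),
                            params=params, stages=stages if keep_stages else None,
                            gene_ids=gene_ids, cell_ids=cell_ids)
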