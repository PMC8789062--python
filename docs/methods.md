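# Methods

## Model

`protocount` simulates an scRNA-seq experiment as a chain of conditional
draws on a genes × cells molecule-count matrix. The stages and their
defaults are described in the README; this note records the assumptions,
numerical choices and limitations behind them.

**Assumptions.** Molecules are exchangeable within a gene-cell entry; no
fragment-length, GC or positional effects; no spike-ins; no read errors or
mapping ambiguity. PCR is deterministic per cell (every molecule in cell *j*
is multiplied by (1+ρ<sub>j</sub>)<sup>C</sup>, rounded to the nearest
integer), so amplification noise enters only through the cell-level
efficiency draw. Thinning stages (capture, equalization, tagmentation) fix
the retained total at round(f<sub>j</sub>·total) — banker's rounding — and
allocate it by a single multinomial, i.e. sampling *with replacement* from
current abundances. A consequence worth knowing: the per-gene zero
probability at the captured stage is exp(−μ(1−e<sup>−λ</sup>)) rather than
the independent-thinning form exp(−λμ); the two agree in the small-λ limit
(relative gap e<sup>λ²μ/2</sup>).

**Randomness.** One master seed is split (`numpy.random.SeedSequence.spawn`)
into seven named streams — parameter draws, latent mRNA, capture,
equalization, tagmentation, sequencing, UMI collapse — in a fixed order, and
the split happens whether or not a stage is active. Toggling equalization
therefore changes nothing upstream or downstream of the equalization draw
itself; matched unEQ/EQ pairs share latent mRNA, capture noise and
tagmentation noise exactly. All unit and acceptance tests are derandomized
through this mechanism.

**Equalization boundary behavior.** τ<sub>j</sub> follows the piecewise rule
literally: a cell exactly at q\* takes the "otherwise" branch (τ = 1) while a
cell just below takes 0.95. The discontinuity is intentional (it reproduces
the stated rule); with `dilute_to_min` the minimum-concentration cell is the
only cell at q\*. q\* is computed over positive concentrations only, so an
empty cell cannot drag the target to zero; empty cells fall in the
below-range branch. No concentration-measurement noise is modeled beyond the
Normal(τ, 0.01) dilution draw.

**UMI tracking.** Distinct captured molecules are recorded at the capture
stage (where unique = copies) and thinned through equalization/tagmentation
by an occupancy approximation: each of u distinct molecules is assumed to
hold an equal share c = T/u of the entry's T copies, and survives a thinning
to K copies with probability 1 − (1 − K/T)<sup>c</sup>; survivor counts are
Binomial(u, p), floored at one distinct molecule wherever copies remain.
This avoids per-molecule bookkeeping (memory O(G·N) instead of O(total
molecules)) and is accurate when c is large, which PCR guarantees
((1.95)<sup>18</sup> ≈ 1.7·10⁵ copies per molecule). At the read level the
collapse is exact: r reads on an entry with u surviving molecules hit a
number of distinct molecules drawn from the classic occupancy distribution
(multinomial of r balls in u equiprobable bins), so E[UMI] =
u(1 − (1 − 1/u)<sup>r</sup>).

**Droplet variant.** Pooling happens at capture; tagmentation and the second
PCR use one global efficiency each (drawn once), and the tagmentation
thinning is a single multinomial over the whole pooled matrix. Equalization
is rejected for droplet runs, since cDNA is pooled before any
per-cell dilution could happen.

## Parameter estimation

Estimation inverts the model stage that dominates each observable:

* **Gene means** — cells rescaled to a common transcript budget (default
  300 000, the order of total transcripts in a human cell), averaged per
  gene. Zero-depth cells are excluded with a warning.
* **Heterogeneity** — 5th/95th percentiles of total-count ratios over 100
  random cell pairs, ratio taken in drawn order so the distribution is
  symmetric about 1. Note these are percentiles of a *ratio* distribution
  and sit outside the latent Uniform bounds; at the moderate heterogeneity
  of a QC-filtered homogeneous population (bounds 0.8–1.2) the overshoot is
  ≈5–12%, and grows with any extra multiplicative depth noise. This is a
  property of the estimator, preserved deliberately.
* **Capture mean** — bounded scalar search (tolerance 1e-4) for the
  μ<sub>λ</sub> whose implied Binomial detection probability, averaged over
  a seeded 100-gene probe sample, matches the observed mean cell detection
  rate. p<sub>g</sub> = μ<sub>g</sub>/m is used exactly as defined (it is a
  per-gene success probability, not a distribution over genes) and clipped
  into [0, 1] for the rare genes with μ<sub>g</sub> &gt; m. The 100-gene
  probe is the dominant error source: single-replicate estimates scatter by
  up to ±0.07 at heavy gene-mean skew; averages over 10 replicates recover a
  true mean of 0.1 to well within ±0.03.
* **Capture SD** — the raw (unscaled) MAD of per-cell detection rates;
  `scaled=True` applies the 1.4826 Normal-consistency factor. The MAD is
  computed on the matrix as given — apply QC first if desired.
* PCR cycles (18/12), PCR/tagmentation efficiencies (Normal(0.95, 0.02))
  and the read budget (grand total of the reference) are protocol defaults,
  not estimated: these stages were not found to be influential and are
  conventionally near-efficient.

## Synthetic reference generator

`fixtures.generate_fixture` emulates a plate-based reference matrix with
known ground truth. Defaults, chosen once as study conditions:

| knob | default | rationale |
|---|---|---|
| genes × cells | 2000 × 100 | desk scale; ~10% of a transcriptome |
| gene-mean shape | log-normal, σ = 3.0, normalized to 300k | heavy skew: top 2.5% of genes carry ~70% of reads, as in real data; implies capture ≈ 0.1–0.2 at detection 0.4 |
| heterogeneity | Uniform(0.8, 1.2) | homogeneous, QC-filtered population |
| capture | mean solved for detection 0.4 (or given), CV 5% | detection 0.4 is typical of full-length plates; tight within-plate dispersion |
| read budget | 150 000 reads/cell | a multiplexed full-length run at desk scale; ≈3 reads per captured molecule |

The generator includes the read-sampling stage (multinomial allocation of
the read budget over captured molecules). Without it the reference's grand
total would equal its molecule count, and any simulation re-sequencing at
that budget would sit at one read per molecule and lose detection for a
purely bookkeeping reason.

What the fixture does *not* emulate: multimodal populations (unless layered
through `population_structure`), batch effects, doublets, ambient RNA,
gene-length bias, or the amplification nonlinearities of real libraries.
Tests passing on it show internal consistency of the model and estimators,
not fidelity to any particular real dataset.

## Diagnostics

* **Count-depth slopes.** For each retained gene (≥10 nonzero cells and
  nonzero median ≥2; UMI variant: any nonzero mean), the 0.5-quantile (LAD)
  regression of log nonzero expression on log total depth, natural logs
  (the slope is base-invariant). The solver enumerates the pairwise-slope
  breakpoints of the convex piecewise-linear objective and is exact; tests
  cross-check it against `statsmodels` QuantReg and brute-force grids.
  Genes whose nonzero cells share a single depth are flagged NaN.
* **Slope modes and MAD.** Genes are split into 10 equal groups by nonzero
  median (ties by index); each group's slope density is a Gaussian KDE
  (Silverman bandwidth) evaluated on 512 equispaced points over [−3, 3]
  (slopes clipped into the grid), mode = argmax with ties to the lower grid
  point; the MAD statistic is the median of |mode − 1|.
* **Depth matching** greedily removes, from whichever dataset currently has
  the higher mean depth, the cell whose removal most reduces the gap, until
  the means differ by ≤0.5% of the pooled mean depth (or a one-cell floor is
  hit, with a warning). Greedy trimming cannot equalize disjoint depth
  distributions; the achieved gap is always reported.
* **Variance decomposition** fits a lowess trend (span 0.3) of per-gene
  variance on mean of log-scale expression; the residual above the trend is
  the biological component, tested by an F-ratio of total to trend with
  (n−1, n−1) degrees of freedom — a deliberate simplification of
  trend-decomposition testing as implemented in dedicated packages — with
  Benjamini–Hochberg control and an FDR &lt; 0.10 call.
* **QC** removes cells below median − 2 SD of log10 depth or above
  median + 2 SD of percent counts in the top-50 genes (fixed cutoffs can be
  supplied); the MAD variant flags cells beyond 5 scaled MADs, with any
  deviation an outlier when the MAD degenerates to zero.
* **Silhouette and dynamic genes.** Silhouette widths use Euclidean
  distance on externally supplied 2-D coordinates (the bundled experiments
  use a PCA of depth-normalized log counts; embedding algorithms themselves
  are out of scope). Dynamic genes are tested by an F-test of a quadratic
  polynomial in pseudotime against the intercept-only model, BH-adjusted,
  and summarized by the AUC of 1 − adjusted p against ground-truth labels.

## The equalization experiments

`experiments.paired_equalization_experiment` runs matched unEQ/EQ pairs
(2000 genes × 80 cells by default, read budget rescaled from the reference)
and reports per-pair depth-SD and gene-variance percent changes, detection
gain, and MAD. Model behavior at the default conditions, for calibration of
expectations:

* Depth-SD reduction is mechanical and holds in essentially every pair
  (equalization removes the content- and efficiency-driven part of depth
  variation, leaving tagmentation/second-PCR noise).
* Mean gene-specific variance drops strongly (depth variation multiplies
  every gene's counts, so removing it removes variance).
* The detection-rate change is small and delicately balanced: dilution thins
  amplified *copies* — each captured molecule holds ~10⁵ copies and
  survives — so equalization costs almost no detection, and it gains
  detection only by relieving read competition in the pooled library. At
  ~3 reads per captured molecule the net effect is a small positive average
  (a fraction of a gene per cell at desk scale). Detection differences of
  hundreds of genes per cell, as seen in real matched experiments, are not
  reproduced by this mechanism alone at these read densities.
* The MAD contrast is noise-limited at 80 cells: equalization narrows the
  depth range, which inflates the sampling noise of every slope estimate,
  opposing the systematic slope distortion it removes. The average MAD is
  lower with equalization at the default conditions, but individual pairs
  and other generator seeds can flip.

`silhouette_experiment` (two populations of 50 + 40 cells, 10% DE genes,
fold changes Normal(1.5, 0.5)) and `dynamic_experiment` (10% dynamic genes,
quadratic B-splines — degree 2, interior knots at 1/3 and 2/3 of an evenly
spaced pseudotime grid, coefficients Normal(5, 5), clamped at zero) layer
population structure on the same protocol model. Fold changes are truncated
at 0.05 and applied as multiply-or-divide with equal probability; DE gene
sets are drawn independently per non-reference population.

## Known limitations

* No fragment-level modeling: counts are molecule/read tallies; gene length,
  GC and positional biases are absent, so real count-depth distortion has
  sources this model does not represent.
* The capture-SD estimator returns a detection-rate-scale MAD used directly
  as the SD of λ; when the estimated μ<sub>λ</sub> is very small this
  over-disperses capture (a property of the estimation recipe, kept as
  specified).
* The occupancy approximation for UMI thinning is per-entry independent; it
  ignores the (weak) negative correlation between entries induced by the
  fixed thinning total.
* Greedy depth matching is deterministic but not optimal; it reports the
  achieved gap rather than guaranteeing the tolerance.
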