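# protocount

Stage-by-stage stochastic simulation of single-cell RNA-seq protocols, with
parameter estimation from reference count matrices and diagnostics for the
technical artifacts that protocol choices — notably cDNA **equalization** —
leave in the counts.

Most scRNA-seq simulators draw final counts from a fitted distribution.
`protocount` instead simulates every step of the experiment, so you can ask
how a change to one step (capture efficiency, PCR cycles, equalizing cDNA
input across cells, read budget) propagates to detection rates, expression
variability and normalization-relevant structure. It is aimed at method
developers and protocol designers who want matched in-silico experiments
("same cells, one protocol knob changed") that no wet-lab design can give at
this price.

## The generative model

For gene *g* = 1..*G* in cell *j* = 1..*N*:

1. **Latent mRNA** — M<sub>g,j</sub> ~ Poisson(ω<sub>j</sub> μ<sub>g</sub>),
   with per-cell mRNA-content scalings ω<sub>j</sub> ~ Uniform(ω<sub>.05</sub>, ω<sub>.95</sub>).
2. **Capture / reverse transcription** — each cell's molecules are thinned by a
   multinomial to round(λ<sub>j</sub> Σ<sub>g</sub> M<sub>g,j</sub>) molecules,
   λ<sub>j</sub> ~ Normal(μ<sub>λ</sub>, σ<sub>λ</sub>) clamped to (0, 1].
   Capture is the dominant source of zeros.
3. **Preamplification PCR** — A<sub>g,j</sub> = Z<sub>g,j</sub>(1 + ρ<sub>j</sub>)<sup>C</sup>
   (default C = 18, ρ<sub>j</sub> ~ Normal(0.95, 0.02)).
4. **Equalization** (optional) — cell concentrations l<sub>j</sub> = Σ<sub>g</sub> A<sub>g,j</sub>
   are diluted toward a target q\* by S<sub>j</sub> ~ Normal(τ<sub>j</sub>, 0.01),
   where τ<sub>j</sub> = 0.95 if l<sub>j</sub> &lt; q\* and q\*/l<sub>j</sub> otherwise;
   q\* is the smallest observed concentration (`dilute_to_min`) or the midpoint
   of the smallest and a user-chosen quantile (`quantile_range`).
5. **Tagmentation** — a second per-cell multinomial thinning with efficiency
   γ<sub>j</sub> ~ Normal(0.95, 0.02).
6. **Second PCR** — B<sub>g,j</sub> = T<sub>g,j</sub>(1 + ρ<sub>2,j</sub>)<sup>C₂</sup>
   (default C₂ = 12).
7. **Pooled sequencing** — Y ~ Multinomial(R, π) over all gene-cell entries,
   π<sub>g,j</sub> = B<sub>g,j</sub> / ΣΣB. Cells compete for the read budget
   in proportion to their amplified cDNA.

Plate-UMI runs track distinct molecules through every stage and report the
number of distinct molecules hit by at least one read. Droplet runs pool all
cells immediately after capture, skip preamplification and equalization, and
use global (not per-cell) tagmentation/PCR efficiencies.

Parameter estimation from a reference matrix follows the model: gene means
from cells rescaled to 300 000 total transcripts; heterogeneity bounds from
the 5th/95th percentiles of total-count ratios of 100 random cell pairs;
μ<sub>λ</sub> by matching the Binomial detection probability
P(X<sub>g</sub> &gt; 0), X<sub>g</sub> ~ Binomial(μ<sub>λ</sub>·m, μ<sub>g</sub>/m),
to the observed mean cell detection rate (P(X<sub>g</sub> &gt; 1) for UMI
data); σ<sub>λ</sub> as the MAD of per-cell detection rates.

Diagnostics include the **count-depth rate** — the per-gene slope of a median
(LAD) quantile regression of log nonzero expression on log depth, summarized
by the median absolute deviation of per-expression-group slope modes from 1
(the **MAD statistic**) — plus detection-rate comparisons on depth-matched
cell subsets, a mean-variance trend decomposition for highly variable genes,
QC filters, silhouette summaries of externally produced embeddings, and a
quadratic-polynomial test for dynamic genes along a supplied pseudotime.

## Worked example

```bash
# 1. a synthetic reference with known ground truth (2000 genes x 100 cells)
protocount fixtures --out ref.csv --seed 1 --genes 2000 --cells 100
# INFO fixture written: 2000 x 100, capture mean 0.1817, realized detection 0.3926

# 2. estimate simulation parameters from it
protocount estimate --counts ref.csv --out params.yaml --seed 1
# INFO estimated mu_lambda=0.1135 sigma_lambda=0.0120 w=(0.729, 1.298) R=15000000

# 3. simulate an equalized experiment from those parameters
protocount simulate --params params.yaml --out sim_eq.csv --seed 1 --equalize

# 4. diagnose the simulated counts
protocount diagnose --counts sim_eq.csv --out reports
# INFO MAD = 0.2818; mean cell detection = 0.3420; 94/100 cells pass QC
```

The estimate step recovers a capture-efficiency mean of 0.1135 against the
generator's true 0.1817-mean thinning seen through sequencing (detection
0.39); the heterogeneity bounds (0.729, 1.298) bracket the generator's
Uniform(0.8, 1.2) scalings as ratio percentiles. The diagnose step reports
the count-depth MAD (0.28 here: moderate distortion), the mean cell
detection rate, and which cells pass the depth / top-50-gene QC rules.
`reports/` contains per-gene slopes and groups, per-group slope modes,
detection tables and the QC table as TSV.

The same workflow is available as a library; `protocount.experiments`
provides the matched unEQ/EQ experiment wrappers used below.

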