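# Methods

`nanobmd` reimplements, as a tested pipeline, a quantitative in vivo / in
vitro comparison of acute pulmonary inflammation induced by poorly soluble
metal-oxide nanomaterials (three TiO2 materials — NM105, NM101, NM100 — and
one CeO2, NM212). Rats exposed by intratracheal instillation are compared
with A549/THP-1 co-cultures exposed at the air-liquid interface (ALI) or in
submerged culture, through four stages: dose-metric harmonisation,
benchmark-dose (BMD) estimation per cytokine, median pooling into a general
pro-inflammatory interval, and LOAEL / ranking comparisons. A synthetic-data
generator stands in for the animal and cell raw data, which were never
deposited.

## Dose metrics and surface-area normalisation

Deposited doses are harmonised across methods by normalising either to the
exposed surface (alveolar surface in vivo, cell-layer surface in vitro) or
to the number of alveolar(-like) macrophages. Defaults, all overridable as
data in `ExposureContext`:

| constant | default | unit |
|---|---|---|
| alveolar surface (rat) | 4000 | cm² |
| alveolar macrophages (rat) | 25×10⁶ | count |
| insert surface / macrophage density | 4.67 / 60,000 | cm², per cm² |
| plate surface / macrophage density | 2 / 25,000 | cm², per cm² |

These constants carry real uncertainty (published alveolar surfaces range
from ~2000 to 4000 cm²; lavage recovers only ~8×10⁶ macrophages), which is
why they are configuration, not code.

Mass doses are additionally expressed as particle surface area per million
macrophages using either the dry-powder BET specific surface area (SSA) of
the primary particles or the SSA of the agglomerates actually reaching the
cells, treated as ideal spheres: `SSA [m²/g] = 6000/(ρ·d)` with `d` in nm
and the effective density ρ in g/cm³ (effective densities include trapped
medium, so ρ ≤ primary density). No shape-factor correction is applied;
sphericity is an explicit modelling assumption, and a consistency checker
(`ssa_consistency_report`) compares derived SSAs against any printed
characterisation values instead of silently adopting them — in the packaged
reference table three of eight cells disagree with the spherical formula
applied to the printed sizes and densities (most likely because the printed
SSAs were computed from unrounded inputs) and are flagged as such.

## Benchmark-dose estimation

Each cytokine's replicate responses are modelled with the nested
exponential family standard in continuous benchmark-dose software:

    m1: a        m2: a·e^{bx}       m3: a·e^{bx^d}
    m4: a(c−(c−1)e^{−bx})           m5: a(c−(c−1)e^{−bx^d})

with a, b > 0, asymptote fold-change c > 1 and shape d ∈ [1, 4]; responses
are strictly positive with lognormal error, log y ~ N(log m(x), σ²). Only
increasing responses are in scope. The critical effect dose (CED) is where
the mean reaches 1.2× background (critical effect size CES = 20%, the value
commonly used for these cytokine endpoints); it has a closed-form inverse
for every model.

Fitting concentrates `log a` and σ out analytically, leaving 1–3 nonlinear
parameters optimised by bounded L-BFGS-B from a deterministic data-driven
start grid plus seeded jitter (default seed 20180604). Doses are scaled by
the top tested dose and log-responses centred before fitting, making the
estimates exactly equivariant under dose rescaling (bit-exact for binary
rescalings) and invariant under response rescaling.

Model selection walks the nested likelihood-ratio ladder
m1 → m2 → {m3, m4} → m5 at α = 0.05, preferring the simpler model when the
extra parameter is not significant (log-likelihood breaks the m3/m4 tie);
an AIC rule is available (`selection="aic"`). If the constant model is
retained, or a saturating model's asymptote lies below 1.2×a, the endpoint
is reported as `no_response` (ND).

The 90% two-sided interval (BMDL, BMDU) is a profile likelihood: the CED
becomes an explicit parameter through the potency b, nuisance parameters
(d and/or the asymptote) are re-optimised at every candidate CED on a
coarse grid with local refinement (the nuisance profiles are multimodal in
a noticeable fraction of candidates, so a single local search is not
enough), and the bounds are bracketed on a 60-point log grid spanning
[lowest positive dose/100, highest dose×100] and refined by log-space
bisection to ~3 significant figures. If the profile never drops below
threshold before 100× the top dose the upper bound is reported as
`unbounded_upper`, not a number.

The threshold uses the finite-sample calibration that is exact for linear
Gaussian models with unknown variance, `(n/2)·log(1 + F(0.90; 1, n−p)/(n−p))`
with p mean-function parameters; it converges to the asymptotic
χ²₁(0.90)/2 = 1.3528 from above. At the replicate counts of these designs
(n = 24–36 observations) the asymptotic threshold measurably under-covers
(87.4% ± 0.7% instead of 90% in a 2000-replicate model-3 simulation at
σ = 0.3); the F calibration restores 91.0% ± 0.6% under the same
conditions.

A known limitation: intervals are conditional on the selected model and do
not propagate model uncertainty. On sparse log-spaced grids the shape
parameter d is nearly unidentifiable, so when the true curve is curved
(d > 1) but the ladder retains m2, the interval can sit tightly around a
biased CED. Model averaging would address this and is out of scope here.

## Pooling, LOAELs, comparisons

The general pro-inflammatory interval per material × method is the median
of the defined per-cytokine BMDLs and the median of the defined BMDUs
(IL-1β, IL-6, IL-8/KC-GRO, TNF-α). ND endpoints are excluded from the
median by default; `nd_policy="infinite"` instead enters them as +∞, which
matters only for the upper bound. Even counts take the midpoint of the two
central values. Display rounding is 2 significant figures; computation is
full precision. `check_published_medians` re-derives printed pooled medians
from printed per-cytokine intervals and flags cells that do not follow the
stated rule (three cells in the packaged reference table do not, and are
reported rather than reproduced).

LOAELs use the Kruskal–Wallis omnibus test (tie-corrected, χ² reference)
gating Dunn's post-hoc z-tests of each treated group against control on
pooled mid-ranks, Bonferroni-adjusted over the treated-vs-control family by
default (Holm and unadjusted are options; the multiplicity treatment of the
original analysis is not documented, so it is configurable). The LOAEL is
the smallest tested dose significant on any included endpoint at α = 0.05;
per-endpoint LOAELs are reported alongside. Under a global null the
probability of a spurious LOAEL is bounded by α × number of endpoints.

Cross-method comparison reports the fold-difference of each method's
effect dose to the in vivo reference in a shared metric. Ranking within a
method orders materials by pooled BMDL (ascending — the conservative
bound), places materials with transitively overlapping closed intervals in
one tie group, and lists ND materials last; the published analysis ranks
qualitatively from interval plots, so this explicit rule is one defensible
reading, stated as such. Interval tables are also re-expressed in four
views (mass/surface, mass/macrophages, surface-area/macrophages under the
BET and the agglomerate SSA), the agglomerate view using the medium that
reaches the cells: aerosol at the ALI, suspension otherwise.

## Synthetic data generator

The generator emulates the study layout: 4 materials × 4 exposure methods
× 4 cytokines; dose grids 0/4/40/400 µg per lungs (n = 6 animals) in vivo,
0/0.1/1/3 µg/cm² at the ALI, 0/1/3/10 µg/cm² in submerged inserts and
0/1/3/10/20 µg/cm² in plates (n = 3 wells, a typical triplicate). Replicates
are drawn as `mean × exp(ε)`, ε ~ N(0, σ²) — multiplicative lognormal noise
matching the fitting likelihood by construction, a deliberate best case; a
gamma mode with the same mean and CV probes error misspecification.
Randomness uses NumPy PCG64 with per-table streams spawned from the study
seed, so studies are bit-reproducible across platforms.

True responder curves use the simplest responding family member (m2), with
potency set so the mean reaches a stated fold-change at the top tested dose
(2–3× for responders, mirroring the multi-fold cytokine increases the
study reported at its highest doses); this places the true CED below the
top dose, where the published intervals also lie. The NM100 in vivo cell is
a true null (constant model). σ = 0.25 is a synthetic choice giving
interval widths of the order of the published tables, not a published
value. Because noise and mean are both well-specified, passing recovery
tests demonstrate the estimation machinery, not robustness to the
misspecification, serum effects, deposition uncertainty or inter-animal
heterogeneity of real BALF/supernatant data.

## Problem sizes and numerical conventions

Simulation-based checks use: 500 replicate datasets for profile-interval
coverage (the acceptance script reports a 200-replicate version), 2000
null simulations for the Kruskal–Wallis type-I rate, 200 replicate studies
for end-to-end pooled-interval bracketing, and 25 replicate studies for
null-material behaviour — sizes chosen to keep Monte-Carlo error a few
percent while the full suite runs in minutes on one core. Degenerate
inputs: exactly constant data give H = 0/p = 1 in the rank tests and
collapse every exponential model onto the constant fit (a residual floor
of 1e-24 on the RSS guards the log-likelihood); noise-free tables collapse
BMDL and BMDU onto the CED. Ties in the rank tests use mid-ranks with the
standard correction.
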