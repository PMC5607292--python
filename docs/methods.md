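# Methods

`cryptdrift` implements a crypt-level stem-cell dynamics assay built on
bisulfite amplicon sequencing of a CpG island in a transcriptionally
silent gene, together with the longitudinal statistical analysis used to
compare treatment arms, and a generative simulator that stands in for
patient material.

## The assay

Methylation at unregulated CpG islands drifts neutrally with cell
division.  Because a colonic crypt's epithelium is renewed from a small
stem-cell niche, the set of distinct per-molecule methylation patterns
(epialleles) observed in one crypt records the recent clonal history of
its stem cells:

* **Tag diversity** — the number of distinct patterns among a crypt's
  reads after error filtering.  Fewer patterns indicate a more recent
  niche succession (one lineage having swept the niche).
* **Percent methylation** — methylated CpG site-calls over total CpG
  site-calls, a proxy for mitotic age.

The amplicon carries 8 CpG sites (1-based offsets 2, 4, 6, 18, 22, 37,
40, 51 within the inner amplicon) and non-CpG control cytosines (offsets
14 and 20, plus a third synthetic control at 44 in the default assay).
The default reference sequence itself is a synthetic 62-bp construct that
satisfies these coordinates; analyses of real data should supply the true
amplicon FASTA and site list via the assay config.  Coordinates in
configs may be 0- or 1-based (`coordinate_base`); internally everything
is 0-based within the inner amplicon.

## Read processing

1. **Demultiplexing** by 5' barcode, exact match by default
   (`max_mismatch_barcode` configurable; equal-distance ties are never
   assigned).
2. **Alignment** against the in-silico converted reference (all non-CpG
   C→T, CpG cytosines kept — the fully methylated assumption) with a
   global Needleman–Wunsch aligner whose substitution rule treats read C
   and T as matches at CpG reference positions.  Default scoring: match
   +1, mismatch −1, linear gap −2; reads scoring below 0.6 × maximum are
   discarded.  Reads are orientation-normalized by the better of the
   forward and reverse-complement score (ties keep forward).  A
   vectorized batch scorer computes exact optimal scores for whole read
   matrices; reads whose optimal score equals their ungapped score are
   genotyped positionally (an optimal alignment by construction, and the
   deterministic tie-break), the rest fall back to full traceback
   (tie-break diagonal > deletion > insertion).
3. **Coverage filter**: `strict` (default) requires every reference
   position to be read-covered; `sites-only` requires only CpG + control
   positions.
4. **Conversion control filter**: every control cytosine must read T.  A
   C marks incomplete bisulfite conversion; any other base is an
   artefact.  Both invalidate the read.
5. **Genotyping**: per CpG, C→M, T→U; any other base or a gap makes the
   read ambiguous and it is discarded.

Every input read ends in exactly one ledger bucket (passed or one of five
discard reasons); conservation is asserted.  Base qualities are read but
not used in calling.

## Crypt summaries

Patterns are tabulated per crypt and filtered at a frequency cutoff
(default 1% of the crypt's passed reads, boundary inclusive, denominator
= total pre-cutoff depth).  The cutoff removes rare artefact patterns
from PCR/sequencing error and residual conversion failure.  Diversity is
the retained distinct-pattern count.  Percent methylation defaults to
read-weighted over post-cutoff patterns (the natural analogue of
clone-based scoring); a pattern-weighted variant is always reported
alongside since the field's wording is ambiguous between the two.  Crypts
with zero passed reads or zero retained patterns are excluded from
regression input with a logged reason (a sampled crypt always carries at
least one true lineage; zero marks assay failure).  A Sanger-style
`clone_subsample` mode draws n=10 reads without replacement and scores
them with no cutoff.  A sensitivity filter restricts to crypts with
depth ≥ 1000×.

Timepoints are encoded both categorically (t0, t4m, t2y) and continuously
in years (4 months = 1/3), so "per year" rates are directly comparable
with per-timepoint means.

## Statistical models

Crypt-level observations are the analysis unit, with within-patient
clustering absorbed by a Gaussian random intercept per patient.

**Diversity** (right-skewed counts): mixed-effects NB2 negative binomial
regression, log link, variance μ + μ²/θ, fixed effects treatment + time +
treatment×time.  The marginal likelihood integrates the random intercept
by adaptive Gauss–Hermite quadrature (default 25 nodes; per-patient modes
by Newton iteration, curvature-scaled nodes).  All parameters (β, log θ,
log σ_b) are maximized jointly by L-BFGS-B with finite-difference
gradients from Poisson-GLM starting values; a Nelder–Mead polish handles
line-search stalls at boundaries (θ→∞ for underdispersed counts, σ_b→0
for unclustered data), and fits are accepted only when the projected
gradient is small.  The likelihood implementation is validated against
dense-grid numerical integration (1e-6 relative) and the σ_b = 0 boundary
against an ordinary NB GLM.

**Percent methylation** (approximately Gaussian): random-intercept linear
regression by maximum likelihood, with the variance ratio
λ = σ_b²/σ_e² profiled out and optimized on a 1-D log grid with local
refinement.  λ = 0 reproduces OLS exactly; results match statsmodels
MixedLM (ML) on test fixtures.

Reported per-group per-timepoint means are conditional on a random
intercept of zero (NB means are exp of the cell linear predictor);
continuous-time fits report exp(slope) as a multiplicative rate per year
(NB) or the additive change per year (linear).  Inference is Wald (z) on
the link scale without small-sample corrections; interaction is tested by
Wald on the interaction term(s) with a likelihood-ratio test against the
additive model reported alongside.  No multiplicity adjustment is
applied; α = 0.05.  The multiplicative projection helper compounds a
baseline mean by rate^years and reports at two decimals (4.46 × 0.96 =
4.28 after one year, then 4.11).

Per-patient trends use unmixed fits per patient — NB regression of
diversity on years (Poisson GLM fallback when the NB MLE fails on flat or
underdispersed trajectories; identical mean structure), OLS slopes for
percent methylation and polyp counts — and Pearson correlations across
patients relate the three, with groups pooled and retained as a label.
Age adjustment refits the mixed models with centered baseline age as an
extra fixed covariate; constant ages are dropped as inestimable and
missing ages refuse adjustment rather than silently proceeding.

## The simulator

**Niche model.**  A crypt niche holds `n_stem` equipotent stem cells
(default 8).  Replacement events arrive as a Poisson process at
`replacement_rate` × `n_stem` per year (default 0.35 per cell per year);
at each event a uniformly chosen cell is replaced by a copy of a
uniformly chosen surviving cell (Moran death–birth).  Methylation drift
is clocked by calendar time along each lineage: between events every cell
gains methylation at unmethylated sites at `mu_gain` per site-year
(default 0.02) and loses it at `mu_loss` (default 0.005).  This decouples
error input from the replacement rate — crypt cells divide continuously
whatever the stem-replacement rate — so faster replacement purely
homogenizes the niche.  (The alternative of attaching errors to
replacement events makes diversity *increase* with the replacement rate,
because mutation injection outpaces homogenization; that inverts the
niche-succession logic the assay rests on and was rejected after
implementation.)  The founder pattern is drawn site-wise at
`ancestor_methylation` (default 0.15, the founder's pre-crypt mitotic
age), and each crypt is burned in for `t_burnin` years (default 3) before
study time begins.  Treatment is modelled as a multiplier on the
replacement rate (sulindac default ×4) applied after baseline.

Defaults were calibrated once, against the simulator's truth tables only,
to the magnitudes a baseline crypt should show (~2–5 retained patterns,
~15–25% methylation, placebo diversity rising over the study window,
sulindac flat-to-declining).  They are calibration targets, not inferred
biology.

**Assay overlay.**  Per-crypt depth is lognormal (default meanlog 8.2,
sdlog 1.6, clipped to [1, 50 000], spanning the 4–49 360 read range such
assays produce).  Reads sample niche cells uniformly; each renders its
cell's epigenotype onto the converted reference.  Error sources: (i)
incomplete bisulfite conversion, modelled per molecule — with probability
`p_conversion_failure` (default 0.01) a read is under-converted and each
of its unmethylated cytosines (controls and U CpGs) independently
survives as C with probability 0.5.  The per-molecule structure is what
makes control-site filtering effective, exactly as in the wet assay;
(ii) inappropriate conversion of methylated C to T at
`p_inappropriate_conversion` (default 0.005) per site; (iii) uniform
substitution sequencing error at `p_seq_error` (default 0.001) per base.
Every read's source cell is recorded, so read-level ground truth
(pattern counts, post-cutoff diversity, percent methylation) is exact.

Reproducibility: a single seed expands to per-crypt substreams via
`SeedSequence(seed, spawn_key=(crypt_index,))` with crypts enumerated
group → patient → timepoint → crypt, so any crypt regenerates in
isolation.  Polyp trajectories are Poisson counts around per-patient
linear trends (slopes lognormally heterogeneous; zero at baseline).

**What the simulator does not emulate.**  FFPE deamination artefacts,
Ion Torrent homopolymer indels, PCR duplicate structure and chimeras,
spatial crypt geometry, selection/APC-driven fitness effects, and
reverse-orientation reads (single-adapter amplicon reads start at the
barcode).  Passing tests therefore demonstrate correctness of the
computational pipeline and calibration of the statistical machinery under
a neutral-drift generative model — not that the biology of real crypts
matches that model.

## Numerical and design choices

* Cutoff boundary inclusive (a pattern at exactly the cutoff is kept);
  denominator is total passed reads.
* Duplicate control positions in configs are deduplicated with a warning
  (assay sheets occasionally list one twice); duplicate CpGs are errors.
* Aligner tie-breaks are deterministic (ungapped preferred, then
  diagonal > deletion > insertion), making the whole pipeline
  byte-reproducible for fixed inputs and config.
* NB optimizer bounds: log θ ∈ [−4, 10], log σ_b ∈ [−8, 3]; boundary
  solutions are reported with a warning rather than failing, since
  θ → upper bound simply means Poisson-like counts.
* Wald CIs everywhere; the LRT is additionally reported for interactions.
* Degenerate inputs: empty crypts and zero-retained crypts are excluded
  and logged; all-zero count trajectories make the per-patient rate
  undefined (excluded with a warning); < 2 patients per arm refuses the
  mixed fits and falls back to per-patient trends.

## Problem sizes in tests and the acceptance script

End-to-end checks simulate the full 240-crypt design at a few hundred
reads per crypt (the cutoff arithmetic is depth-invariant), and probe
deep-coverage error suppression separately at ≥ 5000×.  Parameter
recovery and calibration studies use 200 replicate cohorts drawn from the
NB-mixed generative model at the trial's scale; the treatment-contrast
check uses 50 end-to-end niche-simulation replicates.  These sizes are
the package's chosen validation scale and are stated in the relevant
tests.

## Known limitations

* The mixed NB model reports conditional (random-intercept-zero) means;
  marginal means over the random-effect distribution would be
  exp(σ_b²/2)-fold larger.  With the small variances typical here the
  difference is minor but documented.
* Wald inference with 8 patients is approximate; the type-I error of the
  interaction test is verified by simulation to sit near nominal at the
  trial's scale, but small-sample corrections are deliberately out of
  scope.
* The aligner is linear-gap and single-amplicon; it is not a read mapper.
* Clone-subsampling concordance with full-depth sequencing is
  demonstrated on simulated crypts only.
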