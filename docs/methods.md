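# Methods

## Screen normalization and scoring

Each physical plate is normalized independently: the surviving fraction of
a well is its raw absorbance divided by the **median of the non-targeting
negative-control wells on the same plate**. The negative-control median is
the standard reference for viability screens (the library wells themselves
are not a safe reference when many siRNAs are toxic), and per-plate
normalization cancels multiplicative plate effects exactly — doubling every
reading on a plate leaves all downstream scores unchanged.

Z-scores are median-centered and MAD-scaled within each stratum:
z = (SF − median)/ (1.4826·MAD), with center and scale estimated from
**sample wells only** (controls are scored against them but never shape
them). The 1.4826 factor makes the MAD a consistent estimator of sigma
under normality. Stratification defaults to per-plate, again to contain
plate-level artifacts; `per_cell_line` is available for single-plate toy
data. The SD is available as an alternative scale; a stratum whose MAD
degenerates to zero falls back to the SD with a logged warning, and if both
vanish (a constant stratum) every z is 0. Whether the two cell lines'
screens are scored jointly or separately is genuinely open; each line is
scored separately here (its plates are distinct strata), which makes the
two lines' z-scales independent of each other's hit load.

## Hit calling

A gene is a synthetic-lethality hit when both conditions hold:

1. **Concordance** — at least `min_concordant` (default 2) of its siRNAs
   score strictly below `threshold` (default −2) in the c-Myc-overexpressing
   line. Independent duplexes rarely share off-target repertoires, so
   requiring two rejects single-rogue-siRNA false positives.
2. **Selectivity** — mean z(overexpressing) − mean z(control) ≤
   `selectivity_margin` (default −1). A uniformly toxic gene (or duplex)
   kills both lines and is rejected; only c-Myc-dependent lethality passes.
   The margin is recorded in every output row so the criterion is auditable.

Inequalities are strict at the threshold boundary. Genes with siRNAs
missing in either line are paired on the intersection, reported in a
missing-data table, and a gene with no complete pair can never be a hit —
concordance cannot be evaluated for it. Hits are ordered by ascending mean
overexpressing-line z. Making the threshold more negative or the
concordance requirement larger can only shrink the hit set (a tested
monotonicity invariant). No B-score or edge-effect correction is applied;
plate normalization plus robust scoring is the intended defense here, and
positional effects are out of scope.

## Screen simulator

The generator emulates the screen's design: 719 genes × 3 siRNAs, each
siRNA plated in triplicate (replicate plates share one layout), 80 sample +
8 negative / 4 positive / 4 death-control wells per 96-well plate, the same
layout screened once per cell line. Readings are
`plate_effect × true_SF × (1 + N(0, 0.05))`, floored at zero, with
lognormal plate effects (sd 0.05 on the log scale). Five planted
synthetic-lethal genes carry true SF 0.4 in the overexpressing line and 1.0
in the control line — a strong-effect regime mirroring the clear separation
validated hits show. 2% of library siRNAs are off-target-toxic with
severity drawn U(0.3, 1.0); off-target toxicity is modeled as
**siRNA-intrinsic** (the same duplex depresses viability in both lines),
since it is sequence-mediated and therefore line-independent. This puts
both filters to work: concordance rejects the single rogue duplex within a
gene, and selectivity rejects the rare gene in which two duplexes happen to
be rogues. Triplicate plating matters quantitatively: siRNA-level z-scores
are means of three well-level scores, which drives the probability of a
noise-only gene showing two concordant z < −2 scores from ~10⁻³ per gene
(single wells) to ~10⁻⁷ — without replicates a 719-gene screen would
produce roughly one coincidental hit per run.

What the simulator does **not** model: transfection-efficiency gradients,
edge/evaporation effects, MTS chemistry nonlinearity, siRNA efficacy
heterogeneity within a gene, and correlated (batch) noise. Passing
recovery tests therefore demonstrates the statistical chain is correct and
well-calibrated for its assumptions, not that real screens of this design
reach precision/recall ≥ 0.9 — real effect sizes and noise are unpublished,
and the defaults are clearly labelled stand-ins.

## Dose-response

Residual activity is a pure affine transform of counts; it is deliberately
not clipped to [0, 100] (noisy counts legitimately exceed the controls), a
`clip` flag exists for display. The 4PL uses the variable-slope
parameterization in log10 concentration with the convention that hill > 0
describes a decreasing (inhibition) curve; the fitted quantity is log IC50,
so the IC50 is positive by construction. Default constraints
bottom ∈ [−10, 50], top ∈ [50, 120], hill ∈ (0, 5] keep the fit in the
inhibition regime while tolerating noisy plateaus; all are overridable.
Optimization is bounded trust-region least squares started from a fixed
deterministic grid — log IC50 at every observed log dose × hill ∈
{0.5, 1, 2} — keeping the best residual sum of squares, ties broken toward
|hill − 1|; the fit is therefore a pure function of the data and
constraints. Confidence intervals are a percentile bootstrap over data
points (default 1000 resamples, caller-seeded); resamples with fewer than
three distinct doses are discarded as unable to constrain a sigmoid, and
bootstrap refits start from the point estimate. Coverage was checked by
simulation at the 53 nM / 3-point-noise regime (60 replicates × 199
resamples in the test suite — sizes chosen to keep the suite fast while the
binomial check stays meaningful): nominal 95% intervals cover truth ≥ 85%,
the usual small-n bootstrap undercoverage.

The titration comparison refuses to interpolate: per-dose differences are
only defined on the shared concentration grid, and the rescue index is the
mean difference over doses ≤ 5 µM (the range where target knockdown is
expected to blunt compound response).

## qPCR

Classic comparative Ct with amplification efficiency fixed at 2
(configurable). The two housekeeping genes are combined by the arithmetic
mean of their Cts — equivalent to the geometric mean of their expression,
the standard multi-reference-gene rule. Technical replicates are averaged
before ΔCt; no outlier rejection. A uniform Ct shift applied to one sample
(pipetting offset) cancels exactly in ΔCt.

## CAM tumor volumes

The spherical volume formula uses the geometric-mean radius of the two
perpendicular diameters, r = ½√(d1·d2): it is symmetric in the diameters,
reduces to the sphere for d1 = d2, and is the standard two-caliper
convention. A `single_diameter` rule (r = d1/2) is exposed for
cross-checking against sources that measure one diameter only. Regression
is strict (ΔV < 0); group summaries are computed over embryos. Between-group
hypothesis testing is deliberately left to standard statistics packages —
the per-embryo table is the exported interface.

## Numerical and interface choices

- CSV exchange is comma-separated UTF-8 with required headers; floats
  round-trip at full precision (`repr` serialization). Readers are
  row-order invariant; controls are identified by the `role` column, never
  by well position, so any plate map is supported.
- All generators are pure functions of (config, seed) — reruns are
  bit-identical; every stochastic routine takes a caller-supplied seed.
- Problem sizes in the analysis drivers (one default screen, 200 titration
  series, 8 embryos per CAM group) are the package's chosen demonstration
  scale; all are parameters.

## Known limitations

- The hit rule is deterministic concordance, not an error-controlled test;
  no FDR is attached to the hit list.
- 4PL fits replicate the named model family, not any specific commercial
  optimizer's internals or its asymptotic CIs.
- qPCR efficiency is assumed shared across genes unless overridden; no
  standard-curve estimation.
- CAM volumes assume spheroid geometry; image-based measurement is out of
  scope.
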