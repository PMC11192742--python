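# Methods

## The assay and its scoring model

A multiplexed DSB-repair reporter experiment transfects two plasmid
cocktails in parallel wells. The *damaged* cocktail contains one linearized
(or otherwise broken) reporter per pathway — a BFP NHEJ reporter (100 ng), a
GFP MMEJ reporter with recessed microhomologies (250 ng) and an mCherry HR
reporter (100 ng) — plus 100 ng of intact AmCyan as a transfection control
and 1000 ng of promoterless carrier DNA. The *undamaged* cocktail carries
100 ng of each intact wild-type plasmid plus the same control and carrier.
Each reporter only expresses if the cell repairs its lesion and restores the
ORF, so repair capacity per pathway is the damaged-to-undamaged ratio of
control-normalized reporter signal:

    %Reporter Expression = 100 · X / Y,
    X, Y = (count_R · MFI_R) / (count_C · MFI_C)  in the damaged / undamaged sample,

with counts and MFIs over gated-positive events on each fluorophore's
primary detector (BFP→VL1, AmCyan→VL2, GFP→BL1, mCherry→YL1). Because
`count · MFI` is the *total* gated fluorescence, the statistic is invariant
to per-channel detector gain (provided the gate is derived from a control
measured at the same gain) and a self-comparison returns exactly 100%.

Two scoring conventions are deliberate assumptions, exposed but not varied
by default:

* **MFI over gated-positive events only** (not all events), on the linear
  scale; the arithmetic mean is used because the count × mean product must
  equal a population total.
* **Compensation precedes counting.** Whether counts are taken pre- or
  post-compensation is ambiguous in practice; the pipeline compensates first
  and offers `compensation: false` to disable.

No correction is applied for the 250 vs 100 ng GFP mass asymmetry of the
standard cocktail: the expected MMEJ score is then 2.5 × the per-plasmid
reactivation probability. This mirrors how such cocktails are actually
scored; `matched_mass_panel()` provides mass-matched cocktails under which
the expected score equals 100 × repair efficiency exactly, and the recovery
experiments use it so that recovered values are comparable to the simulated
truth.

## Synthetic-data generator

`simulate_sample` draws, per cell:

1. cocktail uptake ~ Bernoulli(`transfection_efficiency`, default 0.4) —
   lipofection delivers the whole cocktail or nothing;
2. one shared uptake factor u ~ LogNormal(0, `uptake_sigma` = 0.8) for all
   plasmids in the cell — this is what makes the co-transfected control
   informative, and it induces the positive correlation between co-delivered
   fluorophores seen in real data;
3. per-plasmid expression u · mass_ng · LogNormal(`expression_mu` = ln 40
   per ng, `expression_sigma` = 0.4), linear in plasmid mass;
4. all-or-none reactivation of each damaged reporter ~
   Bernoulli(repair efficiency); defaults NHEJ 0.12, HR 0.015, MMEJ 0.003,
   the magnitudes typical of the three pathways in glioblastoma lines;
5. detector signals: fluorophore abundances mixed through the spillover
   matrix, plus per-channel LogNormal(ln 20, 0.5) autofluorescence and
   N(0, 5) instrument noise, floored at 0.

Repair is modeled all-or-none (not graded intensity) because the reporters
are restored-ORF constructs: a repaired plasmid expresses like its wild-type
counterpart. This yields a closed-form anchor — under matched cocktail
masses and gates that capture essentially all expressing cells, both the
count ratio and the MFI ratio of damaged to undamaged reporter match the
Bernoulli rate in expectation, so E[%Reporter Expression] ≈ 100 × repair
efficiency — which the recovery tests exercise.

The default spillover matrix (off-diagonals 0 – 0.2) and all distributional
defaults are implementation fixtures chosen to look like routine transient
transfection data on a four-color instrument; no instrument calibration
stands behind them. The generator does **not** emulate scatter-gated debris
and doublets, acquisition-time drift, logicle-scale artifacts, or graded
(partial-repair) intensities — so passing recovery tests demonstrate the
correctness of the estimator under the stated model, not robustness to
those real-data features.

Cell-cycle samples draw DNA content from
N(g1_position, cv·g1_position) for G1, N(2·g1_position, 2·cv·g1_position)
for G2/M, and Uniform(mode, 2·mode) for S, with a two-component lognormal
marker stain whose positive-component probability is phase-dependent.
Defaults: g1_position 50,000 (arbitrary PI-area units), cv 0.04, fractions
(0.6, 0.2, 0.2) — a typical asynchronous cycling population.

Determinism: every generator consumes a single `numpy` Generator seeded from
the truth object (or an explicit seed); identical parameters and seed give
bit-identical tables.

## Flow processing

**Spillover** is estimated per single-color control: events above the
negative control's 99.9th percentile on the primary channel (≥ 100
required), median background subtracted, and each off-channel coefficient
taken as the least-squares slope through the origin (Theil–Sen by flag).
Negative slopes clip to 0. Compensation solves the per-event linear mixing
system exactly; matrices with condition number above 1e12 are refused with a
diagnostic. Compensated intensities may be negative — they are estimates of
abundance, not measurements.

**Positive gates** are a high quantile of the (compensated) negative
control, default 0.999: a 0.1% false-positive tolerance is standard
practice where no numeric rule is otherwise fixed. The quantile is a config
knob. A gate with zero positive events propagates a missing MFI so that
downstream division fails loudly rather than silently scoring 0.

**Cell-cycle gating** finds the G1 mode as the dominant smoothed-density
peak (Gaussian KDE, Silverman bandwidth) in the lower part of the
distribution and searches for a G2/M mode in [1.8, 2.2] × G1. Peak widths
are half-widths at half maximum measured on each peak's plateau-free side
(left for G1, right for G2/M) after subtracting the S-plateau step, with the
KDE kernel width deconvolved. Events outside [0.75, 2.5] × G1 mode are
excluded as debris/aggregates. The G1/S and S/G2M boundaries are **placed
where the expected misclassification balances**: the Gaussian tail mass a
gate at mode + c·σ surrenders, f_peak·(1 − Φ(c)), is set equal to the
S-plateau mass it swallows, f_S·c·σ/span, and c is solved per boundary
(clamped to [0.5, 4]). A fixed symmetric mode ± 2σ gate cannot meet a ±0.02
fraction-recovery tolerance under this model — at cv 0.04 it systematically
mislabels ~16% of S under the G2/M gate — whereas the balanced boundaries
are unbiased to first order for any phase mixture; recovery is within
±0.006 across the tested grid. If no G2/M peak exists the S/G2M boundary
falls back to 1.5 × G1 mode and the labels carry a warning flag. Phase
calls are hard gates throughout; no Dean–Jett–Fox/Watson mixture
deconvolution is attempted.

## Statistics

* **t-tests**: unpaired, two-tailed, pooled variance by default (Welch by
  flag). Pooled is the conventional choice for n = 3 replicate designs; the
  default is an assumption, not an inference.
* **Holm–Šidák**: step-down, adjusted p for the i-th smallest raw p is
  1 − (1 − p_(i))^(m − i + 1) under a running maximum, capped at 1
  (delegated to statsmodels). Families are defined explicitly by the caller
  — one family per comparison panel; p-values are never pooled across
  panels automatically.
* **Dunnett**: one-way ANOVA pools the error variance (df = N − k); each
  group-vs-control statistic is referred to the equicorrelated multivariate
  t distribution (correlation λ_iλ_j, λ_i = √(n_i/(n_i+n_0)); ½ for
  balanced designs). The rectangle probability is computed by deterministic
  quadrature — conditioning on the shared control variate (Gauss–Hermite,
  96 nodes) and the pooled-SD chi variable (Gauss–Legendre on the
  probability scale, 96 nodes) factorizes it into products of normal CDFs —
  reproducible to well under 1e-4 absolute, with Monte-Carlo and
  scipy cross-checks in the tests. The two-sided critical value for k = 3,
  df = 8, α = 0.05 reproduces the tabulated 2.88.

## Study sizes and numerical choices in the verification suite

Recovery experiments use 100,000 events per sample and 3 replicates, with
single-color controls of 10,000 events; cell-cycle and marker recovery use
50,000 events. At 0.1% repair efficiency only ~40 cells per 100,000-event
replicate express the reporter, so the efficiency-grid experiment scales
replicates with 1/prevalence (12 at 0.1%, 4 at 0.5%, else 3) to keep the
Monte-Carlo error of the mean well inside the 15% tolerance, and gates at
the 99.99th background percentile: under the default 99.9th-percentile gate
the ~0.1% false-positive background population rivals the true-positive
population at that prevalence and inflates the score by several percent —
a real property of the statistic at prevalences near the false-positive
rate, worth knowing when interpreting very low scores.

Ties and degenerate inputs: zero-variance replicate groups and single-value
groups raise rather than return p-values; a zero undamaged ratio (Y = 0)
flags the score undefined (NaN) instead of dividing; empty gates propagate
missing MFIs; phase fractions are reported over non-excluded events only.

## Known limitations

* The simulator's measurement model is linear with additive background; it
  does not reproduce photodetector saturation, spectral crosstalk
  nonlinearity, or spillover-spreading noise, so compensation here is exact
  in expectation in a way real compensation is not.
* Scatter-based debris/doublet exclusion is assumed to have happened
  upstream; the event tables carry fluorescence channels only.
* The FCS writer emits a minimal single-dataset FCS 3.1 (float32 list mode)
  and the reader preserves only channel names and a few bookkeeping
  keywords.
* Cell-cycle gating assumes a flat S-phase plateau between two Gaussian
  peaks; strongly skewed S distributions would bias the balanced
  boundaries.
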