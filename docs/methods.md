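# Methods

## The reduced clock model

The model is a mass-action TTFL built around stoichiometric
sequestration: repressor complexes bind the free BMAL1–CLOCK pool `A`
1:1 into transcriptionally inactive complexes, and E-box transcription
reads only the *free* activator,

```
dM_g/dt = basal_g + vmax_g · A/(K_act + A) − deg_g · M_g
```

for g ∈ {Per1, Per2, Cry1, Cry2, Chrono, Rev}. There is no explicit
Hill repression term anywhere on an E-box gene; all repression emerges
from titration. *Bmal1* is the one exception, repressed by nuclear
REV-ERB through `vmax_B · K_rep/(K_rep + REV)`.

State (19 variables): seven mRNAs; cytoplasmic PER (one pool translated
from both *Per* mRNAs), CRY1, CRY2, CHRONO; nuclear REV-ERB and free
`A`; three nuclear repressor pools PER·CRY1, PER·CRY2 and PER·CHRONO
(CHRONO enters the nucleus in complex with PER2, at the same
association rate as the PER–CRY routes); and the three sequestered
complexes `A:PER·X`. *Chrono* mRNA decays through the same parameter
symbol as *Per2* mRNA (`deg_M_Per2`), encoding their near-identical
transcript kinetics, and the *Chrono* transcription rule carries the
CHRONO sequestration channel exactly like the other E-box genes.

Three structural choices matter for the dynamics and were made after
explicit failure analysis of the alternatives:

1. **Complex co-degradation.** A sequestered complex `A:R` is cleared
   whole (`clr_C_*`), destroying the bound activator along with the
   repressor. If the activator is instead recycled on clearance, the
   only route out of the activator pool is slow free-pool degradation;
   the steady state of free `A` is then pinned at `tl_Bmal1·M_B/deg_A`
   independent of repression, the feedback loses its gain, and — worse —
   a knockout's stored activator takes ~a week to drain, producing a
   monotone flood instead of the observed damped cycling. With
   co-degradation the activator budget turns over on the clearance
   timescale (~8–11 h) and activator production is balanced against
   repressor production at comparable flux (near-1:1 stoichiometric
   balance), which is where sequestration oscillators are robust.
2. **PER in excess.** PER turnover is dominated by first-order
   degradation, not by partner binding, so the CRY/CHRONO proteins (not
   PER) are rate-limiting for repressor-pool formation. In the opposite
   (PER-limited) regime the repressor flux becomes proportional to *Per*
   mRNA directly, deleting the CRY-protein delay stage from the loop and
   killing the oscillation.
3. **Slow stages, tight binding.** Each stage of the loop (mRNA,
   protein, repressor pool, sequestered complex) has a lifetime of
   5–10 h, giving the phase lag a 24-h relaxation oscillation needs, and
   sequestration is tight (`seq_off/seq_on ≈ 10⁻³` a.u. ≪ the activator
   pool), which makes titration effectively ultrasensitive.

**Channel asymmetry.** CRY1 is the strong/slow repressor: its complex
dissociates (`seq_off_PC1` = 0.10 vs 0.142 h⁻¹ pre-calibration) and
clears (`clr_C_PC1` = 0.09 vs 0.119 h⁻¹) more slowly than CRY2's, and
carries less production flux. CHRONO is a weak channel with kinetics
close to CRY2's (slightly faster unbinding and clearance) at ~19% of a
CRY channel's translation flux. This asymmetry produces the period
ladder: removing slow CRY1 leaves the fast channels and shortens the
period; removing fast CRY2 (or CHRONO) leaves the slow channel dominant
and lengthens it. Because all channels draw on shared PER and titrate a
shared activator, the CHRONO channel partially inherits the flux of
knocked-out CRY channels — which is why *Chrono* loss barely moves the
period in a *Cry1*-knockout background, yet CHRONO alone sustains
several damped cycles in the *Cry1*/*Cry2* double knockout before the
system spirals into its fixed point. DEC2 binding is represented in the
contact rules (and therefore in complex enumeration and detailed-mode
extension) but not as a dynamic species in the reduced network.

**Phases.** The REV-ERB arm is fast (protein lifetime 0.5 h, *Bmal1*
mRNA lifetime 0.67 h pre-calibration), so *Bmal1* mRNA sits close to
true antiphase with the E-box genes (~11.7 CT h from *Chrono* mRNA);
slower REV kinetics would rotate *Bmal1* toward the E-box phase and
break the antiphasic structure. *Cry2* mRNA decays more slowly
(0.08 h⁻¹) than *Per2*/*Chrono* mRNA (0.2 h⁻¹), giving it the observed
smaller relative amplitude and later peak.

**Calibration.** Multiplying every rate constant by `c` (leaving the
concentration-dimension constants `K_*` untouched) rescales time
exactly, so after qualitative tuning the wild-type period is set to
23.80 h by a single exact rescaling (`calibrate_period`). The committed
set is `default_reduced_v1` (`chronosim/params_default.py`), stored
together with the wild-type limit-cycle snapshot at the *Per2* mRNA
peak; perturbation runs start from that snapshot at simulated day 0, so
pre-steady-state transients (the damped dKO cycles) are visible.

**Perturbation semantics.** Knockout zeroes `vmax` and `basal` and the
transcript's initial condition; knockdown multiplies both by the given
fraction; overexpression adds one zeroth-order production reaction for
the gene's protein. The default overexpression rate equals the gene's
mean wild-type translation flux (doubling total production, configurable
via `gene:oe:<rate>`).

## Detailed mode

`build_detailed_model` extends an externally supplied base-model
definition (ModelSpec JSON) with *Chrono* mRNA dynamics and every
CHRONO-containing complex allowed by the contact rules (CHRONO binds
BMAL1, PER2, DEC2; not PER1, CRY1, DEC1; the CHRONO–CRY2 contact is
deliberately not modelled because CHRONO repression does not require
CRY2). Complexes are cliques of allowed contacts up to a configurable
size, assembled by association/dissociation against their next-smaller
sub-complex, and the count of newly added state variables is recorded in
metadata. The published large clock model is not bundled; without it
detailed mode raises an explicit error, and the machinery is validated
against small synthetic base definitions.

## Rhythmicity classification

After discarding the transient: interpolated peaks (cubic spline
refinement, ≥12 h apart, earliest-time tie-break) define per-cycle
peak-to-trough amplitudes. *Sustained*: the last five amplitudes vary by
<2% and exceed 10⁻³ of the mean level. *Damped*: amplitudes decay with a
fitted exponential rate λ > 10⁻³ h⁻¹ and at least two peaks exist.
Otherwise *arrhythmic*. With fewer than three usable peaks a
damped-cosine fit acts as fallback, accepted only with ≥2 detected
peaks and a credible fitted period (< min(span/3, 48 h)) so a monotone
approach to a fixed point is never labelled damped. Period estimates are
reproducible to <0.01 h under 10× tolerance tightening (tested).

## Rhythm analysis stack

* **Chi-squared periodogram.** For trial period `P` (grid step = bin
  width, default 20–28 h at 6-min resolution) with `K` bins/cycle and
  `N` complete cycles, `Qp = N·Σ_h(M_h−M)²/σ̂²` with
  `σ̂² = Σ_i(x_i−M)²/(KN)`; under white noise `Qp ~ χ²(K−1)`, and the
  significance line is the upper-α quantile (α = 0.05, Bonferroni off by
  default, flaggable). The best period maximizes `Qp − threshold` among
  significant periods; a zero-variance series yields Qp ≡ 0 and no best
  period. Measured type-I error at a single pre-registered period is
  ≈0.035–0.05 at α = 0.05 (the folding denominator couples weakly to the
  numerator, making the test slightly conservative).
* **Free-running period** uses the first 7 days of constant darkness,
  rebinned to 6-min columns — sparse 1-min counts make per-bin variance
  too high otherwise.
* **Detrending** subtracts a centred running mean (default 24 h),
  trimming half a window at each edge. It removes polynomial drift up to
  first order exactly and is idempotent for in-band signals; note that a
  24-h window attenuates off-24-h periodic components slightly (a 27.3-h
  rhythm keeps ~78% of its amplitude), which biases amplitude — not
  period or damping — estimates from detrended traces.
* **Damped-cosine fit** solves the linear parameters (baseline, cosine
  and sine amplitudes) exactly at each step of a Levenberg–Marquardt
  search over (P, λ) started from a deterministic grid (dominant FFT
  period plus 16–32 h in 4-h steps; λ ∈ {0, 0.005, 0.02} h⁻¹). Flat
  input returns a `degenerate` flag rather than raising.
* **CT conventions.** For model trajectories CT0 is the *Bmal1* mRNA
  peak (configurable); one period maps to 24 CT hours; phase differences
  are wrapped into (−12, +12]. Phase of a cycle is the interpolated
  maximum, not a center of mass.

## Synthetic data

Generators are pure functions of (parameters, seed) via
`numpy.random.default_rng`.

* **Actograms**: inhomogeneous Poisson counts in 1-min bins; the rate is
  a two-level day/night profile with ~1-h logistic transitions
  (night/day ratio = `nocturnality`, cycle mean = `mean_rate`), entrained
  to lights-off during LD and free-running at the chosen period in DD.
  The expected dark-phase share is nocturnality/(nocturnality+1) minus a
  ~2% edge term from the smoothed transitions; the exact expectation is
  available as `expected_actogram_counts` / `activity_rate_profile`.
* **Bioluminescence**: damped cosine + linear drift + Gaussian noise, in
  kcpm, sampled every 10 min by default.
* **qPCR**: trajectory mRNA sampled every 4 h from CT0 in triplicate
  with mean-preserving multiplicative lognormal noise (CV given);
  `max100` normalization scales the largest replicate-mean to exactly
  100.

What these emulate — and what they do not: the actogram model captures
binning, nocturnal consolidation, entrainment vs free run, and Poisson
counting noise, but not activity bouts, ultradian structure, or
individual variability in activity onset; the bioluminescence model has
stationary Gaussian noise and a linear baseline, not the multiplicative,
decaying-luminophore noise of real recordings. Passing tests therefore
demonstrate the *analysis pipeline's* correctness on data with known
truth, not robustness to every artefact of real recordings.

## Problem sizes and numerics

Simulations integrate 30 settle days plus 10 observation days on a
0.05-h output grid with LSODA at rtol 10⁻⁸ / atol 10⁻¹⁰ (stiff-capable;
binding is ~100× faster than transcription). The full nine-genotype
battery completes in ~15 s on one CPU; the periodogram null calibration
uses 1000 Poisson replicates of a 7-day, 6-min-bin series at a single
pre-registered 24-h period. Concentrations below −10·atol are treated
as solver noise; rate evaluation clamps negatives to zero.

## Known limitations

* The reduced model reproduces orderings and qualitative phenotypes; its
  quantitative period shifts (e.g. +0.13 h for *Chrono* loss, −0.67 h
  for *Cry1* loss) are artifacts of this parameterization, not
  predictions, and the detailed-mode numerical targets require the
  external base model.
* Light input is not modelled: LD entrainment exists only in the
  synthetic actogram generator, so jet-lag/re-entrainment protocols and
  light-pulse induction are out of scope.
* The damped dKO's mean peak interval (~35 h during decay) is reported
  as its "period"; damped relaxations toward a focus generically slow as
  they decay, so this number should not be read as a free-running
  period.
* DEC1/DEC2 dynamics, stochastic (SSA) simulation and SBML export are
  not implemented.
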