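# Methods

This note documents the models implemented in `oligofret`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that shape the results.

## Measurement model

A confocal two-channel instrument with 1 ms binning observes a dilute
solution of labeled protein scanned at constant speed (so encounter rates
are size-independent). Donor excitation only; the acceptor channel receives
FRET-sensitized emission. Per-event quantities use the **max-bin rule**:
the brightness recorded in the single brightest 1 ms bin of a burst — the
moment the particle crosses the center of the confocal volume — enters the
FRET and size formulas, for single- and multi-bin events alike.

Instrument defaults (all overridable in `InstrumentConfig`):

| parameter | default | unit | rationale |
|---|---|---|---|
| bin width | 1 | ms | acquisition binning |
| donor / acceptor threshold | 20 / 10 | photons/bin | optimized burst thresholds for these channels |
| γ | 0.26 | — | donor/acceptor quantum-yield + detection correction |
| single-donor brightness | 30 | photons/bin | calibrates apparent size |
| donor / acceptor background | 2 / 1 | photons/bin | not reported anywhere; chosen so the thresholds sit > 5σ above background, consistent with thresholds that remove background noise |
| coincidence detection efficiency | 0.25 | — | dual-labeled dsDNA calibration |
| probe volume / scan speed | 4 fL / 200 μm s⁻¹ | | geometry for the scanned-volume calibration |

Burst max-bin intensities are corrected by subtracting the mean per-bin
background of each channel before the FRET/size formulas. Without this, the
donor background systematically depresses E and inflates apparent sizes;
with it, round trips against ground truth close. The single-donor
brightness is re-estimated per dataset as the mode of a lognormal fit to
non-coincident donor burst brightnesses (single fluorophores crossing a
Gaussian beam produce lognormal brightness distributions), falling back to
the configured calibration below 20 usable events.

### Known estimator biases (intentional, documented)

The proximity-ratio FRET estimator E = I_A/(γ·I_DA + I_A) is a nonlinear
function of Poisson counts and carries a second-order (Jensen) bias of
order −γ·X·Y·(1−γ)/D³ ≈ −0.005 at 10-mer brightness; threshold detection
preferentially discards events whose binomial labeling put few donors on
the particle, inflating the mean apparent size of a 10-mer population by
~3–4%. Both effects are properties of the measurement itself, not of this
implementation — the test suite therefore validates the pipeline against
an independent per-event Monte-Carlo oracle of the same estimator rather
than against a false unbiasedness claim.

## Synthetic data

The generator emulates exactly the statistical structure the analysis
assumes: Poisson event arrivals at a rate proportional to number
concentration (via the dsDNA molar burst-rate calibration, 0.76 burst s⁻¹
pM⁻¹, so simulation and concentration estimation are mutually consistent);
binomial donor/acceptor labeling at p = 0.5; event brightness linear in the
donor count (justified by lifetime measurements showing no self-quenching
in soluble species); Poisson photon noise and background; single-bin square
transits by default, with species flagged "large" spread over a 2–6-bin
triangular profile to exercise the max-bin rule and the five-bin exclusion.
Only a fraction of dual-labeled transits (the coincidence detection
efficiency, 25%) registers in both channels; the rest are emitted into one
randomly chosen channel, emulating imperfectly overlapping detection
volumes. A `tccd` mode excites both dyes directly (donor signal ∝ donors,
acceptor ∝ acceptors, no transfer) for labeling-stoichiometry analyses.

Not emulated: Brownian-dynamics transit profiles and the confocal PSF,
triplet blinking, polarization, donor leakage and acceptor
direct-excitation under donor-only excitation, and diffusion-time/size
correlations. Passing round-trip tests therefore demonstrate correctness of
the analysis under the stated noise model, not robustness to every
photophysical artifact of real data.

Population time courses are drawn from the closed-form pre-lag moments with
mean-one lognormal noise (multiplicative noise keeps concentrations
positive); degradation ladders use a logistic in log concentration with
additive Gaussian noise clipped to [0, 1]; bulk fibrillization uses the
sigmoid-with-sloped-baselines form. All generators are bit-reproducible
given (config, seed); sub-generators derive deterministically from one
top-level seed.

## Burst and population analysis

Bins are 0-based; burst ranges inclusive; a burst is a maximal run of bins
at or above threshold. Coincidence requires ≥ 1 overlapping bin, with
greedy one-to-one pairing in donor start-bin order and ties broken by the
earlier acceptor. Events longer than 5 bins or larger than 150-mers are
excluded as fibrillar; every exclusion is counted and logged. The expected
number of chance coincidences of the two event trains, r_D·r_A·τ·T, is
subtracted from the coincident count before rates and the association
quotient Q = r_C/(2 r_B) are computed; Q is corrected upward by the
coincidence detection efficiency and by the visible fraction
1 − p^n − (1−p)^n of dual-labeled oligomers.

Histograms use right-closed bins ((0,5], (5,10], …; (0.55,0.60], …) so the
deterministic boundary rule "size exactly 5 is small, exactly 15 is medium"
holds; the size classes are small 2–5, medium 5–15, large 15–150 with
representative sizes 4, 10 and 30 monomers (the class medians). Mass-
weighted histograms (each event weighted by its apparent size) are kept
separate from the number histograms used for fitting.

The global FRET fit shares Gaussian centers and widths across all time
points with free per-time amplitudes: one component for the small and large
classes, two (ordered means, parameterized as mean + positive separation)
for the medium class. Ten multi-starts over a mean grid on [0.3, 0.9];
σ bounded to [0.02, 0.3]; non-convergence from every start raises a flagged
fit failure. Residuals are **unweighted**: weighting by observed counts
(Neyman χ²) overweights downward-fluctuating bins and measurably biases the
fitted means (+0.003 on the high-FRET mean at N = 5000 in Monte-Carlo),
so it is deliberately avoided. Fitted areas become event counts through the
equivalent-bin rule (area re-expressed as one 0.05-wide bin of equal area);
negative areas are clipped to zero with a warning.

Bulk concentrations apply, in this fixed order: count → burst rate (÷
measurement duration); ÷ coincidence efficiency; ÷ visible fraction of the
representative size; rate → single-molecule concentration by the chosen
calibration; × dilution factor (10⁵ aggregation, 10³ disaggregation); ÷
dilution-stability factor (3 for type A, 1.5 for type B); mass = number ×
representative size; mass fraction against m_tot = 70 μM (1 mg/ml) by
default. The order is not uniquely determined by any source; it is fixed
here and all corrections are multiplicative, so only the grouping — not the
result — depends on it. Two burst-rate calibrations are exposed: the dsDNA
reference (0.76 burst s⁻¹ pM⁻¹) and the scanned-volume rate (great-circle
area of the 4 fL spherical probe × 200 μm/s = 6.09×10⁻¹³ L/s × N_A per
molar). They disagree by a constant ~2× factor; both are reported,
neither is silently corrected toward the other.

## Empirical kinetic fits

* **Sigmoid** (bulk fibrillization): y = (y_i + m_i x) + (y_f + m_f x) /
  (1 + e^{−(x−x₀)/τ}). Lag time by the standard tangent construction,
  x₀ − 2τ. Flat data (range within 5× the point-to-point noise estimate)
  raises a fit failure instead of returning spurious parameters.
* **Exponential with lag**: y = A(1 − e^{−(x−x₀)r}) for x > x₀, 0 before;
  fit by bounded least squares with multiple lag starts. Scale-equivariant.
  When replicate measurements exist, fitting the per-time replicate mean
  (the standard treatment of repeated aggregation experiments) removes the
  small-lag bias that pooled fitting shows at 10% noise.
* **Proteinase K**: two-parameter logistic in log₁₀(c); Cm is the midpoint.
  Unbracketed midpoints warn about extrapolation; all-intact data raise a
  failure. ln 2/k_c converts the fitted conversion rate into a half-time
  (5×10⁻⁶ s⁻¹ → 38.5 hr).

Confidence intervals are parametric bootstrap (200 resamples by default,
seeded): refit on model + Gaussian residual noise, percentile intervals.

Times are hours in the empirical fits, SI seconds and molar inside the
mechanistic model, with explicit conversion at the boundary.

## Nucleation–conversion master equation

Sizes n_c…j_max are tracked for both types; all rate constants are
size-independent (the standard simplification; size-dependent hooks would
multiply per-size factors). Terms: primary nucleation k_n·m^{n_c} into type
A at size n_c only (no direct type-B nucleation from monomer), elongation
2·m·k₊ per size step (one monomer consumed), dissociation 2·k_off (one
monomer released; not allowed out of the nucleus size, so mass bookkeeping
stays closed), size-preserving A↔B conversion (k_c forward, k_c_rev
reverse), and a B → fibril sink k_c2. Monomer balance closes the system by
mass conservation — total monomer equivalents m + Σ j f(j) + Σ j g(j) +
sink are conserved identically by construction and verified to 10⁻⁶
relative over every integration. Elongation flux through j_max is absorbed
into the sink (recorded, so truncation never destroys mass), and a runtime
check warns when ≥ 1% of oligomers sit within 3 sizes of the boundary.
Defaults: n_c = 2, j_max = 200. Integration uses LSODA at rtol 10⁻⁸.

Before significant monomer depletion the zeroth moments follow the closed
forms quoted in the README; Q_A plateaus at k_n′·m_tot/k_c and P_B grows
as ½·k_c·k_n′·m_tot·t² at leading order. Because the moments depend on k_n
and n_c only through k_n′ = k_n·m_tot^{n_c−1}, the nucleation order is not
identifiable pre-depletion and only k_n′ is reported. The closed forms
drift from the full integration in proportion to the accumulated depletion
(≈ 2× for n_c = 2); at the default parameters depletion reaches ~0.9% by
30 hr and the moments agree within 1%.

Rate inference is joint **unweighted** least squares of the closed forms
against Q_A and P_B concentrations restricted to t ≤ 30 hr (beyond the
pre-lag window the neglected processes — depletion, reverse conversion,
the fibrillar sink — cause underfitting, and the fitter warns). No noise
model or weighting is prescribed by any source for this fit; unweighted
least squares on concentrations is the simplest defensible choice and is
documented as such. Optimization runs in log-parameter space (enforcing
positivity); initialization exploits the structure of the solution — k_n′
from the early slope of Q_A, then k_c from the quadratic rise of P_B.
Q-only data leave k_c effectively unidentifiable (it enters only through
the plateau); the model flags this and the ratio k_n′/k_c remains
constrained.

## Problem sizes and defaults in validation

Recovery checks run at the published study conditions: oligomer time
courses with 15 points over 2–30 hr, 10% lognormal noise, 5 replicates,
50 seeds; growth-law fits with 17 points over 0–100 hr, Gaussian noise of
10% of the plateau, 5 replicates, 50 seeds; FRET mixtures of 5000 events,
σ = 0.10, 20 seeds; protease ladders 0.01–10 μg/ml, 5% noise, 3
replicates, 50 seeds. Demo pipeline traces default to 2×10⁵ bins (200 s)
per time point — enough for a few hundred coincident events per trace at
picomolar concentrations.

## Known limitations

* The lag-time estimator of the exponential-lag model is intrinsically
  noisy for slow-growing classes (the likelihood is flat in x₀ when
  r·(t_max − x₀) ≲ 1); at 10% noise the per-experiment spread of the
  fitted lag is ±2.5 hr, matching the large printed uncertainties of such
  fits, and ~20% of fits collapse to a zero lag.
* Gaussian component widths are validated only by recovery tests (no
  external reference values exist for them).
* The master equation is deterministic; at the very low copy numbers of
  early nucleation a stochastic treatment would differ, but the fitted
  observables are bulk-averaged number concentrations where the
  deterministic limit is appropriate.
* No ALEX/PIE-style corrections beyond γ: donor leakage and acceptor
  direct excitation are neither simulated nor corrected.
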