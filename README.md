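# oligofret

Single-molecule FRET analysis of amyloid oligomer populations and
nucleation–conversion kinetics.

## The problem

During the aggregation of amyloid-forming proteins such as α-synuclein,
small soluble oligomers form long before fibrils appear. These oligomers —
not the fibrils — are widely implicated in cytotoxicity, but they are rare
(picomolar against micromolar monomer), heterogeneous in size, and
structurally diverse, which puts them below the detection limit of bulk
methods. Single-molecule two-channel fluorescence solves this: when a
50/50 mixture of donor- and acceptor-labeled monomers aggregates, only
oligomers carry both dyes and produce *coincident* bursts in the two
detection channels, with a FRET efficiency that reports how compact the
oligomer is.

`oligofret` implements the full analysis chain for such experiments, plus a
seeded synthetic-data generator so that every stage can be validated against
known ground truth without raw photon data:

1. **Burst analysis** — threshold binned two-channel photon traces, pair
   coincident donor/acceptor bursts, and compute per-event FRET efficiency
   and apparent oligomer size from max-bin intensities:

   E = I_A / (γ·I_DA + I_A),  size = 2·(I_DA + I_A/γ) / I_D,monomer

   Events longer than five 1 ms bins or larger than 150-mers are classified
   as fibrillar and excluded.
2. **Population analysis** — 2-D histograms (5-mer × 0.05-FRET bins), three
   size classes (2–5, 5–15, 15–150 mers), and a global Gaussian fit of the
   per-class FRET histograms with centers and widths shared across all
   incubation times. The medium class resolves two populations: mid-FRET,
   protease-sensitive **type A** and high-FRET, protease-resistant
   **type B**. Fitted component areas convert to bulk number and mass
   concentrations via a dsDNA burst-rate calibration and
   dilution/visibility/detection corrections.
3. **Kinetics** — empirical fits: sigmoid with sloped baselines for bulk
   fibrillization, single exponential with lag `y = A(1 − e^{−(x−x₀)r})`
   for oligomer growth, and a logistic in log concentration for
   proteinase-K digestion midpoints (Cm).
4. **Mechanistic model** — a size-resolved nucleation–conversion–growth
   master equation: type A oligomers nucleate from monomer (order n_c),
   grow/shrink by monomer exchange and convert (rate k_c) into type B;
   before the bulk lag time the number concentrations obey

   Q_A(t) = (k_n′·m_tot/k_c)(1 − e^{−k_c t}),
   P_B(t) = (k_n′·m_tot/k_c)(k_c t + e^{−k_c t} − 1)

   with k_n′ = k_n·m_tot^{n_c−1} the effective nucleation rate. Joint least
   squares on these closed forms infers k_n′ and k_c from measured
   oligomer time courses.

All fitters are scikit-learn-style estimators (`fit`/`predict`,
`get_params`, fitted attributes with trailing underscores) and compose with
sklearn tooling; module-level `fit_*` functions are thin wrappers.

## Worked example

```python
import numpy as np
from oligofret import InstrumentConfig
from oligofret.simulate import SpeciesSpec, simulate_photon_trace, \
    generate_timecourse_dataset
from oligofret.bursts import TraceAnalyzer, visible_fraction
from oligofret.nucleation import NucleationConversionModel
from oligofret.kinetics import conversion_halftime

ins = InstrumentConfig()          # 1 ms bins, thresholds 20/10, gamma 0.26
rng = np.random.default_rng(0)
species = [
    SpeciesSpec(size=1, fret_true=0.0, number_concentration=25e-12),
    SpeciesSpec(size=10, fret_true=0.74, number_concentration=5e-12),
]
trace, truth = simulate_photon_trace(species, ins, 300_000, rng)
events, summary = TraceAnalyzer(
    ins, mean_visible_fraction=visible_fraction(10, 0.5)).analyze(trace)
olig = events[events["category"] == "oligomer"]
print(f"donor bursts: {summary.n_donor_bursts}, "
      f"coincident events: {summary.n_coincident}")
print(f"mean FRET efficiency = {olig['E'].mean():.3f}")
print(f"mean apparent size = {olig['apparent_size'].mean():.1f} monomers")
print(f"estimated concentration = {summary.oligomer_concentration_pM:.1f} pM")

times = np.linspace(2, 30, 15)    # hours, pre-lag-phase window
df = generate_timecourse_dataset(4e-8, 5e-6, 70e-6, times, 0.1, 5,
                                 np.random.default_rng(1))
g = df.groupby("time_hr").mean()
model = NucleationConversionModel(m_tot=70e-6).fit(
    g.index.to_numpy() * 3600, g["Q_A"].to_numpy(), g["P_B"].to_numpy())
print(f"kn' = {model.kn_prime_:.2e} s^-1, kc = {model.kc_:.2e} s^-1")
print(f"conversion half-time = {conversion_halftime(model.kc_):.1f} hr")
```

Output:

```
donor bursts: 3379, coincident events: 272
mean FRET efficiency = 0.727
mean apparent size = 9.8 monomers
estimated concentration = 4.6 pM
kn' = 3.96e-08 s^-1, kc = 4.95e-06 s^-1
conversion half-time = 38.9 hr
```

The 300 s trace of a 5 pM 10-mer population (true E = 0.74) plus 25 pM
monomers yields 272 coincident events whose mean FRET efficiency and
apparent size recover the ground truth to within shot-noise accuracy, and
the efficiency-corrected dsDNA calibration recovers the input concentration.
The rate-constant fit on a noisy synthetic time course (truth
k_n′ = 4×10⁻⁸ s⁻¹, k_c = 5×10⁻⁶ s⁻¹ at 70 μM monomer) recovers both rates
within 2%; ln 2/k_c converts the conversion rate to a half-time of ~39 hr —
the slow structural maturation of type A into type B oligomers.

There is also a CLI:

```bash
oligofret simulate --seed 2 --duration 100000 --out trace.tsv
oligofret analyze --trace trace.tsv --out results/
oligofret fit-kinetics --mode explag --data timecourse.tsv --out fit.json
oligofret fit-model --data moments.tsv --tmax-hr 30 --out model.json
oligofret run-all --seed 1 --out demo/
```

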