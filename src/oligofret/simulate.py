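"""Seeded synthetic-data generators for the single-molecule oligomer pipeline.

Everything downstream (burst detection, 2-D size/FRET classification,
population kinetics, rate-constant inference) is validated against data from
these generators, which reproduce the statistical structure the analysis
assumes:

* diffusing monomers and oligomers of known size ``n`` and FRET efficiency
  ``E``, with binomial donor/acceptor labeling at ``p = 0.5``, Poisson photon
  emission and Poisson background, binned at 1 ms;
* oligomer number-concentration time courses following the closed-form
  early-time solutions of the nucleation-conversion model;
* sigmoidal bulk fibrillization curves and logistic proteinase-K
  degradation ladders.

All generators take an explicit ``numpy.random.Generator`` (or an integer
seed) and are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DSDNA_MOLAR_BURST_RATE, InstrumentConfig
from .nucleation import analytic_moments

__all__ = [
    "SpeciesSpec",
    "PhotonTrace",
    "draw_label_stoichiometry",
    "simulate_photon_trace",
    "generate_timecourse_dataset",
    "generate_pk_dataset",
    "generate_bulk_aggregation",
]


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class SpeciesSpec:
    """One diffusing species: ``size`` monomers, true FRET efficiency
    ``fret_true`` (ignored for monomers), at molar number concentration
    ``number_concentration``.  ``large`` species transit the probe volume
    slowly and occupy a multi-bin triangular intensity profile."""

    size: int
    fret_true: float
    number_concentration: float  # molar
    large: bool = False
    transit_bins: int = 3  # used only when large=True; 2..6

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"species size must be >= 1, got {self.size}")
        if not 0 <= self.fret_true <= 1:
            raise ValueError("fret_true must be in [0, 1]")
        if self.number_concentration < 0:
            raise ValueError("number_concentration must be >= 0")
        if self.large and not 2 <= self.transit_bins <= 6:
            raise ValueError("transit_bins must be in 2..6 for large species")


@dataclass
class PhotonTrace:
    """Two aligned per-bin photon-count channels (1 ms bins by default)."""

    donor: np.ndarray
    acceptor: np.ndarray
    bin_width_ms: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=np.int64)
        self.acceptor = np.asarray(self.acceptor, dtype=np.int64)
        if self.donor.shape != self.acceptor.shape:
            raise ValueError("donor and acceptor traces must be the same length")

    @property
    def n_bins(self) -> int:
        return int(self.donor.size)

    @property
    def duration_s(self) -> float:
        return self.n_bins * self.bin_width_ms * 1e-3


def draw_label_stoichiometry(n: int, p_donor: float, rng) -> tuple[int, int]:
    """Draw the donor/acceptor composition of an ``n``-mer.

    Each subunit independently carries a donor with probability ``p_donor``
    (an acceptor otherwise), so ``n_donor ~ Binomial(n, p_donor)`` — the
    Pascal's-triangle statistics that set which oligomers are visible to a
    two-color measurement.
    """
    if n < 1:
        raise ValueError(f"oligomer size must be >= 1, got {n}")
    if not 0 <= p_donor <= 1:
        raise ValueError("p_donor must be in [0, 1]")
    rng = _as_rng(rng)
    n_d = int(rng.binomial(n, p_donor))
    return n_d, n - n_d


def _event_rate_per_bin(conc_molar: float, instrument: InstrumentConfig) -> float:
    """Expected detected transits per bin at the given number concentration.

    Uses the dsDNA molar burst-rate calibration (0.76 burst/s/pM) so that
    round-trip tests through the concentration estimators are self-consistent.
    """
    conc_pm = conc_molar * 1e12
    return DSDNA_MOLAR_BURST_RATE * conc_pm * instrument.bin_width_s


def simulate_photon_trace(
    species: list[SpeciesSpec],
    instrument: InstrumentConfig,
    duration: int,
    rng,
    p_donor: float = 0.5,
    mode: str = "fret",
) -> tuple[PhotonTrace, pd.DataFrame]:
    """Simulate a binned two-channel photon trace.

    Each species produces transits as a Poisson process in time with rate
    proportional to its number concentration.  For a transit of an ``n``-mer
    carrying ``n_d`` donors and ``n_a`` acceptors:

    * ``mode="fret"`` (donor excitation only): mean donor signal is
      ``n_d * B * (1 - E_eff)`` and mean acceptor signal
      ``n_d * B * E_eff * gamma``, with ``E_eff = E`` if the particle holds
      at least one acceptor and 0 otherwise (no acceptor, no transfer);
    * ``mode="tccd"`` (both dyes directly excited, no transfer): mean donor
      signal ``n_d * B`` and mean acceptor signal ``n_a * B * gamma``.

    ``B`` is the single-donor brightness.  Signals are Poisson photon counts
    added on top of Poisson background in both channels.  Species flagged
    ``large`` spread their intensity over a triangular multi-bin transit
    profile (peak at the center bin), exercising the max-bin analysis rule.

    Imperfect overlap of the two detection volumes means only a fraction of
    dual-labeled transits (``instrument.coincidence_detection_efficiency``,
    calibrated at 25% with dual-labeled dsDNA) register in both channels;
    the remainder are emitted into a single randomly chosen channel.  This
    makes the analyzer's efficiency-corrected concentration estimates
    consistent with the simulated ground truth.

    Returns the trace and a ground-truth table with one row per emitted
    transit: ``bin, size, n_donor, n_acceptor, true_E``.
    """
    if duration < 1:
        raise ValueError("duration must be >= 1 bin")
    if mode not in ("fret", "tccd"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = _as_rng(rng)

    total_rate = sum(
        _event_rate_per_bin(s.number_concentration, instrument) for s in species
    )
    if total_rate > 0.1:
        warnings.warn(
            f"expected event rate {total_rate:.3g} per bin leaves the "
            "single-molecule regime (events will overlap)",
            stacklevel=2,
        )

    donor = rng.poisson(instrument.background_rate_donor, size=duration).astype(float)
    acceptor = rng.poisson(
        instrument.background_rate_acceptor, size=duration
    ).astype(float)

    B = instrument.monomer_donor_brightness
    truth_rows: list[tuple[int, int, int, int, float]] = []

    for sp in species:
        rate = _event_rate_per_bin(sp.number_concentration, instrument)
        if rate == 0:
            continue
        n_events_per_bin = rng.poisson(rate, size=duration)
        event_bins = np.repeat(np.arange(duration), n_events_per_bin)
        for b in event_bins:
            n_d, n_a = draw_label_stoichiometry(sp.size, p_donor, rng)
            if mode == "fret":
                e_eff = sp.fret_true if n_a > 0 else 0.0
                mean_d = n_d * B * (1.0 - e_eff)
                mean_a = n_d * B * e_eff * instrument.gamma
            else:
                mean_d = n_d * B
                mean_a = n_a * B * instrument.gamma
            if mean_d > 0 and mean_a > 0:
                # dual-channel transit: registered in both channels only with
                # the calibrated coincidence detection efficiency
                u = rng.random()
                if u >= instrument.coincidence_detection_efficiency:
                    if u < (1 + instrument.coincidence_detection_efficiency) / 2:
                        mean_a = 0.0
                    else:
                        mean_d = 0.0
            if sp.large:
                k = sp.transit_bins
                profile = np.minimum(np.arange(1, k + 1), np.arange(k, 0, -1))
                profile = profile / profile.max()
                bins = b + np.arange(k)
                bins = bins[bins < duration]
                prof = profile[: bins.size]
                donor[bins] += rng.poisson(mean_d * prof)
                acceptor[bins] += rng.poisson(mean_a * prof)
            else:
                donor[b] += rng.poisson(mean_d)
                acceptor[b] += rng.poisson(mean_a)
            truth_rows.append((int(b), sp.size, n_d, n_a, sp.fret_true))

    truth = pd.DataFrame(
        truth_rows, columns=["bin", "size", "n_donor", "n_acceptor", "true_E"]
    ).sort_values("bin", kind="stable", ignore_index=True)
    trace = PhotonTrace(
        donor=donor.astype(np.int64),
        acceptor=acceptor.astype(np.int64),
        bin_width_ms=instrument.bin_width_ms,
    )
    return trace, truth


def generate_timecourse_dataset(
    kn_prime: float,
    kc: float,
    mtot: float,
    times_hr,
    noise_cv: float = 0.1,
    replicates: int = 1,
    rng=None,
) -> pd.DataFrame:
    """Noisy type-A / type-B oligomer number-concentration time courses.

    Evaluates the closed-form early-time moments Q_A(t), P_B(t) of the
    nucleation-conversion model and multiplies each replicate observation by
    mean-one lognormal noise with coefficient of variation ``noise_cv``
    (multiplicative noise keeps concentrations positive).

    Parameters are in SI units (s^-1, molar); ``times_hr`` in hours.
    Returns a tidy frame with columns ``time_hr, replicate, Q_A, P_B`` (M).
    """
    if kn_prime <= 0 or kc < 0:
        raise ValueError("rates must be positive (kc may be 0 for the limit)")
    times_hr = np.asarray(times_hr, dtype=float)
    if np.any(times_hr < 0):
        raise ValueError("times must be >= 0")
    rng = _as_rng(rng)

    t_s = times_hr * 3600.0
    q, p = analytic_moments(t_s, kn_prime, kc, mtot)

    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        mu = -0.5 * sigma**2  # mean-one lognormal
    rows = []
    for rep in range(replicates):
        if noise_cv > 0:
            fq = rng.lognormal(mu, sigma, size=times_hr.size)
            fp = rng.lognormal(mu, sigma, size=times_hr.size)
        else:
            fq = fp = np.ones(times_hr.size)
        rows.append(
            pd.DataFrame(
                {
                    "time_hr": times_hr,
                    "replicate": rep,
                    "Q_A": q * fq,
                    "P_B": p * fp,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def generate_pk_dataset(
    cm: float,
    hill_slope: float,
    pk_concs,
    noise_sd: float = 0.05,
    replicates: int = 1,
    rng=None,
) -> pd.DataFrame:
    """Synthetic proteinase-K limited-digestion ladder.

    Fraction of protein remaining intact after fixed-time digestion at
    protease concentration ``c`` follows a logistic in log concentration,
    ``1 / (1 + (c / cm)^hill_slope)``, so ``cm`` is the protease
    concentration at which half the species is degraded.  Additive Gaussian
    noise (SD ``noise_sd``) is clipped to [0, 1].

    Returns columns ``pk_conc, replicate, fraction_intact``.
    """
    if cm <= 0:
        raise ValueError("cm must be positive")
    pk_concs = np.asarray(pk_concs, dtype=float)
    if np.any(pk_concs <= 0):
        raise ValueError("pk concentrations must be positive")
    rng = _as_rng(rng)

    clean = 1.0 / (1.0 + (pk_concs / cm) ** hill_slope)
    rows = []
    for rep in range(replicates):
        noisy = clean + rng.normal(0.0, noise_sd, size=pk_concs.size)
        rows.append(
            pd.DataFrame(
                {
                    "pk_conc": pk_concs,
                    "replicate": rep,
                    "fraction_intact": np.clip(noisy, 0.0, 1.0),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def sigmoid_with_baselines(
    x, yi: float, mi: float, yf: float, mf: float, x0: float, tau: float
):
    """Sigmoidal fibrillization curve with sloped baselines.

    ``y = (yi + mi*x) + (yf + mf*x) / (1 + exp(-(x - x0)/tau))``: a logistic
    transition of width ``tau`` centered at ``x0`` between a pre-transition
    baseline line and that line plus ``yf + mf*x``.
    """
    from scipy.special import expit

    x = np.asarray(x, dtype=float)
    return (yi + mi * x) + (yf + mf * x) * expit((x - x0) / tau)


def generate_bulk_aggregation(
    times,
    yi: float = 0.0,
    mi: float = 0.0,
    yf: float = 1.0,
    mf: float = 0.0,
    x0: float = 36.0,
    tau: float = 6.0,
    noise_sd: float = 0.0,
    rng=None,
) -> pd.DataFrame:
    """Sigmoidal bulk-fibrillization time course (e.g. ThT or SEC monomer
    loss) with optional additive Gaussian noise.  Times in hours."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    times = np.asarray(times, dtype=float)
    rng = _as_rng(rng)
    y = sigmoid_with_baselines(times, yi, mi, yf, mf, x0, tau)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=times.size)
    return pd.DataFrame({"time_hr": times, "signal": y})
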