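"""Size/FRET population analysis of coincident oligomer events.

Retained oligomer events are histogrammed on a fixed 2-D grid (size bins of
5 monomers up to 150; FRET bins of 0.05 on [0, 1]), classified into three
size classes — small (2-5 mers), medium (5-15 mers), large (15-150 mers) —
and the per-class FRET histograms across all incubation time points are fit
globally to Gaussian components whose center and width are shared across
time while the amplitudes evolve.  The medium class requires two components
(the structurally distinct low- and high-FRET populations); small and large
carry one each.  Fitted component areas are converted to event counts, then
to bulk number and mass concentrations through the burst-rate calibration
and the dilution/visibility/detection-efficiency/stability corrections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .config import REPRESENTATIVE_SIZES, InstrumentConfig
from .bursts import burst_rate_to_concentration, visible_fraction
from .exceptions import FitFailureError

__all__ = [
    "SIZE_BIN_EDGES",
    "FRET_BIN_EDGES",
    "OligomerHistogram2D",
    "build_histogram2d",
    "assign_size_class",
    "GlobalGaussianFRET",
    "global_gaussian_fit",
    "component_counts",
    "to_bulk_concentrations",
    "brightness_ratio_by_size",
]

SIZE_BIN_EDGES = np.arange(0.0, 155.0, 5.0)  # (0,5], (5,10], ..., (145,150]
FRET_BIN_EDGES = np.round(np.arange(0.0, 1.05, 0.05), 10)

#: Size-class boundaries; boundary sizes belong to the lower class.
_CLASS_UPPER = (("small", 5.0), ("medium", 15.0), ("large", 150.0))


def _bin_right_closed(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Index of the right-closed bin (lo, hi] containing each value;
    -1 for values outside the grid."""
    idx = np.searchsorted(edges, values, side="left") - 1
    idx[values == edges[0]] = -1
    idx[(values <= edges[0]) | (values > edges[-1])] = -1
    return idx


@dataclass
class OligomerHistogram2D:
    """Event counts on the fixed apparent-size x FRET grid for one time
    point.  ``counts[i, j]`` covers size bin i and FRET bin j; bins are
    right-closed.  ``weighted`` marks mass-weighted (display) histograms."""

    counts: np.ndarray
    time_point_hr: float
    size_bin_edges: np.ndarray = field(default_factory=lambda: SIZE_BIN_EDGES.copy())
    fret_bin_edges: np.ndarray = field(default_factory=lambda: FRET_BIN_EDGES.copy())
    weighted: bool = False

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def fret_marginal(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def size_marginal(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def build_histogram2d(
    events: pd.DataFrame, time_point_hr: float, mass_weighted: bool = False
) -> OligomerHistogram2D:
    """Histogram retained oligomer events on the fixed size x FRET grid.

    ``mass_weighted=True`` weighs each event by its apparent size, turning
    the number distribution into the relative-mass distribution used for
    display; fitting always uses number histograms.
    """
    counts = np.zeros((SIZE_BIN_EDGES.size - 1, FRET_BIN_EDGES.size - 1))
    if len(events):
        if (events["category"] != "oligomer").any():
            raise ValueError("histograms accept only retained oligomer events")
        si = _bin_right_closed(events["apparent_size"].to_numpy(float),
                               SIZE_BIN_EDGES)
        fi = _bin_right_closed(events["E"].to_numpy(float), FRET_BIN_EDGES)
        # E = 0 (acceptor-dark) sits at the grid edge; keep it in the first bin
        fi[events["E"].to_numpy(float) == 0.0] = 0
        w = events["apparent_size"].to_numpy(float) if mass_weighted else None
        ok = (si >= 0) & (fi >= 0)
        np.add.at(counts, (si[ok], fi[ok]), w[ok] if w is not None else 1.0)
    return OligomerHistogram2D(
        counts=counts, time_point_hr=time_point_hr, weighted=mass_weighted
    )


def assign_size_class(apparent_size: float) -> str:
    """small (<=5), medium (<=15) or large (<=150) monomers; boundary sizes
    go to the lower class.  Sizes above 150 must have been excluded as
    fibrillar upstream."""
    if not 1 < apparent_size <= 150:
        raise ValueError(
            f"size {apparent_size} outside the oligomer range (1, 150]; "
            "fibrillar events must be excluded before classification"
        )
    for label, upper in _CLASS_UPPER:
        if apparent_size <= upper:
            return label
    raise AssertionError("unreachable")


def _gauss(x, amp, mean, sigma):
    return amp * np.exp(-0.5 * ((x - mean) / sigma) ** 2)


class GlobalGaussianFRET(BaseEstimator):
    """Global Gaussian fit of FRET histograms across incubation times.

    Least squares on binned counts with component centers and widths shared
    across all time points and one free amplitude per component per time
    point.  The residuals are unweighted: weighting by the observed counts
    (a Neyman chi-square) systematically pulls the fitted means toward
    downward-fluctuating bins and is avoided deliberately.
    Ten multi-starts spread the initial means over a grid on [0.3, 0.9];
    widths are bounded to [0.02, 0.3].  With two components the fitted means
    are reported in increasing order.

    Parameters
    ----------
    n_components : int
        1 for the small and large size classes, 2 for the medium class.
    share_sigma : bool
        Use a single width for all components (the populations are
        instrument-width limited); per-component widths otherwise.

    Attributes
    ----------
    means_ : ndarray of shape (n_components,), increasing
    sigmas_ : ndarray of shape (n_components,)
    amplitudes_ : DataFrame indexed by time point, one column per component
    areas_ : DataFrame, Gaussian areas (counts x bin width) per time point
    """

    N_STARTS = 10
    SIGMA_BOUNDS = (0.02, 0.3)
    MEAN_GRID = (0.3, 0.9)

    def __init__(self, n_components: int = 1, share_sigma: bool = False):
        self.n_components = n_components
        self.share_sigma = share_sigma

    def fit(self, histograms: dict[float, np.ndarray], bin_edges=None):
        """``histograms`` maps time point (hr) -> FRET histogram counts on
        the 0.05 grid (length 20)."""
        if bin_edges is None:
            bin_edges = FRET_BIN_EDGES
        bin_edges = np.asarray(bin_edges, float)
        centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
        times = sorted(histograms)
        if len(times) < 1:
            raise FitFailureError("need at least one time point")
        counts = {t: np.asarray(histograms[t], float) for t in times}
        for t, c in counts.items():
            if c.size != centers.size:
                raise ValueError(f"histogram at t={t} not on the expected grid")

        nc = self.n_components
        lo, hi = self.MEAN_GRID
        rng_means = np.linspace(lo, hi, self.N_STARTS)
        best = None
        for s in range(self.N_STARTS):
            params = lmfit.Parameters()
            for k in range(nc):
                # spread the start means around the grid point, keeping order
                m0 = np.clip(rng_means[s] + 0.12 * (k - (nc - 1) / 2), 0.05, 0.95)
                params.add(f"mean{k}", value=m0, min=0.0, max=1.0)
                if self.share_sigma and k > 0:
                    params.add(f"sigma{k}", expr="sigma0")
                else:
                    params.add(f"sigma{k}", value=0.08,
                               min=self.SIGMA_BOUNDS[0], max=self.SIGMA_BOUNDS[1])
            if nc == 2:
                # enforce mean0 < mean1 via a positive separation parameter
                params.add("sep", value=0.15, min=1e-3, max=1.0)
                params["mean1"].set(expr="mean0 + sep")
            for ti, t in enumerate(times):
                peak = max(counts[t].max(), 1.0)
                for k in range(nc):
                    params.add(f"amp_{ti}_{k}", value=peak / nc, min=0.0)

            def residual(p):
                res = []
                for ti, t in enumerate(times):
                    model = np.zeros_like(centers)
                    for k in range(nc):
                        model += _gauss(centers, p[f"amp_{ti}_{k}"],
                                        p[f"mean{k}"], p[f"sigma{k}"])
                    res.append(model - counts[t])
                return np.concatenate(res)

            try:
                result = lmfit.minimize(residual, params, method="leastsq")
            except Exception:
                continue
            if best is None or result.chisqr < best.chisqr:
                best = result

        if best is None or not best.success:
            raise FitFailureError(
                "global Gaussian fit failed to converge from any start",
                details={"n_starts": self.N_STARTS},
            )

        p = best.params
        means = np.array([p[f"mean{k}"].value for k in range(nc)])
        sigmas = np.array([p[f"sigma{k}"].value for k in range(nc)])
        order = np.argsort(means)
        self.means_ = means[order]
        self.sigmas_ = sigmas[order]
        amps = pd.DataFrame(
            {
                f"c{rank}": [p[f"amp_{ti}_{order[rank]}"].value
                             for ti in range(len(times))]
                for rank in range(nc)
            },
            index=pd.Index(times, name="time_hr"),
        )
        self.amplitudes_ = amps
        bw = float(np.diff(bin_edges).mean())
        self.bin_width_ = bw
        self.areas_ = amps * (np.sqrt(2 * np.pi) * self.sigmas_)
        self.fit_result_ = best
        self.times_ = times
        return self

    def predict(self, fret_values, time_point):
        """Model histogram intensity at the given FRET values for one fitted
        time point."""
        self._check_fitted()
        ti = self.times_.index(time_point)
        x = np.asarray(fret_values, float)
        model = np.zeros_like(x)
        for k in range(self.n_components):
            model += _gauss(x, self.amplitudes_.iloc[ti, k],
                            self.means_[k], self.sigmas_[k])
        return model

    def component_counts(self) -> pd.DataFrame:
        """Event counts per component and time point: each Gaussian's area
        re-expressed as a single bin of width 0.05 with the same area, whose
        height is the event count attributed to the component."""
        self._check_fitted()
        counts = self.areas_ / self.bin_width_
        neg = counts < 0
        if neg.any().any():
            warnings.warn("negative fitted area clipped to 0", stacklevel=2)
        return counts.clip(lower=0.0)

    def _check_fitted(self):
        if not hasattr(self, "means_"):
            raise FitFailureError("model is not fitted")


def global_gaussian_fit(
    histograms: dict[float, np.ndarray],
    n_components: int,
    share_sigma: bool = False,
) -> GlobalGaussianFRET:
    """Thin wrapper over :class:`GlobalGaussianFRET`."""
    return GlobalGaussianFRET(n_components, share_sigma).fit(histograms)


def component_counts(model: GlobalGaussianFRET) -> pd.DataFrame:
    """Equivalent-bin event counts of a fitted model (see
    :meth:`GlobalGaussianFRET.component_counts`)."""
    return model.component_counts()


def to_bulk_concentrations(
    count: float,
    size_class: str,
    oligomer_type: str,
    duration_s: float,
    instrument: InstrumentConfig,
    dilution_factor: float = 1e5,
    stability_factors: dict[str, float] | None = None,
    m_tot_uM: float = 70.0,
    p_donor: float = 0.5,
    calibration: str = "dsDNA_reference",
) -> dict[str, float]:
    """Convert a fitted event count to bulk concentrations.

    The burst rate (count / measurement duration) is corrected upward for
    the coincidence detection efficiency and for the invisible single-color
    labelings of the class's representative size, converted to a
    single-molecule concentration via the chosen burst-rate calibration,
    scaled to bulk by the dilution factor, and divided by the
    dilution-stability factor (detected numbers rise 3x for type A and 1.5x
    for type B upon dilution).  Mass uses the representative size (4-, 10-
    or 30-mer).

    Returns ``number_nM``, ``mass_uM`` (monomer equivalents) and
    ``mass_fraction`` of the total protein.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if size_class not in REPRESENTATIVE_SIZES:
        raise ValueError(f"unknown size class {size_class!r}")
    if oligomer_type not in ("A", "B"):
        raise ValueError("oligomer_type must be 'A' or 'B'")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    stability = (stability_factors or {"A": 3.0, "B": 1.5})[oligomer_type]
    rep_size = REPRESENTATIVE_SIZES[size_class]

    rate = count / duration_s
    corrected = rate / (
        instrument.coincidence_detection_efficiency
        * visible_fraction(rep_size, p_donor)
    )
    conc_sm_pM = burst_rate_to_concentration(corrected, calibration, instrument)
    number_nM = conc_sm_pM * 1e-3 * dilution_factor / stability
    mass_uM = number_nM * 1e-3 * rep_size
    return {
        "number_nM": number_nM,
        "mass_uM": mass_uM,
        "mass_fraction": mass_uM / m_tot_uM,
    }


def brightness_ratio_by_size(
    events: pd.DataFrame, gamma: float, by: str = "class", min_events: int = 25
) -> pd.DataFrame:
    """Mean donor/acceptor max-bin brightness ratio per size group for
    TCCD-type (direct dual-excitation) coincident events.

    The acceptor intensity is de-scaled by gamma before the ratio, so equal
    donor and acceptor labeling gives a ratio near 1 regardless of size; a
    size trend or a ratio far outside ~[0.7, 1.4] signals a labeling bias.
    ``by`` groups by size class or by the 5-mer histogram bin; groups with
    fewer than ``min_events`` events are omitted (too noisy to interpret).
    """
    if events.empty:
        return pd.DataFrame(columns=["group", "n_events", "ratio"])
    ev = events[events["category"] == "oligomer"].copy()
    if by == "class":
        ev["group"] = ev["apparent_size"].map(assign_size_class)
    elif by == "bin":
        idx = _bin_right_closed(ev["apparent_size"].to_numpy(float), SIZE_BIN_EDGES)
        ev["group"] = [
            f"({SIZE_BIN_EDGES[i]:g},{SIZE_BIN_EDGES[i+1]:g}]" for i in idx
        ]
    else:
        raise ValueError("by must be 'class' or 'bin'")
    rows = []
    for g, sub in ev.groupby("group"):
        if len(sub) < min_events:
            continue
        rows.append(
            {
                "group": g,
                "n_events": len(sub),
                "ratio": sub["I_DA"].mean() / (sub["I_A"].mean() / gamma),
            }
        )
    return pd.DataFrame(rows)
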