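"""Burst detection, coincidence pairing, per-event FRET/size arithmetic."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oligofret.bursts import (
    BurstEvent,
    TraceAnalyzer,
    apparent_size,
    association_quotient,
    burst_rate_to_concentration,
    classify_event,
    detect_bursts,
    fret_efficiency,
    pair_coincident,
    scanned_volume_rate,
    visible_fraction,
)
from oligofret.exceptions import CalibrationError, OligofretError
from oligofret.simulate import PhotonTrace, SpeciesSpec, simulate_photon_trace


def _trace(donor, acceptor=None):
    donor = np.asarray(donor)
    if acceptor is None:
        acceptor = np.zeros_like(donor)
    return PhotonTrace(donor=donor, acceptor=np.asarray(acceptor))


class TestDetectBursts:
    def test_all_below_threshold_gives_nothing(self):
        assert detect_bursts(_trace([1, 5, 19, 3]), 20, "donor") == []

    def test_single_supra_threshold_bin(self):
        (ev,) = detect_bursts(_trace([0, 25, 0]), 20, "donor")
        assert (ev.start_bin, ev.end_bin, ev.duration_bins) == (1, 1, 1)
        assert ev.max_bin_intensity == 25

    def test_contiguous_run_merges_with_max_bin_rule(self):
        (ev,) = detect_bursts(_trace([0, 21, 35, 28, 0]), 20, "donor")
        assert ev.duration_bins == 3
        assert ev.max_bin_intensity == 35
        assert ev.summed_intensity == 84

    def test_counts_injected_pulses(self, rng):
        counts = rng.poisson(2, 5000)
        positions = np.arange(100, 5000, 250)  # separated, known k
        counts[positions] = 50
        events = detect_bursts(_trace(counts), 20, "donor")
        assert len(events) == len(positions)

    def test_run_at_trace_edges_detected(self):
        events = detect_bursts(_trace([30, 2, 2, 40]), 20, "donor")
        assert [(e.start_bin, e.end_bin) for e in events] == [(0, 0), (3, 3)]

    def test_empty_trace(self):
        assert detect_bursts(_trace([]), 20, "donor") == []


class TestPairCoincident:
    def test_disjoint_ranges_do_not_pair(self, instrument):
        d = [BurstEvent("donor", 0, 1, 30, 50)]
        a = [BurstEvent("acceptor", 5, 6, 15, 20)]
        assert pair_coincident(d, a, instrument) == []

    def test_identical_single_bin_events_pair(self, instrument):
        d = [BurstEvent("donor", 3, 3, 30, 30)]
        a = [BurstEvent("acceptor", 3, 3, 15, 15)]
        (ev,) = pair_coincident(d, a, instrument, subtract_background=False)
        assert ev.I_DA == 30 and ev.I_A == 15

    def test_one_to_one_greedy_with_earlier_acceptor_tiebreak(self, instrument):
        d = [BurstEvent("donor", 0, 4, 30, 100)]
        a = [
            BurstEvent("acceptor", 2, 2, 12, 12),
            BurstEvent("acceptor", 0, 1, 15, 20),
        ]
        (ev,) = pair_coincident(d, a, instrument, subtract_background=False)
        assert ev.I_A == 15  # earlier-starting acceptor wins

    def test_chance_coincidence_rate_matches_analytic(self, instrument):
        # two independent Poisson event trains: rate ~ r_D * r_A * tau
        rng = np.random.default_rng(99)
        n_bins = 400_000
        p_d, p_a = 0.01, 0.008
        donor_bins = np.flatnonzero(rng.random(n_bins) < p_d)
        acceptor_bins = np.flatnonzero(rng.random(n_bins) < p_a)
        d = [BurstEvent("donor", int(b), int(b), 30, 30) for b in donor_bins]
        a = [BurstEvent("acceptor", int(b), int(b), 15, 15) for b in acceptor_bins]
        pairs = pair_coincident(d, a, instrument)
        expected = p_d * p_a * n_bins
        assert abs(len(pairs) - expected) < 3 * np.sqrt(expected)


class TestEventArithmetic:
    def test_fret_zero_when_no_acceptor_signal(self):
        assert fret_efficiency(0, 40, 0.26) == 0.0

    def test_fret_half_at_symmetric_intensities_gamma_one(self):
        assert fret_efficiency(30, 30, 1.0) == pytest.approx(0.5)

    def test_fret_worked_example_at_instrument_gamma(self):
        # gamma=0.26: I_A=13, I_DA=50 -> 13/(0.26*50 + 13) = 0.5
        assert fret_efficiency(13, 50, 0.26) == pytest.approx(0.5)

    def test_fret_undefined_for_dark_event(self):
        with pytest.raises(OligofretError):
            fret_efficiency(0, 0, 0.26)

    def test_size_single_visible_donor_implies_dimer(self):
        assert apparent_size(0, 30, 0.26, 30) == pytest.approx(2.0)

    def test_size_worked_example(self):
        # 2*(30 + 7.8/0.26)/30 = 2*(30+30)/30 = 4
        assert apparent_size(7.8, 30, 0.26, 30) == pytest.approx(4.0)

    def test_size_at_exclusion_boundary(self):
        # all-acceptor-signal event calibrated to exactly 150 monomers
        assert apparent_size(0.26 * 2250, 0, 0.26, 30) == pytest.approx(150.0)

    def test_size_requires_calibration(self):
        with pytest.raises(CalibrationError):
            apparent_size(10, 10, 0.26, 0)

    @given(
        i_a=st.floats(0, 1e4),
        i_da=st.floats(0.1, 1e4),
        gamma=st.floats(0.01, 1.0),
    )
    def test_fret_bounded_and_size_positive(self, i_a, i_da, gamma):
        e = fret_efficiency(i_a, i_da, gamma)
        assert 0.0 <= e <= 1.0
        assert apparent_size(i_a, i_da, gamma, 30.0) > 0


class TestClassification:
    @pytest.mark.parametrize(
        "size,duration,expected",
        [
            (4, 1, "oligomer"),
            (150, 5, "oligomer"),
            (160, 1, "excluded_fibrillar"),  # above the 150-mer cutoff
            (10, 6, "excluded_fibrillar"),  # longer than five bins
        ],
    )
    def test_fibrillar_exclusion_rules(self, size, duration, expected):
        assert classify_event(size, duration) == expected


class TestSampleQuantities:
    def test_association_quotient_zero_without_coincidence(self):
        assert association_quotient(0.0, 50.0) == 0.0

    def test_association_quotient_raw(self):
        assert association_quotient(1.0, 50.0) == pytest.approx(0.01)

    def test_association_quotient_efficiency_corrected(self):
        assert association_quotient(1.0, 50.0, 0.25, 1.0) == pytest.approx(0.04)

    def test_association_quotient_requires_monomers(self):
        with pytest.raises(OligofretError):
            association_quotient(1.0, 0.0)

    @pytest.mark.parametrize("n,expected", [(1, 0.0), (2, 0.5), (5, 0.9375)])
    def test_visible_fraction_known_values(self, n, expected):
        assert visible_fraction(n, 0.5) == pytest.approx(expected)

    @pytest.mark.parametrize("n", range(1, 11))
    @pytest.mark.parametrize("p", [0.3, 0.5, 0.7])
    def test_visible_fraction_matches_exhaustive_enumeration(self, n, p):
        # enumerate all 2^n labelings and add up those with both colors
        prob = 0.0
        for mask in range(2**n):
            n_d = bin(mask).count("1")
            if 0 < n_d < n:
                prob += p**n_d * (1 - p) ** (n - n_d)
        assert visible_fraction(n, p) == pytest.approx(prob, abs=1e-12)

    def test_dsdna_reference_calibration(self, instrument):
        assert burst_rate_to_concentration(0.0, "dsDNA_reference", instrument) == 0
        assert burst_rate_to_concentration(
            0.76, "dsDNA_reference", instrument
        ) == pytest.approx(1.0)

    def test_scanned_volume_rate_from_probe_geometry(self, instrument):
        # sphere of 4 fL has great-circle radius 0.985 um; times 200 um/s
        assert scanned_volume_rate(instrument) == pytest.approx(6.08e-13, rel=0.01)

    def test_unknown_calibration_method(self, instrument):
        with pytest.raises(ValueError):
            burst_rate_to_concentration(1.0, "guesswork", instrument)


def _event_level_oracle(size, e_true, instrument, n_draws, rng):
    """Independent per-event Monte Carlo of the estimator: Poisson intensities
    at the true means plus background, threshold selection, background
    correction, then the FRET/size formulas - no trace or burst search."""
    B = instrument.monomer_donor_brightness
    es, sizes = [], []
    for _ in range(n_draws):
        n_d = rng.binomial(size, 0.5)
        n_a = size - n_d
        e_eff = e_true if n_a > 0 else 0.0
        i_da = rng.poisson(n_d * B * (1 - e_eff) + instrument.background_rate_donor)
        i_a = rng.poisson(
            n_d * B * e_eff * instrument.gamma + instrument.background_rate_acceptor
        )
        if i_da < instrument.donor_threshold or i_a < instrument.acceptor_threshold:
            continue
        i_da -= instrument.background_rate_donor
        i_a -= instrument.background_rate_acceptor
        es.append(fret_efficiency(i_a, i_da, instrument.gamma))
        sizes.append(apparent_size(i_a, i_da, instrument.gamma, B))
    return np.array(es), np.array(sizes)


class TestRoundTrip:
    def test_pipeline_matches_event_level_oracle(self, instrument):
        size, e_true = 10, 0.74
        rng = np.random.default_rng(42)
        species = [SpeciesSpec(size=size, fret_true=e_true,
                               number_concentration=20e-12)]
        trace, _ = simulate_photon_trace(species, instrument, 200_000, rng)
        events, _ = TraceAnalyzer(instrument, estimate_brightness=False).analyze(trace)
        olig = events[events["category"] == "oligomer"]
        assert len(olig) >= 500

        oracle_e, oracle_size = _event_level_oracle(
            size, e_true, instrument, 40_000, np.random.default_rng(7)
        )
        se_e = np.sqrt(olig["E"].var() / len(olig) + oracle_e.var() / oracle_e.size)
        se_s = np.sqrt(
            olig["apparent_size"].var() / len(olig)
            + oracle_size.var() / oracle_size.size
        )
        assert abs(olig["E"].mean() - oracle_e.mean()) < 2 * se_e
        assert abs(olig["apparent_size"].mean() - oracle_size.mean()) < 2 * se_s
        # accuracy against ground truth: shot-noise/selection bias stays small
        assert abs(olig["E"].mean() - e_true) < 0.02
        assert abs(olig["apparent_size"].mean() - size) / size < 0.05

    def test_concentration_estimate_recovers_simulated_truth(self, instrument):
        # forward simulation at a known concentration; the analyzer's
        # efficiency-corrected dsDNA-calibrated estimate must invert it
        rng = np.random.default_rng(21)
        conc_pm = 8.0
        species = [SpeciesSpec(size=10, fret_true=0.6,
                               number_concentration=conc_pm * 1e-12)]
        trace, _ = simulate_photon_trace(species, instrument, 400_000, rng)
        _, summary = TraceAnalyzer(
            instrument, mean_visible_fraction=visible_fraction(10, 0.5)
        ).analyze(trace)
        # ~10% loss from dim low-n_d labelings below threshold is expected
        assert summary.oligomer_concentration_pM == pytest.approx(conc_pm, rel=0.12)

    def test_monomers_only_produce_chance_level_coincidence(self, instrument):
        rng = np.random.default_rng(5)
        species = [SpeciesSpec(size=1, fret_true=0.0, number_concentration=50e-12)]
        trace, _ = simulate_photon_trace(species, instrument, 300_000, rng)
        events, summary = TraceAnalyzer(instrument).analyze(trace)
        expected_chance = (
            summary.n_donor_bursts * summary.n_acceptor_bursts / trace.n_bins
        )
        assert summary.n_coincident <= expected_chance + 3 * np.sqrt(
            max(expected_chance, 1)
        )

    def test_retained_events_satisfy_invariants(self, instrument):
        rng = np.random.default_rng(11)
        species = [
            SpeciesSpec(size=4, fret_true=0.61, number_concentration=10e-12),
            SpeciesSpec(size=30, fret_true=0.68, number_concentration=3e-12,
                        large=True),
        ]
        trace, _ = simulate_photon_trace(species, instrument, 150_000, rng)
        events, _ = TraceAnalyzer(instrument).analyze(trace)
        olig = events[events["category"] == "oligomer"]
        assert olig["E"].between(0, 1).all()
        assert (olig["apparent_size"] <= 150).all()
        assert (olig["duration_bins"] <= 5).all()
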