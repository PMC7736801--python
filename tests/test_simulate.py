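"""Simulator: reference construction, capture statistics, rendering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest, norm

from dropread import (
    ChannelComponents,
    IntensityModel,
    SimConfig,
    call_occupancy,
    default_intensity_model,
    fit_mixture,
    make_reference,
    poisson_multi_fraction,
    poisson_occupancy,
    render_intensities,
    simulate_blanks,
    simulate_methyl_plate,
    simulate_release,
    solve_capture_rate,
)


class TestMakeReference:
    def test_forced_gc_composition(self):
        seq, _ = make_reference(100, 1.0, 0, seed=1)
        assert set(seq) <= {"G", "C"}
        seq, _ = make_reference(100, 0.0, 0, seed=1)
        assert set(seq) <= {"A", "T"}

    def test_realized_gc_within_binomial_error(self):
        seq, _ = make_reference(10000, 0.25, 0, seed=7)
        gc = sum(c in "GC" for c in seq) / len(seq)
        # 3 sigma binomial bound: sqrt(0.25 * 0.75 / 10000) = 0.00433
        assert 0.237 <= gc <= 0.263

    def test_homopolymer_embedded_at_reported_position(self):
        seq, start = make_reference(50, 0.5, homopolymer_len=16, seed=2)
        assert start is not None
        run = seq[start : start + 16]
        assert len(set(run)) == 1

    def test_same_seed_identical(self):
        assert make_reference(500, 0.4, 8, seed=9) == make_reference(500, 0.4, 8, seed=9)

    def test_homopolymer_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            make_reference(10, 0.5, homopolymer_len=11, seed=0)


class TestCaptureStatistics:
    def test_solved_rate_reproduces_multi_fraction_by_monte_carlo(self):
        # independent check of the truncated-Poisson calibration: raw Poisson
        # draws at the solved rate show 21% multi-base among occupied
        rate = solve_capture_rate(0.21)
        k = np.random.default_rng(0).poisson(rate, 200000)
        occ = k >= 1
        frac = (k >= 2).sum() / occ.sum()
        se = math.sqrt(0.21 * 0.79 / occ.sum())
        assert abs(frac - 0.21) < 3 * se

    def test_truncation_swallows_whole_reference(self):
        cfg = SimConfig(n_droplets=1, seed=0, capture_rate=1e6, contamination_rate=0.0)
        (truth,) = simulate_release("ACGT", cfg)
        assert truth.captured == ("A", "C", "G", "T")

    def test_occupancy_and_multi_fraction_match_closed_forms(self):
        cfg = SimConfig(n_droplets=100000, seed=3, contamination_rate=0.0)
        ref, _ = make_reference(200000, 0.5, 0, seed=1)
        truths = simulate_release(ref, cfg)
        k = np.array([len(t.captured) for t in truths])
        p1 = (k >= 1).mean()
        expect_p1 = poisson_occupancy(cfg.capture_rate)
        assert abs(p1 - expect_p1) < 3 * math.sqrt(expect_p1 * (1 - expect_p1) / k.size)
        n_occ = (k >= 1).sum()
        frac = (k >= 2).sum() / n_occ
        expect = poisson_multi_fraction(cfg.capture_rate)
        assert abs(frac - expect) < 3 * math.sqrt(expect * (1 - expect) / n_occ)

    @settings(max_examples=25, deadline=None)
    @given(
        seed=st.integers(0, 2**31 - 1),
        n=st.integers(1, 60),
        rate=st.floats(0.05, 3.0),
        contamination=st.floats(0.0, 0.2),
        ref_len=st.integers(1, 80),
    )
    def test_conservation_property(self, seed, n, rate, contamination, ref_len):
        """Captured multisets, concatenated in order, spell a reference prefix."""
        ref, _ = make_reference(ref_len, 0.5, 0, seed=seed)
        cfg = SimConfig(
            n_droplets=n, seed=seed, capture_rate=rate, contamination_rate=contamination
        )
        truths = simulate_release(ref, cfg)
        released = "".join("".join(sorted(t.captured)) for t in truths)
        # multisets are stored sorted; compare base counts prefix-wise
        consumed = sum(len(t.captured) for t in truths)
        assert consumed <= ref_len
        pos = 0
        for t in truths:
            chunk = ref[pos : pos + len(t.captured)]
            assert tuple(sorted(chunk)) == t.captured
            pos += len(t.captured)
        assert len(released) == consumed

    def test_determinism_byte_identical(self):
        cfg = SimConfig(n_droplets=500, seed=42)
        ref, _ = make_reference(300, 0.5, 0, seed=5)
        a = simulate_release(ref, cfg)
        b = simulate_release(ref, cfg)
        assert a == b
        ra = render_intensities(a, cfg.intensity_model, seed=7)
        rb = render_intensities(b, cfg.intensity_model, seed=7)
        assert ra == rb

    def test_blank_reported_rate_matches_contamination(self):
        cfg = SimConfig(n_droplets=50000, seed=11)
        truths = simulate_blanks(cfg)
        p = cfg.contamination_rate
        se = math.sqrt(p * (1 - p) / cfg.n_droplets)
        for ch in cfg.channels:
            rate = np.mean([t.reported_channels[ch] for t in truths])
            # misidentification (0.1%) perturbs this well below 3 SE
            assert abs(rate - p) < 3 * se + cfg.misidentify_rate


class TestRenderIntensities:
    def test_near_zero_variance_pins_unoccupied_location(self):
        channels = tuple(SimConfig(n_droplets=1, seed=0).channels)
        comp = ChannelComponents(2.0, 1e-9, 3.0, 1e-9)
        model = IntensityModel(components={ch: comp for ch in channels})
        truths = simulate_blanks(SimConfig(n_droplets=20, seed=0, contamination_rate=0.0))
        recs = render_intensities(truths, model, seed=1)
        for r in recs:
            for ch in channels:
                assert r.intensity[ch] == pytest.approx(100.0, rel=1e-6)

    def test_blank_intensities_follow_unoccupied_component(self, default_model):
        cfg = SimConfig(n_droplets=100000, seed=21, contamination_rate=0.0)
        truths = simulate_blanks(cfg)
        recs = render_intensities(truths, default_model, seed=22)
        comp = default_model.components["ch532"]
        x = np.log10([r.intensity["ch532"] for r in recs[:1000]])
        stat = kstest(x, norm(comp.unoccupied_loc, comp.unoccupied_scale).cdf)
        assert stat.pvalue > 0.01

    def test_diameters_unimodal_and_capped(self, default_model):
        cfg = SimConfig(n_droplets=5000, seed=4)
        recs = render_intensities(simulate_blanks(cfg), default_model, seed=5)
        d = np.array([r.diameter_um for r in recs])
        assert d.max() <= 15.0 and d.min() > 4.0
        assert 9.0 < np.median(d) < 11.0

    def test_round_trip_separated_components_recover_flags(self):
        """Render then re-call: with negligible overlap the occupancy chain
        reproduces the generating channel flags exactly."""
        cfg = SimConfig(
            n_droplets=4000,
            seed=8,
            contamination_rate=0.2,  # plenty of occupied droplets in every channel
            misidentify_rate=0.0,
        )
        comp = ChannelComponents(2.0, 0.1, 3.2, 0.1)  # 12-scale-unit separation
        model = IntensityModel(components={ch: comp for ch in cfg.channels})
        truths = simulate_blanks(cfg)
        recs = render_intensities(truths, model, seed=9)
        fits = {ch: fit_mixture([r.intensity[ch] for r in recs]) for ch in cfg.channels}
        calls = call_occupancy(recs, fits)
        for t, c in zip(truths, calls):
            assert c.occupied == dict(t.reported_channels)


class TestMethylPlate:
    def test_all_empty_plate(self):
        records, labels = simulate_methyl_plate(200, (1.0, 0.0, 0.0), seed=3)
        assert set(labels) == {"empty"}
        model = default_intensity_model(("ch1", "ch2"))
        comp = model.components["ch1"]
        x = np.log10([r.intensity["ch1"] for r in records])
        assert np.all(x < comp.occupied_loc)  # all drawn from unoccupied component

    def test_three_populations_present(self):
        records, labels = simulate_methyl_plate(10000, (0.4, 0.3, 0.3), seed=5)
        counts = {lab: labels.count(lab) for lab in set(labels)}
        for lab, frac in zip(("empty", "dCTP", "5mdCTP"), (0.4, 0.3, 0.3)):
            se = math.sqrt(frac * (1 - frac) / 10000)
            assert abs(counts[lab] / 10000 - frac) < 4 * se

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            simulate_methyl_plate(10, (-0.1, 0.6, 0.5), seed=0)
        with pytest.raises(ValueError):
            simulate_methyl_plate(10, (0.5, 0.3, 0.3), seed=0)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_droplets=0),
            dict(capture_rate=0.0),
            dict(contamination_rate=1.5),
            dict(misidentify_rate=-0.1),
            dict(channel_map={"A": "x", "C": "x", "G": "y", "T": "z"}),
            dict(channel_map={"A": "x", "C": "y", "G": "z"}),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        base = dict(n_droplets=10, seed=0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            SimConfig(**base)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            simulate_release("", SimConfig(n_droplets=5, seed=0))
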