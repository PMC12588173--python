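"""Greenwood mapping, dendrite frequency transfer, semitone and rate metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cochleomap.errors import AttachmentError, DomainError, InvalidInputError
from cochleomap.geometry import AngleProfile, Centerline3D
from cochleomap.tonotopy import (
    DEFAULT_GREENWOOD,
    DendriteTrace,
    GreenwoodParams,
    TonotopicMap,
    attach_dendrites,
    fit_greenwood,
    greenwood_forward,
    greenwood_inverse,
    map_oc_frequencies,
    octave_bands,
    rate_of_change,
    semitone_difference,
    transfer_to_sg,
)

# printed OC/SG frequency pairs at 90-degree increments and their
# absolute semitone differences (the populated cells of the specimen table)
TABLE_PAIRS = [
    (0, 13876, 13996, 0.1),
    (90, 4951, 5119, 0.6),
    (180, 2590, 2645, 0.4),
    (270, 1493, 1467, 0.3),
    (360, 832, 834, 0.0),
    (450, 519, 463, 2.0),
    (540, 363, 336, 1.3),
    (630, 245, 202, 3.3),
    (720, 152, 20, 35.1),
]


class TestGreenwood:
    @pytest.mark.parametrize(
        "x,expected_hz",
        [
            ((34.10 - 21.38) / 34.10, 859),  # end of turn one
            ((34.10 - 29.75) / 34.10, 161),  # end of turn two
            (0.0, 20),  # apical terminus
            (1.0, 20677),  # basal limit
        ],
    )
    def test_forward_turn_end_frequencies(self, x, expected_hz):
        assert round(greenwood_forward(x)) == expected_hz

    def test_forward_k_zero_gives_A(self):
        p = GreenwoodParams(A=165.4, a=2.1, k=0.0)
        assert greenwood_forward(0.0, p) == pytest.approx(165.4)

    def test_forward_domain_error(self):
        with pytest.raises(DomainError):
            greenwood_forward(1.2)

    def test_inverse_apical_endpoint(self):
        assert greenwood_inverse(DEFAULT_GREENWOOD.f_min) == pytest.approx(0.0, abs=1e-12)

    def test_inverse_of_forward_half(self):
        assert greenwood_inverse(greenwood_forward(0.5)) == pytest.approx(0.5, abs=1e-12)

    def test_inverse_at_round_window_frequency(self):
        # basal-most OC frequency of the specimen table
        assert greenwood_inverse(13876.0) == pytest.approx(0.918, abs=5e-4)

    def test_round_trip_grid(self):
        x = np.linspace(0.0, 1.0, 1000)
        back = greenwood_inverse(greenwood_forward(x))
        assert np.allclose(back, x, atol=1e-12)

    def test_inverse_domain_error(self):
        with pytest.raises(DomainError):
            greenwood_inverse(10.0)


class TestFitGreenwood:
    def test_recovers_parameters_noiselessly(self):
        x = np.linspace(0.0, 1.0, 20)
        fit = fit_greenwood(np.stack([x, greenwood_forward(x)], axis=1))
        for got, true in [
            (fit.params.A, 165.4),
            (fit.params.a, 2.1),
            (fit.params.k, 0.88),
        ]:
            assert abs(got - true) / true < 1e-3
        assert fit.converged

    def test_too_few_samples(self):
        with pytest.raises(InvalidInputError):
            fit_greenwood([(0.0, 20.0), (0.5, 600.0), (1.0, 20000.0)])

    def test_nondistinct_x_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_greenwood([(0.1, 50.0)] * 5)

    def test_noisy_recovery_median_within_5pct(self):
        rng = np.random.default_rng(2024)
        x = np.linspace(0.0, 1.0, 50)
        f_true = greenwood_forward(x)
        ratios_A, ratios_a = [], []
        for _ in range(100):
            f = f_true * 10.0 ** rng.normal(0.0, 0.01, size=x.size)
            fit = fit_greenwood(np.stack([x, f], axis=1))
            ratios_A.append(fit.params.A / 165.4)
            ratios_a.append(fit.params.a / 2.1)
        assert abs(np.median(ratios_A) - 1.0) < 0.05
        assert abs(np.median(ratios_a) - 1.0) < 0.05


class TestMapOcFrequencies:
    @pytest.fixture()
    def straight_bm(self):
        s = np.array([0.0, 10.0, 21.38, 29.75, 34.10])
        pts = np.stack([s, np.zeros_like(s), np.zeros_like(s)], axis=1)
        bm = Centerline3D(pts, label="BM")
        return bm, AngleProfile(np.linspace(0.0, 1040.0, len(s)))

    def test_turn_end_frequencies(self, straight_bm):
        bm, angles = straight_bm
        m = map_oc_frequencies(bm, angles)
        assert round(m.freq_hz[2]) == 859
        assert round(m.freq_hz[3]) == 161

    def test_apex_equals_greenwood_at_zero(self, straight_bm):
        bm, angles = straight_bm
        m = map_oc_frequencies(bm, angles)
        assert m.freq_hz[-1] == pytest.approx(greenwood_forward(0.0), rel=1e-12)

    def test_strictly_decreasing_base_to_apex(self, straight_bm):
        bm, angles = straight_bm
        m = map_oc_frequencies(bm, angles)
        assert np.all(np.diff(m.freq_hz) < 0)

    def test_misaligned_angles_rejected(self, straight_bm):
        bm, _ = straight_bm
        with pytest.raises(InvalidInputError):
            map_oc_frequencies(bm, AngleProfile(np.zeros(3)))


class TestTransferToSg:
    def test_radial_dendrites_preserve_angle_frequency(self, preset_pipeline):
        oc, sg = preset_pipeline["oc_map"], preset_pipeline["sg_map"]
        onset = preset_pipeline["bundle"].spec.rotation_onset_deg
        below = sg.angle_deg < onset - 10.0
        assert below.sum() >= 10
        oc_f = oc.freq_at_angle(sg.angle_deg[below])
        assert np.allclose(oc_f, sg.freq_hz[below], rtol=5e-3)

    def test_apical_rotation_compresses_sg(self, preset_pipeline):
        sg, oc = preset_pipeline["sg_map"], preset_pipeline["oc_map"]
        assert sg.angle_deg[-1] <= 720.0 + 2.0
        assert oc.angle_deg[-1] >= 1040.0 - 2.0

    def test_record_conservation_and_order(self, preset_pipeline):
        b = preset_pipeline["bundle"]
        sub = b.dendrites[:5]
        sg_map = transfer_to_sg(
            preset_pipeline["oc_map"], sub, b.sg, preset_pipeline["sg_angles"]
        )
        assert len(sg_map.s) == 5
        assert np.all(np.diff(sg_map.s) > 0)

    def test_coincident_attachments_averaged_geometrically(self):
        s = np.linspace(0.0, 10.0, 11)
        pts = np.stack([s, np.zeros_like(s), np.zeros_like(s)], axis=1)
        oc = TonotopicMap(s, (10 - s) / 10, s * 10, 2000.0 * 2.0 ** (-s / 2.0))
        sg_line = Centerline3D(pts + [0.0, 1.0, 0.0], label="SG")
        angles = AngleProfile(s * 10)
        dd = [
            DendriteTrace(np.array([[0.0, 0, 0], [0.0, 1, 0]]), bm_attach=0.0, sg_attach=3.0),
            DendriteTrace(np.array([[4.0, 0, 0], [4.0, 1, 0]]), bm_attach=4.0, sg_attach=3.0),
            DendriteTrace(np.array([[8.0, 0, 0], [8.0, 1, 0]]), bm_attach=8.0, sg_attach=8.0),
        ]
        sg_map = transfer_to_sg(oc, dd, sg_line, angles)
        assert len(sg_map.s) == 2
        f1, f2 = oc.freq_at_s(0.0), oc.freq_at_s(4.0)
        assert sg_map.freq_hz[0] == pytest.approx(np.sqrt(f1 * f2), rel=1e-12)

    def test_detached_endpoint_raises(self, preset_pipeline):
        b = preset_pipeline["bundle"]
        stray = DendriteTrace(b.dendrites[0].points + np.array([0.0, 0.0, 30.0]))
        with pytest.raises(AttachmentError):
            attach_dendrites([stray], b.bm, b.sg)

    def test_needs_two_dendrites(self, preset_pipeline):
        b = preset_pipeline["bundle"]
        with pytest.raises(InvalidInputError):
            transfer_to_sg(
                preset_pipeline["oc_map"], b.dendrites[:1], b.sg,
                preset_pipeline["sg_angles"],
            )


class TestSemitones:
    @pytest.mark.parametrize("angle,oc,sg,expected", TABLE_PAIRS)
    def test_specimen_table_cells(self, angle, oc, sg, expected):
        assert round(semitone_difference(oc, sg), 1) == expected

    def test_identity_and_octave(self):
        assert semitone_difference(440.0, 440.0) == 0.0
        assert semitone_difference(880.0, 440.0) == pytest.approx(12.0)

    @given(st.floats(10.0, 2e4), st.floats(10.0, 2e4))
    def test_symmetry(self, f1, f2):
        assert semitone_difference(f1, f2) == pytest.approx(semitone_difference(f2, f1))

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            semitone_difference(0.0, 440.0)


class TestRateOfChange:
    def exp_map(self, delta=2.0, n=101):
        s = np.linspace(0.0, 20.0, n)
        return TonotopicMap(s, (20 - s) / 20, s * 50, 10000.0 * 2.0 ** (-s / delta))

    def test_exponential_map_constant_rate(self):
        delta = 2.0
        rp = rate_of_change(self.exp_map(delta), axis="length")
        assert np.allclose(rp.rate, 12.0 / delta, rtol=1e-2)

    def test_constant_frequency_zero_rate(self):
        s = np.linspace(0.0, 10.0, 50)
        m = TonotopicMap(s, (10 - s) / 10, s, np.full_like(s, 440.0))
        rp = rate_of_change(m, axis="length")
        assert np.allclose(rp.rate, 0.0, atol=1e-12)

    def test_integral_matches_total_span(self, preset_pipeline):
        oc = preset_pipeline["oc_map"]
        for axis in ("length", "angle"):
            rp = rate_of_change(oc, axis=axis)
            span = semitone_difference(oc.freq_hz[0], oc.freq_hz[-1])
            assert abs(rp.total_semitones() - span) / span < 0.02

    def test_angle_axis_units(self):
        rp = rate_of_change(self.exp_map(), axis="angle")
        assert rp.unit == "semitones/deg"

    def test_non_monotone_axis_rejected(self):
        s = np.array([0.0, 1.0, 2.0, 3.0])
        m = TonotopicMap(s, (3 - s) / 3, np.array([0.0, 10.0, 5.0, 20.0]),
                         1000.0 * 2.0 ** (-s))
        with pytest.raises(InvalidInputError):
            rate_of_change(m, axis="angle")


class TestOctaveBands:
    def synthetic_map(self):
        f = np.geomspace(20480.0, 20.0, 200)
        s = np.linspace(0.0, 30.0, 200)
        return TonotopicMap(s, (30 - s) / 30, s * 30, f)

    def test_counting_powers_of_two(self):
        bands = octave_bands(self.synthetic_map(), ref_hz=20.0)
        assert len(bands) == 11
        assert bands["freq_hz"].iloc[0] == pytest.approx(20.0)
        assert bands["freq_hz"].iloc[-1] == pytest.approx(20480.0)

    def test_positions_round_trip_through_inverse(self, preset_pipeline):
        oc = preset_pipeline["oc_map"]
        bands = octave_bands(oc, ref_hz=40.0)
        L = preset_pipeline["bundle"].bm.total_length
        x_from_pos = (L - bands["s_mm"].to_numpy()) / L
        x_from_freq = np.array([greenwood_inverse(f) for f in bands["freq_hz"]])
        assert np.allclose(x_from_pos, x_from_freq, atol=1e-6)

    def test_reversed_orientation_mirrors_positions(self):
        m = self.synthetic_map()
        rev = TonotopicMap(m.s, m.x[::-1], m.angle_deg, m.freq_hz[::-1], label="rev")
        b1 = octave_bands(m, 20.0)
        b2 = octave_bands(rev, 20.0)
        assert np.allclose(b1["freq_hz"], b2["freq_hz"])
        assert np.allclose(b2["s_mm"].to_numpy(), m.s[-1] - b1["s_mm"].to_numpy(), atol=1e-9)

    def test_band_semitone_conservation(self, preset_pipeline):
        oc = preset_pipeline["oc_map"]
        bands = octave_bands(oc, ref_hz=oc.freq_hz[-1])
        f = bands["freq_hz"].to_numpy()
        total = semitone_difference(f[0], f[-1])
        assert abs(sum(semitone_difference(f[i], f[i + 1]) for i in range(len(f) - 1)) - total) < 1e-9

    def test_reference_outside_range_rejected(self):
        with pytest.raises(DomainError):
            octave_bands(self.synthetic_map(), ref_hz=5.0)
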