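"""Frequency sweeps, peak detection and mode classification."""

import numpy as np
import pytest

import ocuvib as ov
from ocuvib.response import (
    FrequencyResponse,
    align_peak_frequencies,
    classify_mode,
    find_peaks,
    resonance_frequencies,
    sweep,
)


class TestSweep:
    def test_grid_arithmetic_141_points(self, flap_model, flap_frf):
        assert len(flap_frf.frequencies) == 141
        assert flap_frf.frequencies[0] == 50.0
        assert flap_frf.frequencies[-1] == 750.0

    def test_linearity_doubling_the_drive_doubles_every_amplitude(self, flap_frf):
        cfg = ov.FlapConfig(drive_pressure_pa=2.0)
        frf2 = sweep(ov.build_flap(cfg), 50.0, 750.0, 5.0)
        assert np.allclose(frf2.amplitude, 2.0 * flap_frf.amplitude, rtol=1e-9)

    def test_invalid_ranges_rejected(self, flap_model):
        with pytest.raises(ValueError):
            sweep(flap_model, 500.0, 100.0, 5.0)
        with pytest.raises(ValueError):
            sweep(flap_model, 50.0, 750.0, -1.0)

    def test_frf_invariants_enforced(self):
        with pytest.raises(ValueError):
            FrequencyResponse([1.0, 1.0, 2.0], [0, 0, 0], [0, 0, 0])
        with pytest.raises(ValueError):
            FrequencyResponse([1.0, 2.0, 3.0], [0, -1, 0], [0, 0, 0])

    def test_csv_round_trip(self, tmp_path, flap_frf):
        path = tmp_path / "frf.csv"
        flap_frf.to_csv(path)
        back = FrequencyResponse.from_csv(path)
        assert np.allclose(back.amplitude, flap_frf.amplitude)


class TestFindPeaks:
    def test_constant_frf_yields_no_peaks(self):
        f = np.arange(50.0, 200.0, 1.0)
        frf = FrequencyResponse(f, np.ones_like(f), np.zeros_like(f))
        assert find_peaks(frf) == []

    def test_three_lorentzians_located_within_1_hz(self):
        """Analytic oracle: sum of Lorentzians centred at 150/300/450 Hz."""
        f = np.arange(50.0, 600.0, 1.0)
        amp = np.zeros_like(f)
        for f0 in (150.0, 300.0, 450.0):
            amp += 1.0 / (1.0 + ((f - f0) / 20.0) ** 2)
        frf = FrequencyResponse(f, amp, np.zeros_like(f))
        peaks = find_peaks(frf)
        assert len(peaks) == 3
        for pk, f0 in zip(peaks, (150.0, 300.0, 450.0)):
            assert pk.frequency == pytest.approx(f0, abs=1.0)
            assert pk.width > 0

    def test_flap_shows_three_modes_between_50_and_750(self, flap_frf):
        assert len(find_peaks(flap_frf)) == 3

    def test_too_few_grid_points_rejected(self):
        frf = FrequencyResponse([1, 2, 3], [0, 1, 0], [0, 0, 0])
        with pytest.raises(ValueError):
            find_peaks(frf)

    def test_refining_the_grid_from_20_to_1_hz_loses_no_peaks(
        self, globe_model, globe_frf_1hz
    ):
        """The 20 Hz grid of the experiment must not show modes that the
        1 Hz grid loses (whole-globe model)."""
        coarse = find_peaks(sweep(globe_model, 50.0, 510.0, 20.0))
        fine = find_peaks(globe_frf_1hz)
        assert len(fine) >= len(coarse)


class TestModeClassification:
    def test_flap_harmonics_add_nodal_circles(self, flap_model, flap_frf):
        peaks = find_peaks(flap_frf)
        shapes = [classify_mode(flap_model, pk) for pk in peaks]
        assert shapes[0].nodal_circles == 0  # fundamental of a clamped disc
        assert shapes[1].nodal_circles == 1
        counts = [s.nodal_circles for s in shapes]
        assert counts == sorted(counts) and len(set(counts)) == len(counts)
        assert all(s.scleral_participation == 0.0 for s in shapes)

    def test_peaks_insensitive_to_smooth_symmetric_load_profile(self, flap_model):
        """Any smooth symmetric excitation finds the same resonances."""
        from ocuvib import fem

        base = resonance_frequencies(flap_model, 50.0, 750.0, 5.0, 1.0)
        tapered = ov.build_flap(ov.FlapConfig())
        mesh, dof = tapered.mesh, tapered.dof
        a = mesh.nodes[:, 0].max()
        load = np.zeros(dof.n_total, dtype=complex)
        for e, le in mesh.edge_sets["v1"]:
            nodes = mesh.edge_nodes(e, le)
            sd = dof.sdofs(nodes)
            taper = np.cos(0.5 * np.pi * mesh.nodes[nodes, 0] / a)
            load[sd[1::2]] += -taper  # z-forces, cosine-tapered
        tapered.load = load
        tapered._system = None
        alt = resonance_frequencies(tapered, 50.0, 750.0, 5.0, 1.0)
        assert len(alt) == len(base)
        for p, q in zip(base, alt):
            assert abs(p.frequency - q.frequency) / p.frequency < 0.005

    def test_elastic_limit_shifts_peaks_little_but_sharpens_them(self, flap_frf):
        """Removing the Prony term moves each resonance by < 3% while the
        peaks sharpen drastically (the finite widths are viscoelastic)."""
        damped = ov.build_flap(ov.FlapConfig())
        elastic = ov.build_flap(ov.FlapConfig(prony=()))
        pk_d = find_peaks(sweep(damped, 50.0, 750.0, 1.0))
        assert len(pk_d) >= 2
        for pk in pk_d:
            lo, hi = pk.frequency - 15.0, pk.frequency + 15.0
            local = sweep(elastic, lo, hi, 0.5)
            f_e = local.frequencies[int(np.argmax(local.amplitude))]
            assert abs(f_e - pk.frequency) / pk.frequency < 0.03
            # undamped response grows without bound as the grid approaches
            # the resonance: far taller than the viscoelastically capped peak
            assert local.amplitude.max() > 10.0 * pk.amplitude


class TestAlignment:
    def test_alignment_skips_missing_modes(self):
        ref = np.array([100.0, 200.0, 300.0])
        other = np.array([102.0, 298.0])
        out = align_peak_frequencies(ref, other)
        assert out[0] == 102.0
        assert np.isnan(out[1])
        assert out[2] == 298.0

    def test_alignment_is_order_preserving(self):
        ref = np.array([100.0, 200.0])
        other = np.array([95.0, 105.0, 201.0])
        out = align_peak_frequencies(ref, other)
        assert out[0] in (95.0, 105.0)
        assert out[1] == 201.0
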