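import numpy as np
import pytest

from trsfx import (
    AmplitudeSet,
    CoefficientSet,
    UnitCell,
    build_two_state_toy,
    calc_structure_factors,
    difference_coefficients,
    find_peaks,
    map_correlation,
    mix_states,
    space_group,
    synthesize_map,
    wilson_scale,
)
from trsfx.maps import DensityMap, expand_to_sphere
from trsfx.reflections import PhaseSet


@pytest.fixture(scope="module")
def dark_amplitudes(toy_sf):
    fd, _ = toy_sf
    return fd.to_amplitude_set("dark")


@pytest.fixture(scope="module")
def dark_phases(toy_sf):
    fd, _ = toy_sf
    return fd.to_phase_set()


class TestWilsonScale:
    def test_identity_target(self, dark_amplitudes):
        model, scaled = wilson_scale(dark_amplitudes, dark_amplitudes)
        assert model.k == pytest.approx(1.0, abs=1e-10)
        assert model.b == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(scaled.amp, dark_amplitudes.amp, rtol=1e-10)

    def test_recovers_constructed_scale_and_b(self, dark_amplitudes):
        # target built as |F_ref| / (2·exp(-10 s²/4)): fitted k = 2, B = 10 Å²
        s2 = 1.0 / dark_amplitudes.d**2
        target = AmplitudeSet(
            hkl=dark_amplitudes.hkl,
            amp=dark_amplitudes.amp / (2.0 * np.exp(-10.0 * s2 / 4.0)),
            sigma=dark_amplitudes.sigma, cell=dark_amplitudes.cell,
            spacegroup=dark_amplitudes.spacegroup, label="constructed",
        )
        model, scaled = wilson_scale(dark_amplitudes, target)
        assert model.k == pytest.approx(2.0, rel=1e-9)
        assert model.b == pytest.approx(10.0, abs=1e-8)
        np.testing.assert_allclose(scaled.amp, dark_amplitudes.amp, rtol=1e-9)

    def test_recovery_robust_to_multiplicative_noise(self, dark_amplitudes):
        # 2% noise: |k̂ - k| <= 0.02 k and |B̂ - B| <= 2 Å² over seeds 1-5
        s2 = 1.0 / dark_amplitudes.d**2
        k_true, b_true = 1.7, 6.0
        for seed in range(1, 6):
            rng = np.random.default_rng(seed)
            amp = dark_amplitudes.amp / (k_true * np.exp(-b_true * s2 / 4.0))
            amp = amp * (1.0 + rng.normal(0.0, 0.02, size=len(amp)))
            target = AmplitudeSet(hkl=dark_amplitudes.hkl, amp=amp,
                                  sigma=dark_amplitudes.sigma,
                                  cell=dark_amplitudes.cell,
                                  spacegroup=dark_amplitudes.spacegroup,
                                  label="noisy")
            model, _ = wilson_scale(dark_amplitudes, target)
            assert abs(model.k - k_true) <= 0.02 * k_true
            assert abs(model.b - b_true) <= 2.0

    def test_insufficient_overlap_names_bins(self, dark_amplitudes):
        small = AmplitudeSet(hkl=dark_amplitudes.hkl[:5],
                             amp=dark_amplitudes.amp[:5],
                             sigma=dark_amplitudes.sigma[:5],
                             cell=dark_amplitudes.cell,
                             spacegroup=dark_amplitudes.spacegroup, label="few")
        with pytest.raises(ValueError, match="common reflections"):
            wilson_scale(dark_amplitudes, small)


class TestDifferenceCoefficients:
    def test_self_difference_is_zero(self, dark_amplitudes, dark_phases):
        coeffs = difference_coefficients(dark_amplitudes, dark_amplitudes, dark_phases)
        np.testing.assert_array_equal(coeffs.values, 0.0)
        dmap = synthesize_map(coeffs, d_min=2.3)
        assert np.abs(dmap.values).max() == 0.0
        assert find_peaks(dmap, 0.1) == []

    def test_single_reflection_arithmetic(self):
        cell = UnitCell(10, 10, 10)
        sg = space_group("P1")
        mk = lambda amp, label: AmplitudeSet(hkl=[[1, 0, 0]], amp=[amp], sigma=[0.0],
                                             cell=cell, spacegroup=sg, label=label)
        phases = PhaseSet(hkl=[[1, 0, 0]], phase_deg=[90.0], cell=cell, spacegroup=sg)
        coeffs = difference_coefficients(mk(11.0, "light"), mk(10.0, "dark"), phases)
        assert coeffs.values[0] == pytest.approx(0.0 + 1.0j, abs=1e-12)

    def test_missing_phases_dropped_and_counted(self, dark_amplitudes, dark_phases):
        partial = PhaseSet(hkl=dark_phases.hkl[:100], phase_deg=dark_phases.phase_deg[:100],
                           cell=dark_phases.cell, spacegroup=dark_phases.spacegroup)
        coeffs = difference_coefficients(dark_amplitudes, dark_amplitudes, partial)
        assert len(coeffs) == 100
        assert coeffs.n_dropped == len(dark_amplitudes) - 100

    def test_disjoint_sets_raise(self, dark_amplitudes, dark_phases):
        cell = dark_amplitudes.cell
        sg = dark_amplitudes.spacegroup
        other = AmplitudeSet(hkl=[[40, 40, 40]], amp=[1.0], sigma=[0.0],
                             cell=cell, spacegroup=sg, label="disjoint")
        with pytest.raises(ValueError, match="share no reflections"):
            difference_coefficients(dark_amplitudes, other, dark_phases)

    def test_amplitude_difference_map_tracks_true_state_difference(self, toy_pair, toy_sf):
        # at α = 0.13 the amplitude-difference map correlates with the true
        # (complex-difference) ρ_M − ρ_dark density; the factor-of-two
        # underestimate affects its amplitude, not its pattern
        dark, m = toy_pair
        fd, fm = toy_sf
        fmix = mix_states(fd, fm, 0.13)
        coeffs = difference_coefficients(
            fmix.to_amplitude_set("mix"), fd.to_amplitude_set("dark"),
            fd.to_phase_set())
        amp_map = synthesize_map(coeffs, d_min=2.3)
        true_coeffs = CoefficientSet(fd.hkl, fm.f - fd.f, dark.cell, dark.spacegroup)
        true_map = synthesize_map(true_coeffs, d_min=2.3, shape=amp_map.shape)
        assert map_correlation(amp_map, true_map) >= 0.5


class TestMapSynthesis:
    def test_single_coefficient_is_cosine_wave(self):
        cell = UnitCell(10, 12, 14)
        sg = space_group("P1")
        f = 3.0 + 2.0j
        coeffs = CoefficientSet(hkl=[[2, 1, -1]], values=[f], cell=cell, spacegroup=sg)
        dmap = synthesize_map(coeffs, d_min=3.0)
        n1, n2, n3 = dmap.shape
        x, y, z = np.meshgrid(np.arange(n1) / n1, np.arange(n2) / n2,
                              np.arange(n3) / n3, indexing="ij")
        phase = 2 * np.pi * (2 * x + 1 * y - 1 * z)
        expected = (2.0 / cell.volume) * (f.real * np.cos(phase) + f.imag * np.sin(phase))
        np.testing.assert_allclose(dmap.values, expected, atol=1e-10)

    def test_zero_coefficients_give_zero_map(self):
        cell = UnitCell(10, 10, 10)
        coeffs = CoefficientSet(hkl=np.empty((0, 3), int), values=np.empty(0, complex),
                                cell=cell, spacegroup=space_group("P1"))
        dmap = synthesize_map(coeffs, d_min=3.0)
        assert dmap.sigma == 0.0
        assert np.all(dmap.values == 0.0)

    def test_parseval_identity(self, toy_sf):
        fd, _ = toy_sf
        coeffs = CoefficientSet.from_reflection_set(fd)
        dmap = synthesize_map(coeffs, d_min=2.3)
        v = fd.cell.volume
        sum_f2 = sum(abs(val) ** 2 for val in expand_to_sphere(coeffs).values())
        integral = (v / dmap.values.size) * np.sum(dmap.values**2)
        assert integral == pytest.approx(sum_f2 / v, rel=1e-6)

    def test_linearity(self, toy_sf):
        fd, fm = toy_sf
        c1 = CoefficientSet.from_reflection_set(fd)
        c2 = CoefficientSet.from_reflection_set(fm)
        combo = CoefficientSet(fd.hkl, 2.0 * fd.f - 0.7 * fm.f, fd.cell, fd.spacegroup)
        m_combo = synthesize_map(combo, d_min=2.3)
        m1 = synthesize_map(c1, d_min=2.3)
        m2 = synthesize_map(c2, d_min=2.3)
        np.testing.assert_allclose(m_combo.values,
                                   2.0 * m1.values - 0.7 * m2.values, atol=1e-10)

    def test_hexagonal_expansion_matches_p1_full_calculation(self, hex_toy):
        # synthesising from the P6_3 ASU must equal the map of the same atoms
        # treated as a P1 structure with symmetry copies written out
        from trsfx.toy import Atom, ToyModel
        dark, _ = hex_toy
        f63 = calc_structure_factors(dark, 3.0)
        m63 = synthesize_map(CoefficientSet.from_reflection_set(f63), d_min=3.0)
        expanded_atoms = []
        for op in dark.spacegroup.symops:
            for atom in dark.atoms:
                pos = (op.rot_array @ np.asarray(atom.frac) + op.trans_array) % 1.0
                expanded_atoms.append(Atom(atom.element, tuple(pos),
                                           atom.occupancy, atom.b_iso))
        p1_model = ToyModel(expanded_atoms, dark.cell, space_group("P1"), label="p1")
        fp1 = calc_structure_factors(p1_model, 3.0)
        mp1 = synthesize_map(CoefficientSet.from_reflection_set(fp1), d_min=3.0,
                             shape=m63.shape)
        np.testing.assert_allclose(m63.values, mp1.values, atol=1e-8 * m63.sigma + 1e-12)

    def test_friedel_violation_detected(self):
        cell = UnitCell(10, 10, 10)
        sg = space_group("P1")
        coeffs = CoefficientSet(hkl=[[1, 0, 0], [-1, 0, 0]],
                                values=[1.0 + 1.0j, 1.0 + 1.0j],  # not conjugates
                                cell=cell, spacegroup=sg)
        with pytest.raises(ValueError, match="inconsistent"):
            synthesize_map(coeffs, d_min=3.0)

    def test_grid_spacing_respects_dmin(self, toy_sf):
        fd, _ = toy_sf
        dmap = synthesize_map(CoefficientSet.from_reflection_set(fd), d_min=2.3)
        for n, length in zip(dmap.shape, (fd.cell.a, fd.cell.b, fd.cell.c)):
            assert length / n <= 2.3 / 3 + 1e-9


class TestPeakSearch:
    def test_zero_map_has_no_peaks(self):
        dmap = DensityMap(values=np.zeros((8, 8, 8)), cell=UnitCell(10, 10, 10))
        assert find_peaks(dmap, 3.0) == []

    def test_displaced_atom_peaks_localise(self, toy_pair, toy_sf):
        # true difference density: strongest positive peak near a new (M)
        # position, strongest negative near a vacated dark position
        dark, m = toy_pair
        fd, fm = toy_sf
        coeffs = CoefficientSet(fd.hkl, fm.f - fd.f, dark.cell, dark.spacegroup)
        dmap = synthesize_map(coeffs, d_min=2.3)
        peaks = find_peaks(dmap, 3.0)
        moved = [i for i in range(len(dark)) if dark.atoms[i].frac != m.atoms[i].frac]
        new_pos = np.array([m.atoms[i].frac for i in moved])
        old_pos = np.array([dark.atoms[i].frac for i in moved])
        top_pos = next(p for p in peaks if p.sign > 0)
        top_neg = next(p for p in peaks if p.sign < 0)
        d_new = dark.cell.min_image_distance(np.array(top_pos.frac)[None, :], new_pos)
        d_old = dark.cell.min_image_distance(np.array(top_neg.frac)[None, :], old_pos)
        assert d_new.min() <= 1.5
        assert d_old.min() <= 1.5

    def test_threshold_monotone(self, toy_pair, toy_sf):
        dark, _ = toy_pair
        fd, fm = toy_sf
        coeffs = CoefficientSet(fd.hkl, fm.f - fd.f, dark.cell, dark.spacegroup)
        dmap = synthesize_map(coeffs, d_min=2.3)
        counts = [len(find_peaks(dmap, thr)) for thr in (2.0, 3.0, 4.0, 5.0)]
        assert counts == sorted(counts, reverse=True)

    def test_peaks_sorted_and_annotated(self, toy_pair, toy_sf):
        dark, m = toy_pair
        fd, fm = toy_sf
        coeffs = CoefficientSet(fd.hkl, fm.f - fd.f, dark.cell, dark.spacegroup)
        peaks = find_peaks(synthesize_map(coeffs, d_min=2.3), 3.0, model=m)
        heights = [abs(p.height_sigma) for p in peaks]
        assert heights == sorted(heights, reverse=True)
        assert all(p.nearest_atom for p in peaks)
        assert all(np.isfinite(p.nearest_distance) for p in peaks)
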