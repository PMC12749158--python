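import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vasosyn.phenotypes import (
    Track,
    aspect_ratio_for_circularity,
    brdu_call,
    circularity,
    contraction_model,
    contractility_assay,
    displacement_rate,
    ellipse_circularity,
    ellipse_perimeter,
    filter_cells,
    gate_cell_cycle,
    link_tracks,
    lipid_compartments,
    lipid_score,
    metabolic_fluxes,
    normalized_rate,
    nuclear_perinuclear_ratio,
    ocr_params,
)
from vasosyn.simulate import simulate_dapi, simulate_ocr_trace, simulate_tracks


class TestCircularity:
    def test_circle_is_one(self):
        assert circularity(np.pi, 2 * np.pi) == pytest.approx(1.0, abs=1e-12)

    def test_unit_square(self):
        assert circularity(1.0, 4.0) == pytest.approx(np.pi / 4)

    def test_elongated_ellipse_matches_numeric_oracle(self):
        # 9.1:1 ellipse with Ramanujan perimeter
        assert ellipse_circularity(9.1) == pytest.approx(0.26, abs=0.01)

    def test_above_one_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            assert circularity(np.pi * 1.01, 2 * np.pi) == 1.0

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            circularity(0.0, 1.0)

    @given(st.floats(1.0, 20.0), st.floats(0.1, 50.0))
    @settings(max_examples=60, deadline=None)
    def test_scale_invariance(self, ratio, scale):
        a, b = ratio * scale, scale
        c_scaled = circularity(np.pi * a * b, ellipse_perimeter(a, b), clip=False)
        assert c_scaled == pytest.approx(ellipse_circularity(ratio), rel=1e-9)

    def test_strictly_decreasing_in_aspect_ratio(self):
        ratios = np.linspace(1, 20, 100)
        vals = [ellipse_circularity(r) for r in ratios]
        assert all(v1 > v2 for v1, v2 in zip(vals, vals[1:]))


class TestFilterCells:
    @pytest.mark.parametrize(
        "area,n_nuclei,kept",
        [(1000, 1, True), (300, 1, False), (1000, 2, False), (400, 1, True), (4000, 1, True), (4001, 1, False)],
    )
    def test_bounds_and_nuclei(self, area, n_nuclei, kept):
        df = pd.DataFrame({"area_um2": [area], "perimeter_um": [100.0], "n_nuclei": [n_nuclei]})
        assert (len(filter_cells(df)) == 1) is kept


class TestContractilityAssay:
    def test_identical_populations_zero_index(self, ellipse_objects):
        objs = filter_cells(ellipse_objects)
        mb, ma, idx = contractility_assay(objs, objs)
        assert idx == pytest.approx(0.0)
        assert mb == ma

    def test_printed_medians_arithmetic(self):
        # medians 0.26 -> 0.37 give a contraction index of ~0.423
        assert (0.37 - 0.26) / 0.26 == pytest.approx(0.423, abs=1e-3)

    def test_rounder_after_population_positive_index(self):
        before = pd.DataFrame(
            {"area_um2": [1000.0] * 3, "perimeter_um": [250.0] * 3, "n_nuclei": [1] * 3}
        )
        after = pd.DataFrame(
            {"area_um2": [1000.0] * 3, "perimeter_um": [180.0] * 3, "n_nuclei": [1] * 3}
        )
        _, _, idx = contractility_assay(before, after)
        assert idx > 0

    def test_empty_errors(self, ellipse_objects):
        with pytest.raises(ValueError):
            contractility_assay(ellipse_objects.iloc[:0], ellipse_objects)


class TestContractionModel:
    def test_zero_shortening_identity(self):
        cb, ca = contraction_model(5.0, 0.0)
        assert ca == pytest.approx(cb)

    def test_calibrated_baseline_volume_mode(self):
        r = aspect_ratio_for_circularity(0.26)
        cb, ca = contraction_model(r, 0.20, mode="volume_conserving_3d")
        assert cb == pytest.approx(0.26, abs=1e-6)
        assert 0.33 <= ca <= 0.41

    @pytest.mark.parametrize("mode", ["area_conserving_2d", "volume_conserving_3d"])
    def test_contraction_increases_circularity(self, mode):
        for r in (2.0, 5.0, 9.2, 15.0):
            for s in (0.05, 0.2, 0.4):
                cb, ca = contraction_model(r, s, mode=mode)
                assert ca > cb

    def test_circle_degenerate_case(self):
        # a shortened circle stays a (swapped-axis) ellipse in the conserving
        # modes, so circularity drops below 1 for all three modes
        for mode in ("area_conserving_2d", "volume_conserving_3d", "width_constant"):
            cb, ca = contraction_model(1.0, 0.2, mode=mode)
            assert cb == pytest.approx(1.0)
            assert ca < 1.0

    def test_invalid_ratio_errors(self):
        with pytest.raises(ValueError):
            contraction_model(0.5, 0.2)


class TestCellCycleGating:
    def test_single_value_all_g1(self):
        with pytest.warns(UserWarning, match="nuclei"):
            gates = gate_cell_cycle(np.full(50, 1000.0))
        assert gates.fractions[0] == pytest.approx(1.0)

    def test_mixture_recovery(self):
        integrals, _ = simulate_dapi(5000, (0.6, 0.2, 0.2), cv=0.05, seed=12)
        gates = gate_cell_cycle(integrals)
        assert gates.fractions[0] == pytest.approx(0.6, abs=0.03)
        assert gates.fractions[1] == pytest.approx(0.2, abs=0.03)
        assert gates.fractions[2] == pytest.approx(0.2, abs=0.03)

    def test_fractions_sum_to_one(self):
        integrals, _ = simulate_dapi(2000, (0.7, 0.1, 0.2), cv=0.08, seed=3)
        gates = gate_cell_cycle(integrals)
        assert sum(gates.fractions) == pytest.approx(1.0)

    def test_debris_excluded(self):
        integrals, _ = simulate_dapi(1000, (0.6, 0.2, 0.2), cv=0.05, seed=5)
        with_debris = np.concatenate([integrals, np.full(50, 1.0), np.full(50, 10_000.0)])
        gates = gate_cell_cycle(with_debris)
        assert gates.n_excluded >= 100

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            gate_cell_cycle([])


class TestBrdU:
    def test_null_sample_positive_at_quantile_complement(self):
        rng = np.random.default_rng(0)
        control = rng.normal(100, 10, 20_000)
        thr, frac = brdu_call(control, control, quantile=0.99)
        assert frac == pytest.approx(0.01, abs=0.002)

    def test_fully_shifted_sample(self):
        control = np.linspace(0, 1, 100)
        thr, frac = brdu_call(np.full(50, 10.0), control)
        assert frac == 1.0

    def test_known_positive_fraction_recovered(self):
        rng = np.random.default_rng(1)
        control = rng.normal(100, 10, 10_000)
        sample = np.concatenate(
            [rng.normal(100, 10, 7000), rng.normal(200, 10, 3000)]
        )
        _, frac = brdu_call(sample, control)
        assert frac == pytest.approx(0.30 + 0.7 * 0.01, abs=0.02)

    def test_mean_sd_alternative(self):
        control = np.random.default_rng(2).normal(100, 10, 5000)
        thr, _ = brdu_call(control, control, method="mean_sd")
        assert thr == pytest.approx(130, abs=2)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            brdu_call([], [1.0])


class TestLipid:
    def make_objects(self, n, intensity=10.0, area=100.0, x=0.0, y=0.0):
        return pd.DataFrame(
            {
                "ch_red_mean": [intensity] * n,
                "area_um2": [area] * n,
                "x_um": [x] * n,
                "y_um": [y] * n,
            }
        )

    def test_direct_formula(self):
        assert lipid_score(self.make_objects(5), 50) == pytest.approx(100.0)

    def test_no_objects_zero(self):
        assert lipid_score(self.make_objects(0), 50) == 0.0

    def test_linear_in_object_count(self):
        s1 = lipid_score(self.make_objects(5), 50)
        s2 = lipid_score(self.make_objects(10), 50)
        assert s2 == pytest.approx(2 * s1)

    def test_zero_nuclei_errors(self):
        with pytest.raises(ValueError):
            lipid_score(self.make_objects(5), 0)

    def test_compartment_split(self):
        nuclei = pd.DataFrame({"x_um": [0.0], "y_um": [0.0], "area_um2": [np.pi * 25]})
        near = self.make_objects(4, x=2.0, y=0.0)  # within r_eq(5) + 5
        far = self.make_objects(4, x=100.0, y=0.0)
        peri, periph = lipid_compartments(near, nuclei)
        assert periph == 0.0 and peri > 0
        peri, periph = lipid_compartments(far, nuclei)
        assert peri == 0.0 and periph > 0
        both = pd.concat([near, far], ignore_index=True)
        peri, periph = lipid_compartments(both, nuclei)
        assert peri == pytest.approx(periph)


class TestOCR:
    def test_worked_example(self):
        trace = pd.DataFrame(
            {
                "time_min": range(4),
                "ocr": [100.0, 40.0, 180.0, 20.0],
                "phase": ["baseline", "oligomycin", "fccp", "rot_aa"],
            }
        )
        p = ocr_params(trace)
        assert p.nmoc == 20 and p.br == 80 and p.pl == 20
        assert p.atp_ocr == 60 and p.max_ocr == 160
        assert p.coupling_methods == pytest.approx(0.6)
        assert p.coupling_results == pytest.approx(0.75)
        assert p.utilization == pytest.approx(0.5)
        assert p.flags == ()

    def test_perfect_coupling_limit(self):
        trace = simulate_ocr_trace(br=80, pl=0, nmoc=20, max_ocr=160)
        p = ocr_params(trace)
        assert p.atp_ocr == pytest.approx(p.br)
        assert p.coupling_results == pytest.approx(1.0)

    def test_flat_trace_flagged(self):
        trace = simulate_ocr_trace(br=0, pl=0, nmoc=50, max_ocr=0)
        p = ocr_params(trace)
        assert "nonpositive_basal_respiration" in p.flags

    def test_leak_exceeding_basal_flagged(self):
        trace = simulate_ocr_trace(br=10, pl=30, nmoc=20, max_ocr=100)
        p = ocr_params(trace)
        assert "proton_leak_exceeds_basal" in p.flags

    def test_missing_phase_errors(self):
        trace = pd.DataFrame({"time_min": [0], "ocr": [1.0], "phase": ["baseline"]})
        with pytest.raises(ValueError, match="phase"):
            ocr_params(trace)

    def test_algebraic_identities_random(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            br, pl, nmoc, mx = rng.uniform(1, 200, 4)
            pl = min(pl, br)
            p = ocr_params(simulate_ocr_trace(br=br, pl=pl, nmoc=nmoc, max_ocr=mx))
            assert p.br + p.nmoc == pytest.approx(p.ocr_baseline)
            assert p.atp_ocr + p.pl == pytest.approx(p.br)
            assert 0 <= p.coupling_methods <= 1


class TestTracks:
    def test_stationary_nuclei_zero_displacement(self):
        frames = simulate_tracks(5, speed_um_h=0.0, n_frames=3, dt_h=2.0, seed=0)
        tracks = link_tracks(frames, max_step=10.0)
        assert len(tracks) == 5
        for t in tracks:
            assert displacement_rate(t, 0.0, 4.0) == pytest.approx(0.0)

    def test_three_four_five_displacement(self):
        t = Track(0, [0.0, 1.0], [0.0, 3.0], [0.0, 4.0])
        assert displacement_rate(t, 0.0, 1.0) == pytest.approx(5.0)

    def test_closed_loop_net_zero(self):
        t = Track(0, [0.0, 1.0, 2.0], [0.0, 5.0, 0.0], [0.0, 5.0, 0.0])
        assert displacement_rate(t, 0.0, 2.0) == 0.0

    def test_directed_motion_recovers_speed(self):
        frames = simulate_tracks(8, speed_um_h=5.0, n_frames=3, dt_h=2.0, seed=1, directed=True)
        tracks = link_tracks(frames, max_step=50.0)
        rates = [displacement_rate(t, 0.0, 4.0) for t in tracks]
        assert np.mean(rates) == pytest.approx(5.0, rel=1e-6)

    def test_crossing_identities_preserved(self):
        # two nuclei far apart moving small steps keep their identities
        frames = pd.DataFrame(
            {
                "time_h": [0, 0, 1, 1],
                "x_um": [0.0, 100.0, 2.0, 98.0],
                "y_um": [0.0, 0.0, 0.0, 0.0],
            }
        )
        tracks = link_tracks(frames, max_step=10.0)
        assert len(tracks) == 2
        assert all(len(t.times) == 2 for t in tracks)

    def test_step_cap_breaks_links(self):
        frames = pd.DataFrame(
            {"time_h": [0, 1], "x_um": [0.0, 50.0], "y_um": [0.0, 0.0]}
        )
        assert link_tracks(frames, max_step=10.0) == []

    def test_rotation_translation_invariance(self):
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        pts = np.array([[0.0, 0.0], [3.0, 4.0]])
        moved = pts @ rot.T + np.array([12.0, -7.0])
        t1 = Track(0, [0.0, 2.0], pts[:, 0], pts[:, 1])
        t2 = Track(0, [0.0, 2.0], moved[:, 0], moved[:, 1])
        assert displacement_rate(t1, 0, 2) == pytest.approx(displacement_rate(t2, 0, 2))


class TestPlateAssays:
    @pytest.mark.parametrize(
        "consumed,produced,expected", [(2.0, 4.0, 1.0), (2.0, 0.0, 0.0), (2.0, 2.0, 0.5)]
    )
    def test_glycolytic_index(self, consumed, produced, expected):
        c, p, idx = metabolic_fluxes(10.0, 10.0 - consumed, 1.0, 1.0 + produced, 1.0)
        assert c == pytest.approx(consumed)
        assert p == pytest.approx(produced)
        assert idx == pytest.approx(expected)

    def test_no_consumption_flagged_nan(self):
        _, _, idx = metabolic_fluxes(10.0, 10.0, 1.0, 2.0, 1.0)
        assert np.isnan(idx)

    def test_zero_protein_errors(self):
        with pytest.raises(ValueError):
            metabolic_fluxes(10, 8, 1, 2, 0.0)

    @pytest.mark.parametrize(
        "f1,f2,t1,t2,prot,expected", [(100, 160, 30, 60, 2, 1.0), (100, 100, 30, 60, 2, 0.0), (160, 100, 30, 60, 2, -1.0)]
    )
    def test_normalized_rate(self, f1, f2, t1, t2, prot, expected):
        assert normalized_rate(f1, f2, t1, t2, prot) == pytest.approx(expected)

    def test_bad_time_order_errors(self):
        with pytest.raises(ValueError):
            normalized_rate(1, 2, 60, 30, 1)

    @pytest.mark.parametrize(
        "nuc,ring,bg,expected", [(30, 20, 10, 2.0), (20, 20, 10, 1.0), (10, 30, 0, 1 / 3)]
    )
    def test_nuclear_perinuclear_ratio(self, nuc, ring, bg, expected):
        assert nuclear_perinuclear_ratio(nuc, ring, bg) == pytest.approx(expected)

    def test_ring_at_background_flagged(self):
        assert np.isnan(nuclear_perinuclear_ratio(30, 10, 10))
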