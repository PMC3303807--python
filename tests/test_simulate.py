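"""Synthetic-plate generator: geometry, rendering, ground-truth consistency."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from emtscreen import (
    ColonySpec,
    EffectModel,
    PackingError,
    RenderSpec,
    SimulationModel,
    rescale_to_spread,
    render_well,
    sample_colony,
    simulate_plate,
    simulate_well,
    spreading_coefficient,
)

from .conftest import sp_bruteforce


class TestColonySpec:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ColonySpec(n_cells=0)
        with pytest.raises(ValueError):
            ColonySpec(n_cells=5, target_sp=0.0)
        with pytest.raises(ValueError):
            ColonySpec(target_sp=-1.0)
        with pytest.raises(ValueError):
            ColonySpec(placement_model="ring")


class TestSampleColony:
    def test_single_cell_at_center(self):
        spec = ColonySpec(n_cells=1, center=(100.0, 200.0), target_sp=0.0)
        pts = sample_colony(spec, seed=0)
        assert pts.shape == (1, 2)
        assert tuple(pts[0]) == (100.0, 200.0)

    def test_rescale_forces_exact_sp(self):
        # four points at (+-a, +-a) rescaled to sp = 100 exactly
        a = 37.0
        pts = np.array([(a, a), (a, -a), (-a, a), (-a, -a)]) + [500, 500]
        scaled = rescale_to_spread(pts, 100.0)
        assert spreading_coefficient(scaled) == pytest.approx(100.0, rel=1e-12)

    @pytest.mark.parametrize(
        "model,n,sp", [("uniform_disk", 500, 200.0), ("gaussian", 300, 250.0)]
    )
    def test_sp_hits_target(self, model, n, sp):
        spec = ColonySpec(
            n_cells=n, center=(1600, 1600), target_sp=sp, placement_model=model
        )
        pts = sample_colony(spec, seed=7)
        assert len(pts) == n
        # independent brute-force evaluation, within 5% of target
        assert 0.95 * sp <= sp_bruteforce(pts) <= 1.05 * sp

    def test_min_separation_respected(self):
        spec = ColonySpec(n_cells=300, center=(1600, 1600), target_sp=300.0,
                          min_separation=12.0)
        pts = sample_colony(spec, seed=3)
        d, _ = cKDTree(pts).query(pts, k=2)
        assert d[:, 1].min() >= 12.0

    def test_deterministic_given_seed(self):
        spec = ColonySpec(n_cells=150, center=(800, 800), target_sp=120.0)
        a = sample_colony(spec, seed=11)
        b = sample_colony(spec, seed=11)
        assert np.array_equal(a, b)
        c = sample_colony(spec, seed=12)
        assert not np.array_equal(a, c)

    def test_infeasible_packing_raises(self):
        # 500 hard disks of radius 25 um cannot fit in a ~50 um spot
        spec = ColonySpec(n_cells=500, center=(500, 500), target_sp=35.0,
                          min_separation=50.0)
        with pytest.raises(PackingError):
            sample_colony(spec, seed=0)


class TestRenderWell:
    def test_noiseless_blob_peaks_at_nucleus(self, render_small):
        render = RenderSpec(
            image_shape=render_small.image_shape,
            noise_sd=0.0,
            background_gradient_amplitude=0.0,
            background_offset=0.0,
            n_outlier_cells=0,
        )
        # field 0 centre lands on an exact pixel sample point
        pos = np.array([[128 * render.pixel_size, 128 * render.pixel_size]])
        f1, _, _ = render_well(pos, pos, render, seed=0)
        field0 = f1[0].pixels
        assert field0.max() == pytest.approx(render.nucleus_peak_intensity)
        assert np.unravel_index(np.argmax(field0), field0.shape) == (128, 128)

    def test_empty_well_is_background_noise_only(self, render_small):
        empty = np.empty((0, 2))
        f1, f2, truth = render_well(empty, empty, render_small, seed=1)
        assert truth.count_t1 == truth.count_t2 == 0
        from emtscreen import measure_well, segment_well

        well, cent = segment_well([f.pixels for f in f1])
        meas = measure_well(well.labels, cent)
        assert meas.cell_count == 0
        assert "empty_well" in meas.flags

    def test_out_of_bounds_position_names_well(self, render_small):
        pos = np.array([[1e6, 50.0]])
        with pytest.raises(ValueError, match="well 'C07'"):
            render_well(pos, pos, render_small, seed=0, well_id="C07")

    def test_tiling_reassembles_montage_exactly(self, render_small):
        rng = np.random.default_rng(0)
        pos = rng.uniform(100, 700, size=(30, 2))
        f1, _, _ = render_well(pos, pos, render_small, seed=2)
        fr, fc = render_small.image_shape
        montage = np.zeros((2 * fr, 2 * fc))
        for f in f1:
            r0, c0 = (f.field_index // 2) * fr, (f.field_index % 2) * fc
            montage[r0 : r0 + fr, c0 : c0 + fc] = f.pixels
        # re-render whole montage with the same substream: must be identical
        from emtscreen.simulate import render_montage

        rng2 = np.random.default_rng([2, 1])
        direct = render_montage(pos, render_small, rng2)
        assert np.array_equal(montage, direct)

    def test_determinism(self, render_small):
        pos = np.array([[400.0, 400.0], [500.0, 380.0]])
        a1, a2, _ = render_well(pos, pos, render_small, seed=9)
        b1, b2, _ = render_well(pos, pos, render_small, seed=9)
        for fa, fb in zip(a1 + a2, b1 + b2):
            assert np.array_equal(fa.pixels, fb.pixels)


class TestSimulateWell:
    def test_ground_truth_self_consistency(self, simulated_well):
        _, _, truth = simulated_well
        c1 = truth.centers_t1[truth.is_colony_t1]
        c2 = truth.centers_t2[truth.is_colony_t2]
        assert spreading_coefficient(c1) == pytest.approx(truth.sp_t1, abs=1e-12)
        assert spreading_coefficient(c2) == pytest.approx(truth.sp_t2, abs=1e-12)
        assert truth.cdr == pytest.approx(truth.sp_t2 / truth.sp_t1, abs=1e-12)
        assert truth.ccr == pytest.approx(truth.count_t2 / truth.count_t1, abs=1e-12)

    def test_growth_and_dispersion_targets(self, colony_small, render_small):
        _, _, truth = simulate_well(
            colony_small, render_small, seed=8, cdr_true=2.2, ccr_true=2.0
        )
        assert truth.count_t1 == 200
        assert truth.count_t2 == 400
        assert truth.cdr == pytest.approx(2.2, rel=1e-9)

    def test_outliers_marked(self, simulated_well, render_small):
        _, _, truth = simulated_well
        n_out = (~truth.is_colony_t1).sum()
        assert n_out == render_small.n_outlier_cells
        # outliers lie well away from every colony cell at T1
        colony = truth.centers_t1[truth.is_colony_t1]
        outl = truth.centers_t1[~truth.is_colony_t1]
        d, _ = cKDTree(colony).query(outl)
        assert d.min() >= 80.0


class TestEffectModel:
    def test_midpoint_at_ic50(self):
        eff = EffectModel(ic50=1e-7, hill=1.3)
        assert eff.cdr_pct(1e-7) == pytest.approx(50.0)

    def test_zero_dose_is_full_dispersion(self):
        assert EffectModel(ic50=1e-7).cdr_pct(0.0) == 100.0


class TestSimulatePlate:
    def test_layout_without_controls_rejected(self):
        layout = pd.DataFrame(
            [("P1", "A02", "test", "X", 1e-6, "EGF")],
            columns=["plate", "well", "role", "compound_id", "concentration", "growth_factor"],
        )
        with pytest.raises(ValueError, match="control"):
            simulate_plate(layout, SimulationModel(), seed=0)

    def test_truth_table_roles(self, mini_plate_layout, colony_small, render_small, tmp_path):
        model = SimulationModel(
            effects={"CPD_A": EffectModel(ic50=5e-7), "CPD_B": EffectModel(ic50=1e-3)}
        )
        _, truth = simulate_plate(
            mini_plate_layout, model, colony=colony_small, render=render_small,
            seed=4, out_dir=tmp_path,
        )
        neg = truth[truth["role"] == "negative_control"]
        pos = truth[truth["role"] == "positive_control"]
        assert (neg["cdr_pct_true"] == 100.0).all()
        assert (pos["cdr_pct_true"] == 0.0).all()
        # potent compound below, inert compound near full dispersion
        a = truth[truth["compound_id"] == "CPD_A"]["cdr_pct_true"]
        b = truth[truth["compound_id"] == "CPD_B"]["cdr_pct_true"]
        assert (a < 50).all() and (b > 90).all()
        # artefacts on disk: images + manifest + ground truth
        assert (tmp_path / "manifest.csv").exists()
        assert (tmp_path / "ground_truth_wells.csv").exists()
        assert (tmp_path / "P1_A01_T1_f0.tif").exists()
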