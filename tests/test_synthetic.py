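"""Generator correctness: analytic truths, determinism, and round trips."""

import numpy as np
import pandas as pd
import pytest

from wormdart.chip import ChannelGeometry, d1_geometry, minimal_plan
from wormdart.stats import fourpl
from wormdart.synthetic import (
    ConcResponseSimConfig,
    EmbryoSpec,
    GeometryError,
    PhenotypeSimConfig,
    SyntheticWormSpec,
    plant_outliers,
    render_channel_stack,
    simulate_conc_response,
    simulate_well_plate,
)

GEO = d1_geometry()
PLAN = minimal_plan()


def constant_geometry(width=98.0, height=60.0, length=3000.0):
    return ChannelGeometry("const", ((0.0, width, height), (length, width, height)), length)


class TestRenderedTruth:
    def test_near_cylinder_volume_closed_form(self):
        # minimal tapering -> the tube is a cylinder of radius r and length L
        spec = SyntheticWormSpec(
            body_length=800.0, max_radius=25.0,
            taper_fraction=0.01, tip_radius_fraction=0.99,
            amplitude=0.0, axial_offset=300.0,
        )
        _, truth = render_channel_stack(spec, constant_geometry(), PLAN)
        expected = np.pi * 25.0**2 * 800.0
        assert truth.true_volume == pytest.approx(expected, rel=1e-3)

    def test_truth_volume_matches_independent_quadrature(self, fixture_suite):
        for fx in fixture_suite:
            if fx["kind"] != "full":
                continue
            spec = fx["spec"]
            u = np.linspace(0, 1, 40001)
            r = spec.radius_at(u)
            expected = np.pi * np.trapezoid(r**2, u * spec.body_length)
            assert fx["truth"].true_volume == pytest.approx(expected, rel=1e-3)

    def test_embryo_bookkeeping(self):
        embryos = (
            EmbryoSpec(500.0, 2.0, "early"),
            EmbryoSpec(600.0, -3.0, "late"),
            EmbryoSpec(700.0, 0.0, "early"),
        )
        spec = SyntheticWormSpec(embryos=embryos, seed=5)
        _, truth = render_channel_stack(spec, GEO, PLAN)
        assert truth.n_early == 2 and truth.n_late == 1
        assert truth.n_total == truth.n_early + truth.n_late == len(truth.embryo_records)
        stages = [r[3] for r in truth.embryo_records]
        assert stages == ["early", "late", "early"]

    def test_zero_embryos(self):
        _, truth = render_channel_stack(SyntheticWormSpec(embryos=()), GEO, PLAN)
        assert (truth.n_early, truth.n_late, truth.n_total) == (0, 0, 0)

    def test_deterministic_given_seed(self):
        spec = SyntheticWormSpec(seed=11, embryos=(EmbryoSpec(600.0, 1.0, "late"),))
        s1, t1 = render_channel_stack(spec, GEO, PLAN)
        s2, t2 = render_channel_stack(spec, GEO, PLAN)
        assert np.array_equal(s1.data, s2.data)
        assert np.array_equal(t1.mask, t2.mask)
        assert t1.embryo_records == t2.embryo_records

    def test_worm_wider_than_channel_raises(self):
        spec = SyntheticWormSpec(body_length=1400.0, max_radius=40.0,
                                 axial_offset=1400.0)
        with pytest.raises(GeometryError):
            render_channel_stack(spec, GEO, PLAN)

    def test_sharpness_peaks_at_true_best_focus(self, one_full_fixture):
        stack = one_full_fixture["stack"]
        truth = one_full_fixture["truth"]
        variances = [np.var(s) for s in stack.data]
        assert int(np.argmax(variances)) == truth.true_best_focus


class TestWellPlateSim:
    def test_zero_noise_reproduces_baselines_exactly(self):
        cfg = PhenotypeSimConfig(
            length_sd=0, area_sd=0, volume_sd=0, embryo_cv=0,
            early_fraction_kappa=float("inf"),
            between_replicate_cv=0, between_well_cv=0,
            early_mean=30, late_mean=15,
            worms_per_well=5, wells_per_condition=2, n_replicates=2,
        )
        worms, _ = simulate_well_plate(cfg)
        assert (worms["length_um"] == cfg.length_mean).all()
        assert (worms["volume_um3"] == cfg.volume_mean).all()
        assert (worms["early_count"] == 30).all()
        assert (worms["late_count"] == 15).all()
        assert (worms["total_count"] == 45).all()

    def test_default_baselines_recovered_at_large_n(self):
        cfg = PhenotypeSimConfig(n_replicates=5, wells_per_condition=10,
                                 worms_per_well=200, seed=42)
        worms, _ = simulate_well_plate(cfg)
        assert len(worms) == 10_000
        for col, mean in [
            ("length_um", cfg.length_mean), ("area_um2", cfg.area_mean),
            ("volume_um3", cfg.volume_mean),
            ("total_count", cfg.early_mean + cfg.late_mean),
        ]:
            sem = worms[col].std() / np.sqrt(len(worms))
            # hierarchical effects inflate the SEM of the grand mean
            tol = max(5 * sem, 3 * mean * np.sqrt(
                cfg.between_replicate_cv**2 / cfg.n_replicates
                + cfg.between_well_cv**2 / 50))
            assert abs(worms[col].mean() - mean) < tol

    def test_total_equals_early_plus_late(self):
        worms, _ = simulate_well_plate(PhenotypeSimConfig(seed=3))
        assert (worms["total_count"] == worms["early_count"] + worms["late_count"]).all()
        assert (worms[["early_count", "late_count"]] >= 0).all().all()

    def test_over_capacity_warns(self):
        with pytest.warns(UserWarning):
            PhenotypeSimConfig(worms_per_well=41)


class TestConcResponseSim:
    def test_noiseless_on_curve_and_top_at_zero(self):
        cfg = ConcResponseSimConfig(noise_cv=0.0, replicates=2)
        df = simulate_conc_response(cfg)
        expected = fourpl(df["concentration"].to_numpy(), cfg.top, cfg.bottom,
                          cfg.ec50, cfg.hill)
        assert np.allclose(df["value"], expected)
        assert (df.loc[df["concentration"] == 0, "value"] == cfg.top).all()

    def test_mean_converges_to_curve(self):
        cfg = ConcResponseSimConfig(noise_cv=0.05, replicates=1000, seed=9)
        df = simulate_conc_response(cfg)
        means = df.groupby("concentration")["value"].mean()
        for c, m in means.items():
            mu = fourpl(c, cfg.top, cfg.bottom, cfg.ec50, cfg.hill)
            assert m == pytest.approx(mu, rel=0.01)

    def test_validation(self):
        with pytest.raises(ValueError):
            ConcResponseSimConfig(concentrations=(0, 1, 2, 3))  # < 5 distinct
        with pytest.raises(ValueError):
            ConcResponseSimConfig(concentrations=(-1, 0, 1, 2, 3))
        with pytest.raises(ValueError):
            ConcResponseSimConfig(hill=-2)


class TestPlantOutliers:
    @pytest.fixture()
    def table(self):
        worms, _ = simulate_well_plate(
            PhenotypeSimConfig(n_replicates=2, wells_per_condition=2, seed=14))
        return worms

    def test_fraction_zero_unchanged(self, table):
        out, labels = plant_outliers(table, 0.0)
        pd.testing.assert_frame_equal(out, table)
        assert labels.sum() == 0

    def test_deterministic(self, table):
        o1, l1 = plant_outliers(table, 0.05, seed=7)
        o2, l2 = plant_outliers(table, 0.05, seed=7)
        pd.testing.assert_frame_equal(o1, o2)
        assert np.array_equal(l1, l2)

    def test_counts_stay_consistent(self, table):
        out, labels = plant_outliers(table, 0.1, displacement=10, seed=3)
        assert labels.sum() == round(0.1 * len(table))
        assert (out["total_count"] == out["early_count"] + out["late_count"]).all()
        assert (out["total_count"] >= 0).all()
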