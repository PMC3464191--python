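"""Binned occupancy pairing, OLS fits, cavity tables, and the pipeline."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chancav.errors import AlignmentError, ChanCavError, FitError
from chancav.pipeline import PipelineConfig, run_pipeline
from chancav.stats import (LinearFit, bin_paired_occupancy, cavity_table,
                           linear_fit, paired_linear_fit)


class TestBinning:
    def test_bin_width_of_frame_spacing_is_identity(self):
        t = np.arange(10.0)
        x = np.arange(10.0) ** 2
        y = -x
        p = bin_paired_occupancy(t, x, y, 1.0)
        assert np.allclose(p.x, x)
        assert np.allclose(p.y, y)

    def test_constant_series_gives_repeated_pair(self):
        t = np.arange(20.0)
        p = bin_paired_occupancy(t, np.full(20, 3.0), np.full(20, 7.0), 5.0)
        assert np.allclose(p.x, 3.0)
        assert np.allclose(p.y, 7.0)

    def test_random_series_matches_manual_block_means(self):
        rng = np.random.default_rng(4)
        t = np.arange(40.0)
        x, y = rng.random(40), rng.random(40)
        p = bin_paired_occupancy(t, x, y, 10.0)
        assert len(p.x) == 4
        for b in range(4):
            assert p.x[b] == pytest.approx(x[10 * b:10 * (b + 1)].mean())
            assert p.y[b] == pytest.approx(y[10 * b:10 * (b + 1)].mean())

    def test_mismatched_series_raise(self):
        with pytest.raises(AlignmentError):
            bin_paired_occupancy(np.arange(5.0), np.zeros(5), np.zeros(4), 1.0)


class TestLinearFit:
    def test_exact_line(self):
        x = np.arange(10.0)
        f = linear_fit(x, 2.0 * x + 1.0)
        assert f.slope == pytest.approx(2.0, abs=1e-12)
        assert f.intercept == pytest.approx(1.0, abs=1e-12)
        assert f.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_independent_y_has_near_zero_r2(self):
        rng = np.random.default_rng(8)
        x = rng.random(5000)
        y = rng.random(5000)
        assert linear_fit(x, y).r_squared < 0.01

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(9)
        x = rng.random(50)
        y = 1.5 * x - 0.3 + rng.normal(scale=0.2, size=50)
        f = linear_fit(x, y)
        A = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert f.slope == pytest.approx(beta[0], abs=1e-10)
        assert f.intercept == pytest.approx(beta[1], abs=1e-10)
        resid = y - A @ beta
        r2 = 1 - (resid ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert f.r_squared == pytest.approx(r2, abs=1e-12)
        # OLS standard errors from the textbook formulas
        s2 = (resid ** 2).sum() / (len(x) - 2)
        cov = s2 * np.linalg.inv(A.T @ A)
        assert f.slope_se == pytest.approx(np.sqrt(cov[0, 0]), abs=1e-10)
        assert f.intercept_se == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-10)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_r2_equals_squared_pearson(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=30)
        y = rng.normal(size=30) + 0.5 * x
        f = linear_fit(x, y)
        r = np.corrcoef(x, y)[0, 1]
        assert abs(f.r_squared - r ** 2) < 1e-12

    def test_degenerate_inputs_raise(self):
        with pytest.raises(FitError):
            linear_fit(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        with pytest.raises(FitError):
            linear_fit(np.full(10, 2.0), np.arange(10.0))


class TestCavityTable:
    def test_constant_cavities(self):
        per_cav = {f"intra_{k}": {"volume": (100.0, 0.0)} for k in range(5)}
        tab = cavity_table(per_cav)
        assert list(tab.columns) == [*per_cav.keys(), "Average"]
        assert (tab.loc["volume"][:-1] == "100.0±0.0").all()
        assert tab.loc["volume", "Average"] == "100.0±0.0"

    def test_average_is_mean_of_cavity_means(self):
        per_cav = {f"c{k}": {"ligand": (float(k), 0.5)} for k in range(5)}
        tab = cavity_table(per_cav)
        assert tab.loc["ligand", "Average"].startswith("2.0±")

    def test_empty_cavity_row_pattern(self):
        per_cav = {"c0": {"ligand": (0.0, 0.0)}, "c1": {"ligand": (1.2, 0.4)}}
        tab = cavity_table(per_cav)
        assert tab.loc["ligand", "c0"] == "0.0±0.0"

    def test_missing_cavity_marked(self):
        per_cav = {"c0": {"volume": (10.0, 1.0)}, "c1": {}}
        tab = cavity_table(per_cav)
        assert tab.loc["volume", "c1"] == "missing"

    def test_average_sd_from_subunit_averaged_series(self):
        rng = np.random.default_rng(2)
        series = {f"c{k}": {"v": rng.random(20)} for k in range(3)}
        per_cav = {cid: {"v": (s["v"].mean(), s["v"].std())}
                   for cid, s in series.items()}
        tab = cavity_table(per_cav, per_cavity_series=series)
        stacked = np.mean([series[f"c{k}"]["v"] for k in range(3)], axis=0)
        expected = f"{stacked.mean():.1f}±{stacked.std():.1f}"
        assert tab.loc["v", "Average"] == expected


class TestPipeline:
    @pytest.fixture(scope="class")
    def tiny_cfg(self):
        return PipelineConfig(
            n_frames=30, dt_ns=1.0, seed=21,
            pore_stride_frames=10, pore_z_step=2.0,
            cavity_stride_ns=10.0, mc_iterations=2000, bootstrap=10,
            bin_width_frames=3, max_lag_fraction=0.4,
            spec_overrides={
                "wall_ring_step": 1.0, "body_lattice": 2.0,
                "shell_spacing": 0.8,
                "kink_angles_deg": [15.0, 0.0, 0.0, 0.0, 0.0],
                "ligand": {"count": 10, "tau_bound": 20.0,
                           "tau_unbound": 60.0},
                "water": {"bulk_count": 200}})

    @pytest.fixture(scope="class")
    def tiny_report(self, tiny_cfg, tmp_path_factory):
        out = tmp_path_factory.mktemp("report")
        return run_pipeline(tiny_cfg, out), out

    def test_report_sections_present(self, tiny_report):
        report, out = tiny_report
        for key in ("geometry", "pore", "cavities", "occupancy", "kinetics",
                    "statistics", "ground_truth", "config"):
            assert key in report
        assert (out / "report.json").exists()
        assert (out / "consensus_frequency.dx").exists()

    def test_kink_angle_recovered(self, tiny_report):
        report, _ = tiny_report
        per_chain = report["geometry"]["kink_per_chain_deg"]
        assert per_chain["A"] == pytest.approx(15.0, abs=1.0)
        assert per_chain["B"] == pytest.approx(0.0, abs=1.0)

    def test_ten_cavities_with_volumes(self, tiny_report):
        report, _ = tiny_report
        vols = {k: v for k, v in report["cavities"].items() if "volume_A3" in v}
        assert len(vols) == 10

    def test_anticorrelations_have_negative_slope(self, tiny_report):
        report, _ = tiny_report
        st = report["statistics"]
        assert st["lipid_vs_ligand_intra"]["slope"] < 0
        assert st["water_vs_ligand_inter"]["slope"] < 0

    def test_rerun_is_deterministic(self, tiny_cfg, tiny_report, tmp_path):
        report1, _ = tiny_report
        report2 = run_pipeline(tiny_cfg, tmp_path / "again")
        assert json.dumps(report1, sort_keys=True, default=float) == \
            json.dumps(report2, sort_keys=True, default=float)

    def test_bad_stride_fails_with_stage_name(self, tiny_cfg, tmp_path):
        import dataclasses

        cfg = dataclasses.replace(tiny_cfg, cavity_stride_ns=500.0)
        with pytest.raises(ChanCavError, match="cavities"):
            run_pipeline(cfg, tmp_path / "bad")

    def test_config_yaml_round_trip(self, tiny_cfg, tmp_path):
        p = tmp_path / "cfg.yaml"
        tiny_cfg.to_yaml(p)
        cfg2 = PipelineConfig.from_yaml(p)
        assert cfg2.seed == tiny_cfg.seed
        assert tuple(cfg2.kink_bottom) == tuple(tiny_cfg.kink_bottom)
        assert cfg2.spec_overrides["ligand"]["count"] == 10

    def test_unknown_config_key_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("definitely_not_a_key: 1\n")
        with pytest.raises(ChanCavError, match="unknown config"):
            PipelineConfig.from_yaml(p)
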