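"""Cohort statistics, multiple-testing correction, and the pipeline."""

import json
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import virtres
from virtres.analysis import (
    StrategyComparison,
    fdr_bh,
    group_compare,
    run_pipeline,
    spared_removed_stats,
)
from virtres.errors import ConfigError, ParameterError, StatisticsError
from virtres.resection import ResectionPlan


class TestFdrBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_bh([0.03]), [0.03])

    def test_hand_computed_pair(self):
        np.testing.assert_allclose(fdr_bh([0.01, 0.04]), [0.02, 0.04])

    def test_hand_computed_quadruple(self):
        np.testing.assert_allclose(
            fdr_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_order_preserved(self):
        adj = fdr_bh([0.04, 0.01])
        np.testing.assert_allclose(adj, [0.04, 0.02])

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            fdr_bh([0.5, 1.2])


def _fake_comparison(n=10, rng=None, offset=0.0):
    rng = rng or np.random.default_rng(0)
    table = pd.DataFrame(
        {
            "subject": np.arange(n),
            "seed_ec": rng.normal(0.1, 0.02, n) + offset,
            "i_t0_pre": rng.normal(0.4, 0.05, n) + offset,
            "i_t0_post_optimal": rng.normal(0.2, 0.05, n) + offset,
        }
    )
    return StrategyComparison(
        table=table, tests=pd.DataFrame(), curves=(), optimal_plans=(),
        strategy_plans=(), betas=(),
    )


class TestGroupCompare:
    def test_swapping_labels_flips_t_keeps_p(self):
        comp = _fake_comparison(12)
        labels = np.array([0] * 6 + [1] * 6)
        a = group_compare(comp, labels)
        b = group_compare(comp, 1 - labels)
        np.testing.assert_allclose(a["statistic"], -b["statistic"])
        np.testing.assert_allclose(a["p"], b["p"])

    def test_single_group_rejected(self):
        comp = _fake_comparison(6)
        with pytest.raises(StatisticsError):
            group_compare(comp, np.ones(6, dtype=int))

    def test_location_chi_square_included(self):
        comp = _fake_comparison(12)
        labels = np.array([0] * 6 + [1] * 6)
        loc = np.array([0, 1] * 6)
        out = group_compare(comp, labels, location=loc)
        assert "chi2" in set(out["test"])
        assert out[out["test"] == "chi2"]["df"].iloc[0] == 1

    def test_type_one_error_near_nominal_under_null(self):
        """Unpaired t-test on identically distributed groups rejects at
        ~the nominal 5% rate (500 simulated cohorts)."""
        rng = np.random.default_rng(123)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            comp = _fake_comparison(19, rng=rng)
            labels = np.array([0] * 10 + [1] * 9)
            out = group_compare(comp, labels)
            p = out[out["measure"] == "seed_ec"]["p"].iloc[0]
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_agreement_with_textbook_t(self):
        x = np.array([1.1, 2.0, 2.9, 4.2, 5.1])
        y = np.array([2.3, 3.1, 4.0, 5.2, 6.3])
        t, p = stats.ttest_ind(x, y)
        nx_, ny = len(x), len(y)
        sp = np.sqrt(((nx_ - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
                     / (nx_ + ny - 2))
        t_hand = (x.mean() - y.mean()) / (sp * np.sqrt(1 / nx_ + 1 / ny))
        assert t == pytest.approx(t_hand, abs=1e-12)


@pytest.fixture(scope="module")
def tiny_cohort():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return virtres.generate_cohort(
            virtres.CohortSpec(n_subjects=3, n_nodes=40, density=0.15,
                               master_seed=21, ez_size_range=(2, 3))
        )


class TestSparedRemoved:

    def test_null_case_t_near_zero(self, tiny_cohort):
        # label *no* candidate as removed except a random half duplicated
        # from the same distribution: use plans that split candidates evenly
        plans = []
        for subj in tiny_cohort:
            cand = virtres.candidate_edges(subj.connectome, subj.ez)
            plans.append(ResectionPlan(
                edges=tuple(cand[::2]), k=len(cand[::2]), strategy="optimal"
            ))
        out = spared_removed_stats(tiny_cohort, plans)
        assert len(out) == 4
        assert set(out.columns) >= {"t", "df", "ci_low", "ci_high", "p", "p_fdr"}

    def test_optimal_plans_remove_hub_connections(self, tiny_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comp = virtres.compare_strategies(
                tiny_cohort, np.random.default_rng(2),
                sa_params=virtres.SAParams(restarts=2), propagation_runs=None,
            )
        out = spared_removed_stats(tiny_cohort, comp.optimal_plans)
        row = out[out["measure"] == "neighbor_ec"].iloc[0]
        assert row["mean_removed"] > row["mean_spared"]
        assert len(out["p_fdr"]) == 4

    def test_too_small_groups_rejected(self, tiny_cohort):
        full_plans = []
        for subj in tiny_cohort:
            cand = virtres.candidate_edges(subj.connectome, subj.ez)
            full_plans.append(ResectionPlan(
                edges=tuple(cand), k=len(cand), strategy="full"
            ))
        with pytest.raises(StatisticsError):
            spared_removed_stats(tiny_cohort, full_plans)


class TestPipeline:
    CONFIG = {
        "cohort": {
            "n_subjects": 3, "n_nodes": 40, "density": 0.15,
            "ez_size_range": [2, 3],
        },
        "density": 0.15,
        "master_seed": 5,
        "n_random": 20,
        "sa": {"restarts": 2},
        "calibration": {"n_runs": 300},
        "propagation_runs": 300,
        "validate_surrogate": False,
    }

    def test_smoke_writes_all_outputs(self, tmp_path):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = run_pipeline(dict(self.CONFIG), output_dir=tmp_path)
        for name in ("strategy_comparison.tsv", "strategy_tests.tsv",
                     "spared_removed.tsv", "plans.tsv", "effect_curves.json",
                     "manifest.json"):
            assert (tmp_path / name).exists(), name
        table = results["comparison"].table
        assert len(table) == 3
        assert (table["ec_full"] == 1.0).all()
        assert (table["ec_optimal"] >= 0.9).all()
        curves = json.loads((tmp_path / "effect_curves.json").read_text())
        assert len(curves) == 3

    def test_determinism(self, tmp_path):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run_pipeline(dict(self.CONFIG), output_dir=tmp_path / "a")
            run_pipeline(dict(self.CONFIG), output_dir=tmp_path / "b")
        for name in ("strategy_comparison.tsv", "plans.tsv", "manifest.json"):
            assert (tmp_path / "a" / name).read_text() == \
                (tmp_path / "b" / name).read_text()

    def test_unknown_key_rejected_with_valid_list(self):
        cfg = dict(self.CONFIG)
        cfg["densty"] = 0.1
        with pytest.raises(ConfigError, match="densty"):
            run_pipeline(cfg, output_dir="unused")

    def test_zero_density_rejected_before_compute(self):
        cfg = dict(self.CONFIG)
        cfg["density"] = 0.0
        with pytest.raises(ParameterError):
            run_pipeline(cfg, output_dir="unused")

    def test_yaml_config_and_input_matrices(self, tmp_path):
        import yaml

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spec = virtres.CohortSpec(
                n_subjects=2, n_nodes=40, density=0.15, master_seed=5,
                ez_size_range=(2, 3),
            )
            cohort = virtres.generate_cohort(spec)
        virtres.synthetic.write_cohort(cohort, spec, tmp_path / "data")
        manifest = json.loads((tmp_path / "data" / "cohort.json").read_text())
        cfg = {
            "inputs": {
                "matrices": [str(tmp_path / "data" / s["matrix"])
                             for s in manifest["subjects"]],
                "ez": [s["ez_nodes"] for s in manifest["subjects"]],
            },
            "density": 0.15,
            "master_seed": 5,
            "n_random": 10,
            "sa": {"restarts": 1},
            "calibration": {"n_runs": 200},
            "propagation_runs": 200,
        }
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = run_pipeline(cfg_path, output_dir=tmp_path / "out")
        assert len(results["comparison"].table) == 2
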