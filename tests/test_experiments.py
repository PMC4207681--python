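"""Experiment orchestration: the UA->SA pipeline and the two model
simplification procedures."""

import numpy as np
import pytest

from fallowsim import (
    ExperimentConfig,
    ExperimentReport,
    LandscapeConfig,
    compare_reports,
    evaluate_design,
    fix_factor,
    indices_from_log,
    make_default_factors,
    paired_comparison,
    refine_explanatory,
    run_experiment,
    saltelli_design,
    simplify_exploratory,
    sobol_indices,
)
from fallowsim.sensitivity import SensitivityResult

TINY = LandscapeConfig(rows=60, cols=60, parcel_count=50)


@pytest.fixture(scope="module")
def smoke_report():
    cfg = ExperimentConfig(
        name="smoke", landscape_config=TINY, landscape_seed=2, N=8, master_seed=3
    )
    return run_experiment(cfg, n_boot=20)


def _report_with_indices(S, ST, names=None, config=None):
    S, ST = np.asarray(S, float), np.asarray(ST, float)
    names = tuple(names or (f"f{i}" for i in range(len(S))))
    sens = SensitivityResult(
        factor_names=names, S=S, ST=ST, V=1.0, mean=10.0, N=64, k=len(S),
        S_se=np.full(len(S), 0.01), ST_se=np.full(len(S), 0.01),
        S_ci=np.zeros((len(S), 2)), ST_ci=np.zeros((len(S), 2)),
    )
    cfg = config or ExperimentConfig(landscape_config=TINY, N=4)
    ua = {"n": 8, "mean": 10.0, "variance": 1.0, "std": 1.0,
          "quantiles": {}, "histogram": {}}
    return ExperimentReport(config=cfg, run_count=cfg.run_count, ua=ua, sens=sens)


class TestRunExperiment:
    def test_run_count_formula(self, smoke_report):
        assert smoke_report.config.k == 9
        assert smoke_report.run_count == 8 * (2 * 9 + 2) == 160

    def test_report_well_formed(self, smoke_report):
        assert set(smoke_report.ua) >= {"mean", "variance", "quantiles"}
        assert smoke_report.sens is not None
        assert len(smoke_report.sens.S) == 9
        d = smoke_report.to_dict()
        assert d["run_count"] == 160

    def test_pipeline_deterministic(self, smoke_report):
        cfg = smoke_report.config
        again = run_experiment(cfg, n_boot=20)
        assert again.ua == smoke_report.ua

    def test_report_roundtrip(self, tmp_path, smoke_report):
        path = tmp_path / "report.json"
        smoke_report.save(path)
        back = ExperimentReport.load(path)
        assert back.ua == smoke_report.ua
        assert back.config.free_names == smoke_report.config.free_names

    def test_published_run_counts(self):
        for k, runs in [(9, 2560), (5, 1536), (8, 2304)]:
            cfg = ExperimentConfig(landscape_config=TINY, N=128)
            specs = cfg.factors
            fixables = [s.name for s in specs if s.name != "n"][: 9 - k]
            for name in fixables:
                from fallowsim import factor_median

                specs = fix_factor(specs, name, factor_median(
                    next(x for x in specs if x.name == name)))
            cfg = ExperimentConfig(landscape_config=TINY, N=128, factors=specs)
            assert cfg.run_count == runs


class TestSimplifyExploratory:
    def test_negligible_factors_fixed_at_median(self):
        names = ("RETIREMENT", "PRODUCTION", "TENURE", "DE", "OWA",
                 "LAND", "BID", "EBI", "n")
        S = [0.02, 0.001, 0.001, 0.001, 0.4, 0.1, 0.02, 0.001, 0.3]
        ST = [0.03, 0.002, 0.002, 0.002, 0.5, 0.2, 0.03, 0.002, 0.4]
        cfg = ExperimentConfig(landscape_config=TINY, N=4,
                               factors=make_default_factors())
        rep = _report_with_indices(S, ST, names=names, config=cfg)
        simple = simplify_exploratory(rep)
        assert set(simple.free_names) == {"n", "OWA", "BID", "LAND", "RETIREMENT"}
        fixed = {s.name: s.fixed_value for s in simple.factors if s.is_fixed}
        assert fixed["n" if "n" in fixed else "DE"] if False else True
        assert fixed == {"PRODUCTION": 1.0, "TENURE": 0.6, "DE": 1000, "EBI": 2}

    def test_threshold_zero_fixes_nothing(self, smoke_report):
        rep = _report_with_indices([0.001, 0.5], [0.001, 0.5])
        out = simplify_exploratory(rep, threshold=0.0)
        assert not any(s.is_fixed for s in out.factors[:2])

    def test_all_negligible_is_error(self):
        rep = _report_with_indices([0.001, 0.002], [0.001, 0.002])
        with pytest.raises(ValueError, match="negligible"):
            simplify_exploratory(rep, threshold=1.0)

    def test_mean_statistic_option(self):
        names = tuple(s.name for s in make_default_factors())
        S = [0.5] * 9
        S[0] = 0.001  # RETIREMENT negligible
        rep = _report_with_indices(S, S, names=names,
                                   config=ExperimentConfig(landscape_config=TINY, N=4))
        out = simplify_exploratory(rep, stat="mean")
        ret = next(s for s in out.factors if s.name == "RETIREMENT")
        # discrete mean 0.94 is snapped to the nearest supported value
        assert ret.fixed_value == 1


class TestRefineExplanatory:
    def test_offer_cap_fixed_at_midpoint(self):
        names = tuple(s.name for s in make_default_factors())
        S = [0.01, 0.01, 0.01, 0.01, 0.2, 0.1, 0.01, 0.01, 0.55]
        rep = _report_with_indices(S, S, names=names,
                                   config=ExperimentConfig(landscape_config=TINY, N=4))
        out = refine_explanatory(rep)
        n_spec = next(s for s in out.factors if s.name == "n")
        assert n_spec.fixed_value == 23
        assert len(out.free_names) == 8

    def test_continuous_factor_fixed_at_half(self):
        names = tuple(s.name for s in make_default_factors())
        S = [0.0] * 9
        S[5] = 0.9  # LAND
        rep = _report_with_indices(S, S, names=names,
                                   config=ExperimentConfig(landscape_config=TINY, N=4))
        out = refine_explanatory(rep)
        land = next(s for s in out.factors if s.name == "LAND")
        assert land.fixed_value == pytest.approx(0.5)

    def test_argmax_tie_takes_lower_index(self):
        names = tuple(s.name for s in make_default_factors())
        S = [0.4, 0.4] + [0.0] * 7
        rep = _report_with_indices(S, S, names=names,
                                   config=ExperimentConfig(landscape_config=TINY, N=4))
        out = refine_explanatory(rep)
        assert next(s for s in out.factors if s.is_fixed).name == "RETIREMENT"


class TestCompare:
    def test_spread_reduction_arithmetic(self):
        base = _report_with_indices([1.0], [1.0])
        base.ua = dict(base.ua, variance=100.0, std=10.0, n=64, mean=10.0)
        rep = _report_with_indices([1.0], [1.0])
        rep.ua = dict(rep.ua, variance=36.0, std=6.0, n=64, mean=10.0)
        c = compare_reports(rep, base)
        assert c["spread_reduction_pct"] == pytest.approx(64.0)

    def test_identical_reports(self, smoke_report):
        c = compare_reports(smoke_report, smoke_report)
        assert c["spread_reduction_pct"] == pytest.approx(0.0)
        assert c["mean_difference"] == 0.0

    def test_variance_increase_reported_negative(self):
        base = _report_with_indices([1.0], [1.0])
        base.ua = dict(base.ua, variance=50.0, n=64)
        rep = _report_with_indices([1.0], [1.0])
        rep.ua = dict(rep.ua, variance=100.0, n=64)
        assert compare_reports(rep, base)["spread_reduction_pct"] < 0

    def test_zero_baseline_variance(self):
        base = _report_with_indices([1.0], [1.0])
        base.ua = dict(base.ua, variance=0.0)
        with pytest.raises(ValueError):
            compare_reports(base, base)


class TestPairedComparison:
    def test_identity_simplification_is_exact(self, smoke_report):
        c = paired_comparison(smoke_report, smoke_report.config)
        assert c["mean_difference"] == 0.0
        assert c["variance_ratio"] == pytest.approx(1.0)

    def test_requires_subset(self, smoke_report):
        import dataclasses

        other = dataclasses.replace(
            smoke_report.config,
            factors=[s for s in smoke_report.config.factors][:0]
            or smoke_report.config.factors,
        )
        # a config whose free factor is not free in the baseline
        base_fixed = simplifiable = smoke_report.config
        cfg_fixed = dataclasses.replace(
            simplifiable, factors=fix_factor(simplifiable.factors, "n", 23)
        )
        rep_fixed = run_experiment(cfg_fixed, n_boot=0)
        with pytest.raises(ValueError, match="not free"):
            paired_comparison(rep_fixed, smoke_report.config)


def test_indices_from_log_matches_direct():
    d = saltelli_design(3, 256)
    ev = evaluate_design(d, lambda u: float(u[0] + u[1] * u[2]))
    direct = sobol_indices(ev, n_boot=0)
    from_log = indices_from_log(ev.log, n_boot=0)
    np.testing.assert_allclose(from_log.S, direct.S)
    np.testing.assert_allclose(from_log.ST, direct.ST)
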