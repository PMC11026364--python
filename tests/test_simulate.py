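"""Synthetic-cohort generator: determinism, moments, structural invariants."""

import numpy as np
import pandas as pd
import pytest

from tracequant.regions import CANONICAL_REGIONS, OTHER_SPARSE
from tracequant.simulate import (
    SimConfig,
    recovery_experiment,
    simulate_plaque_dataset,
    simulate_tracing_cohort,
)


def _small_config(**overrides):
    cfg = SimConfig()
    cfg.group_sizes = {"WT young": 4, "WT middle": 4, "5xFAD young": 4, "5xFAD middle": 4}
    cfg.sex_counts = {g: (2, 2) for g in cfg.group_sizes}
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


class TestTracingCohort:
    def test_same_seed_identical_output(self):
        cfg = _small_config()
        a = simulate_tracing_cohort(cfg, 123)
        b = simulate_tracing_cohort(cfg, 123)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_different_seed_differs(self):
        cfg = _small_config()
        a, _ = simulate_tracing_cohort(cfg, 1)
        b, _ = simulate_tracing_cohort(cfg, 2)
        assert not a.equals(b)

    def test_zero_rate_region_absent(self):
        cfg = _small_config()
        for g in cfg.kappa:
            cfg.kappa[g]["MEC"] = 0.0
        records, _ = simulate_tracing_cohort(cfg, 9)
        assert not (records["region"] == "MEC").any()

    def test_kappa_recovery_at_scale(self):
        # single-group Monte Carlo: mean per-mouse CSI within 5% of kappa
        cfg = SimConfig()
        cfg.group_sizes = {"WT young": 400}
        cfg.sex_counts = {"WT young": (200, 200)}
        records, metas = simulate_tracing_cohort(cfg, 77)
        starters = records.groupby("mouse_id")["n_starter"].sum()
        ca1 = (records[records["region"] == "CA1_py"]
               .groupby("mouse_id")["n_input"].sum()
               .reindex(starters.index, fill_value=0))
        mean_csi = (ca1 / starters).mean()
        assert mean_csi == pytest.approx(37.7953, rel=0.05)

    def test_overdispersion_beyond_poisson(self):
        cfg = SimConfig()
        cfg.group_sizes = {"WT young": 300}
        cfg.sex_counts = {"WT young": (150, 150)}
        cfg.starter_log_sd = 1e-6  # hold S essentially fixed to isolate NB noise
        records, _ = simulate_tracing_cohort(cfg, 31)
        counts = (records[records["region"] == "CA1_py"]
                  .groupby("mouse_id")["n_input"].sum())
        assert counts.var() > 2.0 * counts.mean()

    def test_starters_only_in_sub(self):
        records, _ = simulate_tracing_cohort(_small_config(), 5)
        assert (records.loc[records["n_starter"] > 0, "region"] == "SUB").all()

    def test_sparse_pool_fraction(self):
        records, _ = simulate_tracing_cohort(SimConfig(), 13)
        frac = (records.loc[records["region"] == OTHER_SPARSE, "n_input"].sum()
                / records["n_input"].sum())
        assert 0.01 < frac < 0.10  # configured at 4%

    def test_invalid_config_lists_fields(self):
        cfg = _small_config()
        cfg.theta["Vis"] = -1.0
        cfg.starter_log_sd = 0.0
        with pytest.raises(ValueError) as err:
            simulate_tracing_cohort(cfg, 0)
        assert "theta" in str(err.value) and "starter_log_sd" in str(err.value)

    def test_from_dict_rejects_unknown_field(self):
        with pytest.raises(ValueError, match="unknown"):
            SimConfig.from_dict({"not_a_field": 1})

    def test_from_dict_merges_nested(self):
        cfg = SimConfig.from_dict({"kappa": {"WT young": {"CA1_py": 10.0}}})
        assert cfg.kappa["WT young"]["CA1_py"] == 10.0
        assert cfg.kappa["WT young"]["SUB"] == pytest.approx(10.1783)


class TestPlaqueDataset:
    def test_determinism(self):
        cfg = SimConfig()
        a = simulate_plaque_dataset(cfg, 3)
        b = simulate_plaque_dataset(cfg, 3)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_wt_zero_plaques(self):
        records, fields, metas = simulate_plaque_dataset(SimConfig(), 11)
        wt = set(metas.query("genotype == 'WT'")["mouse_id"])
        assert not records["mouse_id"].isin(wt).any()

    def test_poisson_count_scale(self):
        cfg = SimConfig()
        cfg.plaque_group_size = 150
        records, fields, metas = simulate_plaque_dataset(cfg, 19)
        fad_ym = metas.query("genotype == '5xFAD' and age_group == 'young' and sex == 'M'")
        counts = (records[records["mouse_id"].isin(fad_ym["mouse_id"])]
                  .groupby("mouse_id").size()
                  .reindex(fad_ym["mouse_id"], fill_value=0))
        # density 1601 mm^-2 x 0.02 mm^2 = 32.02 expected plaques per animal
        assert counts.mean() == pytest.approx(1601.0 * 0.02, rel=0.08)

    def test_size_mean_matches_target(self):
        cfg = SimConfig()
        cfg.plaque_group_size = 60
        records, fields, metas = simulate_plaque_dataset(cfg, 23)
        fad_mm = metas.query("genotype == '5xFAD' and age_group == 'middle' and sex == 'M'")
        sizes = records[records["mouse_id"].isin(fad_mm["mouse_id"])]["area_um2"]
        assert sizes.mean() == pytest.approx(130.4, rel=0.05)


class TestRecovery:
    def test_single_replicate_degenerate(self):
        cfg = _small_config()
        report = recovery_experiment(cfg, n_replicates=1, seed=42)
        assert report.n_replicates == 1
        assert set(report.rates["significance_rate"].unique()) <= {0.0, 1.0}
        assert len(report.bias) == 4 * len(CANONICAL_REGIONS)

    def test_replicate_count_validation(self):
        with pytest.raises(ValueError):
            recovery_experiment(_small_config(), n_replicates=0, seed=1)
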