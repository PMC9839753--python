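import numpy as np
import pandas as pd
import pytest

import latentdomains as ld


def make_table(values: dict, meta: pd.DataFrame | None = None, **kw) -> ld.BehavioralTable:
    df = pd.DataFrame(values)
    return ld.BehavioralTable(values=df, variable_meta=meta, **kw)


class TestSelectVariables:
    def test_high_missingness_dropped(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(50)
        a = base + 0.1 * rng.standard_normal(50)
        b = base + 0.1 * rng.standard_normal(50)
        c = base.copy()
        c[:6] = np.nan  # 12% missing
        table = make_table({"a": a, "b": b, "c": c})
        kept, report = ld.select_variables(table)
        assert dict(report.dropped)["c"] == "missing_ge_10pct"
        assert set(report.kept) == {"a", "b"}

    def test_constant_variable_dropped_for_no_correlation(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(60)
        table = make_table(
            {"a": base, "b": base + 0.1 * rng.standard_normal(60), "flat": np.ones(60)}
        )
        _, report = ld.select_variables(table)
        assert dict(report.dropped)["flat"] == "no_correlation_gt_0.1"

    def test_six_variable_toy_with_two_violations(self):
        # composite and adjusted duplicate are the two violations -> 4 kept
        rng = np.random.default_rng(2)
        base = rng.standard_normal(80)
        vals = {
            "x1": base + 0.2 * rng.standard_normal(80),
            "x2": base + 0.2 * rng.standard_normal(80),
            "x3": base + 0.2 * rng.standard_normal(80),
            "x4": base + 0.2 * rng.standard_normal(80),
            "comp": base,  # composite of the others
            "x1_adj": base + 0.2 * rng.standard_normal(80),
        }
        meta = pd.DataFrame(
            {
                "is_composite": [False] * 4 + [True, False],
                "adjusted_of": [None] * 5 + ["x1"],
            },
            index=list(vals),
        )
        kept, report = ld.select_variables(make_table(vals, meta))
        assert len(report.kept) == 4
        reasons = dict(report.dropped)
        assert reasons["comp"] == "composite"
        assert reasons["x1_adj"] == "adjusted_duplicate"
        # every variable accounted for exactly once
        assert sorted(report.kept + [d for d, _ in report.dropped]) == sorted(vals)

    def test_all_dropped_raises(self):
        table = make_table({"a": np.ones(20), "b": np.zeros(20)})
        with pytest.raises(ValueError, match="all variables dropped"):
            ld.select_variables(table)


class TestSplitByFamily:
    def _table(self, family_sizes, seed=0):
        n = sum(family_sizes)
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({"a": rng.standard_normal(n), "b": rng.standard_normal(n)})
        fam = pd.Series(
            np.repeat([f"f{i}" for i in range(len(family_sizes))], family_sizes),
            index=df.index,
        )
        return ld.BehavioralTable(values=df, family_id=fam)

    def test_singletons_split_in_halves(self):
        table = self._table([1] * 100)
        a, b = ld.split_by_family(table, seed=0)
        assert a.n_subjects == b.n_subjects == 50

    def test_mixed_family_sizes_balanced_without_splitting(self):
        table = self._table([3, 3, 2, 2])
        a, b = ld.split_by_family(table, seed=1)
        assert {a.n_subjects, b.n_subjects} == {5}
        assert set(a.family_id) & set(b.family_id) == set()

    @pytest.mark.parametrize("seed", range(20))
    def test_no_family_spans_both_subsets(self, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(1, 5, size=12).tolist()
        table = self._table(sizes, seed=seed)
        a, b = ld.split_by_family(table, seed=seed)
        assert set(a.family_id) & set(b.family_id) == set()
        assert a.n_subjects + b.n_subjects == table.n_subjects

    def test_dominant_family_warns(self):
        table = self._table([8, 1, 1])
        with pytest.warns(UserWarning, match="more than half"):
            ld.split_by_family(table, seed=0)


class TestImputeChained:
    def test_complete_table_unchanged(self):
        table = make_table({"a": np.arange(10.0), "b": np.arange(10.0)[::-1]})
        out = ld.impute_chained(table, seed=0)
        pd.testing.assert_frame_equal(out.values, table.values)

    def test_beats_mean_imputation_on_correlated_data(self):
        rng = np.random.default_rng(3)
        n = 400
        a = rng.standard_normal(n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.standard_normal(n)
        truth = b.copy()
        mask = rng.random(n) < 0.10
        b[mask] = np.nan
        table = make_table({"a": a, "b": b})
        out = ld.impute_chained(table, seed=0)
        rmse = np.sqrt(np.mean((out.values["b"].to_numpy()[mask] - truth[mask]) ** 2))
        rmse_mean = np.sqrt(np.mean((np.nanmean(b) - truth[mask]) ** 2))
        assert rmse < rmse_mean
        # observed entries untouched
        assert np.allclose(out.values["b"].to_numpy()[~mask], truth[~mask])

    def test_no_missing_entries_remain_and_deterministic(self, planted_4factor):
        _, table, _ = planted_4factor
        with_na = ld.plant_missingness(table, 0.05, seed=2)
        out1 = ld.impute_chained(with_na, seed=5)
        out2 = ld.impute_chained(with_na, seed=5)
        assert not out1.values.isna().any().any()
        pd.testing.assert_frame_equal(out1.values, out2.values)

    def test_fully_missing_variable_rejected(self):
        table = make_table({"a": np.arange(5.0), "b": [np.nan] * 5})
        with pytest.raises(ValueError, match="fully missing"):
            ld.impute_chained(table, seed=0)


class TestRegressConfounds:
    def _table(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        age = rng.integers(22, 38, n).astype(float)
        gender = rng.integers(0, 2, n).astype(float)
        conf = pd.DataFrame({"age": age, "gender": gender})
        return conf, rng

    def test_exact_confound_gives_zero_residuals(self):
        conf, rng = self._table()
        table = make_table({"v": 2.0 * conf["age"]}, confounds=conf)
        out = ld.regress_confounds(table)
        assert np.abs(out.values["v"]).max() < 1e-10

    def test_orthogonal_variable_only_centered(self):
        conf, rng = self._table(seed=1)
        v = rng.standard_normal(200)
        # orthogonalize v against the design explicitly
        D = np.column_stack([np.ones(200), conf["age"], conf["gender"]])
        v = v - D @ np.linalg.lstsq(D, v, rcond=None)[0]
        v = v + 5.0  # add back a mean; residuals should remove it
        out = ld.regress_confounds(make_table({"v": v}, confounds=conf))
        assert np.allclose(out.values["v"], v - v.mean(), atol=1e-10)

    def test_residuals_orthogonal_to_confounds(self, planted_4factor):
        _, table, _ = planted_4factor
        out = ld.regress_confounds(table)
        for c in ("age", "gender"):
            r = out.values.apply(lambda col: np.corrcoef(col, table.confounds[c])[0, 1])
            assert np.abs(r).max() < 1e-10

    def test_constant_confound_dropped_with_warning(self):
        conf = pd.DataFrame({"age": np.full(50, 30.0), "gender": np.tile([0.0, 1.0], 25)})
        table = make_table({"v": np.random.default_rng(0).standard_normal(50)}, confounds=conf)
        with pytest.warns(UserWarning, match="constant"):
            ld.regress_confounds(table)


class TestInvertAndZscore:
    def test_inversion_flips_only_flagged_columns(self):
        meta = pd.DataFrame({"is_error_measure": [True, False]}, index=["rt", "acc"])
        table = make_table({"rt": np.arange(5.0), "acc": np.arange(5.0)}, meta)
        out = ld.invert_error_measures(table)
        assert np.allclose(out.values["rt"], -np.arange(5.0))
        assert np.allclose(out.values["acc"], np.arange(5.0))
        # involution
        back = ld.invert_error_measures(out)
        pd.testing.assert_frame_equal(back.values, table.values)

    def test_zscore_moments(self, planted_4factor):
        _, table, _ = planted_4factor
        out = ld.zscore(table)
        assert np.abs(out.values.mean()).max() < 1e-12
        assert np.abs(out.values.std(ddof=1) - 1).max() < 1e-12
        again = ld.zscore(out)
        assert np.allclose(again.values, out.values, atol=1e-12)

    def test_constant_column_named_in_error(self):
        table = make_table({"ok": np.arange(5.0), "flat": np.ones(5)})
        with pytest.raises(ValueError, match="flat"):
            ld.zscore(table)


def test_full_chain_preserves_latent_correlation_structure():
    """Confounded generation, after the preprocessing chain, matches the
    correlation structure of a confound-free generation of the same model."""
    L = ld.block_loadings(3, 8, 0.7)
    uniq = 1 - (L**2).sum(1)
    eff = np.column_stack([np.full(24, 0.05), np.full(24, 0.5)])
    spec_conf = ld.SyntheticSpec(2000, L, uniq, confound_effects=eff, seed=11)
    spec_free = ld.SyntheticSpec(2000, L, uniq, seed=11)
    t_conf, _ = ld.generate_factor_data(spec_conf)
    t_free, _ = ld.generate_factor_data(spec_free)
    clean = ld.zscore(ld.regress_confounds(t_conf))
    C1 = np.corrcoef(clean.values.to_numpy(), rowvar=False)
    C2 = np.corrcoef(t_free.values.to_numpy(), rowvar=False)
    assert np.abs(C1 - C2).max() < 0.08
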