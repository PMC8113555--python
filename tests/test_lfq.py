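"""Log2 transform, low-tail imputation, Welch testing, enrichment calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from telopull.io import ProteinGroupTable, SampleInfo
from telopull.lfq import (
    EnrichmentThresholds,
    ImputationParams,
    call_enrichment,
    impute_low_tail,
    log2_transform,
    results_to_frame,
    welch_test,
    welch_test_matrix,
    write_volcano,
)


def _table(values, sheet=None, ids=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    if sheet is None:
        half = m // 2
        sheet = [SampleInfo(f"b{i}", "bait", i + 1) for i in range(half)] + [
            SampleInfo(f"c{i}", "control", i + 1) for i in range(m - half)
        ]
    ids = ids or [f"P{i}" for i in range(n)]
    mat = pd.DataFrame(values, index=pd.Index(ids, name="protein_id"),
                       columns=[s.name for s in sheet])
    flags = pd.DataFrame(
        {"contaminant": False, "reverse": False, "only_by_site": False}, index=mat.index
    )
    return ProteinGroupTable(intensities=mat, flags=flags, sample_sheet=sheet)


class TestLog2Transform:
    def test_examples(self):
        t = _table([[8.0, np.nan, 0.0, 2.0]])
        out = log2_transform(t).intensities.iloc[0]
        assert out.iloc[0] == 3.0
        assert np.isnan(out.iloc[1])  # missing stays missing
        assert np.isnan(out.iloc[2])  # 0 becomes missing
        assert out.iloc[3] == 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            log2_transform(_table([[-1.0, 1, 1, 1]]))


class TestImputeLowTail:
    def test_no_missing_is_identity(self):
        rng = np.random.default_rng(0)
        t = _table(rng.uniform(20, 30, size=(10, 4)))
        out = impute_low_tail(t, ImputationParams(seed=1))
        pd.testing.assert_frame_equal(out.intensities, t.intensities)
        assert not out.imputed.values.any()

    def test_draws_confined_to_low_quantile_band_with_beta_mean(self):
        # observed uniform on [20, 30]; imputed values must fall between
        # the 0.2% and 2.5% quantiles, with mean near the band midpoint
        # (Beta(2,2) is symmetric) within 3 standard errors.
        rng = np.random.default_rng(42)
        vals = rng.uniform(20, 30, size=(500, 8))
        missing = rng.random(vals.shape) < 0.25
        observed = vals[~missing]
        vals_missing = vals.copy()
        vals_missing[missing] = np.nan
        t = _table(vals_missing, sheet=[
            SampleInfo(f"b{i}", "bait", i + 1) for i in range(4)
        ] + [SampleInfo(f"c{i}", "control", i + 1) for i in range(4)])
        out = impute_low_tail(t, ImputationParams(seed=3))
        imputed = out.intensities.values[missing]
        lo, hi = np.quantile(observed, [0.002, 0.025])
        assert imputed.min() >= lo and imputed.max() <= hi
        # Beta(2,2) on [lo,hi]: mean (lo+hi)/2, var (hi-lo)^2/20
        se = np.sqrt((hi - lo) ** 2 / 20 / imputed.size)
        assert abs(imputed.mean() - (lo + hi) / 2) < 3 * se

    def test_seeded_determinism(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(25, 2, size=(50, 4))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        t = _table(vals)
        a = impute_low_tail(t, ImputationParams(seed=9)).intensities
        b = impute_low_tail(t, ImputationParams(seed=9)).intensities
        assert np.array_equal(a.values, b.values)

    def test_too_few_observed_values_error_names_count(self):
        vals = np.full((4, 4), np.nan)
        vals[0, :3] = [20, 21, 22]
        with pytest.raises(ValueError, match="3 observed"):
            impute_low_tail(_table(vals))

    def test_observed_values_untouched(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(25, 2, size=(30, 4))
        mask = rng.random(vals.shape) < 0.2
        vals_missing = vals.copy()
        vals_missing[mask] = np.nan
        t = _table(vals_missing)
        out = impute_low_tail(t, ImputationParams(seed=0))
        assert np.array_equal(out.intensities.values[~mask], vals[~mask])

    def test_imputed_never_exceed_high_quantile(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            vals = rng.normal(25, 2, size=(100, 6))
            vals[rng.random(vals.shape) < 0.3] = np.nan
            t = _table(vals, sheet=[SampleInfo(f"b{i}", "bait", i + 1) for i in range(3)]
                       + [SampleInfo(f"c{i}", "control", i + 1) for i in range(3)])
            out = impute_low_tail(t, ImputationParams(seed=seed))
            obs = vals[~np.isnan(vals)]
            hi = np.quantile(obs, 0.025)
            assert np.nanmax(out.intensities.values[np.isnan(vals)]) <= hi


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_derived_closed_form_example(self):
        # independently evaluated via the Welch formulas: sa2=sb2=5/3,
        # se=sqrt(5/6), t=9/sqrt(5/6)=9.859006..., df=6 by symmetry
        t, df, p = welch_test([10, 11, 12, 13], [1, 2, 3, 4])
        assert t == pytest.approx(9.859006035092989, rel=1e-12)
        assert df == pytest.approx(6.0, rel=1e-12)
        assert p == pytest.approx(6.280125725146623e-05, rel=1e-9)

    def test_zero_variance_unequal_means_gives_tiny_finite_p(self):
        t, df, p = welch_test([0, 0, 0, 0], [1, 1, 1, 1])
        assert np.isinf(t) and t < 0
        assert 0 < p < 1e-300

    def test_group_too_small_rejected(self):
        with pytest.raises(ValueError):
            welch_test([1.0], [1, 2, 3])

    def test_matches_scipy_on_many_random_vectors(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            na, nb = rng.integers(2, 9, size=2)
            a = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), na)
            b = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), nb)
            t, df, p = welch_test(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)


class TestWelchProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    _group = st.lists(
        st.floats(-50, 50, allow_nan=False, allow_infinity=False),
        min_size=2, max_size=8,
    )

    @given(a=_group, b=_group)
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_antisymmetric_under_group_swap(self, a, b):
        t1, df1, p1 = welch_test(a, b)
        t2, df2, p2 = welch_test(b, a)
        assert t1 == -t2 or (t1 == 0 and t2 == 0)
        assert df1 == df2
        assert p1 == p2

    @given(a=_group, b=_group, shift=st.floats(-20, 20, allow_nan=False))
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_invariant_under_common_shift(self, a, b, shift):
        t1, _, p1 = welch_test(a, b)
        t2, _, p2 = welch_test([x + shift for x in a], [x + shift for x in b])
        if np.isfinite(t1) and abs(t1) < 1e6:
            assert t2 == pytest.approx(t1, rel=1e-6, abs=1e-6)
            assert p2 == pytest.approx(p1, rel=1e-5, abs=1e-12)


class TestCallEnrichment:
    def _run(self, bait_log2, ctrl_log2, **thr):
        n = len(bait_log2)
        vals = np.column_stack([
            np.tile(np.asarray(bait_log2)[:, None], 3),
            np.tile(np.asarray(ctrl_log2)[:, None], 3),
        ]).astype(float)
        rng = np.random.default_rng(0)
        vals += rng.normal(0, 0.05, vals.shape)
        sheet = [SampleInfo(f"b{i}", "bait", i + 1) for i in range(3)] + [
            SampleInfo(f"c{i}", "control", i + 1) for i in range(3)
        ]
        t = _table(2.0**vals, sheet=sheet)
        return call_enrichment(t, EnrichmentThresholds(**thr), ImputationParams(seed=0))

    def test_joint_gate(self):
        # 60 null proteins + one strongly bait-enriched
        base = np.full(60, 25.0)
        bait = np.append(base, 29.0)
        ctrl = np.append(base, 25.0)
        res = {r.protein_id: r for r in self._run(bait, ctrl, min_fold=4, max_p=0.01)}
        assert res["P60"].enriched_in == "bait"
        assert all(r.enriched_in == "none" for k, r in res.items() if k != "P60")

    def test_fold_change_gate_blocks_significant_but_small_effects(self):
        base = np.full(60, 25.0)
        bait = np.append(base, 26.5)  # ~2.8-fold < 4-fold
        ctrl = np.append(base, 25.0)
        res = {r.protein_id: r for r in self._run(bait, ctrl, min_fold=4, max_p=0.01)}
        assert res["P60"].p_value < 0.01  # significant...
        assert res["P60"].enriched_in == "none"  # ...but under the fold gate

    def test_control_side_symmetric(self):
        base = np.full(60, 25.0)
        bait = np.append(base, 25.0)
        ctrl = np.append(base, 29.0)
        res = {r.protein_id: r for r in self._run(bait, ctrl, min_fold=4, max_p=0.01)}
        assert res["P60"].enriched_in == "control"

    def test_label_swap_negates_fc_and_keeps_p(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(25, 2, size=(80, 8))
        sheet_fwd = [SampleInfo(f"s{i}", "bait" if i < 4 else "control", i + 1)
                     for i in range(8)]
        sheet_swp = [SampleInfo(f"s{i}", "control" if i < 4 else "bait", i + 1)
                     for i in range(8)]
        t_fwd = _table(2.0**vals, sheet=sheet_fwd)
        t_swp = _table(2.0**vals, sheet=sheet_swp)
        r_fwd = results_to_frame(call_enrichment(t_fwd)).set_index("protein_id")
        r_swp = results_to_frame(call_enrichment(t_swp)).set_index("protein_id")
        assert np.allclose(r_fwd["log2_fc"], -r_swp.loc[r_fwd.index, "log2_fc"])
        assert np.allclose(r_fwd["p_value"], r_swp.loc[r_fwd.index, "p_value"])

    def test_missing_condition_rejected(self):
        sheet = [SampleInfo(f"b{i}", "bait", i + 1) for i in range(4)]
        t = _table(np.full((3, 4), 100.0), sheet=sheet)
        with pytest.raises(ValueError, match="control"):
            call_enrichment(t)

    def test_results_sorted_by_p_then_fc(self):
        rng = np.random.default_rng(3)
        t = _table(2.0 ** rng.normal(25, 2, size=(50, 6)),
                   sheet=[SampleInfo(f"b{i}", "bait", i + 1) for i in range(3)]
                   + [SampleInfo(f"c{i}", "control", i + 1) for i in range(3)])
        res = call_enrichment(t)
        keys = [(r.p_value, -abs(r.log2_fc), r.protein_id) for r in res]
        assert keys == sorted(keys)


class TestWriteVolcano:
    def test_empty_results_write_header_only(self, tmp_path):
        paths = write_volcano([], tmp_path, plot=True)
        lines = paths["tsv"].read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("protein_id")

    def test_rerun_is_byte_identical(self, tmp_path):
        rng = np.random.default_rng(8)
        vals = rng.normal(25, 2, size=(40, 6))
        vals[rng.random(vals.shape) < 0.15] = np.nan
        t = _table(
            2.0**vals,
            sheet=[SampleInfo(f"b{i}", "bait", i + 1) for i in range(3)]
            + [SampleInfo(f"c{i}", "control", i + 1) for i in range(3)],
        )
        res = call_enrichment(t, imputation=ImputationParams(seed=4))
        p1 = write_volcano(res, tmp_path / "a", plot=False)["tsv"].read_bytes()
        res2 = call_enrichment(t, imputation=ImputationParams(seed=4))
        p2 = write_volcano(res2, tmp_path / "b", plot=False)["tsv"].read_bytes()
        assert p1 == p2
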