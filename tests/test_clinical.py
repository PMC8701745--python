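"""Spearman association: exact small-n p-values and the screening grid."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dcmpanel.clinical import CorrelationResult, correlate_panel, significant_pairs, spearman
from dcmpanel.containers import ExpressionMatrix, SampleMetadata
from dcmpanel.errors import InputError


def exact_p_oracle(x, y):
    """Pure-python full enumeration of all n! rank permutations."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    def rho_of(a, b):
        n = len(a)
        am, bm = sum(a) / n, sum(b) / n
        num = sum((ai - am) * (bi - bm) for ai, bi in zip(a, b))
        da = math.sqrt(sum((ai - am) ** 2 for ai in a))
        db = math.sqrt(sum((bi - bm) ** 2 for bi in b))
        return num / (da * db)

    observed = abs(rho_of(rx, ry))
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(rho_of(rx, list(perm))) >= observed - 1e-12:
            count += 1
    return count / total


class TestSpearman:
    def test_monotone_increasing_gives_one(self):
        x = [1.0, 2.5, 3.0, 7.0]
        y = [10.0, 20.0, 21.0, 30.0]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(1.0)

    def test_monotone_decreasing_gives_minus_one(self):
        rho, _ = spearman([1, 2, 3, 4], [9, 7, 6, 2])
        assert rho == pytest.approx(-1.0)

    def test_three_point_exact_example(self):
        # all 6 permutations of 3 ranks have |rho| >= 0.5, hence p = 1
        rho, p = spearman([1, 2, 3], [1, 3, 2])
        assert rho == pytest.approx(0.5)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7])
    def test_exact_p_matches_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(15):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            if rng.random() < 0.3:  # inject ties
                x[0] = x[1]
            _, p = spearman(x, y)
            assert p == pytest.approx(exact_p_oracle(x, y), abs=1e-12)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=20), rng.normal(size=20)
        rho, p = spearman(x, y)
        rho_ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(rho_ref.statistic)
        assert p == pytest.approx(rho_ref.pvalue, rel=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=12), rng.normal(size=12)
        rho1, p1 = spearman(x, y)
        rho2, p2 = spearman(np.exp(x), np.tanh(y))
        assert rho1 == pytest.approx(rho2)
        assert p1 == pytest.approx(p2)

    def test_zero_rank_variance_is_flagged_nan(self):
        rho, p = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(rho) and math.isnan(p)

    def test_too_short_rejected(self):
        with pytest.raises(InputError):
            spearman([1.0, 2.0], [1.0, 2.0])


def _expr_and_meta(n=8, n_genes=3, seed=0, clinical=None, extra_cols=None):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"DCM_{i:02d}" for i in range(n)]
    expr = ExpressionMatrix(
        pd.DataFrame(rng.normal(8, 1, (n_genes, n)), index=genes, columns=samples)
    )
    frame = pd.DataFrame({"group": "DCM"}, index=samples)
    if clinical is not None:
        for name, values in clinical.items():
            frame[name] = values
    if extra_cols is not None:
        for name, values in extra_cols.items():
            frame[name] = values
    return expr, SampleMetadata(frame)


class TestCorrelatePanel:
    def test_noise_free_link_attains_rho_one_and_passes(self):
        expr, _ = _expr_and_meta(n=8)
        cov = 2.0 * expr.frame.loc["g0"].to_numpy()
        expr2, meta = _expr_and_meta(n=8, clinical={"LVEDD": cov})
        res = correlate_panel(expr, ["g0", "g1"], meta)
        row = res.frame.set_index(["gene", "covariate"]).loc[("g0", "LVEDD")]
        assert row["rho"] == pytest.approx(1.0)
        assert bool(row["passed"])

    def test_grid_shape_is_panel_by_covariates(self):
        expr, meta = _expr_and_meta(
            n=8, clinical={"LVEDD": np.arange(8.0), "age": np.arange(8.0) * 2}
        )
        res = correlate_panel(expr, ["g0", "g1", "g2"], meta)
        assert len(res.frame) == 3 * 2

    def test_pairwise_complete_drops_missing(self):
        clinical = {"LVEDD": [1.0, 2.0, np.nan, 4.0, 5.0, 6.0, 7.0, 8.0]}
        expr, meta = _expr_and_meta(n=8, clinical=clinical)
        res = correlate_panel(expr, ["g0"], meta)
        assert res.frame.loc[0, "n_used"] == 7

    def test_stratum_filters_samples(self):
        clinical = {"LVEDD": np.arange(8.0)}
        extra = {"NYHA": [3, 3, 3, 3, 4, 4, 4, 4]}
        expr, meta = _expr_and_meta(n=8, clinical=clinical, extra_cols=extra)
        res = correlate_panel(expr, ["g0"], meta, stratum="NYHA=3")
        assert res.frame.loc[0, "n_used"] == 4
        # the stratum column itself is not correlated against
        assert set(res.frame["covariate"]) == {"LVEDD"}

    def test_small_stratum_rejected_by_name(self):
        extra = {"NYHA": [3, 4, 4, 4, 4, 4, 4, 4]}
        expr, meta = _expr_and_meta(n=8, clinical={"LVEDD": np.arange(8.0)}, extra_cols=extra)
        with pytest.raises(InputError, match="NYHA=3"):
            correlate_panel(expr, ["g0"], meta, stratum="NYHA=3")

    def test_unknown_panel_gene_rejected(self):
        expr, meta = _expr_and_meta(n=8, clinical={"LVEDD": np.arange(8.0)})
        with pytest.raises(InputError):
            correlate_panel(expr, ["nope"], meta)


class TestSignificantPairs:
    def _result(self, rows):
        frame = pd.DataFrame(rows, columns=["gene", "covariate", "rho", "p", "n_used", "passed"])
        frame["fdr"] = frame["p"]
        return CorrelationResult(frame=frame, rho_min=0.5, p_max=0.05)

    def test_boundary_conventions(self):
        res = self._result(
            [
                ("NEAT1", "LVEDD", 0.73, 0.05, 8, True),  # p boundary inclusive
                ("NPPA", "LVESD", 0.96, 0.0004, 11, True),
                ("g3", "age", 0.4, 0.001, 11, False),  # rho bound strict
                ("g4", "age", 0.5, 0.001, 11, False),  # |rho| exactly 0.5 excluded
            ]
        )
        pairs = significant_pairs(res)
        assert list(pairs["gene"]) == ["NPPA", "NEAT1"]

    def test_sorted_by_p(self):
        res = self._result(
            [
                ("a", "x", 0.9, 0.04, 8, True),
                ("b", "y", 0.8, 0.001, 8, True),
            ]
        )
        assert list(significant_pairs(res)["gene"]) == ["b", "a"]
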