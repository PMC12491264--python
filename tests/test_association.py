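import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from multioptosis import AnalysisConfig, classify_tnc, fit_hrc, fit_smc, holm_adjust
from multioptosis.association import (
    EndpointArray,
    rank_sum_p,
    spearman_screen,
    tumor_normal_screen,
)
from multioptosis.errors import SizeError, ValidationError
from multioptosis.synthetic import generate_survival

CFG = AnalysisConfig()


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def holm_oracle(pvalues):
    """Brute-force step-down: sort, multiply by (m - i), cumulative max, cap."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running = 0.0
    for rank_idx, i in enumerate(order):
        running = max(running, (m - rank_idx) * pvalues[i])
        adj[i] = min(1.0, running)
    return adj


def spearman_oracle(x, y):
    """Naive rank-then-Pearson."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


def rank_sum_exact_oracle(x, y):
    """Exact two-sided rank-sum p by enumerating group assignments."""
    pooled = list(x) + list(y)
    n = len(x)
    obs = sum(stats.rankdata(pooled)[:n])
    stats_all = []
    for idx in itertools.combinations(range(len(pooled)), n):
        r = stats.rankdata(pooled)
        stats_all.append(sum(r[list(idx)]))
    stats_all = np.array(stats_all)
    mean = stats_all.mean()
    p = np.mean(np.abs(stats_all - mean) >= np.abs(obs - mean) - 1e-12)
    return p


# ---------------------------------------------------------------------------
# holm_adjust
# ---------------------------------------------------------------------------


def test_holm_worked_examples():
    # hand step-down: sorted multipliers 3,2,1 then cumulative max
    assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])
    assert holm_adjust([0.2]) == pytest.approx([0.2])
    assert holm_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])
    assert holm_adjust([]) == []


def test_holm_matches_oracle_on_all_small_permutations():
    base = [0.001, 0.02, 0.04, 0.2, 0.6, 0.9]
    for k in range(1, 7):
        for perm in itertools.permutations(base[:k]):
            assert holm_adjust(list(perm)) == pytest.approx(holm_oracle(list(perm)))


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=12))
@settings(max_examples=200, deadline=None)
def test_holm_dominates_raw_p_and_matches_oracle(ps):
    adj = holm_adjust(ps)
    assert all(a >= p - 1e-12 for a, p in zip(adj, ps))
    assert adj == pytest.approx(holm_oracle(ps))


def test_holm_rejects_out_of_range():
    with pytest.raises(ValueError):
        holm_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# spearman_screen
# ---------------------------------------------------------------------------


def _screen_frame(rows, samples=None):
    samples = samples or [f"s{i}" for i in range(len(next(iter(rows.values()))))]
    return pd.DataFrame(rows, index=samples).T


def test_perfect_monotone_feature_is_significant():
    n = 10
    pheno = pd.Series(np.arange(n, dtype=float), index=[f"s{i}" for i in range(n)])
    layer = _screen_frame({"f1": list(range(n))})
    res = spearman_screen(layer, pheno, CFG)
    (rec,) = res.records
    assert rec.rho == pytest.approx(1.0)
    assert rec.p == 0.0 and rec.significant
    assert rec.scs == "P"


def test_textbook_spearman_value():
    # 1 - 6*sum(d^2)/(n(n^2-1)) with sum(d^2) = 4
    pheno = pd.Series([2, 1, 4, 3, 5], index=[f"s{i}" for i in range(5)], dtype=float)
    layer = _screen_frame({"f1": [1, 2, 3, 4, 5]})
    (rec,) = spearman_screen(layer, pheno, CFG).records
    assert rec.rho == pytest.approx(0.8)


def test_constant_features_are_excluded_with_reason():
    pheno = pd.Series(np.arange(6, dtype=float), index=[f"s{i}" for i in range(6)])
    layer = _screen_frame({"flat": [3.0] * 6, "ok": [1, 5, 2, 4, 3, 6]})
    res = spearman_screen(layer, pheno, CFG)
    assert res.excluded == {"flat": "zero variance"}
    assert [r.feature_id for r in res.records] == ["ok"]
    with pytest.warns(UserWarning):
        empty = spearman_screen(_screen_frame({"flat": [1.0] * 6}), pheno, CFG)
    assert len(empty) == 0


def test_screen_agrees_with_rank_then_pearson_oracle():
    rng = np.random.default_rng(5)
    samples = [f"s{i}" for i in range(40)]
    vals = rng.standard_normal((20, 40))
    vals[::3] = np.round(vals[::3], 1)  # inject ties
    layer = pd.DataFrame(vals, index=[f"f{i}" for i in range(20)], columns=samples)
    pheno = pd.Series(rng.standard_normal(40), index=samples)
    res = spearman_screen(layer, pheno, CFG)
    for rec in res:
        row = layer.loc[rec.feature_id].to_numpy()
        assert rec.rho == pytest.approx(spearman_oracle(row, pheno.to_numpy()), abs=1e-12)
        scipy_p = stats.spearmanr(row, pheno.to_numpy()).pvalue
        assert rec.p == pytest.approx(scipy_p, rel=1e-9)


def test_screen_requires_three_samples():
    pheno = pd.Series([1.0, 2.0], index=["a", "b"])
    with pytest.raises(SizeError):
        spearman_screen(pd.DataFrame([[1.0, 2.0]], index=["f"], columns=["a", "b"]), pheno)


# ---------------------------------------------------------------------------
# TNC
# ---------------------------------------------------------------------------


def test_tnc_codes_follow_polarity_rules():
    rng = np.random.default_rng(3)
    normal = rng.standard_normal(20)
    assert classify_tnc([1.0, 2.0], None) == 0  # no normals -> no data
    assert classify_tnc(normal, normal) == 1  # same values -> unchanged
    assert classify_tnc(normal + 3, normal) == 3  # shifted up -> overexpressed
    assert classify_tnc(normal - 3, normal) == 2
    # significant p but tied medians stays unchanged
    assert classify_tnc([1, 1, 1], [1, 1, 1], padj=0.01) == 1
    with pytest.raises(SizeError):
        classify_tnc([], normal)


def test_tnc_antisymmetry_under_group_swap():
    rng = np.random.default_rng(9)
    for _ in range(5):
        a = rng.standard_normal(15)
        b = rng.standard_normal(15) + rng.uniform(-2, 2)
        fwd, rev = classify_tnc(a, b), classify_tnc(b, a)
        assert {fwd, rev} in ({0}, {1}, {2, 3}) or fwd == rev == 1


def test_rank_sum_p_matches_exact_enumeration_oracle():
    rng = np.random.default_rng(7)
    for n, m in [(4, 5), (5, 5), (6, 4)]:
        x = rng.standard_normal(n)
        y = rng.standard_normal(m) + 0.5
        assert rank_sum_p(x, y) == pytest.approx(rank_sum_exact_oracle(x, y), abs=1e-9)


def test_tumor_normal_screen_adjusts_across_genes():
    rng = np.random.default_rng(2)
    samples_t = [f"t{i}" for i in range(30)]
    samples_n = [f"n{i}" for i in range(30)]
    tumor = pd.DataFrame(
        rng.standard_normal((10, 30)), index=[f"g{i}" for i in range(10)], columns=samples_t
    )
    normal = pd.DataFrame(
        rng.standard_normal((10, 30)), index=[f"g{i}" for i in range(10)], columns=samples_n
    )
    tumor.loc["g0"] += 4  # one clearly shifted gene
    out = tumor_normal_screen(tumor, normal)
    assert (out["padj"] >= out["p"] - 1e-12).all()
    assert out.loc["g0", "padj"] < 0.05


# ---------------------------------------------------------------------------
# HRC / SMC
# ---------------------------------------------------------------------------


def _surv_with_effect(beta, n=500, seed=3, censoring=0.0):
    rng = np.random.default_rng(seed)
    x = pd.Series(rng.standard_normal(n), index=[f"s{i}" for i in range(n)])
    surv = generate_survival(beta * x, censoring_rate=censoring, seed=seed + 1)
    return x, surv


def test_hrc_recovers_planted_risky_and_protective_effects():
    x, surv = _surv_with_effect(0.7)
    arr, fits = fit_hrc(x, {"OS": surv}, CFG)
    assert arr.letters[3] == "B"
    assert fits["OS"].log_hr == pytest.approx(0.7, abs=0.2)

    x, surv = _surv_with_effect(-0.7)
    arr, fits = fit_hrc(x, {"OS": surv}, CFG)
    assert arr.letters[3] == "C"
    assert fits["OS"].log_hr == pytest.approx(-0.7, abs=0.2)


def test_hrc_null_covariate_is_class_a():
    x, surv = _surv_with_effect(0.7, seed=5)
    rng = np.random.default_rng(12)
    permuted = pd.Series(rng.permutation(x.to_numpy()), index=x.index)
    arr, _ = fit_hrc(permuted, {"OS": surv}, CFG)
    assert arr.letters[3] == "A"


def test_hrc_skips_underpowered_endpoints():
    x = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
    surv = pd.DataFrame(
        {"time": [1.0, 2.0, 3.0], "event": [1, 0, 0]}, index=["a", "b", "c"]
    )
    arr, fits = fit_hrc(x, {"DSS": surv}, CFG)
    assert arr.letters[0] == "A"
    assert fits["DSS"].flag == "fit_skipped"
    with pytest.raises(ValueError):
        bad = surv.copy()
        bad.loc["a", "time"] = -1.0
        bad["event"] = 1
        fit_hrc(x, {"DSS": bad}, CFG)


def test_smc_mutation_carriers_with_higher_hazard_code_b():
    rng = np.random.default_rng(21)
    n = 400
    idx = [f"s{i}" for i in range(n)]
    mut = pd.Series((rng.random(n) < 0.3).astype(float), index=idx)
    surv = generate_survival(1.2 * mut.to_numpy(), censoring_rate=0.1, seed=22)
    surv.index = idx
    arr, _ = fit_smc(mut, "mutation", {"OS": surv}, CFG)
    assert arr.letters[3] == "B"  # MT poorer


def test_smc_continuous_null_is_a_and_deleted_cnv_codes_b():
    rng = np.random.default_rng(31)
    n = 400
    idx = [f"s{i}" for i in range(n)]
    x = pd.Series(rng.standard_normal(n), index=idx)
    surv = generate_survival(np.zeros(n), censoring_rate=0.2, seed=32)
    surv.index = idx
    arr, _ = fit_smc(x, "mrna", {"OS": surv}, CFG)
    assert arr.letters[3] == "A"

    cnv = pd.Series(rng.choice([-2, -1, 0, 1, 2], p=[0.02, 0.28, 0.4, 0.28, 0.02], size=n),
                    index=idx, dtype=float)
    hazard = np.where(cnv < 0, 1.5, 0.0)
    surv = generate_survival(hazard, censoring_rate=0.1, seed=33)
    surv.index = idx
    arr, _ = fit_smc(cnv, "cnv", {"OS": surv}, CFG)
    assert arr.letters[3] == "B"  # Deleted poorer


def test_smc_cnv_pooled_contrast_codes_d():
    rng = np.random.default_rng(41)
    n = 500
    idx = [f"s{i}" for i in range(n)]
    cnv = pd.Series(rng.choice([-1, 0, 1], p=[0.25, 0.5, 0.25], size=n), index=idx, dtype=float)
    # both deleted and duplicated share the same elevated hazard
    hazard = np.where(cnv != 0, 1.5, 0.0)
    surv = generate_survival(hazard, censoring_rate=0.1, seed=42)
    surv.index = idx
    arr, _ = fit_smc(cnv, "cnv", {"OS": surv}, CFG)
    assert arr.letters[3] == "D"


def test_endpoint_array_letter_constraints():
    with pytest.raises(ValidationError):
        EndpointArray("HRC", ("A", "B", "C", "D"))
    with pytest.raises(ValidationError):
        EndpointArray("SMC", ("A", "B", "C", "D"), layer="mrna")
    EndpointArray("SMC", ("A", "B", "C", "D"), layer="cnv")  # allowed
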