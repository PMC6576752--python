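import numpy as np
import pandas as pd
import pytest
import scipy.stats

from aeqtl.models import (AeQTLRegressor, AllelicVarianceTest,
                          CollinearityError, EQTLRegressor,
                          InteractionRegressor, P_FLOOR, annotate_fdr, bh_fdr,
                          compute_pcs, fit_aeqtl, fit_eqtl, fit_txsnp_aeqtl,
                          variance_test)
from aeqtl.types import QtlResult


def ols_oracle(y, X):
    """Independent check: normal equations + explicit t CDF."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    t = beta / se
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df)
    return beta, se, t, p


def test_aeqtl_matches_oracle(fraction_table):
    est = AeQTLRegressor().fit(fraction_table[["group"]],
                               fraction_table["fraction_p1"])
    X = np.column_stack([np.ones(len(fraction_table)),
                         fraction_table["group"].to_numpy(float)])
    beta, se, t, p = ols_oracle(fraction_table["fraction_p1"], X)
    assert est.slope_ == pytest.approx(beta[1], abs=1e-10)
    assert est.stderr_ == pytest.approx(se[1], abs=1e-10)
    assert est.tvalue_ == pytest.approx(t[1], abs=1e-8)
    assert est.pvalue_ == pytest.approx(p[1], abs=1e-10)


def test_aeqtl_with_covariates_matches_oracle(fraction_table, rng):
    cov = pd.DataFrame({"age": rng.uniform(20, 80, len(fraction_table)),
                        "sex": rng.integers(0, 2, len(fraction_table))})
    r = fit_aeqtl(fraction_table, cov, pair_id="p")
    X = np.column_stack([np.ones(len(fraction_table)),
                         fraction_table["group"].to_numpy(float),
                         cov["age"], cov["sex"]])
    beta, se, _, p = ols_oracle(fraction_table["fraction_p1"], X)
    assert r.slope == pytest.approx(beta[1], abs=1e-10)
    assert r.stderr == pytest.approx(se[1], abs=1e-10)
    assert r.pvalue == pytest.approx(p[1], abs=1e-10)
    assert r.covariates == ("age", "sex")


def test_exact_fit_guards():
    g = np.array([0, 0, 1, 1, 2, 2])
    # perfectly linear, nonzero slope: the floor p-value, not an overflow
    X = pd.DataFrame({"group": g})
    est = AeQTLRegressor().fit(X, 0.5 - 0.1 * g)
    assert est.exact_fit_ and est.pvalue_ == P_FLOOR
    assert est.slope_ == pytest.approx(-0.1)
    # constant response: zero slope, no evidence
    est0 = AeQTLRegressor().fit(X, np.full(6, 0.5))
    assert est0.slope_ == 0.0 and est0.pvalue_ == 1.0


def test_direction_reporting():
    g = np.array([0, 0, 1, 1, 2, 2])
    X = pd.DataFrame({"group": g})
    down_with_group = AeQTLRegressor().fit(X, 0.5 - 0.1 * g)
    # fraction falls as the designated allele moves to parent 2: that
    # allele carries the higher share, so its effect is "up"
    assert down_with_group.to_result("p", risk_is_designated=True).direction == "up"
    assert down_with_group.to_result("p", risk_is_designated=False).direction == "down"


def test_categorical_coding(rng):
    g = rng.integers(0, 3, 60)
    y = 0.5 - 0.05 * g + rng.normal(0, 0.02, 60)
    est = AeQTLRegressor(coding="categorical").fit(pd.DataFrame({"group": g}), y)
    assert 0 < est.pvalue_ <= 1
    assert est.slope_ == pytest.approx(-0.05, abs=0.03)


def test_collinear_covariate_dropped(fraction_table):
    X = fraction_table[["group"]].copy()
    X["dup"] = X["group"].astype(float)  # exactly collinear with the group
    est = AeQTLRegressor().fit(X, fraction_table["fraction_p1"])
    assert est.dropped_columns_ == ["dup"]
    plain = AeQTLRegressor().fit(fraction_table[["group"]],
                                 fraction_table["fraction_p1"])
    assert est.slope_ == pytest.approx(plain.slope_, abs=1e-12)


def test_constant_group_unidentifiable():
    X = pd.DataFrame({"group": np.ones(10, dtype=int)})
    with pytest.raises(CollinearityError):
        AeQTLRegressor().fit(X, np.random.default_rng(0).normal(0.5, 0.1, 10))


def test_input_validation(fraction_table):
    with pytest.raises(ValueError, match="lengths differ"):
        AeQTLRegressor().fit(fraction_table[["group"]], [0.5, 0.6])
    bad = fraction_table[["group"]].copy()
    bad.loc[0, "group"] = 3
    with pytest.raises(ValueError, match="0, 1 or 2"):
        AeQTLRegressor().fit(bad, fraction_table["fraction_p1"])


def test_orthogonal_covariate_leaves_slope_unchanged(fraction_table, rng):
    y = fraction_table["fraction_p1"].to_numpy()
    g = fraction_table["group"].to_numpy(float)
    base = np.column_stack([np.ones(len(g)), g])
    z = rng.normal(size=len(g))
    z -= base @ np.linalg.lstsq(base, z, rcond=None)[0]  # orthogonalize
    with_cov = fit_aeqtl(fraction_table, pd.DataFrame({"z": z}))
    without = fit_aeqtl(fraction_table)
    assert with_cov.slope == pytest.approx(without.slope, abs=1e-8)


def test_eqtl_exact_linear(rng):
    dosage = rng.integers(0, 3, 30)
    r = fit_eqtl(3.0 + 2.0 * dosage, dosage, pair_id="e")
    assert r.slope == pytest.approx(2.0) and r.pvalue == P_FLOOR
    assert r.direction == "up"


def test_eqtl_null_p_uniform(rng):
    pvals = []
    for _ in range(200):
        dosage = rng.integers(0, 3, 50)
        y = rng.normal(0, 1, 50)  # independent of dosage
        pvals.append(EQTLRegressor().fit(pd.DataFrame({"dosage": dosage}), y).pvalue_)
    assert scipy.stats.kstest(pvals, "uniform").pvalue > 0.001


def test_interaction_exact_and_validation(rng):
    g = np.tile([0, 1, 2], 20)
    mod = np.repeat([0, 1], 30)
    y = 0.5 - 0.1 * g * mod  # pure interaction, noiseless
    est = InteractionRegressor().fit(
        pd.DataFrame({"group": g, "moderator": mod}), y)
    assert est.slope_ == pytest.approx(-0.1) and est.pvalue_ == P_FLOOR
    assert set(est.stratum_fits_) == {0, 1}
    with pytest.raises(ValueError, match="binary"):
        InteractionRegressor().fit(
            pd.DataFrame({"group": g, "moderator": g}), y)


def test_interaction_power(rng):
    hits = 0
    for _ in range(50):
        g = rng.integers(0, 3, 400)
        mod = rng.integers(0, 2, 400)
        y = 0.5 - 0.1 * g * mod + rng.normal(0, 0.1, 400)
        est = InteractionRegressor().fit(
            pd.DataFrame({"group": g, "moderator": mod}), y)
        hits += est.pvalue_ < 0.05
    assert hits / 50 > 0.8


def test_variance_test():
    rng = np.random.default_rng(3)
    het = np.repeat([True, False], 50)
    f = np.where(het, rng.normal(0.5, 0.15, 100), rng.normal(0.5, 0.02, 100))
    est = AllelicVarianceTest().fit(f, het)
    assert est.pvalue_ < 0.01
    # all fractions identical: no dispersion anywhere, no evidence
    flat = AllelicVarianceTest().fit(np.full(100, 0.5), het)
    assert flat.pvalue_ == 1.0
    with pytest.raises(ValueError, match="strata"):
        AllelicVarianceTest().fit(f, np.ones(100, dtype=bool))
    r = variance_test(f, het, pair_id="v")
    assert isinstance(r, QtlResult) and r.model == "variance_test"


def test_compute_pcs():
    rng = np.random.default_rng(4)
    # rank-1 matrix: PC1 carries everything, further columns are zero
    u = rng.normal(size=20)
    M = np.outer(u, rng.normal(size=8))
    scores = compute_pcs(M, 5)
    assert scores.shape == (20, 5)
    assert np.var(scores[:, 0]) > 1e-6
    assert np.allclose(scores[:, 1:], 0.0, atol=1e-8)
    # scores of a full-rank matrix are mutually orthogonal
    X = rng.normal(size=(30, 10))
    s = compute_pcs(X, 4)
    gram = s.T @ s
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()
    # missing values are mean-imputed, not fatal
    Xm = X.copy()
    Xm[0, 0] = np.nan
    assert compute_pcs(Xm, 2).shape == (30, 2)
    with pytest.raises(ValueError, match="all-missing"):
        compute_pcs(np.full((3, 4), np.nan), 2)


def test_bh_fdr_hand_example():
    q, rej, cutoff = bh_fdr([0.001, 0.01, 0.02, 0.9], alpha=0.05)
    assert list(rej) == [True, True, True, False]
    assert cutoff == 0.02
    assert q[0] == pytest.approx(0.004)
    assert q[3] == pytest.approx(0.9)


def test_bh_fdr_edges():
    q, rej, cutoff = bh_fdr([1.0, 1.0, 1.0])
    assert not rej.any() and cutoff == 0.0 and (q == 1.0).all()
    _, rej1, cut1 = bh_fdr([0.04])
    assert rej1[0] and cut1 == 0.04
    q0, rej0, c0 = bh_fdr([])
    assert len(q0) == 0 and len(rej0) == 0 and c0 == 0.0
    with pytest.raises(ValueError):
        bh_fdr([0.0, 0.5])
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


def test_annotate_fdr():
    res = [QtlResult(f"p{i}", "aeqtl_gene", 0.0, 1.0, 0.0, p)
           for i, p in enumerate([0.001, 0.5])]
    cutoff = annotate_fdr(res, alpha=0.05)
    assert cutoff == 0.001
    assert res[0].extras["significant"] and not res[1].extras["significant"]
    assert res[0].qvalue == pytest.approx(0.002)


def test_fit_txsnp_applies_per_txsnp_testability(rng):
    # txA testable (6 vs 6), txB not (2 vs 2)
    rows = []
    for i in range(6):
        rows.append(("S%d" % i, "txA", 0.6 + 0.01 * i, 0))
        rows.append(("T%d" % i, "txA", 0.4 + 0.01 * i, 2))
    for i in range(2):
        rows.append(("U%d" % i, "txB", 0.5, 0))
        rows.append(("V%d" % i, "txB", 0.5, 2))
    df = pd.DataFrame(rows, columns=["sample", "txsnp_id", "fraction_p1", "group"])
    out = fit_txsnp_aeqtl(df, pair_id="rs|g", min_group_n=5, min_groups=2)
    assert [r.extras["txsnp_id"] for r in out] == ["txA"]
    assert out[0].model == "aeqtl_txsnp"
    assert out[0].pair_id == "rs|g:txA"
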