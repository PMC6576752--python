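"""Association models: aeQTL and eQTL regressions, interaction and
variance-based tests, principal-component covariates and FDR control.

Estimators follow the scikit-learn protocol (``fit``, ``get_params``,
fitted attributes with a trailing underscore) so they compose with sklearn
pipelines; the ``fit_*`` module functions are thin wrappers kept for
pipeline code.

The aeQTL model is ordinary least squares

    fraction_P1 ~ risk-SNP group + covariates

with the phase-coded group treated as a numeric 0/1/2 trend (a categorical
coding is available for sensitivity analysis), and a two-sided t-test on
the group coefficient.  The comparison eQTL model regresses total
expression on allele dosage with the identical covariate set.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .types import QtlResult

#: p-value reported when the fit is exact (zero residual variance, nonzero
#: slope); the conventional double-precision floor.
P_FLOOR = 2.2e-16
_ZERO_RESID_TOL = 1e-24  # residual mean square below this is "exact"


class CollinearityError(ValueError):
    """Design matrix rank-deficient in a way covariate pruning cannot fix."""


def _prune_collinear(X: pd.DataFrame, protected: Sequence[str]) -> tuple[pd.DataFrame, list[str]]:
    """Drop covariate columns that are collinear with what precedes them.

    Protected columns (intercept, the tested regressor) may not be dropped;
    if adding one of them does not increase rank the design is unusable.
    """
    keep: list[str] = []
    dropped: list[str] = []
    rank = 0
    for col in X.columns:
        cand = X[keep + [col]].to_numpy(dtype=float)
        new_rank = np.linalg.matrix_rank(cand)
        if new_rank > rank:
            keep.append(col)
            rank = new_rank
        elif col in protected:
            raise CollinearityError(
                f"column {col!r} is collinear with {keep}; the effect is not "
                "identifiable"
            )
        else:
            dropped.append(col)
    return X[keep], dropped


def _ols(y: np.ndarray, X: pd.DataFrame, term: str):
    """OLS fit returning (model_result, slope, se, t, p, zero_resid_flag)
    for one coefficient, with the exact-fit p-value guard."""
    res = sm.OLS(y, X).fit()
    slope = float(res.params[term])
    se = float(res.bse[term])
    mse = float(res.mse_resid) if res.df_resid > 0 else 0.0
    if mse < _ZERO_RESID_TOL:
        # no residual noise: p is 1 for a zero slope, the numeric floor
        # otherwise (reported as a "< 2.2e-16"-style bound)
        if abs(slope) < 1e-12:
            return res, 0.0, se, 0.0, 1.0, True
        return res, slope, se, np.inf if se == 0 else slope / se, P_FLOOR, True
    t = float(res.tvalues[term])
    p = float(res.pvalues[term])
    if not np.isfinite(p):
        p = 1.0
    return res, slope, se, t, p, False


def _direction(slope: float, risk_is_designated: bool) -> str:
    """Effect direction relative to the risk allele.

    Group runs from designated-allele-on-parent-1 (0) to on-parent-2 (2);
    a negative slope means the designated allele carries the higher
    expression share, i.e. "up" for that allele.
    """
    eff = -slope if risk_is_designated else slope
    return "up" if eff > 0 else "down"


class _BaseQtlEstimator(BaseEstimator):
    """Shared OLS machinery: design assembly, pruning, fitted attributes."""

    _term = "group"
    _model_name = "aeqtl_gene"

    def _assemble(self, X: pd.DataFrame, term_cols: list[str]) -> pd.DataFrame:
        cov = X.drop(columns=[c for c in term_cols if c in X.columns])
        design = pd.DataFrame(index=X.index)
        design["const"] = 1.0
        for c in term_cols:
            design[c] = np.asarray(X[c], dtype=float)
        for c in cov.columns:
            design[c] = np.asarray(cov[c], dtype=float)
        return design

    def _finish(self, res, slope, se, t, p, exact, design, dropped, group_n):
        self.results_ = res
        self.slope_ = slope
        self.stderr_ = se
        self.tvalue_ = t
        self.pvalue_ = p
        self.exact_fit_ = exact
        self.dropped_columns_ = dropped
        self.nobs_ = int(design.shape[0])
        self.df_resid_ = int(res.df_resid)
        self.residuals_ = np.asarray(res.resid)
        self.fitted_values_ = np.asarray(res.fittedvalues)
        self.group_n_ = group_n
        self.feature_names_in_ = list(design.columns)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        design = self._assemble(X, [self._term])
        cols = [c for c in self.feature_names_in_ if c in design.columns]
        return np.asarray(self.results_.predict(design[cols]))

    def to_result(self, pair_id: str, risk_is_designated: bool = True,
                  **extras) -> QtlResult:
        return QtlResult(
            pair_id=pair_id,
            model=self._model_name,
            slope=self.slope_,
            stderr=self.stderr_,
            tvalue=self.tvalue_,
            pvalue=self.pvalue_,
            group_n=self.group_n_,
            direction=_direction(self.slope_, risk_is_designated)
            if self.slope_ != 0 else None,
            covariates=tuple(self.feature_names_in_[2:]),
            extras=extras,
        )


class AeQTLRegressor(_BaseQtlEstimator):
    """Phase-aware allelic-expression QTL regression.

    Fit ``y`` (per-sample fraction_P1) on the 0/1/2 phase-coded risk-SNP
    group plus covariates.

    Parameters
    ----------
    group_col : name of the group column in ``X``.
    coding : "numeric" fits the group as a linear 0/1/2 trend (default);
        "categorical" fits two indicator contrasts and reports the joint
        F-test p with the 0-vs-2 contrast as the slope.

    Attributes (after ``fit``)
    --------------------------
    slope_, stderr_, tvalue_, pvalue_ : the group-effect test.
    group_n_ : usable individuals per group (0, 1, 2).
    dropped_columns_ : covariates removed as collinear.
    """

    _model_name = "aeqtl_gene"

    def __init__(self, group_col: str = "group", coding: str = "numeric"):
        self.group_col = group_col
        self.coding = coding

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        groups = np.asarray(X[self.group_col], dtype=int)
        if not np.isin(groups, [0, 1, 2]).all():
            raise ValueError("risk-SNP group must be 0, 1 or 2")
        gn = tuple(int((groups == k).sum()) for k in (0, 1, 2))

        if self.coding == "numeric":
            design = self._assemble(
                X.assign(group=groups), ["group"]
            )
            design, dropped = _prune_collinear(design, protected=["const", "group"])
            res, slope, se, t, p, exact = _ols(y, design, "group")
            return self._finish(res, slope, se, t, p, exact, design, dropped, gn)

        if self.coding == "categorical":
            Xc = X.drop(columns=[self.group_col]).copy()
            Xc["g1"] = (groups == 1).astype(float)
            Xc["g2"] = (groups == 2).astype(float)
            design = self._assemble(Xc, ["g1", "g2"])
            design, dropped = _prune_collinear(design, ["const", "g1", "g2"])
            res = sm.OLS(y, design).fit()
            ftest = res.f_test(np.eye(len(design.columns))[[1, 2]])
            slope = float(res.params["g2"]) / 2.0  # per-group-step scale
            p = float(ftest.pvalue)
            self._finish(res, slope, float(res.bse["g2"]) / 2.0,
                         float(res.tvalues["g2"]), p, False, design, dropped, gn)
            return self

        raise ValueError(f"unknown coding {self.coding!r}")


class EQTLRegressor(_BaseQtlEstimator):
    """Comparison eQTL model: total expression ~ allele dosage + covariates.

    ``X`` must carry a ``dosage`` column (risk-allele copies 0/1/2, no
    phase needed); ``y`` is expression on the analysis scale (the pipeline
    default is log2(normalized + 1))."""

    _term = "dosage"
    _model_name = "eqtl"

    def __init__(self, dosage_col: str = "dosage"):
        self.dosage_col = dosage_col

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        dosage = np.asarray(X[self.dosage_col], dtype=float)
        gn = tuple(int((dosage == k).sum()) for k in (0, 1, 2))
        design = self._assemble(X.rename(columns={self.dosage_col: "dosage"}),
                                ["dosage"])
        design, dropped = _prune_collinear(design, ["const", "dosage"])
        res, slope, se, t, p, exact = _ols(y, design, "dosage")
        return self._finish(res, slope, se, t, p, exact, design, dropped, gn)


class InteractionRegressor(_BaseQtlEstimator):
    """Moderated aeQTL: fraction ~ group * moderator + covariates.

    The reported p-value is the interaction coefficient's; per-stratum
    main-effect fits are stored in ``stratum_fits_`` (moderator 0 and 1).
    """

    _term = "group:moderator"
    _model_name = "interaction"

    def __init__(self, group_col: str = "group", moderator_col: str = "moderator"):
        self.group_col = group_col
        self.moderator_col = moderator_col

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        groups = np.asarray(X[self.group_col], dtype=float)
        mod = np.asarray(X[self.moderator_col], dtype=float)
        if not np.isin(mod, [0.0, 1.0]).all():
            raise ValueError("moderator must be binary 0/1")
        gn = tuple(int((groups == k).sum()) for k in (0, 1, 2))
        Xi = X.drop(columns=[self.group_col, self.moderator_col]).copy()
        Xi["group"] = groups
        Xi["moderator"] = mod
        Xi["group:moderator"] = groups * mod
        design = self._assemble(Xi, ["group", "moderator", "group:moderator"])
        design, dropped = _prune_collinear(
            design, ["const", "group", "moderator", "group:moderator"]
        )
        res, slope, se, t, p, exact = _ols(y, design, "group:moderator")
        self._finish(res, slope, se, t, p, exact, design, dropped, gn)
        # per-stratum main effects
        self.stratum_fits_ = {}
        for level in (0, 1):
            mask = mod == level
            if mask.sum() >= 4 and len(np.unique(groups[mask])) > 1:
                sub = X.loc[mask].drop(columns=[self.moderator_col])
                self.stratum_fits_[level] = AeQTLRegressor(
                    group_col=self.group_col
                ).fit(sub, y[mask])
        return self


class AllelicVarianceTest(BaseEstimator):
    """Phase-free fallback: allelic imbalance should be more variable in
    risk-heterozygous than risk-homozygous individuals.

    A one-sided Brown-Forsythe-type test: two-sample t on the absolute
    deviations |f - median(f within stratum)|, alternative "greater" for
    the heterozygous stratum.  Needs no phasing, at a steep power cost
    relative to the phase-coded regression.
    """

    def __init__(self):
        pass

    def fit(self, fractions, risk_het):
        f = np.asarray(fractions, dtype=float)
        het = np.asarray(risk_het, dtype=bool)
        if het.all() or (~het).all():
            raise ValueError("need both heterozygous and homozygous strata")
        dev_het = np.abs(f[het] - np.median(f[het]))
        dev_hom = np.abs(f[~het] - np.median(f[~het]))
        if np.ptp(dev_het) == 0 and np.ptp(dev_hom) == 0:
            t, p = 0.0, 1.0  # no dispersion anywhere: no evidence
        else:
            t, p = scipy.stats.ttest_ind(
                dev_het, dev_hom, equal_var=False, alternative="greater"
            )
            t, p = float(t), float(p)
        self.tvalue_ = t
        self.pvalue_ = p
        self.n_het_, self.n_hom_ = int(het.sum()), int((~het).sum())
        self.mean_abs_dev_ = (float(dev_het.mean()), float(dev_hom.mean()))
        return self

    def to_result(self, pair_id: str, **extras) -> QtlResult:
        return QtlResult(
            pair_id=pair_id, model="variance_test",
            slope=self.mean_abs_dev_[0] - self.mean_abs_dev_[1],
            stderr=float("nan"), tvalue=self.tvalue_, pvalue=self.pvalue_,
            group_n=(self.n_het_, self.n_hom_, 0), extras=extras,
        )


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

def compute_pcs(matrix, k: int) -> np.ndarray:
    """Top-k principal-component scores of a samples x features matrix.

    Missing entries are mean-imputed per feature; columns are centered.
    When k exceeds the matrix rank the trailing columns are zero (flagged
    via ``compute_pcs.n_informative_``-style return is avoided: callers get
    a (n_samples, k) array and can inspect column variances).
    """
    X = np.asarray(matrix, dtype=float).copy()
    if X.ndim != 2:
        raise ValueError("expected a 2-D samples x features matrix")
    if np.isnan(X).all(axis=1).any():
        raise ValueError("all-missing sample row")
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    k_eff = min(k, min(X.shape) - 1) if min(X.shape) > 1 else 0
    scores = np.zeros((X.shape[0], k))
    if k_eff > 0:
        pca = PCA(n_components=k_eff, svd_solver="full")
        scores[:, :k_eff] = pca.fit_transform(X)
    return scores


def covariate_frame(
    samples: Sequence[str],
    covariates: Optional[pd.DataFrame],
    geno_pcs: Optional[np.ndarray] = None,
    expr_pcs: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Assemble the standard covariate design: age, sex, genotype PCs,
    expression PCs, plus any extra numeric columns present."""
    out = pd.DataFrame(index=pd.Index(samples, name="sample"))
    if covariates is not None:
        cov = covariates.reindex(samples)
        for c in cov.columns:
            if pd.api.types.is_numeric_dtype(cov[c]):
                out[c] = cov[c].astype(float)
    if geno_pcs is not None:
        for j in range(geno_pcs.shape[1]):
            out[f"geno_pc{j + 1}"] = geno_pcs[:, j]
    if expr_pcs is not None:
        for j in range(expr_pcs.shape[1]):
            out[f"expr_pc{j + 1}"] = expr_pcs[:, j]
    return out


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(pvalues, alpha: float = 0.05):
    """Benjamini-Hochberg step-up.

    Returns (qvalues, significant flags, realized p-value cutoff), where
    the cutoff is the largest p-value called significant (0.0 when none
    are).  Gene-level and txSNP-level families must be corrected in
    separate calls.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool), 0.0
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    cutoff = float(p[reject].max()) if reject.any() else 0.0
    return q, reject, cutoff


def annotate_fdr(results: list[QtlResult], alpha: float = 0.05) -> float:
    """Attach q-values in place to one correction family; returns the
    realized p cutoff."""
    if not results:
        return 0.0
    q, rej, cutoff = bh_fdr([r.pvalue for r in results], alpha)
    for r, qv, s in zip(results, q, rej):
        r.qvalue = float(qv)
        r.extras["significant"] = bool(s)
    return cutoff


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------

def _attach_covariates(X: pd.DataFrame, covariates: Optional[pd.DataFrame],
                       samples) -> pd.DataFrame:
    """Row-align a covariate frame to X, positionally when already aligned."""
    if covariates is None:
        return X
    if len(covariates) == len(X):
        cov = covariates
    else:
        cov = covariates.reindex(samples)
    for c in cov.columns:
        X[c] = cov[c].to_numpy()
    return X


def fit_aeqtl(records: pd.DataFrame, covariates: Optional[pd.DataFrame] = None,
              pair_id: str = "", coding: str = "numeric",
              risk_is_designated: bool = True, **extras) -> QtlResult:
    """Fit the gene-level aeQTL model on a SampleFractionRecord table."""
    X = records[["group"]].reset_index(drop=True)
    samples = records["sample"] if "sample" in records else records.index
    X = _attach_covariates(X, covariates, samples)
    est = AeQTLRegressor(coding=coding).fit(X, records["fraction_p1"])
    return est.to_result(pair_id, risk_is_designated, **extras)


def fit_eqtl(expression, dosage, covariates: Optional[pd.DataFrame] = None,
             pair_id: str = "", **extras) -> QtlResult:
    X = pd.DataFrame({"dosage": np.asarray(dosage, dtype=float)})
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        for c in cov.columns:
            X[c] = cov[c].to_numpy()
    est = EQTLRegressor().fit(X, expression)
    r = est.to_result(pair_id, **extras)
    r.direction = "up" if est.slope_ > 0 else ("down" if est.slope_ < 0 else None)
    return r


def fit_txsnp_aeqtl(per_txsnp_records: pd.DataFrame,
                    covariates: Optional[pd.DataFrame] = None,
                    pair_id: str = "", min_group_n: int = 5,
                    min_groups: int = 2,
                    risk_is_designated: bool = True) -> list[QtlResult]:
    """One aeQTL fit per txSNP, applying the testability rule per txSNP."""
    from .core import testable
    from .types import FilterConfig

    cfg = FilterConfig(min_group_n=min_group_n, min_groups=min_groups)
    out = []
    aligned = covariates is not None and len(covariates) == len(per_txsnp_records)
    for tid in sorted(per_txsnp_records["txsnp_id"].unique()):
        mask = (per_txsnp_records["txsnp_id"] == tid).to_numpy()
        block = per_txsnp_records[mask]
        if not testable(block["group"], cfg):
            continue
        cov_b = covariates[mask] if aligned else covariates
        r = fit_aeqtl(block, cov_b, pair_id=f"{pair_id}:{tid}",
                      risk_is_designated=risk_is_designated, txsnp_id=tid)
        r.model = "aeqtl_txsnp"
        out.append(r)
    return out


def fit_interaction(records: pd.DataFrame, moderator,
                    covariates: Optional[pd.DataFrame] = None,
                    pair_id: str = "") -> QtlResult:
    X = records[["group"]].reset_index(drop=True)
    X["moderator"] = np.asarray(moderator, dtype=float)
    samples = records["sample"] if "sample" in records else records.index
    X = _attach_covariates(X, covariates, samples)
    est = InteractionRegressor().fit(X, records["fraction_p1"])
    r = est.to_result(pair_id)
    r.extras["stratum_pvalues"] = {
        k: v.pvalue_ for k, v in est.stratum_fits_.items()
    }
    return r


def variance_test(fractions, risk_het, pair_id: str = "") -> QtlResult:
    return AllelicVarianceTest().fit(fractions, risk_het).to_result(pair_id)
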