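"""Best-subset model building for the critical shoulder angle.

The statistical stage mirrors the study design: Pearson screening of the 17
candidate predictors, variance-inflation-factor (VIF) assessment of
collinearity, leave-one-out cross-validation (LOOCV) combined with
exhaustive best-subset linear regression to pick the model size and
membership, and drop-one AIC / adjusted-R² importance for the selected
variables.

The public surface is a statsmodels-style pair: :class:`CSAPredictorModel`
is built from a cohort table and its :meth:`~CSAPredictorModel.fit` returns
a :class:`SubsetSelectionResults` carrying the LOOCV error curve, the
selected model with coefficient estimates/CIs/p-values, and methods for the
drop-one importance table and residual diagnostics.  Module-level functions
(`pearson_screen`, `vif`, `loocv_best_subset`, `collinearity_loop`,
`drop_one`, `diagnostics`) wrap the same machinery.

Cross-validation is honest by default: the best subset of every size is
re-selected inside each leave-one-out fold.  This is computed exactly (not
approximately) through the deleted-residual identities

    RSS_{-i}(S) = RSS(S) - e_i^2 / (1 - h_i),     e_{loo,i} = e_i / (1 - h_i),

which reproduce the literal refit-per-fold procedure while enumerating each
subset only once.  A ``cv="fixed"`` mode cross-validates the full-data best
subset of each size instead, for comparison.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ModelBuildError",
    "CSAPredictorModel",
    "SubsetSelectionResults",
    "DropOneReport",
    "DiagnosticsReport",
    "pearson_screen",
    "vif",
    "aic_gaussian",
    "loocv_best_subset",
    "collinearity_loop",
    "drop_one",
    "diagnostics",
]

MAX_EXHAUSTIVE_PREDICTORS = 20


class ModelBuildError(ValueError):
    """Raised for invalid model-building inputs or budgets."""


def aic_gaussian(rss: float, n: int, k_slopes: int) -> float:
    """Gaussian profile-likelihood AIC, counting intercept and variance.

    AIC = n·log(RSS/n) + 2·(k + 2) for k slope parameters; additive
    constants (n·log 2π + n) are dropped, which cancels in comparisons
    between models fit to the same data.
    """
    if rss <= 0:
        rss = np.finfo(float).tiny
    return float(n * np.log(rss / n) + 2.0 * (k_slopes + 2))


def _validate_table(table: pd.DataFrame, outcome: str) -> tuple[pd.DataFrame, pd.Series]:
    if outcome not in table.columns:
        raise ModelBuildError(f"outcome column {outcome!r} not in table")
    if table.isna().any().any():
        raise ModelBuildError("table contains missing values")
    X = table.drop(columns=[outcome]).astype(float)
    y = table[outcome].astype(float)
    zero_var = X.columns[X.std(ddof=0) == 0.0]
    if len(zero_var):
        raise ModelBuildError(f"zero-variance column(s): {list(zero_var)}")
    return X, y


def pearson_screen(table: pd.DataFrame, outcome: str = "CSA") -> pd.Series:
    """Sample Pearson correlation of each predictor with the outcome."""
    X, y = _validate_table(table, outcome)
    if len(X) < 3:
        raise ModelBuildError("need at least 3 rows for correlation screening")
    r = {c: float(stats.pearsonr(X[c], y)[0]) for c in X.columns}
    return pd.Series(r, name="pearson_r")


def vif(table: pd.DataFrame, variables: list[str] | None = None,
        outcome: str = "CSA") -> pd.Series:
    """Variance inflation factor 1/(1−R²) per predictor.

    Each variable is regressed (with intercept) on the remaining ones; the
    outcome column is excluded from the design.
    """
    if outcome in table.columns:
        X, _ = _validate_table(table, outcome)
    else:
        X = table.astype(float)
    if variables is not None:
        X = X[list(variables)]
    cols = list(X.columns)
    if len(cols) < 2:
        raise ModelBuildError("VIF needs at least 2 variables")
    A = np.column_stack([np.ones(len(X)), X.to_numpy()])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ModelBuildError("design matrix is rank deficient; VIF undefined")
    out = {}
    Xv = X.to_numpy()
    for j, c in enumerate(cols):
        yj = Xv[:, j]
        Dj = np.column_stack([np.ones(len(Xv)), np.delete(Xv, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Dj, yj, rcond=None)
        resid = yj - Dj @ beta
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / ss_tot
        out[c] = float(1.0 / max(1.0 - r2, np.finfo(float).eps))
    return pd.Series(out, name="vif")


# ---------------------------------------------------------------------------
# Exhaustive subset enumeration with exact LOOCV


def _subset_scan(
    Xc: np.ndarray,
    yc: np.ndarray,
    sizes: range,
    chunk: int = 4096,
):
    """Scan all subsets of each size once; yield per-size summaries.

    For every subset the full-data RSS, the per-fold deleted RSS and the
    per-fold deleted (LOO) residuals are computed via the leverage
    identities.  Returns, per size k:
      best_full: (subset, rss) minimizing full-data RSS;
      fold_best: per fold, the minimum deleted-RSS subset and its LOO error.
    """
    n, p = Xc.shape
    G = Xc.T @ Xc
    g = Xc.T @ yc
    yty = float(yc @ yc)
    for k in sizes:
        best_rss = np.inf
        best_sub: tuple[int, ...] | None = None
        fold_best_rss = np.full(n, np.inf)
        fold_best_loo = np.full(n, np.nan)
        fold_best_sub = [None] * n
        combos = itertools.combinations(range(p), k)
        while True:
            A = np.fromiter(
                itertools.chain.from_iterable(itertools.islice(combos, chunk)),
                dtype=np.intp,
            ).reshape(-1, k)
            if len(A) == 0:
                break
            Gs = G[A[:, :, None], A[:, None, :]]
            gs = g[A]
            try:
                beta = np.linalg.solve(Gs, gs[..., None])[..., 0]
            except np.linalg.LinAlgError:
                beta = np.stack([
                    np.linalg.lstsq(Gs[i], gs[i], rcond=None)[0]
                    for i in range(len(A))
                ])
            rss = yty - np.einsum("mk,mk->m", beta, gs)
            Xs = Xc[:, A]                         # (n, m, k)
            e = yc[:, None] - np.einsum("nmk,mk->nm", Xs, beta)
            try:
                Ct = np.linalg.solve(Gs, np.transpose(Xs, (1, 2, 0)))
            except np.linalg.LinAlgError:
                Ct = np.stack([
                    np.linalg.lstsq(Gs[i], Xs[:, i, :].T, rcond=None)[0]
                    for i in range(len(A))
                ])
            h = 1.0 / n + np.einsum("nmk,mkn->nm", Xs, Ct)
            denom = 1.0 - h
            bad = denom < 1e-10
            denom = np.where(bad, np.nan, denom)
            fold_rss = rss[None, :] - e * e / denom
            loo = e / denom
            fold_rss = np.where(bad, np.inf, fold_rss)

            j = int(np.argmin(rss))
            if rss[j] < best_rss:
                best_rss = float(rss[j])
                best_sub = tuple(int(v) for v in A[j])
            jf = np.argmin(fold_rss, axis=1)
            rows = np.arange(n)
            better = fold_rss[rows, jf] < fold_best_rss
            fold_best_rss[better] = fold_rss[rows, jf][better]
            fold_best_loo[better] = loo[rows, jf][better]
            for i in np.nonzero(better)[0]:
                fold_best_sub[i] = tuple(int(v) for v in A[jf[i]])
        yield k, (best_sub, best_rss), (fold_best_sub, fold_best_loo)


def _loocv_fixed_subset(Xc: np.ndarray, yc: np.ndarray, cols: tuple[int, ...]) -> np.ndarray:
    """Exact LOO residuals for one fixed subset via the leverage identity."""
    n = len(yc)
    Xs = Xc[:, cols]
    G = Xs.T @ Xs
    beta = np.linalg.lstsq(G, Xs.T @ yc, rcond=None)[0]
    e = yc - Xs @ beta
    h = 1.0 / n + np.einsum("nk,nk->n", Xs, np.linalg.lstsq(G, Xs.T, rcond=None)[0].T)
    return e / (1.0 - h)


# ---------------------------------------------------------------------------
# Results objects


@dataclass
class DropOneReport:
    """AIC and adjusted R² of the optimal model refit without each variable."""

    table: pd.DataFrame  # index: removed variable; columns: aic, adj_r2

    @property
    def ranking(self) -> list[str]:
        """Variables ranked most-important first (largest AIC on removal)."""
        return list(self.table.sort_values("aic", ascending=False).index)


@dataclass
class DiagnosticsReport:
    """Residual diagnostics for a fitted model."""

    residuals: np.ndarray
    fitted: np.ndarray
    skew: float
    excess_kurtosis: float
    probplot_r: float
    het_abs_resid_corr: float
    heteroscedastic: bool

    def plot(self, path=None):
        """Residual-vs-fitted and normal probability plots (optional file)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        axes[0].scatter(self.fitted, self.residuals, s=12)
        axes[0].axhline(0.0, color="k", lw=0.8)
        axes[0].set_xlabel("fitted CSA (deg)")
        axes[0].set_ylabel("residual (deg)")
        stats.probplot(self.residuals, plot=axes[1])
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


@dataclass
class SubsetSelectionResults:
    """Outcome of LOOCV best-subset selection on a cohort table.

    Attributes mirror the model-building procedure: ``mse_by_size`` is the
    average leave-one-out squared prediction error for each model size,
    ``optimal_size`` its argmin (ties toward the smaller size), and
    ``coefficients`` the full-data OLS fit of the best subset of that size
    with normal-theory 95% confidence bounds.  P-values are reported but
    are not a selection criterion.
    """

    mse_by_size: pd.Series
    optimal_size: int
    selected_variables: list[str]
    coefficients: pd.DataFrame
    full_model_mse: float
    loocv_mse: float
    adjusted_r2: float
    vif_by_variable: pd.Series
    removed_collinear: list[str] = field(default_factory=list)
    cv_mode: str = "honest"
    _model: "CSAPredictorModel | None" = field(default=None, repr=False)

    def __post_init__(self) -> None:
        tol = 1e-12 * float(self.mse_by_size.max()) + np.finfo(float).tiny
        if self.mse_by_size.loc[self.optimal_size] > float(self.mse_by_size.min()) + tol:
            raise ModelBuildError("optimal_size must be the argmin of mse_by_size")
        if len(self.selected_variables) != self.optimal_size:
            raise ModelBuildError("selected set size mismatch")

    # -- derived reports ----------------------------------------------------
    def drop_one(self) -> DropOneReport:
        """Refit the optimal model leaving each selected variable out."""
        m = self._require_model()
        rows = {}
        X, y = m.exog, m.endog
        n = len(y)
        for v in self.selected_variables:
            keep = [c for c in self.selected_variables if c != v]
            res = sm.OLS(y, sm.add_constant(X[keep])).fit()
            rows[v] = {
                "aic": aic_gaussian(float(res.ssr), n, len(keep)),
                "adj_r2": float(res.rsquared_adj),
            }
        return DropOneReport(pd.DataFrame(rows).T[["aic", "adj_r2"]])

    def diagnostics(self, het_threshold: float = 0.3) -> DiagnosticsReport:
        """Normality and constant-variance summaries of the residuals."""
        m = self._require_model()
        res = sm.OLS(
            m.endog, sm.add_constant(m.exog[self.selected_variables])
        ).fit()
        resid = np.asarray(res.resid)
        fitted = np.asarray(res.fittedvalues)
        (_, _), (_, _, pr) = stats.probplot(resid)
        het = float(np.corrcoef(np.abs(resid), fitted)[0, 1])
        return DiagnosticsReport(
            residuals=resid,
            fitted=fitted,
            skew=float(stats.skew(resid)),
            excess_kurtosis=float(stats.kurtosis(resid)),
            probplot_r=float(pr),
            het_abs_resid_corr=het,
            heteroscedastic=bool(abs(het) > het_threshold),
        )

    def summary(self) -> str:
        """Human-readable selection summary."""
        lines = [
            "LOOCV best-subset selection".center(64),
            "=" * 64,
            f"cv mode: {self.cv_mode}    optimal size: {self.optimal_size}"
            f"    LOOCV MSE: {self.loocv_mse:.3f}",
            f"full-data MSE: {self.full_model_mse:.3f}"
            f"    adjusted R2: {self.adjusted_r2:.3f}",
        ]
        if self.removed_collinear:
            lines.append(f"removed (collinear): {', '.join(self.removed_collinear)}")
        lines.append("-" * 64)
        lines.append("LOOCV MSE by model size:")
        for k, v in self.mse_by_size.items():
            marker = " <-- optimal" if int(k) == self.optimal_size else ""
            lines.append(f"  size {int(k):2d}: {v:10.3f}{marker}")
        lines.append("-" * 64)
        lines.append(self.coefficients.to_string(float_format=lambda x: f"{x:10.3f}"))
        lines.append("=" * 64)
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "cv_mode": self.cv_mode,
            "mse_by_size": {int(k): float(v) for k, v in self.mse_by_size.items()},
            "optimal_size": int(self.optimal_size),
            "selected_variables": list(self.selected_variables),
            "coefficients": self.coefficients.reset_index()
            .rename(columns={"index": "term"}).to_dict(orient="records"),
            "full_model_mse": float(self.full_model_mse),
            "loocv_mse": float(self.loocv_mse),
            "adjusted_r2": float(self.adjusted_r2),
            "vif_by_variable": {k: float(v) for k, v in self.vif_by_variable.items()},
            "removed_collinear": list(self.removed_collinear),
        }

    def _require_model(self) -> "CSAPredictorModel":
        if self._model is None:
            raise ModelBuildError("results are detached from their model/table")
        return self._model


class CSAPredictorModel:
    """Multivariable linear prediction model for the CSA.

    Parameters
    ----------
    table : DataFrame with the predictor columns and the outcome column
        (default "CSA", degrees).  No missing values are allowed.
    outcome : outcome column name.
    """

    def __init__(self, table: pd.DataFrame, outcome: str = "CSA") -> None:
        X, y = _validate_table(table, outcome)
        if len(X.columns) > MAX_EXHAUSTIVE_PREDICTORS:
            raise ModelBuildError(
                f"{len(X.columns)} predictors exceed the exhaustive-search "
                f"budget ({MAX_EXHAUSTIVE_PREDICTORS}); reduce the candidate "
                "set or cap max_size"
            )
        self.table = table.reset_index(drop=True)
        self.outcome = outcome
        self.exog = X.reset_index(drop=True)
        self.endog = y.reset_index(drop=True)

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, outcome: str = "CSA"):
        return cls(table, outcome=outcome)

    @property
    def nobs(self) -> int:
        return len(self.endog)

    def screen(self) -> pd.Series:
        return pearson_screen(self.table, self.outcome)

    def vif(self) -> pd.Series:
        return vif(self.table, outcome=self.outcome)

    def fit(
        self,
        max_size: int | None = None,
        cv: str = "honest",
        chunk: int = 4096,
    ) -> SubsetSelectionResults:
        """Run LOOCV + best-subset selection and fit the optimal model.

        ``cv="honest"`` reselects the best subset of each size inside every
        leave-one-out fold; ``cv="fixed"`` selects per-size subsets on the
        full data first and cross-validates those fixed subsets.
        """
        X = self.exog.to_numpy(dtype=float)
        y = self.endog.to_numpy(dtype=float)
        n, p = X.shape
        if max_size is None:
            max_size = min(p, n - 2)
        if max_size >= n - 1:
            raise ModelBuildError("max_size must be < n - 1 for LOOCV")
        if max_size < 1 or max_size > p:
            raise ModelBuildError("max_size must lie in [1, n_predictors]")
        if cv not in ("honest", "fixed"):
            raise ModelBuildError("cv must be 'honest' or 'fixed'")

        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        mse = {}
        best_full = {}
        for k, (bsub, brss), (fsub, floo) in _subset_scan(
            Xc, yc, range(1, max_size + 1), chunk=chunk
        ):
            best_full[k] = (bsub, brss)
            if cv == "honest":
                mse[k] = float(np.mean(floo**2))
            else:
                loo = _loocv_fixed_subset(Xc, yc, bsub)
                mse[k] = float(np.mean(loo**2))
        mse_by_size = pd.Series(mse).sort_index()
        # Ties break toward the smaller size (parsimony); a tiny relative
        # tolerance treats numerically indistinguishable minima (e.g. the
        # exactly-interpolating sizes of a noiseless cohort) as ties.
        tol = 1e-12 * float(mse_by_size.max()) + np.finfo(float).tiny
        min_mse = float(mse_by_size.min())
        optimal_size = int(min(k for k, v in mse_by_size.items() if v <= min_mse + tol))
        sel_idx, sel_rss = best_full[optimal_size]
        names = [self.exog.columns[i] for i in sel_idx]

        ols = sm.OLS(y, sm.add_constant(self.exog[names])).fit()
        ci = ols.conf_int(alpha=0.05)
        coef = pd.DataFrame(
            {
                "estimate": ols.params,
                "ci_lower": ci[0] if isinstance(ci, pd.DataFrame) else ci[:, 0],
                "ci_upper": ci[1] if isinstance(ci, pd.DataFrame) else ci[:, 1],
                "p_value": ols.pvalues,
            }
        )
        try:
            vifs = vif(self.table, outcome=self.outcome)
        except ModelBuildError:
            vifs = pd.Series(dtype=float, name="vif")
        return SubsetSelectionResults(
            mse_by_size=mse_by_size,
            optimal_size=optimal_size,
            selected_variables=names,
            coefficients=coef,
            full_model_mse=float(sel_rss / n),
            loocv_mse=float(mse_by_size.loc[optimal_size]),
            adjusted_r2=float(ols.rsquared_adj),
            vif_by_variable=vifs,
            cv_mode=cv,
            _model=self,
        )


# ---------------------------------------------------------------------------
# Functional surface


def loocv_best_subset(
    table: pd.DataFrame,
    max_size: int | None = None,
    outcome: str = "CSA",
    cv: str = "honest",
) -> SubsetSelectionResults:
    """LOOCV + best-subset selection on a cohort table (see model class)."""
    return CSAPredictorModel(table, outcome=outcome).fit(max_size=max_size, cv=cv)


def collinearity_loop(
    table: pd.DataFrame,
    vif_threshold: float = 10.0,
    max_size: int | None = None,
    outcome: str = "CSA",
    cv: str = "honest",
) -> tuple[SubsetSelectionResults, list[dict]]:
    """Remove high-VIF variables one at a time in separate selection runs.

    Every variable whose VIF exceeds the threshold is removed singly, a full
    model-building run is executed for each candidate removal (plus the
    no-removal baseline), and the run whose optimal model attains the
    smallest LOOCV MSE is returned together with the full trace.
    """
    try:
        vifs = vif(table, outcome=outcome)
        flagged = [c for c in vifs.index if vifs[c] > vif_threshold]
    except ModelBuildError:
        # VIF is undefined (e.g. fewer rows than predictors); nothing can be
        # flagged, so only the baseline run executes.
        flagged = []
    predictors = [c for c in table.columns if c != outcome]
    candidates: list[list[str]] = [[]]
    for v in flagged:
        if len(predictors) - 1 < 1:
            raise ModelBuildError("collinearity removal would delete all variables")
        candidates.append([v])
    trace = []
    best: SubsetSelectionResults | None = None
    for removed in candidates:
        sub = table.drop(columns=removed)
        res = loocv_best_subset(sub, max_size=max_size, outcome=outcome, cv=cv)
        res.removed_collinear = list(removed)
        trace.append(
            {
                "removed": list(removed),
                "optimal_size": res.optimal_size,
                "loocv_mse": res.loocv_mse,
                "selected": list(res.selected_variables),
            }
        )
        if best is None or res.loocv_mse < best.loocv_mse:
            best = res
    assert best is not None
    return best, trace


def drop_one(result: SubsetSelectionResults, table: pd.DataFrame | None = None) -> DropOneReport:
    """Drop-one importance of the selected variables (see results class)."""
    if table is not None and result._model is None:
        result._model = CSAPredictorModel(table)
    return result.drop_one()


def diagnostics(
    result: SubsetSelectionResults, table: pd.DataFrame | None = None
) -> DiagnosticsReport:
    """Residual diagnostics of the optimal model (see results class)."""
    if table is not None and result._model is None:
        result._model = CSAPredictorModel(table)
    return result.diagnostics()
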