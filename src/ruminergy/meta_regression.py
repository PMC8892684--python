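"""Citation-adjusted mixed-model meta-regression on treatment-mean databases.

The model for the DE→ME relationship is a linear mixed model with the study
citation as the grouping factor:

    y_ij = (β0 + u_i) + (β1 + v_i) · x_ij + ε_ij

with (u_i, v_i) bivariate normal study deviations and independent residuals.
Fitting is by REML.  *Citation-adjusted* data (the St-Pierre construction)
remove the predicted study deviations from each observation,

    y_adj_ij = y_ij − (û_i + v̂_i · x_ij),

so an ordinary regression of y_adj on x displays the fixed-effect
relationship; r² and RMSPE of that ordinary regression are the precision and
accuracy statistics reported for the model.

The same machinery with an intercept-only fixed part and a random study
intercept yields the citation-adjusted mean of a quantity (used for the
methane energy yield per kg of DMI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

__all__ = [
    "MixedEnergyRegression",
    "MixedRegressionResults",
    "AdjustedData",
    "FitStats",
    "fit_lmm",
    "citation_adjust",
    "adjusted_fit_stats",
    "citation_adjusted_mean",
]


@dataclass
class AdjustedData:
    """Per-observation citation-adjusted response paired with its covariate."""

    x: np.ndarray
    y_adj: np.ndarray
    study: np.ndarray
    source: "MixedRegressionResults | None" = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"study": self.study, "x": self.x, "y_adj": self.y_adj})


@dataclass
class FitStats:
    """Precision/accuracy of the ordinary regression on adjusted data."""

    slope: float
    intercept: float
    r2: float
    rmspe: float
    p_intercept: float
    p_slope: float
    n: int


@dataclass
class MixedRegressionResults:
    """REML estimates of the study-level mixed regression.

    ``structure`` records where on the fallback ladder the fit succeeded:
    ``intercept_slope`` (correlated random intercept and slope),
    ``intercept_slope_uncorrelated``, ``intercept_only``, or ``ols`` (no
    random structure identifiable — single study or an exact fit).
    """

    beta0: float
    beta1: float | None
    se_beta0: float
    se_beta1: float | None
    ci_beta0: tuple[float, float]
    ci_beta1: tuple[float, float] | None
    p_beta0: float
    p_beta1: float | None
    var_u: float
    var_v: float
    cov_uv: float
    sigma2: float
    blups: pd.DataFrame  # index: study; columns u, v
    converged: bool
    structure: str
    n_obs: int
    n_studies: int
    notes: list[str] = field(default_factory=list)
    _x: np.ndarray | None = None
    _y: np.ndarray | None = None
    _study: np.ndarray | None = None

    # -- citation adjustment ------------------------------------------------
    def citation_adjust(self, x=None, y=None, study=None) -> AdjustedData:
        return citation_adjust(
            self._x if x is None else np.asarray(x, float),
            self._y if y is None else np.asarray(y, float),
            self._study if study is None else np.asarray(study),
            self,
        )

    def adjusted_fit_stats(self) -> FitStats:
        return adjusted_fit_stats(self.citation_adjust())

    def summary(self) -> str:
        lines = [
            "Mixed-model regression (REML)",
            f"  structure: {self.structure}   converged: {self.converged}",
            f"  n_obs = {self.n_obs}, n_studies = {self.n_studies}",
            f"  intercept = {self.beta0:.4f}  (SE {self.se_beta0:.4f}, "
            f"95% CI [{self.ci_beta0[0]:.4f}, {self.ci_beta0[1]:.4f}], p = {self.p_beta0:.3g})",
        ]
        if self.beta1 is not None:
            lines.append(
                f"  slope     = {self.beta1:.4f}  (SE {self.se_beta1:.4f}, "
                f"95% CI [{self.ci_beta1[0]:.4f}, {self.ci_beta1[1]:.4f}], p = {self.p_beta1:.3g})"
            )
        lines.append(
            f"  var(u) = {self.var_u:.5f}, var(v) = {self.var_v:.5f}, "
            f"cov(u,v) = {self.cov_uv:.5f}, sigma2 = {self.sigma2:.5f}"
        )
        for n in self.notes:
            lines.append(f"  note: {n}")
        return "\n".join(lines)


class MixedEnergyRegression:
    """Model object: y regressed on x with study-level random deviations.

    Parameters
    ----------
    y, x : response and covariate vectors (e.g. ME and DE, Mcal/kg DM).
        ``x=None`` fits an intercept-only model (citation-adjusted mean).
    study : study/citation identifier per observation.
    random : ``"intercept_slope"`` (default) or ``"intercept_only"``.
    """

    def __init__(self, y, x, study, random: str = "intercept_slope"):
        self.y = np.asarray(y, dtype=float)
        self.x = None if x is None else np.asarray(x, dtype=float)
        self.study = np.asarray(study)
        if random not in {"intercept_slope", "intercept_only"}:
            raise ValueError("random must be 'intercept_slope' or 'intercept_only'")
        if self.x is None and random == "intercept_slope":
            random = "intercept_only"
        self.random = random
        if len(self.y) < 3:
            raise ValueError("need at least 3 observations")
        if self.x is not None and len(self.x) != len(self.y):
            raise ValueError("x and y lengths differ")
        if len(self.study) != len(self.y):
            raise ValueError("study and y lengths differ")
        if self.x is not None and np.ptp(self.x) == 0 and random != "intercept_only":
            raise ValueError("x is constant; only an intercept-only model is identifiable")

    @classmethod
    def from_database(cls, db, y: str = "me", x: str | None = "de", **kw):
        from .data import with_derived

        f = with_derived(db)
        cols = [y] + ([x] if x else [])
        mask = f[cols].notna().all(axis=1)
        f = f[mask]
        return cls(f[y].to_numpy(), f[x].to_numpy() if x else None, f["citation_id"].to_numpy(), **kw)

    # -- fitting ------------------------------------------------------------
    def _exog(self):
        if self.x is None:
            return np.ones((len(self.y), 1)), ["intercept"]
        return np.column_stack([np.ones_like(self.x), self.x]), ["intercept", "x"]

    def _ols_result(self, note: str) -> MixedRegressionResults:
        exog, names = self._exog()
        beta, *_ = np.linalg.lstsq(exog, self.y, rcond=None)
        resid = self.y - exog @ beta
        n, p = exog.shape
        dof = max(n - p, 1)
        sigma2 = float(resid @ resid / dof)
        cov = sigma2 * np.linalg.pinv(exog.T @ exog)
        se = np.sqrt(np.diag(cov))
        tq = stats.t.ppf(0.975, dof)
        studies = list(dict.fromkeys(self.study))
        blups = pd.DataFrame(0.0, index=pd.Index(studies, name="study"), columns=["u", "v"])

        def ci(i):
            return (beta[i] - tq * se[i], beta[i] + tq * se[i])

        def pval(i):
            if se[i] == 0:
                return 0.0 if beta[i] != 0 else 1.0
            return float(2 * stats.t.sf(abs(beta[i] / se[i]), dof))

        has_slope = len(beta) > 1
        return MixedRegressionResults(
            beta0=float(beta[0]),
            beta1=float(beta[1]) if has_slope else None,
            se_beta0=float(se[0]),
            se_beta1=float(se[1]) if has_slope else None,
            ci_beta0=ci(0),
            ci_beta1=ci(1) if has_slope else None,
            p_beta0=pval(0),
            p_beta1=pval(1) if has_slope else None,
            var_u=0.0,
            var_v=0.0,
            cov_uv=0.0,
            sigma2=sigma2,
            blups=blups,
            converged=True,
            structure="ols",
            n_obs=n,
            n_studies=len(studies),
            notes=[note],
            _x=self.x,
            _y=self.y,
            _study=self.study,
        )

    def fit(self, reml: bool = True) -> MixedRegressionResults:
        """REML fit with an automatic fallback ladder for singular structures.

        Ladder: correlated intercept+slope → uncorrelated → intercept-only →
        ordinary least squares.  Each step down is recorded in ``notes``; the
        ``converged`` flag is honest (a flagged, non-converged result is
        returned rather than raising).
        """
        studies = list(dict.fromkeys(self.study))
        if len(studies) < 2:
            return self._ols_result("single study: random variances not identifiable, OLS fit")

        exog, names = self._exog()
        # an exact linear fit leaves nothing for the variance components
        beta_ols, *_ = np.linalg.lstsq(exog, self.y, rcond=None)
        resid = self.y - exog @ beta_ols
        if np.max(np.abs(resid)) < 1e-10 * max(1.0, float(np.max(np.abs(self.y)))):
            return self._ols_result("response is an exact linear function of x; variances ~ 0")

        ladder: list[str]
        if self.random == "intercept_slope":
            ladder = ["intercept_slope", "intercept_slope_uncorrelated", "intercept_only"]
        else:
            ladder = ["intercept_only"]

        notes: list[str] = []
        last = None
        for structure in ladder:
            res = self._fit_structure(structure, reml, notes)
            if res is not None:
                last = res
                if res.converged and self._structure_ok(res):
                    res.notes = notes + res.notes
                    return res
                notes.append(f"{structure}: singular or non-converged, stepping down")
        if last is not None:
            last.notes = notes + last.notes + ["returning last (flagged) fit on the ladder"]
            return last
        out = self._ols_result("all mixed structures failed; OLS fallback")
        out.converged = False
        out.notes = notes + out.notes
        return out

    @staticmethod
    def _structure_ok(res: "MixedRegressionResults") -> bool:
        if not np.isfinite([res.var_u, res.var_v, res.sigma2, res.beta0]).all():
            return False
        if res.var_u < 0 or res.var_v < 0 or res.sigma2 < 0:
            return False
        if res.var_u > 0 and res.var_v > 0:
            corr = res.cov_uv / np.sqrt(res.var_u * res.var_v)
            if abs(corr) > 1 + 1e-8:
                return False
        return True

    def _fit_structure(self, structure: str, reml: bool, notes: list[str]):
        exog, names = self._exog()
        re_slope = structure.startswith("intercept_slope") and self.x is not None
        exog_re = (
            np.column_stack([np.ones_like(self.y), self.x]) if re_slope
            else np.ones((len(self.y), 1))
        )
        model = MixedLM(self.y, exog, groups=self.study, exog_re=exog_re)
        free = None
        if structure == "intercept_slope_uncorrelated":
            free = MixedLMParams.from_components(
                fe_params=np.ones(exog.shape[1]), cov_re=np.eye(2)
            )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = model.fit(reml=reml, free=free, method=["lbfgs", "powell"], maxiter=2000)
        except (np.linalg.LinAlgError, ValueError):
            return None

        fe = np.asarray(fit.fe_params, dtype=float)
        se = np.asarray(fit.bse_fe, dtype=float)
        cov_re = np.asarray(fit.cov_re, dtype=float)
        var_u = float(cov_re[0, 0])
        var_v = float(cov_re[1, 1]) if re_slope else 0.0
        cov_uv = float(cov_re[0, 1]) if re_slope else 0.0
        sigma2 = float(fit.scale)
        studies = list(dict.fromkeys(self.study))
        try:
            re_dict = fit.random_effects
        except (ValueError, np.linalg.LinAlgError):
            # variance component on the boundary (~0): the BLUPs are zero
            re_dict = {s: np.zeros(2 if re_slope else 1) for s in studies}
            notes.append("singular random-effect covariance: BLUPs set to 0")
        blup_rows = []
        for s in studies:
            vals = np.asarray(re_dict[s], dtype=float)
            u = float(vals[0])
            v = float(vals[1]) if re_slope and len(vals) > 1 else 0.0
            blup_rows.append((u, v))
        blups = pd.DataFrame(
            blup_rows, index=pd.Index(studies, name="study"), columns=["u", "v"]
        )

        # between-study t reference for fixed-effect inference
        dof = max(len(studies) - exog.shape[1], 1)
        tq = stats.t.ppf(0.975, dof)

        def ci(i):
            return (float(fe[i] - tq * se[i]), float(fe[i] + tq * se[i]))

        def pval(i):
            if se[i] == 0:
                return 0.0 if fe[i] != 0 else 1.0
            return float(2 * stats.t.sf(abs(fe[i] / se[i]), dof))

        has_slope = exog.shape[1] > 1
        return MixedRegressionResults(
            beta0=float(fe[0]),
            beta1=float(fe[1]) if has_slope else None,
            se_beta0=float(se[0]),
            se_beta1=float(se[1]) if has_slope else None,
            ci_beta0=ci(0),
            ci_beta1=ci(1) if has_slope else None,
            p_beta0=pval(0),
            p_beta1=pval(1) if has_slope else None,
            var_u=var_u,
            var_v=var_v,
            cov_uv=cov_uv,
            sigma2=sigma2,
            blups=blups,
            converged=bool(fit.converged),
            structure=structure,
            n_obs=len(self.y),
            n_studies=len(studies),
            notes=[],
            _x=self.x,
            _y=self.y,
            _study=self.study,
        )


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------


def fit_lmm(x, y, study, random: str = "intercept_slope") -> MixedRegressionResults:
    """Fit the study-level mixed regression of y on x (see the module docstring)."""
    return MixedEnergyRegression(y, x, study, random=random).fit()


def citation_adjust(x, y, study, fit: MixedRegressionResults) -> AdjustedData:
    """Remove predicted study deviations: y_adj = y − (û_i + v̂_i·x)."""
    x = np.zeros(len(y)) if x is None else np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    study = np.asarray(study)
    known = set(fit.blups.index)
    unknown = sorted({s for s in study} - known)
    if unknown:
        raise ValueError(f"studies not present in the fitted model: {unknown}")
    u = fit.blups["u"].reindex(study).to_numpy()
    v = fit.blups["v"].reindex(study).to_numpy()
    return AdjustedData(x=x, y_adj=y - (u + v * x), study=study, source=fit)


def adjusted_fit_stats(adj: AdjustedData) -> FitStats:
    """Ordinary regression of the adjusted response on x: r², RMSPE, p-values.

    RMSPE uses the n denominator (prediction-error convention), so it equals
    the root of the mean squared residual of the displayed line.
    """
    x, y = adj.x, adj.y_adj
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 adjusted points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    rmspe = float(np.sqrt(sse / n))
    dof = n - 2
    s2 = sse / dof if dof > 0 else 0.0
    cov = s2 * np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.diag(cov))

    def pval(i):
        if se[i] == 0:
            return 0.0 if beta[i] != 0 else 1.0
        return float(2 * stats.t.sf(abs(beta[i] / se[i]), dof))

    return FitStats(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        r2=float(r2),
        rmspe=rmspe,
        p_intercept=pval(0),
        p_slope=pval(1),
        n=n,
    )


def citation_adjusted_mean(y, study) -> dict:
    """Citation-adjusted mean of y: the fixed intercept of an intercept-only
    mixed model with a random study intercept.  Returns the estimate, its SE,
    95% CI, and the underlying results object."""
    res = MixedEnergyRegression(y, None, study, random="intercept_only").fit()
    return {"mean": res.beta0, "se": res.se_beta0, "ci": res.ci_beta0, "fit": res}
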