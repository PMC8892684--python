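"""Precision/accuracy evaluation of methane prediction equations.

Given observed and predicted daily methane, the statistics reported per
equation are:

* r² and the regression of observed on predicted, with t-based 95% CIs for
  the intercept and slope (a good equation has intercept CI covering 0 and
  slope CI covering 1);
* RMSPE = sqrt(mean((pred − obs)²)) and RMSPE as % of the observed mean;
* the decomposition of MSPE into mean bias (p̄ − ō)², slope bias
  (s_p − r·s_o)², and random error (1 − r²)·s_o², expressed as % of MSPE —
  all moments use the population (n) denominator so the three components sum
  to MSPE exactly;
* Lin's concordance correlation coefficient,
  CCC = 2·cov(o,p) / (var(o) + var(p) + (ō − p̄)²).

Note on conventions: report headers in this literature sometimes label the
bias columns "% of RMSPE", but the components can only sum to 100 as
percentages of the (squared) MSPE, which is the scale used here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import EnergyDatabase, with_derived
from .energetics import (
    DEFAULT_CONFIG,
    EnergyConfig,
    me_from_de,
    multiple_of_maintenance,
    nem_from_me,
    predict_methane,
)

__all__ = [
    "ccc",
    "mspe_decompose",
    "obs_vs_pred_regression",
    "EvaluationResult",
    "MethaneEquationEvaluator",
    "EvaluationSuite",
    "observed_methane_g_per_d",
    "predicted_methane_g_per_d",
    "evaluate_equations",
]


def _pop_moments(obs, pred):
    o = np.asarray(obs, dtype=float)
    p = np.asarray(pred, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError("obs and pred must be equal-length 1-d vectors")
    if len(o) < 2:
        raise ValueError("need at least 2 observations")
    mo, mp = o.mean(), p.mean()
    vo = float(((o - mo) ** 2).mean())
    vp = float(((p - mp) ** 2).mean())
    cov = float(((o - mo) * (p - mp)).mean())
    return o, p, mo, mp, vo, vp, cov


def ccc(obs, pred) -> float:
    """Lin's concordance correlation coefficient (population moments).

    Measures agreement with the identity line: the product of Pearson
    precision and a location/scale accuracy factor.  Two constant equal
    vectors are perfectly concordant (1 by convention).
    """
    o, p, mo, mp, vo, vp, cov = _pop_moments(obs, pred)
    denom = vo + vp + (mo - mp) ** 2
    if denom == 0:
        return 1.0  # both constant with equal means
    return float(2 * cov / denom)


def mspe_decompose(obs, pred) -> dict:
    """Decompose mean squared prediction error into mean, slope and error bias.

    mean_bias = (p̄ − ō)²; slope_bias = (s_p − r·s_o)²;
    error_bias = (1 − r²)·var(o); the three sum to mean((p − o)²) exactly
    (population moments throughout).  Percentages are of MSPE.
    """
    o, p, mo, mp, vo, vp, cov = _pop_moments(obs, pred)
    mspe = float(((p - o) ** 2).mean())
    mean_bias = (mp - mo) ** 2
    so, sp = np.sqrt(vo), np.sqrt(vp)
    if so > 0 and sp > 0:
        r = cov / (so * sp)
    else:
        r = 0.0  # a constant vector carries no correlation
    slope_bias = (sp - r * so) ** 2
    error_bias = (1.0 - r**2) * vo
    out = {
        "mspe": mspe,
        "mean_bias": float(mean_bias),
        "slope_bias": float(slope_bias),
        "error_bias": float(error_bias),
    }
    if mspe > 0:
        for k in ("mean_bias", "slope_bias", "error_bias"):
            out[k + "_pct"] = 100.0 * out[k] / mspe
    else:
        out["mean_bias_pct"] = out["slope_bias_pct"] = out["error_bias_pct"] = 0.0
    return out


def obs_vs_pred_regression(obs, pred, alpha: float = 0.05) -> dict:
    """Regress observed on predicted; report the line, CIs, r², RMSPE.

    CIs are t-based with n − 2 degrees of freedom.  RMSPE is
    sqrt(mean((pred − obs)²)) with the n denominator, i.e. identical to
    sqrt(MSPE) from :func:`mspe_decompose` on the same vectors.
    """
    o = np.asarray(obs, dtype=float)
    p = np.asarray(pred, dtype=float)
    n = len(o)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(p) == 0:
        raise ValueError("zero variance in predictions")
    X = np.column_stack([np.ones_like(p), p])
    beta, *_ = np.linalg.lstsq(X, o, rcond=None)
    resid = o - X @ beta
    sse = float(resid @ resid)
    sst = float(((o - o.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    dof = n - 2
    s2 = sse / dof if dof > 0 else 0.0
    cov = s2 * np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    tq = stats.t.ppf(1 - alpha / 2, dof)
    rmspe = float(np.sqrt(((p - o) ** 2).mean()))
    mean_obs = float(o.mean())
    return {
        "intercept": float(beta[0]),
        "slope": float(beta[1]),
        "ci_intercept": (float(beta[0] - tq * se[0]), float(beta[0] + tq * se[0])),
        "ci_slope": (float(beta[1] - tq * se[1]), float(beta[1] + tq * se[1])),
        "r2": float(r2),
        "rmspe": rmspe,
        "rmspe_pct_mean": 100.0 * rmspe / mean_obs if mean_obs != 0 else np.nan,
        "n": n,
    }


@dataclass
class EvaluationResult:
    """Per-equation evaluation record (one report row)."""

    equation: str
    n: int
    r2: float
    rmspe: float
    rmspe_pct_mean: float
    mean_bias_pct: float
    slope_bias_pct: float
    error_bias_pct: float
    ccc: float
    op_intercept: float
    op_slope: float
    ci_intercept: tuple[float, float]
    ci_slope: tuple[float, float]
    intercept_covers_zero: bool
    slope_covers_one: bool
    n_dropped: int = 0


# -- deriving observed/predicted g/d from a database ------------------------


def observed_methane_g_per_d(db: EnergyDatabase, cfg: EnergyConfig | None = None) -> pd.Series:
    """Observed daily methane in g/d from the calorimetry columns.

    Mcal/d = (ch4 % of DE / 100) × DE × DMI, then Mcal → L → g along the
    calorimetric chain (9.45 kcal/L, 0.716 g/L).
    """
    cfg = cfg if cfg is not None else DEFAULT_CONFIG
    f = with_derived(db)
    mcal_d = f["ch4_mcal_per_kg_dm"] * f["dmi"]
    return mcal_d * cfg.units.g_per_mcal_calorimetric


def predicted_methane_g_per_d(
    db: EnergyDatabase,
    equation: str,
    cfg: EnergyConfig | None = None,
    me_source: str = "eq1",
) -> pd.Series:
    """Per-row predicted methane (g/d) for one equation; NaN where inputs are missing.

    ``me_source`` controls how the NEm chain for the intake-adjusted equation
    obtains dietary ME: ``"eq1"``/``"eq2"`` predict it from DE, ``"observed"``
    uses the ME column.
    """
    cfg = cfg if cfg is not None else DEFAULT_CONFIG
    f = with_derived(db)
    out = pd.Series(np.nan, index=f.index, dtype=float)
    for i, r in f.iterrows():
        try:
            if equation in ("eq3", "dmi_c", "ellis_2c"):
                if pd.isna(r["dmi"]):
                    continue
                pred = predict_methane(equation, dmi=r["dmi"], units=cfg.units)
            elif equation in ("ipcc_tier2", "global_tier2"):
                if pd.isna(r["ge_intake_mcal_d"]):
                    continue
                ge_mj = r["ge_intake_mcal_d"] * cfg.units.mj_per_mcal
                pred = predict_methane(equation, ge_intake_mj_d=ge_mj, units=cfg.units)
            elif equation == "eq4":
                if pd.isna(r["dmi"]) or pd.isna(r["bw"]) or pd.isna(r["de"]):
                    continue
                if me_source == "observed":
                    if pd.isna(r["me"]):
                        continue
                    me = r["me"]
                else:
                    me = me_from_de(r["de"], method=me_source)
                mom = multiple_of_maintenance(
                    r["bw"], r["dmi"], nem_from_me(me, cfg.ne_coeffs), cfg
                )
                import warnings as _w

                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    pred = predict_methane(equation, dmi=r["dmi"], mom=mom, units=cfg.units)
            else:
                raise ValueError(f"unknown equation {equation!r}")
        except ValueError:
            raise
        out.iloc[f.index.get_loc(i)] = pred.g_per_d
    return out


class EvaluationSuite:
    """Results container for a multi-equation evaluation run."""

    def __init__(self, results: list[EvaluationResult]):
        self.results = results

    def __iter__(self):
        return iter(self.results)

    def __getitem__(self, equation: str) -> EvaluationResult:
        for r in self.results:
            if r.equation == equation:
                return r
        raise KeyError(equation)

    def table(self) -> pd.DataFrame:
        """Report with one row per equation, in input order."""
        return pd.DataFrame(
            [
                {
                    "equation": r.equation,
                    "n": r.n,
                    "r2": r.r2,
                    "rmspe_g_d": r.rmspe,
                    "rmspe_pct_mean": r.rmspe_pct_mean,
                    "mean_bias_pct": r.mean_bias_pct,
                    "slope_bias_pct": r.slope_bias_pct,
                    "error_bias_pct": r.error_bias_pct,
                    "ccc": r.ccc,
                }
                for r in self.results
            ]
        ).set_index("equation")

    def to_markdown(self) -> str:
        t = self.table().round(3)
        return t.to_markdown()

    def plot(self, equation: str, obs, pred, ax=None):
        """Observed-vs-predicted scatter with the y = x line and the fitted
        regression (dashed) annotated with its 95% confidence limits."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        r = self[equation]
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        o = np.asarray(obs, float)
        p = np.asarray(pred, float)
        ax.scatter(p, o, s=14, alpha=0.7, edgecolor="none")
        lims = [min(p.min(), o.min()), max(p.max(), o.max())]
        ax.plot(lims, lims, "-", color="black", lw=1, label="y = x")
        xx = np.linspace(lims[0], lims[1], 50)
        ax.plot(
            xx,
            r.op_intercept + r.op_slope * xx,
            "--",
            color="tab:red",
            lw=1,
            label=(
                f"fit: {r.op_intercept:.1f} + {r.op_slope:.3f}x\n"
                f"95% CI int [{r.ci_intercept[0]:.2f}, {r.ci_intercept[1]:.2f}], "
                f"slope [{r.ci_slope[0]:.3f}, {r.ci_slope[1]:.3f}]"
            ),
        )
        ax.set_xlabel(f"Predicted methane, g/d ({equation})")
        ax.set_ylabel("Observed methane, g/d")
        ax.legend(fontsize=7, loc="upper left")
        return ax


class MethaneEquationEvaluator:
    """Model-style evaluator: database in, Table-style report out.

    Parameters
    ----------
    db : treatment-mean database with observed methane (% of DE), DE, DMI
        and, per equation, the inputs it needs (GE intake for the Tier 2
        equations; BW and the NEm chain for the intake-adjusted equation).
    equations : list of method ids to evaluate, in report order.
    cfg : energy configuration (units, NEm chain).
    me_source : ME source for the NEm chain ("eq1", "eq2" or "observed").

    Rows missing the inputs of a given equation are dropped for that
    equation only; the per-equation drop count lands in the report.
    """

    def __init__(
        self,
        db: EnergyDatabase,
        equations: list[str] | None = None,
        cfg: EnergyConfig | None = None,
        me_source: str = "eq1",
    ):
        self.db = db
        self.equations = list(
            equations
            if equations is not None
            else ["eq3", "eq4", "ipcc_tier2", "ellis_2c", "dmi_c", "global_tier2"]
        )
        self.cfg = cfg if cfg is not None else DEFAULT_CONFIG
        self.me_source = me_source

    def fit(self) -> EvaluationSuite:
        obs_all = observed_methane_g_per_d(self.db, self.cfg)
        results = []
        self._vectors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for eq in self.equations:
            pred_all = predicted_methane_g_per_d(self.db, eq, self.cfg, self.me_source)
            mask = obs_all.notna() & pred_all.notna()
            o = obs_all[mask].to_numpy()
            p = pred_all[mask].to_numpy()
            n_dropped = int(len(obs_all) - mask.sum())
            reg = obs_vs_pred_regression(o, p)
            dec = mspe_decompose(o, p)
            results.append(
                EvaluationResult(
                    equation=eq,
                    n=int(mask.sum()),
                    r2=reg["r2"],
                    rmspe=reg["rmspe"],
                    rmspe_pct_mean=reg["rmspe_pct_mean"],
                    mean_bias_pct=dec["mean_bias_pct"],
                    slope_bias_pct=dec["slope_bias_pct"],
                    error_bias_pct=dec["error_bias_pct"],
                    ccc=ccc(o, p),
                    op_intercept=reg["intercept"],
                    op_slope=reg["slope"],
                    ci_intercept=reg["ci_intercept"],
                    ci_slope=reg["ci_slope"],
                    intercept_covers_zero=reg["ci_intercept"][0] <= 0 <= reg["ci_intercept"][1],
                    slope_covers_one=reg["ci_slope"][0] <= 1 <= reg["ci_slope"][1],
                    n_dropped=n_dropped,
                )
            )
            self._vectors[eq] = (o, p)
        return EvaluationSuite(results)

    def vectors(self, equation: str) -> tuple[np.ndarray, np.ndarray]:
        """(observed, predicted) g/d vectors used for ``equation`` (after fit())."""
        return self._vectors[equation]


def evaluate_equations(
    db: EnergyDatabase,
    equations: list[str] | None = None,
    cfg: EnergyConfig | None = None,
    me_source: str = "eq1",
) -> EvaluationSuite:
    """One-call evaluation of a list of methane equations against a database."""
    return MethaneEquationEvaluator(db, equations, cfg, me_source).fit()
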