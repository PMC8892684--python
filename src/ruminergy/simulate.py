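"""Synthetic treatment-mean databases with known truth.

Emulates the statistical structure of the respiration-calorimetry
development database: studies with correlated random intercept/slope
deviations around a linear DE→ME fixed effect, covariates drawn over
realistic ranges (DE 1.8–3.9 Mcal/kg; intake 0.77–2.44 % of BW), and a
methane energy yield per kg of DMI that either sits on a study-shifted
constant or shrinks with the multiple of maintenance.  Urinary energy closes
the DE − ME balance after methane.

Draw order (stable across versions, so fixtures are reproducible): for each
study in order — (u_i, v_i), then the number of observations; for each
observation — DE, digestibility (sets GE), BW, DMI %BW, then the ME residual
(resampled while the energy ordering is infeasible), then the methane noise.
A single seeded :class:`numpy.random.Generator` is threaded through all
draws; identical seeds give byte-identical CSV output.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .data import EnergyDatabase
from .energetics import (
    DEFAULT_CONFIG,
    EnergyConfig,
    multiple_of_maintenance,
    nem_from_me,
)

__all__ = ["GeneratorParams", "generate_database", "generate_evaluation_set"]


@dataclass(frozen=True)
class GeneratorParams:
    """True parameters of the synthetic development database.

    Defaults reproduce the study conditions of the development data: 34
    studies totalling ~134 treatment means, fixed effects β0 = −0.3926,
    β1 = 1.0001, residual SD 0.04 Mcal/kg (the adjusted-fit RMSPE scale),
    DE uniform on 1.8–3.9 Mcal/kg, intake 0.77–2.44 % of BW, BW 130–560 kg.
    Random-effect SDs (0.15, 0.05, ρ = −0.9) give ≈0.07 Mcal/kg
    between-study spread in ME at DE = 3, typical of calorimetry studies.
    """

    n_studies: int = 34
    obs_per_study: tuple[int, int] = (2, 6)
    beta0: float = -0.3926
    beta1: float = 1.0001
    sd_u: float = 0.15
    sd_v: float = 0.05
    rho_uv: float = -0.9
    sigma: float = 0.04
    de_range: tuple[float, float] = (1.8, 3.9)
    ch4_model: str = "intercept"  # or "slope_vs_mom"
    ch4_intercept: float = 0.2433  # Mcal/kg DMI at the citation-adjusted level
    ch4_mom_intercept: float = 0.3344
    ch4_mom_slope: float = -0.05639
    ch4_study_sd: float = 0.03
    ch4_noise_sd: float = 0.015
    bw_range: tuple[float, float] = (130.0, 560.0)
    dmi_pct_bw_range: tuple[float, float] = (0.77, 2.44)
    digestibility_range: tuple[float, float] = (0.46, 0.80)
    seed: int = 0

    def __post_init__(self):
        if min(self.sd_u, self.sd_v, self.sigma, self.ch4_study_sd, self.ch4_noise_sd) < 0:
            raise ValueError("SDs must be >= 0")
        if abs(self.rho_uv) > 1:
            raise ValueError("|rho_uv| must be <= 1")
        for rng_name in ("obs_per_study", "de_range", "bw_range", "dmi_pct_bw_range", "digestibility_range"):
            lo, hi = getattr(self, rng_name)
            if lo > hi:
                raise ValueError(f"{rng_name} must be ordered")
        if self.ch4_model not in {"intercept", "slope_vs_mom"}:
            raise ValueError("ch4_model must be 'intercept' or 'slope_vs_mom'")


def _draw_study_effects(rng: np.random.Generator, p: GeneratorParams):
    cov = np.array(
        [
            [p.sd_u**2, p.rho_uv * p.sd_u * p.sd_v],
            [p.rho_uv * p.sd_u * p.sd_v, p.sd_v**2],
        ]
    )
    if p.sd_u == 0 and p.sd_v == 0:
        return 0.0, 0.0
    u, v = rng.multivariate_normal([0.0, 0.0], cov, method="cholesky" if _psd_strict(cov) else "svd")
    return float(u), float(v)


def _psd_strict(cov) -> bool:
    try:
        np.linalg.cholesky(cov)
        return True
    except np.linalg.LinAlgError:
        return False


def generate_database(
    params: GeneratorParams, cfg: EnergyConfig | None = None
) -> tuple[EnergyDatabase, dict]:
    """Generate a synthetic treatment-mean database and its truth record.

    Infeasible draws (ME outside (0, DE) after noise) are resampled, with the
    resample count reported in the truth record.  Urinary energy is the
    closure term of DE − ME after methane, floored at 0 (flooring counted).
    """
    cfg = cfg if cfg is not None else DEFAULT_CONFIG
    p = params
    rng = np.random.default_rng(p.seed)
    rows = []
    truth_studies = {}
    n_resampled = 0
    n_floored = 0
    for i in range(p.n_studies):
        sid = f"synth_{i + 1:03d}"
        u, v = _draw_study_effects(rng, p)
        s_ch4 = rng.normal(0.0, p.ch4_study_sd) if p.ch4_study_sd > 0 else 0.0
        lo, hi = p.obs_per_study
        n_obs = int(rng.integers(lo, hi + 1))
        truth_studies[sid] = {"u": u, "v": v, "ch4_study": s_ch4, "n_obs": n_obs}
        for j in range(n_obs):
            de = float(rng.uniform(*p.de_range))
            dig = float(rng.uniform(*p.digestibility_range))
            ge = de / dig
            bw = float(rng.uniform(*p.bw_range))
            dmi_pct = float(rng.uniform(*p.dmi_pct_bw_range))
            dmi = dmi_pct / 100.0 * bw
            mean_me = p.beta0 + p.beta1 * de + u + v * de
            me = mean_me + (rng.normal(0.0, p.sigma) if p.sigma > 0 else 0.0)
            tries = 0
            while not (0.0 < me < de) and tries < 200:
                me = mean_me + (rng.normal(0.0, p.sigma) if p.sigma > 0 else 0.0)
                n_resampled += 1
                tries += 1
            if not (0.0 < me < de):
                raise ValueError(
                    "infeasible energy balance: ME cannot be placed in (0, DE) "
                    f"for study {sid} (DE = {de:.3f}); check beta/sd settings"
                )
            if p.ch4_model == "intercept":
                ch4_per_kg = p.ch4_intercept + s_ch4
            else:
                nem = nem_from_me(me, cfg.ne_coeffs)
                mom = multiple_of_maintenance(bw, dmi, nem, cfg)
                ch4_per_kg = p.ch4_mom_intercept + p.ch4_mom_slope * mom + s_ch4
            if p.ch4_noise_sd > 0:
                ch4_per_kg += rng.normal(0.0, p.ch4_noise_sd)
            # methane cannot exceed the DE−ME gap nor go negative
            gap = de - me
            ch4_per_kg = min(max(ch4_per_kg, 0.0), gap)
            urine_per_kg = gap - ch4_per_kg
            if urine_per_kg <= 0:
                n_floored += 1
                urine_per_kg = 0.0
            rows.append(
                {
                    "citation_id": sid,
                    "diet_label": f"diet_{j + 1}",
                    "animal_desc": "synthetic steer",
                    "n_animals": 6,
                    "bw": round(bw, 1),
                    "dmi": round(dmi, 3),
                    "ge": round(ge, 4),
                    "de": round(de, 4),
                    "me": round(me, 4),
                    "me_de_ratio": round(me / de, 4),
                    "ch4_pct_de": round(100.0 * ch4_per_kg / de, 4),
                    "urine_pct_de": round(100.0 * urine_per_kg / de, 4),
                }
            )
    frame = pd.DataFrame(rows)
    db = EnergyDatabase(frame, source_label=f"synthetic(seed={p.seed})")
    truth = {
        "params": asdict(p),
        "studies": truth_studies,
        "n_resampled": n_resampled,
        "n_urine_floored": n_floored,
    }
    return db, truth


def generate_evaluation_set(
    params: GeneratorParams,
    equation: str = "eq3",
    bias: float = 0.0,
    noise_sd: float = 0.0,
    scale: float = 1.0,
    cfg: EnergyConfig | None = None,
    me_source: str = "eq1",
) -> EnergyDatabase:
    """Synthetic independent evaluation set with controllable disagreement.

    Observed daily methane (g/d) is the named equation's prediction with its
    deviations from the mean prediction stretched by ``scale``, shifted by
    ``bias`` (g/d), plus Gaussian noise; the result is written back into the
    methane-as-%-of-DE column via the calorimetric chain.  ``bias`` injects
    pure mean bias; ``scale`` ≠ 1 pivots around the mean and injects slope
    bias without mean bias — useful for exercising the MSPE decomposition.
    """
    from .evaluation import predicted_methane_g_per_d  # local import: avoid cycle

    cfg = cfg if cfg is not None else DEFAULT_CONFIG
    db, _ = generate_database(params, cfg)
    rng = np.random.default_rng(params.seed + 1)  # independent of the base draws
    pred = predicted_methane_g_per_d(db, equation, cfg, me_source)
    noise = rng.normal(0.0, noise_sd, size=len(pred)) if noise_sd > 0 else 0.0
    p_arr = pred.to_numpy()
    obs_g = p_arr.mean() + scale * (p_arr - p_arr.mean()) + bias + noise
    obs_g = np.maximum(obs_g, 0.0)
    mcal_d = obs_g / cfg.units.g_per_mcal_calorimetric
    frame = db.frame.copy()
    frame["ch4_pct_de"] = 100.0 * mcal_d / (frame["de"] * frame["dmi"])
    # keep the energy balance coherent: urine absorbs what methane released
    gap_pct = 100.0 * (frame["de"] - frame["me"]) / frame["de"]
    frame["urine_pct_de"] = np.maximum(gap_pct - frame["ch4_pct_de"], 0.0)
    return EnergyDatabase(frame, source_label=f"synthetic-eval({equation}, seed={params.seed})")
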