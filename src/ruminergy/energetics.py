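"""Deterministic energy-system equations for growing/finishing beef cattle.

Covers the ME-from-DE predictor family, the net-energy chain (dietary NEm and
NEg from ME via cubic equations), multiple of maintenance, six enteric-methane
prediction equations, and the unit conversions that tie them together.

Two methane unit conventions coexist in this literature and must never be
mixed within one conversion chain:

* the **calorimetric** chain — 9.45 kcal per litre of methane and 0.716 g per
  litre, giving 0.055224 MJ/g; used by the equations developed on
  respiration-calorimetry energy data (``eq3``, ``eq4``);
* the **tier** convention — a flat 0.05565 MJ/g of methane; used by
  inventory-style (Tier 2) equations printed in g/d or built with ÷0.05565.

The two differ by about 0.8%; each prediction records which route filled its
secondary scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "UnitConstants",
    "NetEnergyCoefficients",
    "EnergyConfig",
    "MethanePrediction",
    "DEFAULT_UNITS",
    "DEFAULT_NE_COEFFS",
    "DEFAULT_CONFIG",
    "ME_FROM_DE_METHODS",
    "METHANE_METHODS",
    "me_from_de",
    "nem_from_me",
    "neg_from_me",
    "multiple_of_maintenance",
    "eq4_rate",
    "predict_methane",
    "convert_methane",
]


@dataclass(frozen=True)
class UnitConstants:
    """Physical constants for methane unit conversion.

    ``kcal_per_l_ch4`` and ``g_per_l_ch4`` define the calorimetric chain;
    ``mj_per_g_ch4`` is the flat tier-convention energy content;
    ``mj_per_mcal`` converts between the two energy units.
    """

    kcal_per_l_ch4: float = 9.45
    g_per_l_ch4: float = 0.716
    mj_per_mcal: float = 4.184
    mj_per_g_ch4: float = 0.05565

    def __post_init__(self):
        for f in ("kcal_per_l_ch4", "g_per_l_ch4", "mj_per_mcal", "mj_per_g_ch4"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be strictly positive")

    @property
    def g_per_mcal_calorimetric(self) -> float:
        """g of methane per Mcal along the calorimetric chain (L then g)."""
        return 1000.0 / self.kcal_per_l_ch4 * self.g_per_l_ch4


DEFAULT_UNITS = UnitConstants()


@dataclass(frozen=True)
class NetEnergyCoefficients:
    """Cubic polynomials mapping dietary ME (Mcal/kg DM) to NEm and NEg.

    Coefficients are (c0, c1, c2, c3) for c0 + c1·ME + c2·ME² + c3·ME³.
    The shipped default is the classic NRC-lineage cubic pair; it is a
    configurable stand-in, and any downstream statistic that depends on the
    NEm chain (multiple of maintenance, the intake-adjusted methane equation)
    is conditional on this choice.
    """

    nem: tuple[float, float, float, float] = (-1.12, 1.37, -0.138, 0.0105)
    neg: tuple[float, float, float, float] = (-1.65, 1.42, -0.174, 0.0122)
    provenance: str = "NRC-lineage cubic (stand-in default; override via config)"

    def __post_init__(self):
        if not all(np.isfinite(self.nem)) or not all(np.isfinite(self.neg)):
            raise ValueError("net-energy coefficients must be finite")


DEFAULT_NE_COEFFS = NetEnergyCoefficients()


@dataclass(frozen=True)
class EnergyConfig:
    """Configuration for the net-energy chain.

    ``nem_requirement_coeff`` is the daily NEm maintenance requirement in Mcal
    per kg of metabolic body weight (BW^0.75); default 0.077.
    """

    nem_requirement_coeff: float = 0.077
    ne_coeffs: NetEnergyCoefficients = field(default_factory=NetEnergyCoefficients)
    units: UnitConstants = field(default_factory=UnitConstants)

    def __post_init__(self):
        if self.nem_requirement_coeff <= 0:
            raise ValueError("nem_requirement_coeff must be > 0")

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "EnergyConfig":
        kw = {}
        if "nem_requirement_coeff" in cfg:
            kw["nem_requirement_coeff"] = float(cfg["nem_requirement_coeff"])
        if "ne_coeffs" in cfg:
            nc = cfg["ne_coeffs"]
            kw["ne_coeffs"] = NetEnergyCoefficients(
                nem=tuple(nc["nem"]),
                neg=tuple(nc["neg"]),
                provenance=nc.get("provenance", "user-supplied"),
            )
        if "units" in cfg:
            kw["units"] = UnitConstants(**cfg["units"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "EnergyConfig":
        import yaml

        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})


DEFAULT_CONFIG = EnergyConfig()


# ---------------------------------------------------------------------------
# ME from DE
# ---------------------------------------------------------------------------

#: method id -> human description
ME_FROM_DE_METHODS = {
    "eq1": "ME = 1.0001 × DE − 0.3926 (updated citation-adjusted regression)",
    "eq2": "ME = DE − 0.39 (recommended constant-offset form)",
    "factor_082": "ME = 0.82 × DE (classic NRC ratio)",
    "gt_linear": "ME = 0.9611 × DE − 0.2999 (earlier growing/finishing regression)",
    "hemphill": "ME = −0.057 × DE² + 1.3764 × DE − 0.9483 (quadratic, high-concentrate)",
    "reynolds_ratio": "ME:DE = 0.9410 + 0.0042·DMI − 0.0017·NDF − 0.0022·CP",
    "dairy_nrc": "ME = 1.01 × DE − 0.45 (lactating dairy cows)",
}


def me_from_de(
    de: float,
    method: str = "eq2",
    dmi: float | None = None,
    ndf: float | None = None,
    cp: float | None = None,
) -> float:
    """Predict dietary ME (Mcal/kg DM) from DE (Mcal/kg DM).

    Parameters
    ----------
    de : digestible energy concentration, Mcal/kg of DM (> 0).
    method : one of ``ME_FROM_DE_METHODS``; default ``eq2`` (ME = DE − 0.39).
    dmi, ndf, cp : required only by ``reynolds_ratio`` (kg/d, % DM, % DM).
    """
    de = float(de)
    if de <= 0:
        raise ValueError("de must be > 0")
    if method == "eq1":
        return 1.0001 * de - 0.3926
    if method == "eq2":
        return de - 0.39
    if method == "factor_082":
        return 0.82 * de
    if method == "gt_linear":
        return 0.9611 * de - 0.2999
    if method == "hemphill":
        return -0.057 * de * de + 1.3764 * de - 0.9483
    if method == "dairy_nrc":
        return 1.01 * de - 0.45
    if method == "reynolds_ratio":
        if dmi is None or ndf is None or cp is None:
            raise ValueError("reynolds_ratio needs dmi, ndf and cp covariates")
        ratio = 0.9410 + 0.0042 * dmi - 0.0017 * ndf - 0.0022 * cp
        return ratio * de
    raise ValueError(f"unknown ME-from-DE method {method!r}")


# ---------------------------------------------------------------------------
# Net-energy chain
# ---------------------------------------------------------------------------


def _cubic(me: float, coeffs: tuple[float, float, float, float]) -> float:
    me = float(me)
    if not 0 < me <= 6:
        raise ValueError("me must be in (0, 6] Mcal/kg DM")
    c0, c1, c2, c3 = coeffs
    return c0 + c1 * me + c2 * me * me + c3 * me**3


def nem_from_me(me: float, coeffs: NetEnergyCoefficients | None = None) -> float:
    """Dietary NEm concentration (Mcal/kg DM) from ME via the cubic equation."""
    coeffs = coeffs if coeffs is not None else DEFAULT_NE_COEFFS
    return _cubic(me, coeffs.nem)


def neg_from_me(me: float, coeffs: NetEnergyCoefficients | None = None) -> float:
    """Dietary NEg concentration (Mcal/kg DM) from ME via the cubic equation."""
    coeffs = coeffs if coeffs is not None else DEFAULT_NE_COEFFS
    return _cubic(me, coeffs.neg)


def multiple_of_maintenance(
    bw: float,
    dmi: float,
    nem_diet: float,
    cfg: EnergyConfig | None = None,
) -> float:
    """Daily NEm intake divided by the NEm maintenance requirement.

    Requirement = ``cfg.nem_requirement_coeff`` × BW^0.75 (Mcal/d);
    intake = DMI × dietary NEm concentration.
    """
    cfg = cfg if cfg is not None else DEFAULT_CONFIG
    for name, v in (("bw", bw), ("dmi", dmi), ("nem_diet", nem_diet)):
        if v is None or v <= 0:
            raise ValueError(f"{name} must be > 0")
    return (dmi * nem_diet) / (cfg.nem_requirement_coeff * bw**0.75)


# ---------------------------------------------------------------------------
# Methane prediction
# ---------------------------------------------------------------------------

METHANE_METHODS = {
    "eq3": "CH4, Mcal/d = 0.2433 × DMI, kg/d",
    "eq4": "CH4, Mcal/kg DMI = 0.3344 − 0.05639 × multiple of maintenance",
    "ipcc_tier2": "CH4, g/d = GE intake, MJ/d × 0.065 ÷ 0.05565",
    "ellis_2c": "CH4, MJ/d = 3.27 + 0.74 × DMI, kg/d",
    "dmi_c": "CH4, g/d = 54.2 + 12.6 × DMI, kg/d",
    "global_tier2": "CH4, g/d = 0.061 × GE intake, MJ/d ÷ 0.05565",
}


@dataclass(frozen=True)
class MethanePrediction:
    """Daily methane on four scales, filled along a single conversion route.

    ``route`` records which mass↔energy convention tied g/d to the energy
    scales: ``"calorimetric"`` (9.45 kcal/L, 0.716 g/L) or ``"tier"``
    (0.05565 MJ/g).  Within the recorded route the four scales are mutually
    consistent to machine precision.
    """

    method: str
    mcal_per_d: float
    mj_per_d: float
    g_per_d: float
    l_per_d: float
    route: str
    negative: bool = False

    def value(self, scale: str) -> float:
        return {
            "mcal_d": self.mcal_per_d,
            "mj_d": self.mj_per_d,
            "g_d": self.g_per_d,
            "l_d": self.l_per_d,
        }[scale]


def eq4_rate(mom: float) -> float:
    """Intake-adjusted methane yield, Mcal per kg of DMI, at a given multiple
    of maintenance.  Decreases with intake level; multiply by DMI for a daily
    value.  Negative beyond mom ≈ 5.93 (far outside the development data)."""
    return 0.3344 - 0.05639 * float(mom)


def _fill_calorimetric(method, mcal, units: UnitConstants, negative):
    l = mcal * 1000.0 / units.kcal_per_l_ch4
    g = l * units.g_per_l_ch4
    return MethanePrediction(method, mcal, mcal * units.mj_per_mcal, g, l, "calorimetric", negative)


def _fill_tier(method, units: UnitConstants, negative, g=None, mj=None):
    if g is None:
        g = mj / units.mj_per_g_ch4
    if mj is None:
        mj = g * units.mj_per_g_ch4
    return MethanePrediction(
        method, mj / units.mj_per_mcal, mj, g, g / units.g_per_l_ch4, "tier", negative
    )


def predict_methane(
    method: str,
    dmi: float | None = None,
    ge_intake_mj_d: float | None = None,
    mom: float | None = None,
    units: UnitConstants | None = None,
    ellis_route: str = "tier",
) -> MethanePrediction:
    """Predict daily enteric methane with one of six equations.

    Required inputs by method: ``eq3``/``ellis_2c``/``dmi_c`` need ``dmi``
    (kg/d); ``eq4`` needs ``dmi`` and ``mom`` (multiple of maintenance);
    ``ipcc_tier2``/``global_tier2`` need ``ge_intake_mj_d`` (MJ/d).

    Each equation is evaluated on its native printed scale and the remaining
    scales filled along that equation's conversion route.  A negative
    prediction (possible for ``eq4`` at very high intake) is returned with
    the ``negative`` flag set, not clamped.
    """
    units = units if units is not None else DEFAULT_UNITS

    def need(name, v):
        if v is None:
            raise ValueError(f"method {method!r} requires input {name!r}")
        return float(v)

    if method == "eq3":
        mcal = 0.2433 * need("dmi", dmi)
        return _fill_calorimetric(method, mcal, units, mcal < 0)
    if method == "eq4":
        mcal = eq4_rate(need("mom", mom)) * need("dmi", dmi)
        if mcal < 0:
            warnings.warn(
                "intake-adjusted methane equation is negative at this multiple of "
                "maintenance (outside the development range); value returned unclamped",
                stacklevel=2,
            )
        return _fill_calorimetric(method, mcal, units, mcal < 0)
    if method == "ipcc_tier2":
        g = need("ge_intake_mj_d", ge_intake_mj_d) * 0.065 / units.mj_per_g_ch4
        return _fill_tier(method, units, g < 0, g=g)
    if method == "global_tier2":
        g = 0.061 * need("ge_intake_mj_d", ge_intake_mj_d) / units.mj_per_g_ch4
        return _fill_tier(method, units, g < 0, g=g)
    if method == "dmi_c":
        g = 54.2 + 12.6 * need("dmi", dmi)
        return _fill_tier(method, units, g < 0, g=g)
    if method == "ellis_2c":
        mj = 3.27 + 0.74 * need("dmi", dmi)
        if ellis_route == "tier":
            return _fill_tier(method, units, mj < 0, mj=mj)
        mcal = mj / units.mj_per_mcal
        return _fill_calorimetric(method, mcal, units, mcal < 0)
    raise ValueError(f"unknown methane method {method!r}")


def convert_methane(
    value: float,
    from_scale: str,
    to_scale: str,
    units: UnitConstants | None = None,
    convention: str = "calorimetric",
) -> float:
    """Convert a methane quantity between {mcal_d, mj_d, g_d, l_d}.

    ``convention`` selects the mass↔energy route: ``"calorimetric"`` goes
    energy → litres (9.45 kcal/L) → grams (0.716 g/L); ``"tier"`` uses the
    flat 0.05565 MJ/g.  Energy↔energy (4.184 MJ/Mcal) and L↔g (0.716 g/L)
    are convention-independent.  The two routes differ by ~0.8% and are never
    mixed within one call.
    """
    units = units if units is not None else DEFAULT_UNITS
    scales = {"mcal_d", "mj_d", "g_d", "l_d"}
    if from_scale not in scales or to_scale not in scales:
        raise ValueError(f"scales must be in {sorted(scales)}")
    if convention not in {"calorimetric", "tier"}:
        raise ValueError(f"unknown convention {convention!r}")
    if from_scale == to_scale:
        return float(value)

    # express everything through litres: 1 L = g_per_l grams and carries
    # kcal_per_l kcal (calorimetric) or g_per_l * mj_per_g MJ (tier)
    if convention == "calorimetric":
        mj_per_l = units.kcal_per_l_ch4 / 1000.0 * units.mj_per_mcal
    else:
        mj_per_l = units.g_per_l_ch4 * units.mj_per_g_ch4
    to_l = {
        "l_d": 1.0,
        "g_d": 1.0 / units.g_per_l_ch4,
        "mj_d": 1.0 / mj_per_l,
        "mcal_d": units.mj_per_mcal / mj_per_l,
    }
    litres = float(value) * to_l[from_scale]
    return litres / to_l[to_scale]
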