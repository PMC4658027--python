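"""Net-energy growth engine for feedlot cattle.

A deliberately transparent NRC-style implementation of the daily energy
budget of a growing animal:

* dietary metabolizable energy (ME, Mcal/kg DM) converts to net energy for
  maintenance (NEm) and gain (NEg) through the standard cubic equations;
* maintenance requires ``0.077 * SBW^0.75`` Mcal NEm/d (times an optional
  environment factor);
* energy retained in gain is size-scaled through the equivalent shrunk
  weight EQSBW = SBW * SRW / AFSBW, so that an animal far from its target
  composition deposits leaner (cheaper) gain:
  ``RE = 0.0635 * (0.891*EQSBW)^0.75 * (0.956*ADG)^1.097`` Mcal/d.

The engine runs forward (intake -> gain -> days on feed, via a daily Euler
loop) and backward (observed gain -> dry matter required, DMR). The forward
gain equation is the exact analytic inverse of the retained-energy
equation, so forward and backward calculations agree to machine precision.

Weather, mud and implant adjustments are out of scope; the single
``maintenance_factor`` knob stands in for environmental maintenance effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .constants import EBG_PER_SWG, EBW_PER_SBW, SRW_KG

__all__ = [
    "DietSpec",
    "GrowthPrediction",
    "diet_energy",
    "me_to_nem",
    "me_to_neg",
    "maintenance_nem",
    "retained_energy",
    "predict_adg_from_dmi",
    "dmi_for_adg",
    "nrc_empirical_dmi",
    "end_bw_dmi",
    "project_days_on_feed",
    "expected_dof",
    "dry_matter_required",
    "predict_cohort",
]

_ME_RANGE = (1.5, 4.0)


def me_to_nem(me):
    """NEm (Mcal/kg) from dietary ME via the standard cubic (no range check)."""
    me = np.asarray(me, dtype=float)
    out = 1.37 * me - 0.138 * me**2 + 0.0105 * me**3 - 1.12
    return out if out.ndim else float(out)


def me_to_neg(me):
    """NEg (Mcal/kg) from dietary ME via the standard cubic (no range check)."""
    me = np.asarray(me, dtype=float)
    out = 1.42 * me - 0.174 * me**2 + 0.0122 * me**3 - 1.65
    return out if out.ndim else float(out)


def diet_energy(me_mcal_kg: float) -> tuple[float, float]:
    """(NEm, NEg) in Mcal/kg for a diet of the given ME concentration.

    At the default feedlot diet of ME = 3.2 Mcal/kg this yields
    NEm = 2.19 (~2.2) and NEg = 1.51 (~1.5) Mcal/kg.
    """
    if not _ME_RANGE[0] < me_mcal_kg < _ME_RANGE[1]:
        raise ValueError(
            f"diet ME {me_mcal_kg} Mcal/kg outside plausible {_ME_RANGE}"
        )
    return me_to_nem(me_mcal_kg), me_to_neg(me_mcal_kg)


@dataclass
class DietSpec:
    """Diet energy description.

    NEm/NEg default to the cubic ME conversions but can be overridden when
    measured values are available.
    """

    me_mcal_kg: float = 3.2
    nem_mcal_kg: Optional[float] = None
    neg_mcal_kg: Optional[float] = None

    def __post_init__(self) -> None:
        nem, neg = diet_energy(self.me_mcal_kg)
        if self.nem_mcal_kg is None:
            self.nem_mcal_kg = nem
        if self.neg_mcal_kg is None:
            self.neg_mcal_kg = neg
        if not self.nem_mcal_kg > self.neg_mcal_kg > 0:
            raise ValueError("need NEm > NEg > 0")


@dataclass
class GrowthPrediction:
    """Per-animal forward/backward prediction under one AFSBW route."""

    method: str  # "HH" or "CT"
    pdmi_kg_d: float
    padg_kg_d: float
    dof_pred_d: int
    edof_d: Optional[float] = None
    dmr_kg_d: Optional[float] = None


def maintenance_nem(sbw_kg, maintenance_factor: float = 1.0):
    """Maintenance NEm requirement, Mcal/d: 0.077 * SBW^0.75 * factor."""
    sbw = np.asarray(sbw_kg, dtype=float)
    if np.any(sbw < 0):
        raise ValueError("shrunk body weight must be non-negative")
    out = 0.077 * sbw**0.75 * maintenance_factor
    return out if out.ndim else float(out)


def _eqsbw(sbw_kg, afsbw_kg, srw_kg):
    return np.asarray(sbw_kg, dtype=float) * srw_kg / np.asarray(afsbw_kg, dtype=float)


def retained_energy(sbw_kg, afsbw_kg, adg_kg_d, srw_kg: float = SRW_KG):
    """Energy retained in gain, Mcal/d, size-scaled by equivalent weight."""
    adg = np.asarray(adg_kg_d, dtype=float)
    eqebw = EBW_PER_SBW * _eqsbw(sbw_kg, afsbw_kg, srw_kg)
    out = np.where(
        adg > 0, 0.0635 * eqebw**0.75 * (EBG_PER_SWG * np.maximum(adg, 0)) ** 1.097, 0.0
    )
    return out if out.ndim else float(out)


def predict_adg_from_dmi(
    dmi_kg_d,
    sbw_kg,
    afsbw_kg,
    diet: DietSpec,
    srw_kg: float = SRW_KG,
    maintenance_factor: float = 1.0,
):
    """Shrunk ADG (kg/d) supported by a given DMI.

    Intake first covers maintenance (NEm_req / NEm kg of feed); the rest
    supplies retained energy at the diet NEg density. The gain equation is
    the exact inverse of :func:`retained_energy`; intakes at or below
    maintenance return zero gain (weight loss is not modelled).
    """
    dmi = np.asarray(dmi_kg_d, dtype=float)
    maint_dm = maintenance_nem(sbw_kg, maintenance_factor) / diet.nem_mcal_kg
    short = dmi <= maint_dm
    if np.any(short):
        warnings.warn("intake at or below maintenance; ADG set to 0", stacklevel=2)
    re_avail = np.maximum(dmi - maint_dm, 0.0) * diet.neg_mcal_kg
    eqebw = EBW_PER_SBW * _eqsbw(sbw_kg, afsbw_kg, srw_kg)
    ebg = (re_avail / (0.0635 * eqebw**0.75)) ** (1.0 / 1.097)
    out = np.where(short, 0.0, ebg / EBG_PER_SWG)
    return out if out.ndim else float(out)


def dmi_for_adg(
    adg_kg_d,
    sbw_kg,
    afsbw_kg,
    diet: DietSpec,
    srw_kg: float = SRW_KG,
    maintenance_factor: float = 1.0,
):
    """DMI (kg/d) needed to sustain a given ADG — inverse of the above."""
    re = retained_energy(sbw_kg, afsbw_kg, adg_kg_d, srw_kg)
    out = (
        maintenance_nem(sbw_kg, maintenance_factor) / diet.nem_mcal_kg
        + np.asarray(re, dtype=float) / diet.neg_mcal_kg
    )
    return out if out.ndim else float(out)


def nrc_empirical_dmi(sbw_kg, diet: DietSpec):
    """Default empirical DMI predictor (kg/d) for growing cattle.

    DMI = SBW^0.75 * (0.2435*NEm - 0.0466*NEm^2 - 0.0869) / NEm.
    """
    nem = diet.nem_mcal_kg
    sbw = np.asarray(sbw_kg, dtype=float)
    out = sbw**0.75 * (0.2435 * nem - 0.0466 * nem**2 - 0.0869) / nem
    return out if out.ndim else float(out)


def end_bw_dmi(final_bw_kg, nem_maint_mcal_kg: float = 2.2):
    """Alternative empirical DMI predictor keyed to end body weight.

    A documented in-package stub behind the pluggable DMI interface: it
    applies the empirical intake form at the animal's end BW with the net
    energy of the diet available for maintenance (default 2.2 Mcal/kg).
    """
    nem = nem_maint_mcal_kg
    bw = np.asarray(final_bw_kg, dtype=float)
    out = bw**0.75 * (0.2435 * nem - 0.0466 * nem**2 - 0.0869) / nem
    return out if out.ndim else float(out)


def project_days_on_feed(
    isbw_kg: float,
    afsbw_kg: float,
    diet: DietSpec,
    dmi_model: Optional[Callable[[float], float]] = None,
    srw_kg: float = SRW_KG,
    maintenance_factor: float = 1.0,
    max_days: int = 1000,
) -> tuple[int, float, float]:
    """Forward daily simulation from entry weight to the AFSBW target.

    Each day: predict DMI (default empirical model), convert to ADG, advance
    SBW (explicit Euler, 1-d step). Returns ``(dof, mean_dmi, mean_adg)``
    where ``dof`` is the first day on which SBW >= AFSBW.
    """
    if not afsbw_kg > isbw_kg:
        raise ValueError("target AFSBW must exceed initial shrunk BW")
    if dmi_model is None:
        dmi_model = lambda sbw: nrc_empirical_dmi(sbw, diet)  # noqa: E731
    sbw = float(isbw_kg)
    dmis, adgs = [], []
    for day in range(1, max_days + 1):
        dmi = float(dmi_model(sbw))
        adg = predict_adg_from_dmi(
            dmi, sbw, afsbw_kg, diet, srw_kg, maintenance_factor
        )
        dmis.append(dmi)
        adgs.append(adg)
        sbw += adg
        if sbw >= afsbw_kg:
            return day, float(np.mean(dmis)), float(np.mean(adgs))
        if adg <= 0:
            raise RuntimeError(
                "projection infeasible: predicted intake cannot support gain"
            )
    raise RuntimeError(f"target not reached within {max_days} d")


def expected_dof(afsbw_ct_kg, isbw_kg, oadg_kg_d):
    """Expected days on feed: (AFSBW_CT - iSBW) / observed ADG.

    Real-valued (not rounded); uses the carcass-trait AFSBW as the unbiased
    endpoint and the observed gain, removing intake/gain model uncertainty.
    """
    oadg = np.asarray(oadg_kg_d, dtype=float)
    if np.any(oadg <= 0):
        raise ValueError("observed ADG must be positive")
    out = (np.asarray(afsbw_ct_kg, dtype=float) - np.asarray(isbw_kg, dtype=float)) / oadg
    if np.any(np.asarray(out) < 0):
        warnings.warn(
            "AFSBW_CT below initial shrunk BW: expected DOF is negative", stacklevel=2
        )
    return out if out.ndim else float(out)


def dry_matter_required(
    isbw_kg: float,
    oadg_kg_d: float,
    dof_obs_d: int,
    afsbw_kg: float,
    diet: DietSpec,
    srw_kg: float = SRW_KG,
    maintenance_factor: float = 1.0,
) -> float:
    """Mean daily dry matter required to support the observed gain (kg/d).

    Backward calculation: walk the observed feeding period with SBW advancing
    by the observed ADG; each day's requirement is maintenance feed plus the
    feed equivalent of the retained energy of that day's gain:
    ``DMR_day = NEm_req/NEm + RE/NEg``.
    """
    if oadg_kg_d is None or dof_obs_d is None:
        raise ValueError("observed ADG and days on feed are required")
    if oadg_kg_d < 0:
        raise ValueError("observed ADG must be non-negative")
    dof = int(dof_obs_d)
    if dof < 1:
        raise ValueError("days on feed must be at least 1")
    days = np.arange(dof, dtype=float)
    sbw = isbw_kg + oadg_kg_d * days
    re = retained_energy(sbw, afsbw_kg, np.full(dof, float(oadg_kg_d)), srw_kg)
    dmr_day = (
        maintenance_nem(sbw, maintenance_factor) / diet.nem_mcal_kg
        + re / diet.neg_mcal_kg
    )
    return float(np.mean(dmr_day))


def predict_cohort(
    df: pd.DataFrame,
    diet: Optional[DietSpec] = None,
    srw_kg: float = SRW_KG,
    maintenance_factor: float = 1.0,
    max_days: int = 1000,
    dmi_model: Optional[Callable[[float], float]] = None,
) -> pd.DataFrame:
    """Growth-engine stage over a composed cohort table.

    Requires ``isbw_kg``, ``adg_kg_d``, ``dof_d`` and the composed
    ``afsbw_hh_kg`` / ``afsbw_ct_kg`` columns. Adds, per route,
    ``pdmi_*_kg_d``, ``padg_*_kg_d``, ``dof_*_d``, plus ``edof_d`` and
    ``dmr_kg_d``. Rows whose projection is infeasible get NaNs.
    """
    diet = diet or DietSpec()
    out = df.copy()
    n = len(out)
    cols = {
        f"{p}_{m}": np.full(n, np.nan)
        for m in ("hh", "ct")
        for p in ("pdmi", "padg", "dof")
    }
    for i, row in enumerate(out.itertuples(index=False)):
        for m in ("hh", "ct"):
            target = getattr(row, f"afsbw_{m}_kg", np.nan)
            if not np.isfinite(target) or target <= row.isbw_kg:
                continue
            try:
                dof, mdmi, madg = project_days_on_feed(
                    row.isbw_kg, target, diet, dmi_model, srw_kg,
                    maintenance_factor, max_days,
                )
            except RuntimeError:
                continue
            cols[f"pdmi_{m}"][i] = mdmi
            cols[f"padg_{m}"][i] = madg
            cols[f"dof_{m}"][i] = dof
    for m in ("hh", "ct"):
        out[f"pdmi_{m}_kg_d"] = cols[f"pdmi_{m}"]
        out[f"padg_{m}_kg_d"] = cols[f"padg_{m}"]
        out[f"dof_{m}_d"] = cols[f"dof_{m}"]

    out["edof_d"] = (out["afsbw_ct_kg"] - out["isbw_kg"]) / out["adg_kg_d"]
    dmr = np.full(n, np.nan)
    for i, row in enumerate(out.itertuples(index=False)):
        target = getattr(row, "afsbw_ct_kg", np.nan)
        if (
            np.isfinite(target)
            and np.isfinite(row.adg_kg_d)
            and np.isfinite(row.dof_d)
            and row.dof_d >= 1
        ):
            dmr[i] = dry_matter_required(
                row.isbw_kg, row.adg_kg_d, int(row.dof_d), target, diet,
                srw_kg, maintenance_factor,
            )
    out["dmr_kg_d"] = dmr
    return out
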