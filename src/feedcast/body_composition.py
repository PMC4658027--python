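"""Body-composition equations for growing feedlot cattle.

Two independent routes to the adjusted final shrunk body weight (AFSBW), the
shrunk weight an animal is expected to carry at the target empty body fat
(default 28 %, i.e. USDA low Choice):

* **Hip-height route (HH)** — hip height and age give a BIF frame score
  (1-9 skeletal-size scale); a sex-specific linear relation maps frame score
  to AFSBW.
* **Carcass-trait route (CT)** — fat thickness, hot carcass weight, marbling
  score and (optionally) ribeye area give empty body fat (EBF, %); hot
  carcass weight gives empty body weight (EBW); AFSBW is then the shrunk
  weight reached after correcting EBW to the target EBF at 14.26 kg per
  percentage unit.

All functions accept scalars or numpy arrays and are pure arithmetic in
double precision; coefficients are stored to full printed precision.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .constants import DEFAULT_AGE_D, DEFAULT_TARGET_EBF_PCT, EBW_PER_SBW

logger = logging.getLogger(__name__)

__all__ = [
    "AnimalRecord",
    "CarcassRecord",
    "BodyComposition",
    "frame_score",
    "afsbw_from_frame",
    "ebf_from_carcass",
    "afsbw_from_carcass",
    "compose_cohort",
    "KG_PER_PCT_EBF",
]

#: AFSBW correction, kg empty body weight per percentage unit of EBF.
KG_PER_PCT_EBF = 14.26

# BIF frame-score polynomials: FS = c0 + c1*HH + c2*Age + c3*Age^2 + c4*HH*Age
# (HH in cm, Age in days; valid between 5 and 21 months of age).
_FRAME_COEFS_MALE = (-11.548, 0.1920, -0.0289, 0.00001947, 0.00001315)
_FRAME_COEFS_FEMALE = (-11.7086, 0.1859, -0.0239, 0.0000146, 0.00002988)

# AFSBW = slope * FS + intercept, by sex class.
_AFSBW_LINES = {
    "bull": (40.0, 440.0),
    "steer": (33.4, 366.6),
    "heifer": (26.7, 293.2),
}

_AGE_VALID_D = (150.0, 640.0)


@dataclass
class AnimalRecord:
    """Live-animal inputs at (and over) the feeding period.

    ``sex`` is ``"steer"`` or ``"heifer"``; the regression indicator ``a``
    (0 = steer, 1 = heifer) is derived from it.
    """

    animal_id: str
    sex: str
    isbw_kg: float
    hip_height_cm: float
    age_d: float = DEFAULT_AGE_D
    oadg_kg_d: Optional[float] = None
    dof_obs_d: Optional[float] = None
    final_bw_kg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in ("steer", "heifer"):
            raise ValueError(f"sex must be 'steer' or 'heifer', got {self.sex!r}")
        if not self.isbw_kg > 0:
            raise ValueError("initial shrunk body weight must be positive")
        if not 90.0 <= self.hip_height_cm <= 160.0:
            raise ValueError(
                f"hip height {self.hip_height_cm} cm outside plausible [90, 160] cm"
            )

    @property
    def a(self) -> int:
        """Sex indicator used throughout the adjustment regressions."""
        return 1 if self.sex == "heifer" else 0


@dataclass
class CarcassRecord:
    """Carcass traits collected at slaughter.

    Marbling score is on the 2-9 USDA scale (2 = practically devoid,
    4 = slight/Select, 5 = small/low Choice, 9 = moderately abundant).
    Ribeye area is optional; its absence selects the reduced EBF equation.
    """

    hcw_kg: float
    ft_cm: float
    marbling: float
    rea_cm2: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.hcw_kg > 0:
            raise ValueError("hot carcass weight must be positive")
        if self.ft_cm < 0:
            raise ValueError("fat thickness cannot be negative")
        if not 2.0 <= self.marbling <= 9.0:
            raise ValueError(f"marbling score {self.marbling} out of [2, 9]")
        if self.rea_cm2 is not None and not self.rea_cm2 > 0:
            raise ValueError("ribeye area must be positive when present")


@dataclass
class BodyComposition:
    """Composition summary for one animal under one prediction route."""

    method: str  # "HH" or "CT"
    afsbw_kg: float
    frame_score: Optional[float] = None
    ebf_pct: Optional[float] = None
    ebw_kg: Optional[float] = None
    ebf_equation: Optional[str] = None
    extra: dict = field(default_factory=dict)


def frame_score(hip_height_cm, age_d=DEFAULT_AGE_D, sex="steer"):
    """BIF frame score from hip height (cm) and age (days).

    Steers (and bulls) use the male polynomial; heifers the female one.
    The score is continuous and deliberately not clamped to the nominal
    1-9 scale. Ages outside the BIF validity window (5-21 months) trigger a
    warning, not an error.
    """
    hip_height_cm = np.asarray(hip_height_cm, dtype=float)
    age_d = np.asarray(age_d, dtype=float)
    if np.any(hip_height_cm <= 0):
        raise ValueError("hip height must be positive")
    if np.any((age_d < _AGE_VALID_D[0]) | (age_d > _AGE_VALID_D[1])):
        warnings.warn(
            "age outside the 150-640 d validity window of the frame-score "
            "equations; extrapolating",
            stacklevel=2,
        )
    if sex in ("steer", "bull"):
        c = _FRAME_COEFS_MALE
    elif sex == "heifer":
        c = _FRAME_COEFS_FEMALE
    else:
        raise ValueError(f"unknown sex {sex!r}")
    fs = (
        c[0]
        + c[1] * hip_height_cm
        + c[2] * age_d
        + c[3] * age_d**2
        + c[4] * hip_height_cm * age_d
    )
    return fs if fs.ndim else float(fs)


def afsbw_from_frame(fs, sex_class="steer"):
    """AFSBW (kg) from frame score via the sex-class specific line."""
    try:
        slope, intercept = _AFSBW_LINES[sex_class]
    except KeyError:
        raise ValueError(
            f"unknown sex class {sex_class!r}; expected one of {sorted(_AFSBW_LINES)}"
        ) from None
    fs = np.asarray(fs, dtype=float)
    if np.any((fs < 1.0) | (fs > 9.0)):
        logger.warning("frame score outside the nominal 1-9 scale; line extrapolated")
    out = slope * fs + intercept
    return out if out.ndim else float(out)


# EBF (%) from carcass traits. The full equation uses ribeye area; the
# reduced one applies when REA was not measured.
_EBF_FULL = (17.76207, 4.68142, 0.01945, 0.81855, -0.06754)
_EBF_REDUCED = (14.08796, 4.7135, 0.01316, 0.90855)


def ebf_from_carcass(ft_cm, hcw_kg, marbling, rea_cm2=None):
    """Empty body fat (%) from carcass traits.

    Returns ``(ebf_pct, equation)`` where ``equation`` is ``"full"`` when
    ribeye area was available and ``"reduced"`` otherwise. With array inputs
    a missing (NaN) REA selects the reduced equation elementwise.
    """
    ft = np.asarray(ft_cm, dtype=float)
    hcw = np.asarray(hcw_kg, dtype=float)
    ms = np.asarray(marbling, dtype=float)
    if np.any((ms < 2.0) | (ms > 9.0)):
        raise ValueError("marbling score out of [2, 9]")

    c = _EBF_FULL
    r = _EBF_REDUCED
    ebf_full = c[0] + c[1] * ft + c[2] * hcw + c[3] * ms
    ebf_reduced = r[0] + r[1] * ft + r[2] * hcw + r[3] * ms
    if rea_cm2 is None:
        out = ebf_reduced
        eq = "reduced"
        return (out if out.ndim else float(out)), eq
    rea = np.asarray(rea_cm2, dtype=float)
    has_rea = ~np.isnan(rea)
    ebf_full = ebf_full + c[4] * np.where(has_rea, rea, 0.0)
    out = np.where(has_rea, ebf_full, ebf_reduced)
    if out.ndim == 0:
        return float(out), ("full" if bool(has_rea) else "reduced")
    eq_arr = np.where(has_rea, "full", "reduced")
    return out, eq_arr


def afsbw_from_carcass(
    carcass: CarcassRecord, target_ebf_pct: float = DEFAULT_TARGET_EBF_PCT
) -> BodyComposition:
    """AFSBW (kg) from carcass traits (the CT route).

    EBW = 1.316 * HCW + 32.39; the weight correction to the target EBF is
    14.26 kg per % EBF, and EBW converts back to shrunk weight through the
    0.891 factor. At exactly the target EBF, AFSBW = EBW / 0.891.
    """
    ebf, eq = ebf_from_carcass(
        carcass.ft_cm, carcass.hcw_kg, carcass.marbling, carcass.rea_cm2
    )
    ebw = 1.316 * carcass.hcw_kg + 32.39
    afsbw = (ebw + KG_PER_PCT_EBF * (target_ebf_pct - ebf)) / EBW_PER_SBW
    return BodyComposition(
        method="CT", afsbw_kg=afsbw, ebf_pct=ebf, ebw_kg=ebw, ebf_equation=eq
    )


def compose_cohort(
    df: pd.DataFrame,
    target_ebf_pct: float = DEFAULT_TARGET_EBF_PCT,
    age_default_d: float = DEFAULT_AGE_D,
) -> pd.DataFrame:
    """Vectorized composition stage over a cohort table.

    Adds ``frame_score``, ``afsbw_hh_kg`` and, when carcass columns are
    present, ``ebf_pct``, ``ebw_kg``, ``afsbw_ct_kg`` and
    ``ebf_equation_used``. The input frame is not mutated.
    """
    out = df.copy()
    age = out["age_d"] if "age_d" in out else pd.Series(age_default_d, index=out.index)
    is_heifer = out["sex"].astype(str).str.lower().eq("heifer")

    hh = out["hip_height_cm"].to_numpy(dtype=float)
    age_arr = age.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fs_m = frame_score(hh, age_arr, sex="steer")
        fs_f = frame_score(hh, age_arr, sex="heifer")
    bad_age = (age_arr < _AGE_VALID_D[0]) | (age_arr > _AGE_VALID_D[1])
    if bad_age.any():
        logger.warning(
            "%d rows have ages outside the 150-640 d frame-score validity window",
            int(bad_age.sum()),
        )
    fs = np.where(is_heifer, fs_f, fs_m)
    out["frame_score"] = fs
    out["afsbw_hh_kg"] = np.where(
        is_heifer, afsbw_from_frame(fs, "heifer"), afsbw_from_frame(fs, "steer")
    )

    if {"hcw_kg", "ft_cm", "marbling"}.issubset(out.columns):
        rea = out["rea_cm2"].to_numpy(dtype=float) if "rea_cm2" in out else None
        ebf, eq = ebf_from_carcass(
            out["ft_cm"].to_numpy(dtype=float),
            out["hcw_kg"].to_numpy(dtype=float),
            out["marbling"].to_numpy(dtype=float),
            rea,
        )
        ebw = 1.316 * out["hcw_kg"].to_numpy(dtype=float) + 32.39
        out["ebf_pct"] = ebf
        out["ebw_kg"] = ebw
        out["afsbw_ct_kg"] = (ebw + KG_PER_PCT_EBF * (target_ebf_pct - ebf)) / EBW_PER_SBW
        out["ebf_equation_used"] = eq if rea is not None else "reduced"
    return out
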