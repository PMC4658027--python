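"""Column dictionary, validated CSV readers/writers, and run configuration.

Plain UTF-8 CSV with a header row is the interchange format throughout;
units are embedded in column names (``_kg``, ``_cm``, ``_d``) so a silent
unit mix-up cannot survive a read. The column dictionary is the contract
every stage reads and writes against; unknown columns pass through
untouched.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ColumnSpec",
    "COLUMN_DICTIONARY",
    "read_cohort",
    "write_cohort",
    "RunConfig",
    "load_config",
    "config_hash",
]


@dataclass(frozen=True)
class ColumnSpec:
    dtype: str  # "str", "float", "int", "category"
    units: str
    required: bool = False
    valid_range: Optional[tuple] = None
    choices: Optional[tuple] = None


COLUMN_DICTIONARY: dict[str, ColumnSpec] = {
    "animal_id": ColumnSpec("str", "", required=True),
    "sex": ColumnSpec("category", "", required=True, choices=("steer", "heifer")),
    "isbw_kg": ColumnSpec("float", "kg", required=True, valid_range=(1.0, None)),
    "hip_height_cm": ColumnSpec("float", "cm", required=True, valid_range=(90.0, 160.0)),
    "age_d": ColumnSpec("float", "d", valid_range=(1.0, None)),
    "adg_kg_d": ColumnSpec("float", "kg/d", required=True, valid_range=(0.0, None)),
    "dof_d": ColumnSpec("float", "d", required=True, valid_range=(1.0, None)),
    "final_bw_kg": ColumnSpec("float", "kg", valid_range=(1.0, None)),
    "hcw_kg": ColumnSpec("float", "kg", valid_range=(1.0, None)),
    "ft_cm": ColumnSpec("float", "cm", valid_range=(0.0, None)),
    "marbling": ColumnSpec("float", "2-9 scale", valid_range=(2.0, 9.0)),
    "rea_cm2": ColumnSpec("float", "cm^2", valid_range=(0.0, None)),
    "usda_yg": ColumnSpec("float", "1-5 scale", valid_range=(1.0, 5.0)),
    "mbv_cab_mrb": ColumnSpec("float", ""),
    "mbv_adg": ColumnSpec("float", ""),
    "mbv_hcw": ColumnSpec("float", ""),
    "mbv_rea": ColumnSpec("float", ""),
    "mbv_snp50_mrb": ColumnSpec("float", ""),
    "mbv_snp50_rea": ColumnSpec("float", ""),
    "mbv_all_mrb": ColumnSpec("float", ""),
    "mbv_all_rea": ColumnSpec("float", ""),
    "mbv_all_adg": ColumnSpec("float", ""),
    "mbv_all_rfi": ColumnSpec("float", ""),
    "mbv_bt_rfi": ColumnSpec("float", ""),
    "leptin_uasms2": ColumnSpec("category", "", choices=("CC", "CT", "TT")),
    "leptin_e2fb": ColumnSpec("category", "", choices=("CC", "CT", "TT")),
    "leptin_class": ColumnSpec("category", ""),
}


def read_cohort(path, dictionary=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a cohort CSV.

    Header matching is case-insensitive; missing required columns raise,
    naming the column. Rows violating a column's range or category contract
    are quarantined (returned separately with a ``quarantine_reason``).
    Returns ``(valid, quarantined)``.
    """
    dictionary = dictionary or COLUMN_DICTIONARY
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c, s in dictionary.items() if s.required and c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")

    reasons = pd.Series("", index=df.index, dtype=object)
    for name, spec in dictionary.items():
        if name not in df.columns:
            continue
        col = df[name]
        if spec.dtype == "float":
            coerced = pd.to_numeric(col, errors="coerce")
            bad = coerced.isna() & col.notna()
            if bad.any():
                reasons[bad] += f"{name} unparseable; "
            df[name] = coerced
            if spec.valid_range is not None:
                lo, hi = spec.valid_range
                out = pd.Series(False, index=df.index)
                if lo is not None:
                    out |= coerced < lo
                if hi is not None:
                    out |= coerced > hi
                out &= coerced.notna()
                if out.any():
                    rng = f"[{lo}, {hi}]" if hi is not None else f">= {lo}"
                    reasons[out] += f"{name} out of {rng}; "
        elif spec.choices is not None:
            bad = col.notna() & ~col.astype(str).isin(spec.choices)
            if bad.any():
                reasons[bad] += f"{name} not in {spec.choices}; "

    quarantined = df[reasons != ""].copy()
    quarantined["quarantine_reason"] = reasons[reasons != ""].str.rstrip("; ")
    valid = df[reasons == ""].copy()
    if len(quarantined):
        logger.warning("quarantined %d of %d rows", len(quarantined), len(df))
    return valid.reset_index(drop=True), quarantined.reset_index(drop=True)


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table as UTF-8 CSV (no index column)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (loadable from YAML)."""

    diet_me_mcal_kg: float = 3.2
    target_ebf_pct: float = 28.0
    srw_kg: float = 478.0
    maintenance_factor: float = 1.0
    max_projection_days: int = 1000
    dmi_model: str = "nrc_empirical"
    entry_p: float = 0.15
    stay_p: float = 0.15
    crossval_reps: int = 1000
    crossval_train_n: int = 750
    seed: int = 0
    n_heifers: int = 681
    n_steers: int = 836
    truth_equation: Optional[str] = None
    truth_residual_sd: Optional[float] = None
    truth_target_total_sd: Optional[float] = None
    input_csv: Optional[str] = None
    out_dir: str = "feedcast_run"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1.5 < self.diet_me_mcal_kg < 4.0:
            raise ValueError("diet_me_mcal_kg out of range")
        if not 0 < self.target_ebf_pct < 50:
            raise ValueError("target_ebf_pct out of range")
        for p in ("entry_p", "stay_p"):
            if not 0 < getattr(self, p) < 1:
                raise ValueError(f"{p} must be in (0, 1)")
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise FileNotFoundError(self.input_csv)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; unknown keys go to ``extra``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {k: v for k, v in raw.items() if k in RunConfig.__dataclass_fields__}
    extra = {k: v for k, v in raw.items() if k not in RunConfig.__dataclass_fields__}
    cfg = RunConfig(**known)
    cfg.extra = extra
    return cfg


def config_hash(cfg: RunConfig) -> str:
    """Stable hash of a configuration for the run manifest."""
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
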