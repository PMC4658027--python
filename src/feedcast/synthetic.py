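"""Synthetic feedlot cohorts with realistic marginal and correlation structure.

The generator emulates a commercial-feedyard database of crossbred heifers
and steers: per-sex means, SDs and ranges for performance traits, carcass
traits and eleven SNP-panel (MBV) scores; a Gaussian-copula correlation
structure linking the MBV scores to phenotypes; and per-sex leptin genotype
frequencies for the UASMS2 and E2FB SNPs.

Marginals are truncated normals whose latent location/scale are solved so
that the *truncated* distribution reproduces the requested mean and SD
exactly (the printed ranges are hard truncation bounds). The marbling score
is additionally discretized to the integer 3-9 scale; its latent variance is
pre-shrunk by the 1/12 rounding variance so the discretized variable still
matches the requested SD.

Optionally, a generating "truth" equation writes a simulated response
(carcass-route AFSBW for the ``eq9``/``eq10`` truths, dry matter required
for ``eq11``/``eq12``) as mean function plus Gaussian residual, enabling
exact parameter-recovery tests for every downstream fitting stage. The
generating coefficients are retrievable via :func:`truth_report`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .body_composition import compose_cohort
from .genomic_adjustment import (
    EQ9,
    EQ10,
    EQ11,
    EQ12,
    apply_eq9,
    apply_eq10,
    apply_eq11,
    apply_eq12,
)
from .growth_engine import DietSpec, end_bw_dmi, nrc_empirical_dmi

__all__ = [
    "GeneratorSpec",
    "TruthSpec",
    "generate",
    "truth_report",
    "TABLE1_MARGINALS",
    "GENOTYPE_COUNTS",
    "MBV_PHENOTYPE_CORR",
    "PHENOTYPE_CORR",
]

# ---------------------------------------------------------------------------
# Default study conditions: per-sex marginals (mean, sd, low, high)
# ---------------------------------------------------------------------------

TABLE1_MARGINALS = {
    "heifer": {
        "isbw_kg": (297.0, 39.7, 182.0, 427.0),
        "hip_height_cm": (117.0, 5.01, 104.0, 144.0),
        "final_bw_kg": (507.0, 54.9, 364.0, 654.0),
        "dof_d": (161.0, 34.9, 91.0, 262.0),
        "adg_kg_d": (1.36, 0.312, 0.514, 2.23),
        "hcw_kg": (326.0, 33.8, 206.0, 430.0),
        "ft_cm": (1.25, 0.46, 0.0, 2.90),
        "rea_cm2": (85.4, 10.95, 53.6, 137.0),
        "marbling": (4.85, 1.12, 3.0, 9.0),
        "mbv_cab_mrb": (49.1, 16.6, 1.94, 97.7),
        "mbv_adg": (0.15, 0.08, -0.11, 0.37),
        "mbv_hcw": (27.2, 8.49, -16.1, 48.6),
        "mbv_rea": (-0.36, 0.47, -2.01, 0.83),
        "mbv_snp50_mrb": (-30.4, 21.9, -82.9, 38.4),
        "mbv_snp50_rea": (-0.56, 0.67, -2.37, 1.5),
        "mbv_all_mrb": (80.7, 20.4, 25.2, 148.0),
        "mbv_all_rea": (1.11, 0.31, 0.13, 2.15),
        "mbv_all_adg": (0.38, 0.10, 0.04, 0.64),
        "mbv_all_rfi": (2.18, 1.93, -4.29, 8.53),
        "mbv_bt_rfi": (1.98, 0.60, 0.07, 3.74),
    },
    "steer": {
        "isbw_kg": (314.0, 45.6, 166.0, 440.0),
        "hip_height_cm": (120.0, 4.99, 104.0, 147.0),
        "final_bw_kg": (556.0, 50.6, 386.0, 704.0),
        "dof_d": (162.0, 42.7, 91.0, 285.0),
        "adg_kg_d": (1.57, 0.414, 0.662, 3.04),
        "hcw_kg": (356.0, 34.1, 248.0, 441.0),
        "ft_cm": (1.14, 0.40, 0.0, 2.41),
        "rea_cm2": (88.3, 10.4, 58.1, 123.0),
        "marbling": (4.51, 1.0, 3.0, 9.0),
        "mbv_cab_mrb": (52.3, 17.9, 3.17, 101.2),
        "mbv_adg": (0.15, 0.08, -0.09, 0.45),
        "mbv_hcw": (26.3, 9.01, -17.7, 53.1),
        "mbv_rea": (-0.42, 0.47, -1.55, 0.87),
        "mbv_snp50_mrb": (-25.6, 22.7, -96.9, 38.1),
        "mbv_snp50_rea": (-0.62, 0.65, -2.16, 1.64),
        "mbv_all_mrb": (84.1, 22.2, 19.8, 145.0),
        "mbv_all_rea": (1.11, 0.31, 0.27, 2.09),
        "mbv_all_adg": (0.40, 0.10, 0.04, 0.69),
        "mbv_all_rfi": (2.25, 1.80, -3.62, 9.61),
        "mbv_bt_rfi": (2.05, 0.57, 0.45, 3.73),
    },
}

#: Per-sex genotype counts (CC, CT, TT) for the two leptin SNPs; drawn
#: probabilities are these counts normalized.
GENOTYPE_COUNTS = {
    "heifer": {"e2fb": (254, 416, 164), "uasms2": (406, 349, 61)},
    "steer": {"e2fb": (233, 333, 113), "uasms2": (313, 282, 70)},
}

# MBV-phenotype correlations (pooled-sex estimates); phenotype keys are the
# observable columns the copula generates.
_MBV_CORR_COLS = ("hip_height_cm", "final_bw_kg", "hcw_kg", "ft_cm", "marbling", "rea_cm2", "dof_d")
_MBV_CORR_ROWS = {
    "mbv_cab_mrb": (-0.060, 0.109, 0.011, 0.261, 0.213, -0.177, 0.016),
    "mbv_adg": (-0.031, 0.069, 0.032, 0.060, 0.046, -0.069, 0.056),
    "mbv_hcw": (0.072, 0.162, 0.158, -0.068, 0.063, 0.144, 0.152),
    "mbv_rea": (0.173, 0.065, 0.138, -0.335, -0.135, 0.370, 0.199),
    "mbv_snp50_mrb": (-0.062, 0.112, 0.020, 0.217, 0.189, -0.148, 0.009),
    "mbv_snp50_rea": (0.097, 0.004, 0.038, -0.152, -0.129, 0.130, 0.061),
    "mbv_all_mrb": (0.013, 0.163, 0.079, 0.145, 0.129, -0.041, 0.135),
    "mbv_all_rea": (0.066, 0.100, 0.101, -0.120, -0.071, 0.159, 0.127),
    "mbv_all_adg": (-0.102, 0.007, -0.044, 0.199, 0.121, -0.144, 0.024),
    "mbv_all_rfi": (0.091, 0.067, 0.099, -0.056, -0.047, 0.106, 0.025),
    "mbv_bt_rfi": (-0.036, 0.083, 0.016, 0.215, 0.153, -0.094, 0.111),
}
MBV_PHENOTYPE_CORR = {
    (mbv, ph): r
    for mbv, row in _MBV_CORR_ROWS.items()
    for ph, r in zip(_MBV_CORR_COLS, row)
}

#: A documented handful of phenotype-phenotype correlations; every pair not
#: listed here (including MBV-MBV pairs) defaults to zero.
PHENOTYPE_CORR = {
    ("isbw_kg", "hip_height_cm"): 0.55,
    ("isbw_kg", "final_bw_kg"): 0.60,
    ("isbw_kg", "dof_d"): -0.55,
    ("final_bw_kg", "adg_kg_d"): 0.45,
    ("final_bw_kg", "hcw_kg"): 0.85,
    ("final_bw_kg", "dof_d"): 0.20,
    ("adg_kg_d", "dof_d"): -0.35,
    ("hcw_kg", "rea_cm2"): 0.45,
    ("ft_cm", "marbling"): 0.35,
}

_VAR_ORDER = tuple(TABLE1_MARGINALS["heifer"].keys())

_TRUTH_DEFAULTS = {
    # (coefficients, residual SD)
    "eq9": (EQ9, 51.3),
    "eq10": (EQ10, 49.0),
    "eq11": (EQ11, 1.11),
    "eq12": (EQ12, 1.17),
}


@dataclass
class TruthSpec:
    """Generating-truth description for the simulated response.

    ``target_total_sd`` optionally rescales the systematic part around its
    mean so the total response SD hits the requested value (used when the
    implied total variability of a response must be calibrated).
    """

    equation: str
    residual_sd: Optional[float] = None
    coefficients: Optional[dict] = None
    target_total_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.equation not in _TRUTH_DEFAULTS:
            raise ValueError(f"unknown truth equation {self.equation!r}")
        coefs, sd = _TRUTH_DEFAULTS[self.equation]
        if self.coefficients is None:
            self.coefficients = dict(coefs)
        if self.residual_sd is None:
            self.residual_sd = sd


@dataclass
class GeneratorSpec:
    """Full description of a synthetic cohort."""

    n_heifers: int = 681
    n_steers: int = 836
    marginals: dict = field(default_factory=lambda: {
        s: dict(v) for s, v in TABLE1_MARGINALS.items()
    })
    mbv_phenotype_corr: dict = field(default_factory=lambda: dict(MBV_PHENOTYPE_CORR))
    phenotype_corr: dict = field(default_factory=lambda: dict(PHENOTYPE_CORR))
    genotype_counts: dict = field(default_factory=lambda: {
        s: dict(v) for s, v in GENOTYPE_COUNTS.items()
    })
    truth: Optional[TruthSpec] = None
    couple_leptin_mbv: bool = False
    leptin_mbv_delta: float = 0.05  # mbv_rea shift per C allele beyond 2
    enforce_ranges: bool = True
    age_d: float = 365.0
    _corr_cache: Optional[pd.DataFrame] = field(
        default=None, init=False, repr=False, compare=False
    )

    def correlation_matrix(self) -> pd.DataFrame:
        """Assembled latent correlation matrix (PSD-repaired if needed)."""
        if self._corr_cache is not None:
            return self._corr_cache
        k = len(_VAR_ORDER)
        R = np.eye(k)
        idx = {v: i for i, v in enumerate(_VAR_ORDER)}
        for (x, y), r in {**self.phenotype_corr, **self.mbv_phenotype_corr}.items():
            if x in idx and y in idx:
                R[idx[x], idx[y]] = R[idx[y], idx[x]] = r
        R = _repair_psd(R)
        self._corr_cache = pd.DataFrame(R, index=_VAR_ORDER, columns=_VAR_ORDER)
        return self._corr_cache


def _repair_psd(R: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Clip negative eigenvalues and renormalize to unit diagonal."""
    w, V = np.linalg.eigh(R)
    if w.min() >= eps:
        return R
    warnings.warn(
        f"correlation matrix not PSD (min eigenvalue {w.min():.3g}); "
        "repaired by eigenvalue clipping",
        stacklevel=2,
    )
    w = np.clip(w, eps, None)
    R2 = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    if np.linalg.eigvalsh(R2).min() < 0:
        raise ValueError("correlation matrix could not be repaired")
    return R2


@lru_cache(maxsize=256)
def _matched_truncnorm(mean: float, sd: float, lo: float, hi: float):
    """Latent (mu, sigma) so the truncated normal has the given mean/SD.

    Returns ``(a, b, mu, sigma)`` in scipy's standardized parameterization.
    Falls back to the nominal parameters (with a warning) if the root solve
    fails, which only happens for infeasible mean/SD/range combinations.
    """

    def eqs(p):
        mu, lnsig = p
        sig = np.exp(lnsig)
        a, b = (lo - mu) / sig, (hi - mu) / sig
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    sol = optimize.root(eqs, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success:
        warnings.warn(
            f"truncated-normal moment match failed for mean={mean}, sd={sd}, "
            f"range=({lo}, {hi}); using nominal parameters",
            stacklevel=2,
        )
        mu, sig = mean, sd
    else:
        mu, sig = float(sol.x[0]), float(np.exp(sol.x[1]))
    return (lo - mu) / sig, (hi - mu) / sig, mu, sig


def _sample_marginal(u: np.ndarray, name: str, params, enforce_ranges: bool = True) -> np.ndarray:
    """Copula uniforms -> truncated-normal marginal (moment-matched)."""
    mean, sd, lo, hi = params
    if name == "marbling":
        # pre-shrink latent variance by the 1/12 integer-rounding variance
        sd = float(np.sqrt(max(sd**2 - 1.0 / 12.0, 1e-4)))
    if not enforce_ranges:
        x = stats.norm.ppf(np.clip(u, 1e-12, 1 - 1e-12), loc=mean, scale=sd)
    else:
        a, b, mu, sig = _matched_truncnorm(mean, sd, lo, hi)
        x = stats.truncnorm.ppf(np.clip(u, 1e-12, 1 - 1e-12), a, b, loc=mu, scale=sig)
    if name == "marbling":
        x = np.clip(np.rint(x), params[2], params[3])
    return x


def _generate_sex(
    spec: GeneratorSpec, sex: str, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    R = spec.correlation_matrix().to_numpy()
    L = np.linalg.cholesky(R)
    z = rng.standard_normal((n, len(_VAR_ORDER))) @ L.T
    u = special.ndtr(z)
    cols = {}
    for j, name in enumerate(_VAR_ORDER):
        cols[name] = _sample_marginal(
            u[:, j], name, spec.marginals[sex][name], spec.enforce_ranges
        )
    df = pd.DataFrame(cols)
    df.insert(0, "sex", sex)
    df.insert(2, "age_d", spec.age_d)

    for snp in ("uasms2", "e2fb"):
        counts = np.asarray(spec.genotype_counts[sex][snp], dtype=float)
        probs = counts / counts.sum()
        df[f"leptin_{snp}"] = rng.choice(["CC", "CT", "TT"], size=n, p=probs)
    df["leptin_class"] = df["leptin_uasms2"] + df["leptin_e2fb"]

    if spec.couple_leptin_mbv:
        n_c = (
            df["leptin_uasms2"].str.count("C") + df["leptin_e2fb"].str.count("C")
        ).to_numpy(dtype=float)
        df["mbv_rea"] = df["mbv_rea"] + spec.leptin_mbv_delta * (n_c - 2.0)
    return df


def _truth_columns(df: pd.DataFrame, spec: GeneratorSpec, rng: np.random.Generator) -> dict:
    """Simulated response under the generating truth; returns truth metadata."""
    truth = spec.truth
    c = truth.coefficients
    a = df["sex"].eq("heifer").to_numpy(dtype=float)
    eq = truth.equation
    if eq == "eq9":
        composed = compose_cohort(df, age_default_d=spec.age_d)
        m = apply_eq9(a, composed["afsbw_hh_kg"].to_numpy(), df["mbv_rea"].to_numpy())
        # rebuild with custom coefficients if they differ from the published set
        if c != EQ9:
            hh = composed["afsbw_hh_kg"].to_numpy()
            m = (
                c["const"] + c["a"] * a
                + (c["afsbw_hh_kg"] + c["a:afsbw_hh_kg"] * a) * hh
                + c["mbv_rea"] * df["mbv_rea"].to_numpy()
            )
        response_col = "truth_afsbw_ct_kg"
    elif eq == "eq10":
        m = apply_eq10(
            a,
            df["hip_height_cm"].to_numpy(),
            df["isbw_kg"].to_numpy(),
            df["mbv_cab_mrb"].to_numpy(),
            df["mbv_rea"].to_numpy(),
        )
        response_col = "truth_afsbw_ct_kg"
    elif eq in ("eq11", "eq12"):
        diet = DietSpec()
        if eq == "eq11":
            mid_sbw = 0.5 * (df["isbw_kg"] + df["final_bw_kg"]).to_numpy()
            pdmi = nrc_empirical_dmi(mid_sbw, diet)
            df["pdmi_hh_kg_d"] = pdmi
            m = apply_eq11(a, pdmi, df["mbv_rea"].to_numpy())
        else:
            pdmi = end_bw_dmi(df["final_bw_kg"].to_numpy())
            df["pdmi_endbw_kg_d"] = pdmi
            m = apply_eq12(a, pdmi, df["mbv_rea"].to_numpy())
        response_col = "truth_dmr_kg_d"
    else:  # pragma: no cover - guarded by TruthSpec
        raise ValueError(eq)

    scale = 1.0
    if truth.target_total_sd is not None:
        var_m = float(np.var(m))
        var_target = truth.target_total_sd**2 - truth.residual_sd**2
        if var_target <= 0:
            raise ValueError("target total SD must exceed the residual SD")
        scale = float(np.sqrt(var_target / var_m))
        m = float(np.mean(m)) + scale * (m - float(np.mean(m)))
    df[response_col] = m + rng.normal(0.0, truth.residual_sd, size=len(df))
    return {
        "equation": eq,
        "coefficients": dict(c),
        "residual_sd": truth.residual_sd,
        "systematic_scale": scale,
        "response_col": response_col,
    }


def generate(spec: Optional[GeneratorSpec] = None, seed: Optional[int] = None) -> pd.DataFrame:
    """Generate a synthetic cohort; deterministic under ``seed``.

    Returns one row per animal with the standard column-dictionary names.
    When a generating truth is active the simulated response appears in a
    ``truth_``-prefixed column and the generating parameters are stored in
    ``df.attrs['truth']`` for :func:`truth_report`.
    """
    spec = spec or GeneratorSpec()
    rng = np.random.default_rng(seed)
    parts = []
    if spec.n_heifers:
        parts.append(_generate_sex(spec, "heifer", spec.n_heifers, rng))
    if spec.n_steers:
        parts.append(_generate_sex(spec, "steer", spec.n_steers, rng))
    df = pd.concat(parts, ignore_index=True)
    df.insert(
        0,
        "animal_id",
        [f"{s[0].upper()}{i:06d}" for i, s in enumerate(df["sex"], start=1)],
    )
    truth_meta = None
    if spec.truth is not None:
        truth_meta = _truth_columns(df, spec, rng)
    df.attrs["truth"] = truth_meta
    return df


def truth_report(cohort: pd.DataFrame) -> pd.DataFrame:
    """Table of the generating parameters of a truth-active cohort.

    Empty for cohorts generated without a truth equation. Coefficients are
    the requested generating values; ``systematic_scale`` records any
    total-SD calibration applied to the non-intercept structure.
    """
    meta = cohort.attrs.get("truth")
    if not meta:
        return pd.DataFrame(columns=["parameter", "value"])
    rows = [
        {"parameter": "equation", "value": meta["equation"]},
        {"parameter": "residual_sd", "value": meta["residual_sd"]},
        {"parameter": "systematic_scale", "value": meta["systematic_scale"]},
        {"parameter": "response_col", "value": meta["response_col"]},
    ]
    rows += [
        {"parameter": f"coef:{k}", "value": v}
        for k, v in meta["coefficients"].items()
    ]
    return pd.DataFrame(rows)
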