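"""Genomic adjustment of growth-model predictions.

Commercial SNP-panel scores (molecular breeding values, MBVs) and two leptin
SNPs (UASMS2, E2FB) are used to explain the disagreement between two
prediction routes of the growth model. The workflow:

1. form per-animal difference ("delta") variables, e.g.
   dAFSBW = AFSBW_CT - AFSBW_HH (carcass route minus hip-height route),
   dDOF = eDOF - DOF_method, dDMI = DMR - DMI_HH;
2. regress the carcass-route quantity (or the delta) on the hip-height-route
   quantity, the sex indicator ``a`` (0 = steer, 1 = heifer) with its
   interaction, and MBV scores — either the published fixed equation forms
   (here ``EQ9``..``EQ12``) or an open stepwise search;
3. summarize leptin genotype frequencies (allele counts, C:T ratios,
   chi-square against the 25:50:25 expectation).

Leptin genotype class and the ribeye-area MBV are mutually exclusive in any
one model (the leptin SNPs are part of that panel), enforced through the
stepwise exclusion list.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GenomicProfile",
    "FittedAdjustment",
    "MBV_NAMES",
    "EQ9",
    "EQ10",
    "EQ11",
    "EQ12",
    "apply_eq9",
    "apply_eq10",
    "apply_eq11",
    "apply_eq12",
    "sex_indicator",
    "compute_deltas",
    "fit_eq9_form",
    "fit_eq10_form",
    "fit_eq11_form",
    "fit_eq12_form",
    "stepwise_ols",
    "expand_candidates",
    "best_subset_ols",
    "leptin_allele_stats",
    "variance_explained",
    "group_effects",
    "DEFAULT_EXCLUSIONS",
]

#: The 11 MBV score names (column names carry an ``mbv_`` prefix).
MBV_NAMES = (
    "cab_mrb",
    "adg",
    "hcw",
    "rea",
    "snp50_mrb",
    "snp50_rea",
    "all_mrb",
    "all_rea",
    "all_adg",
    "all_rfi",
    "bt_rfi",
)

_GENOTYPES = ("CC", "CT", "TT")

#: Predictor pairs that never co-enter one model (collinear by construction).
DEFAULT_EXCLUSIONS = (("leptin_class", "mbv_rea"),)


@dataclass
class GenomicProfile:
    """MBV scores and leptin genotypes for one animal."""

    mbv: dict
    uasms2: str
    e2fb: str

    def __post_init__(self) -> None:
        if self.uasms2 not in _GENOTYPES or self.e2fb not in _GENOTYPES:
            raise ValueError("genotypes must be one of CC/CT/TT")
        unknown = set(self.mbv) - set(MBV_NAMES)
        if unknown:
            raise ValueError(f"unknown MBV names: {sorted(unknown)}")

    @property
    def leptin_class(self) -> str:
        """Nine-level UASMS2 x E2FB combination (e.g. 'CCCT')."""
        return self.uasms2 + self.e2fb


@dataclass
class FittedAdjustment:
    """A fitted linear adjustment: term table plus an applier.

    ``terms`` maps term name -> (coefficient, SE, p-value); ``design``
    rebuilds the model matrix from a cohort frame so the fit can be applied
    to new data.
    """

    response: str
    terms: pd.DataFrame
    n: int
    rmse: float
    r2: float
    design_cols: list = field(default_factory=list)
    prepare: Optional[object] = None  # callable df -> df, applied before predict

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        if self.prepare is not None:
            df = self.prepare(df)
        X = _design_matrix(df, self.design_cols)
        return X @ self.terms["coef"].to_numpy()

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "n": int(self.n),
            "rmse": float(self.rmse),
            "r2": float(self.r2),
            "terms": {
                t: {
                    "coef": float(r["coef"]),
                    "se": float(r["se"]),
                    "p": float(r["p"]),
                }
                for t, r in self.terms.iterrows()
            },
        }


def sex_indicator(df: pd.DataFrame) -> np.ndarray:
    """Indicator ``a``: 0 for steers, 1 for heifers."""
    return df["sex"].astype(str).str.lower().eq("heifer").to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Published adjustment equations (fixed coefficient sets)
# ---------------------------------------------------------------------------
# AFSBW_CT = (312.8 - 175.9 a) + (0.5354 + 0.392 a) AFSBW_HH + 44.5 MBV_REA
EQ9 = {
    "const": 312.8,
    "a": -175.9,
    "afsbw_hh_kg": 0.5354,
    "a:afsbw_hh_kg": 0.392,
    "mbv_rea": 44.5,
}

# AFSBW_CT from hip height and initial SBW (fully sex-interacted quadratic
# response surface) plus the marbling and ribeye-area MBVs.
EQ10 = {
    "const": -1184.7,
    "a": 15758.0,
    "hh": 34.292,
    "a:hh": -270.98,
    "isbw": -2.155,
    "a:isbw": -53.347,
    "hh:isbw": 0.00888,
    "a:hh:isbw": 0.9126,
    "hh2": -0.165,
    "a:hh2": 1.152,
    "hh2:isbw": 0.00009,
    "a:hh2:isbw": -0.00387,
    "mbv_cab_mrb": -0.257,
    "mbv_rea": 39.04,
}

# DMR on model-predicted DMI: each unit of MBV_REA lowers DMR by ~0.6 kg/d.
EQ11 = {
    "const": -3.41,
    "a": 6.93,
    "pdmi": 1.48,
    "a:pdmi": -1.054,
    "mbv_rea": -0.606,
}

# As EQ11 but with the end-BW empirical DMI predictor.
EQ12 = {
    "const": 0.71,
    "a": 3.01,
    "pdmi": 0.959,
    "a:pdmi": -0.453,
    "mbv_rea": -0.45,
}


def apply_eq9(a, afsbw_hh_kg, mbv_rea):
    """Predicted AFSBW_CT (kg) from the published coefficients."""
    a = np.asarray(a, dtype=float)
    out = (
        EQ9["const"]
        + EQ9["a"] * a
        + (EQ9["afsbw_hh_kg"] + EQ9["a:afsbw_hh_kg"] * a) * np.asarray(afsbw_hh_kg, float)
        + EQ9["mbv_rea"] * np.asarray(mbv_rea, float)
    )
    return out if out.ndim else float(out)


def apply_eq10(a, hh_cm, isbw_kg, mbv_cab_mrb, mbv_rea):
    """Predicted AFSBW_CT (kg) from hip height, initial SBW and two MBVs."""
    a = np.asarray(a, dtype=float)
    hh = np.asarray(hh_cm, dtype=float)
    isbw = np.asarray(isbw_kg, dtype=float)
    c = EQ10
    out = (
        c["const"] + c["a"] * a
        + (c["hh"] + c["a:hh"] * a) * hh
        + (c["isbw"] + c["a:isbw"] * a) * isbw
        + (c["hh:isbw"] + c["a:hh:isbw"] * a) * hh * isbw
        + (c["hh2"] + c["a:hh2"] * a) * hh**2
        + (c["hh2:isbw"] + c["a:hh2:isbw"] * a) * hh**2 * isbw
        + c["mbv_cab_mrb"] * np.asarray(mbv_cab_mrb, float)
        + c["mbv_rea"] * np.asarray(mbv_rea, float)
    )
    return out if out.ndim else float(out)


def _apply_dmr(coefs, a, pdmi, mbv_rea):
    a = np.asarray(a, dtype=float)
    out = (
        coefs["const"]
        + coefs["a"] * a
        + (coefs["pdmi"] + coefs["a:pdmi"] * a) * np.asarray(pdmi, float)
        + coefs["mbv_rea"] * np.asarray(mbv_rea, float)
    )
    return out if out.ndim else float(out)


def apply_eq11(a, pdmi_kg_d, mbv_rea):
    """Predicted DMR (kg/d) from model-predicted DMI and MBV_REA."""
    return _apply_dmr(EQ11, a, pdmi_kg_d, mbv_rea)


def apply_eq12(a, pdmi_endbw_kg_d, mbv_rea):
    """Predicted DMR (kg/d) from the end-BW DMI predictor and MBV_REA."""
    return _apply_dmr(EQ12, a, pdmi_endbw_kg_d, mbv_rea)


# ---------------------------------------------------------------------------
# Delta variables
# ---------------------------------------------------------------------------

def compute_deltas(df: pd.DataFrame) -> pd.DataFrame:
    """Per-animal difference variables between prediction routes.

    Missing operands propagate as NaN — a missing prediction never becomes a
    zero delta.
    """
    out = df.copy()

    def col(name):
        return out[name] if name in out else pd.Series(np.nan, index=out.index)

    out["d_afsbw_kg"] = col("afsbw_ct_kg") - col("afsbw_hh_kg")
    out["d_adg_hh_kg_d"] = col("adg_kg_d") - col("padg_hh_kg_d")
    out["d_adg_ct_kg_d"] = col("adg_kg_d") - col("padg_ct_kg_d")
    out["d_dof_hh_d"] = col("edof_d") - col("dof_hh_d")
    out["d_dof_ct_d"] = col("edof_d") - col("dof_ct_d")
    out["d_dmi_kg_d"] = col("dmr_kg_d") - col("pdmi_hh_kg_d")
    return out


# ---------------------------------------------------------------------------
# OLS fitting of the published equation forms
# ---------------------------------------------------------------------------

def _design_matrix(df: pd.DataFrame, cols: Sequence[str]) -> np.ndarray:
    """Model matrix from column expressions.

    A column expression is either a frame column name, ``const``, or a
    ``:``-joined product of column names (``a:afsbw_hh_kg``). ``<col>2``
    squares (``hh2`` style names must exist as real columns or be written
    as ``col*col`` products).
    """
    n = len(df)
    out = np.empty((n, len(cols)))
    for j, expr in enumerate(cols):
        if expr == "const":
            out[:, j] = 1.0
            continue
        prod = np.ones(n)
        for part in expr.split(":"):
            prod = prod * df[part].to_numpy(dtype=float)
        out[:, j] = prod
    return out


def _ols_fit(
    df: pd.DataFrame, response: str, design_cols: list[str], check_rank: bool = True
) -> FittedAdjustment:
    data = df[[response] + sorted({p for c in design_cols for p in c.split(":") if p != "const"})]
    data = data.dropna()
    y = data[response].to_numpy(dtype=float)
    X = _design_matrix(data, design_cols)
    if check_rank:
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # name the term whose removal restores full rank
            for j, name in enumerate(design_cols):
                Xr = np.delete(X, j, axis=1)
                if np.linalg.matrix_rank(Xr) == rank:
                    raise ValueError(f"design matrix rank deficient; offending term: {name}")
            raise ValueError("design matrix rank deficient")
    res = sm.OLS(y, X).fit()
    terms = pd.DataFrame(
        {"coef": res.params, "se": res.bse, "p": res.pvalues}, index=design_cols
    )
    rmse = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else np.nan
    return FittedAdjustment(
        response=response,
        terms=terms,
        n=int(res.nobs),
        rmse=rmse,
        r2=float(res.rsquared),
        design_cols=list(design_cols),
    )


def _with_sex_indicator(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    if "a" not in out:
        out["a"] = sex_indicator(out)
    return out


def fit_eq9_form(df: pd.DataFrame, response: str = "afsbw_ct_kg") -> FittedAdjustment:
    """OLS of AFSBW_CT on {a, AFSBW_HH, a x AFSBW_HH, MBV_REA}.

    A single-sex cohort drops the sex terms with a warning.
    """
    data = _with_sex_indicator(df)
    cols = ["const", "a", "afsbw_hh_kg", "a:afsbw_hh_kg", "mbv_rea"]
    if data["a"].nunique() < 2:
        warnings.warn("single-sex cohort: sex terms dropped", stacklevel=2)
        cols = ["const", "afsbw_hh_kg", "mbv_rea"]
    fit = _ols_fit(data, response, cols)
    fit.prepare = _with_sex_indicator
    return fit


def fit_eq10_form(df: pd.DataFrame, response: str = "afsbw_ct_kg") -> FittedAdjustment:
    """OLS with the full sex-interacted HH/iSBW response surface plus MBVs."""
    data = _prepare_eq10(df)
    cols = [
        "const", "a",
        "hh", "a:hh",
        "isbw", "a:isbw",
        "hh:isbw", "a:hh:isbw",
        "hh2", "a:hh2",
        "hh2:isbw", "a:hh2:isbw",
        "mbv_cab_mrb", "mbv_rea",
    ]
    fit = _ols_fit(data, response, cols)
    fit.prepare = _prepare_eq10
    return fit


def _prepare_eq10(df: pd.DataFrame) -> pd.DataFrame:
    data = _with_sex_indicator(df)
    data = data.rename(columns={"hip_height_cm": "hh", "isbw_kg": "isbw"})
    data["hh2"] = data["hh"] ** 2
    return data


def _fit_dmr_form(df: pd.DataFrame, response: str, pdmi_col: str) -> FittedAdjustment:
    def prep(frame: pd.DataFrame) -> pd.DataFrame:
        return _with_sex_indicator(frame).rename(columns={pdmi_col: "pdmi"})

    data = prep(df)
    cols = ["const", "a", "pdmi", "a:pdmi", "mbv_rea"]
    if data["a"].nunique() < 2:
        warnings.warn("single-sex cohort: sex terms dropped", stacklevel=2)
        cols = ["const", "pdmi", "mbv_rea"]
    fit = _ols_fit(data, response, cols)
    fit.prepare = prep
    return fit


def fit_eq11_form(
    df: pd.DataFrame, response: str = "dmr_kg_d", pdmi_col: str = "pdmi_hh_kg_d"
) -> FittedAdjustment:
    """OLS of DMR on {a, pDMI, a x pDMI, MBV_REA} (model-predicted DMI)."""
    return _fit_dmr_form(df, response, pdmi_col)


def fit_eq12_form(
    df: pd.DataFrame, response: str = "dmr_kg_d", pdmi_col: str = "pdmi_endbw_kg_d"
) -> FittedAdjustment:
    """As the EQ11 form but with the end-BW empirical DMI predictor."""
    return _fit_dmr_form(df, response, pdmi_col)


# ---------------------------------------------------------------------------
# Stepwise and best-subset selection
# ---------------------------------------------------------------------------

def expand_candidates(
    df: pd.DataFrame,
    base: Sequence[str],
    sex_interactions: bool = True,
    quadratics: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Augment a cohort frame with sex-interaction and quadratic candidates.

    Returns the augmented frame and the full candidate column list
    (base + ``a:x`` + ``x^2`` columns, materialized as real columns).
    """
    out = _with_sex_indicator(df)
    cands = list(base)
    for x in base:
        if sex_interactions and out[x].dtype != object:
            name = f"a_x_{x}"
            out[name] = out["a"] * out[x].astype(float)
            cands.append(name)
        if quadratics and out[x].dtype != object:
            name = f"{x}_sq"
            out[name] = out[x].astype(float) ** 2
            cands.append(name)
    return out, cands


def _excluded(candidate: str, selected: Iterable[str], exclusions) -> bool:
    for pair in exclusions:
        if candidate in pair and any(s in pair and s != candidate for s in selected):
            return True
    return False


def stepwise_ols(
    df: pd.DataFrame,
    response: str,
    candidates: Sequence[str],
    entry_p: float = 0.15,
    stay_p: float = 0.15,
    exclusions=DEFAULT_EXCLUSIONS,
) -> FittedAdjustment:
    """Classic forward-entry / backward-elimination variable selection.

    At each step the not-yet-entered candidate with the smallest partial
    p-value enters if below ``entry_p``; after every entry, included terms
    with p above ``stay_p`` are removed (largest first). Ties are broken by
    candidate list order, so the procedure is deterministic for fixed data
    and thresholds. Candidates on the mutual-exclusion list are barred while
    their partner is in the model (logged).
    """
    if len(df) <= len(candidates) + 5:
        raise ValueError("too few rows for the number of candidates")
    data = df[[response] + list(candidates)].dropna()
    selected: list[str] = []
    changed = True
    while changed:
        changed = False
        # forward step
        best_p, best_c = None, None
        for c in candidates:
            if c in selected or _excluded(c, selected, exclusions):
                continue
            fit = _ols_fit(data, response, ["const"] + selected + [c], check_rank=False)
            p = fit.terms.loc[c, "p"]
            if np.isfinite(p) and (best_p is None or p < best_p):
                best_p, best_c = p, c
        if best_c is not None and best_p < entry_p:
            selected.append(best_c)
            changed = True
        # backward step(s)
        while selected:
            fit = _ols_fit(data, response, ["const"] + selected, check_rank=False)
            pvals = fit.terms.loc[selected, "p"]
            worst = pvals.idxmax()
            if pvals[worst] > stay_p:
                selected.remove(worst)
                changed = True
            else:
                break
    return _ols_fit(data, response, ["const"] + selected, check_rank=False)


def best_subset_ols(
    df: pd.DataFrame,
    response: str,
    candidates: Sequence[str],
    criterion: str = "bic",
    max_size: Optional[int] = None,
) -> FittedAdjustment:
    """Exhaustive best-subset search (small candidate pools only).

    Serves as an independent selection oracle against which the stepwise
    procedure can be checked on small instances.
    """
    data = df[[response] + list(candidates)].dropna()
    max_size = max_size or len(candidates)
    best, best_score = None, np.inf
    y = data[response].to_numpy(dtype=float)
    n = len(y)
    for k in range(0, max_size + 1):
        for subset in itertools.combinations(candidates, k):
            X = _design_matrix(data, ["const"] + list(subset))
            res = sm.OLS(y, X).fit()
            score = res.bic if criterion == "bic" else res.aic
            if score < best_score - 1e-12:
                best_score, best = score, list(subset)
    return _ols_fit(data, response, ["const"] + best, check_rank=False)


# ---------------------------------------------------------------------------
# Leptin genotype statistics and variance accounting
# ---------------------------------------------------------------------------

def leptin_allele_stats(cc: int, ct: int, tt: int) -> dict:
    """Allele counts, C:T ratio and chi-square against 25:50:25 genotypes.

    ``chi2``/``p`` test the observed CC:CT:TT counts against the 25:50:25
    expectation (df = 2).
    """
    counts = np.array([cc, ct, tt], dtype=float)
    if np.any(counts < 0) or not float(counts.sum()) > 0:
        raise ValueError("genotype counts must be non-negative with positive total")
    total = counts.sum()
    c_alleles = 2 * cc + ct
    t_alleles = 2 * tt + ct
    chi2, p = stats.chisquare(counts, f_exp=total * np.array([0.25, 0.5, 0.25]))
    return {
        "n": int(total),
        "c_alleles": int(c_alleles),
        "t_alleles": int(t_alleles),
        "ct_ratio": c_alleles / t_alleles if t_alleles else np.inf,
        "chi2": float(chi2),
        "p": float(p),
    }


def variance_explained(
    df: pd.DataFrame, response: str, base: Sequence[str], added: Sequence[str]
) -> dict:
    """Incremental variance explained (percent) by nested OLS models."""
    data = df[[response] + list(base) + list(added)].dropna()
    if len(data) <= 10:
        raise ValueError("need more than 10 complete rows")
    r2_base = _ols_fit(data, response, ["const"] + list(base), check_rank=False).r2
    r2_full = _ols_fit(
        data, response, ["const"] + list(base) + list(added), check_rank=False
    ).r2
    return {
        "r2_base": r2_base,
        "r2_full": r2_full,
        "increment_pct": 100.0 * (r2_full - r2_base),
    }


def group_effects(
    df: pd.DataFrame,
    response: str,
    factors: Sequence[str] = ("sex", "leptin_class"),
) -> pd.DataFrame:
    """Fixed-effects model for classificatory factors with LS-means.

    Additive two-factor (default) linear model; returns one row per factor
    level with its least-squares mean (prediction averaged over an equally
    weighted grid of the other factors), SE of the level coefficient, and
    the model F-statistic p-value. Levels with <2 observations are dropped
    with a warning.
    """
    data = df[[response] + list(factors)].dropna().copy()
    for f in factors:
        counts = data[f].value_counts()
        thin = counts[counts < 2].index
        if len(thin):
            warnings.warn(f"dropping {f} levels with <2 obs: {list(thin)}", stacklevel=2)
            data = data[~data[f].isin(thin)]
    dummies = pd.get_dummies(
        data[list(factors)].astype(str), drop_first=True, dtype=float, prefix_sep="::"
    )
    X = sm.add_constant(dummies, has_constant="add")
    res = sm.OLS(data[response].to_numpy(dtype=float), X).fit()

    rows = []
    levels = {f: sorted(data[f].astype(str).unique()) for f in factors}
    for f in factors:
        others = [g for g in factors if g != f]
        for lev in levels[f]:
            # equally weighted grid over the other factors' levels
            grid = pd.DataFrame(
                [
                    {f: lev, **dict(zip(others, combo))}
                    for combo in itertools.product(*(levels[g] for g in others))
                ]
                or [{f: lev}]
            )
            # indicator columns built explicitly so single-level grids still
            # activate the right dummies
            gd = pd.DataFrame(0.0, index=grid.index, columns=dummies.columns)
            for colname in dummies.columns:
                fac, level = colname.split("::", 1)
                gd[colname] = (grid[fac].astype(str) == level).astype(float)
            gX = sm.add_constant(gd, has_constant="add")
            rows.append(
                {
                    "factor": f,
                    "level": lev,
                    "lsmean": float(np.mean(gX.to_numpy() @ res.params.to_numpy())),
                    "n": int((data[f].astype(str) == lev).sum()),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["model_f_pvalue"] = float(res.f_pvalue)
    out.attrs["model"] = res
    return out
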