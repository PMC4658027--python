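"""Model-adequacy statistics and repeated random-split cross-validation.

The mean square error of prediction (MSEP) is decomposed into three additive
components (population moments, divide-by-n, so the partition is exact):

* mean bias        ``(mean(P) - mean(O))^2``  — translation error;
* systematic bias  ``(sd(P) - r * sd(O))^2``  — slope/scaling error;
* random error     ``(1 - r^2) * sd(O)^2``    — incomplete covariation.

Precision is summarized by r^2 and concordance by Lin's coefficient
``CCC = r * Cb`` where the accuracy component
``Cb = 2 sd(O) sd(P) / (sd(O)^2 + sd(P)^2 + (mean(O) - mean(P))^2)``
measures how far the fitted line sits from the identity line.

Cross-validation repeatedly splits the cohort in two (default 750 training /
remainder testing), refits the model form on the training half, scores the
adequacy statistics on the held-out half, and reports the 2.5 % / 97.5 %
quantiles (numpy's default linear interpolation) over replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["AdequacyStats", "CrossValSummary", "adequacy", "cross_validate", "ModelSpec"]

_CV_STATS = (
    "ccc",
    "cb",
    "r2",
    "mean_bias_pct",
    "systematic_bias_pct",
    "random_pct",
    "rmsep",
    "mean_diff",
)


@dataclass
class AdequacyStats:
    """Adequacy of predictions P against observations O.

    ``mean_diff`` is the signed mean difference mean(P) - mean(O) in original
    units; ``mean_bias_sq`` is its square, the first MSEP component. The
    three ``*_sq`` components sum exactly to ``msep``; the ``*_pct`` fields
    express them as percentages of MSEP. ``degenerate`` is set when either
    vector has zero variance, in which case r, r2, ccc and cb are NaN.
    """

    n: int
    msep: float
    rmsep: float
    mean_diff: float
    mean_bias_sq: float
    systematic_bias_sq: float
    random_err_sq: float
    mean_bias_pct: float
    systematic_bias_pct: float
    random_pct: float
    r: float
    r2: float
    ccc: float
    cb: float
    degenerate: bool = False


@dataclass
class CrossValSummary:
    """Replicate quantiles of adequacy statistics under random 2-fold splits."""

    reps: int
    train_n: int
    quantiles: pd.DataFrame  # index: statistic; columns: q2.5, q97.5
    pooled_mean_diff: float
    pooled_rmsep: float
    skipped: int = 0
    replicates: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)


def adequacy(observed, predicted) -> AdequacyStats:
    """Full adequacy panel for one (observed, predicted) pair."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError("observed and predicted must be 1-d vectors of equal length")
    if len(o) < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(o)) and np.all(np.isfinite(p))):
        raise ValueError("inputs must be finite")

    n = len(o)
    msep = float(np.mean((p - o) ** 2))
    mean_diff = float(np.mean(p) - np.mean(o))
    var_o = float(np.var(o))  # population moments throughout
    var_p = float(np.var(p))
    sd_o, sd_p = np.sqrt(var_o), np.sqrt(var_p)
    cov = float(np.mean((o - o.mean()) * (p - p.mean())))

    degenerate = var_o == 0.0 or var_p == 0.0
    if degenerate:
        warnings.warn("zero variance: correlation-based statistics undefined", stacklevel=2)
        r = np.nan
    else:
        r = cov / (sd_o * sd_p)

    mean_bias_sq = mean_diff**2
    if degenerate:
        systematic_sq = (sd_p - sd_o) ** 2
        random_sq = msep - mean_bias_sq - systematic_sq
        ccc = cb = r2 = np.nan
    else:
        systematic_sq = (sd_p - r * sd_o) ** 2
        random_sq = (1.0 - r**2) * var_o
        r2 = r**2
        cb = 2.0 * sd_o * sd_p / (var_o + var_p + mean_diff**2)
        ccc = r * cb

    def pct(x):
        return 100.0 * x / msep if msep > 0 else np.nan

    return AdequacyStats(
        n=n,
        msep=msep,
        rmsep=float(np.sqrt(msep)),
        mean_diff=mean_diff,
        mean_bias_sq=mean_bias_sq,
        systematic_bias_sq=float(systematic_sq),
        random_err_sq=float(random_sq),
        mean_bias_pct=pct(mean_bias_sq),
        systematic_bias_pct=pct(systematic_sq),
        random_pct=pct(random_sq),
        r=float(r) if np.isfinite(r) else np.nan,
        r2=float(r2) if not degenerate else np.nan,
        ccc=float(ccc) if not degenerate else np.nan,
        cb=float(cb) if not degenerate else np.nan,
        degenerate=degenerate,
    )


@dataclass
class ModelSpec:
    """A fittable model form for cross-validation.

    ``fit(df)`` must return an object with ``predict(df) -> array``;
    ``response`` names the observed column scored against the predictions.
    """

    response: str
    fit: object  # callable df -> fitted


def cross_validate(
    df: pd.DataFrame,
    model_spec: ModelSpec,
    reps: int = 1000,
    train_n: int = 750,
    seed: Optional[int] = None,
) -> CrossValSummary:
    """Repeated random 2-fold cross-validation of a model form.

    Each replicate draws ``train_n`` rows without replacement for fitting;
    the remaining rows are scored with :func:`adequacy`. Fully reproducible
    from ``seed`` (per-replicate substreams are spawned deterministically).
    Replicates whose fit fails (e.g. singular design) are skipped and
    counted; a warning is raised if more than 1 % are skipped.
    """
    if len(df) < train_n + 3:
        raise ValueError("cohort too small for the requested training size")
    if reps < 2:
        raise ValueError("need at least 2 replicates")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(reps)
    rows = []
    skipped = 0
    for k in range(reps):
        rng = np.random.default_rng(children[k])
        idx = rng.permutation(len(df))
        train = df.iloc[idx[:train_n]]
        test = df.iloc[idx[train_n:]]
        try:
            fitted = model_spec.fit(train)
            pred = np.asarray(fitted.predict(test), dtype=float)
        except (np.linalg.LinAlgError, ValueError):
            skipped += 1
            continue
        obs = test[model_spec.response].to_numpy(dtype=float)
        ok = np.isfinite(obs) & np.isfinite(pred)
        st = adequacy(obs[ok], pred[ok])
        rows.append({s: getattr(st, s if s != "mean_diff" else "mean_diff") for s in _CV_STATS})
    if skipped > 0.01 * reps:
        warnings.warn(f"{skipped}/{reps} cross-validation replicates skipped", stacklevel=2)
    repframe = pd.DataFrame(rows)
    q = repframe.quantile([0.025, 0.975]).T  # numpy/pandas linear interpolation
    q.columns = ["q2.5", "q97.5"]
    return CrossValSummary(
        reps=reps,
        train_n=train_n,
        quantiles=q,
        pooled_mean_diff=float(repframe["mean_diff"].mean()),
        pooled_rmsep=float(repframe["rmsep"].mean()),
        skipped=skipped,
        replicates=repframe,
    )
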