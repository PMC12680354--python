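"""Agreement statistics between estimated and ground-truth abundances.

Lin's concordance correlation coefficient (CCC) measures closeness to the
identity line y = x (penalizing scale and location shifts, unlike Pearson);
NRMSE is RMSE scaled by the truth's standard deviation; MRD is the median
relative difference over expressed transcripts; PET is the percentage of
truly expressed transcripts that are detected.  Correlation-type metrics
are computed on log2(x+1)-transformed values by default (expression is
conventionally compared on a log scale; +1 guards zeros), MRD and PET on
the untransformed values; the transform used is recorded in the report.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MetricReport", "ccc", "nrmse", "mrd", "pet", "evaluate"]


@dataclass(frozen=True)
class MetricReport:
    ccc: float
    pearson: float
    spearman: float
    nrmse: float
    mrd: float
    pet: float
    n_transcripts: int
    transform: str
    unit: str

    def to_dict(self) -> dict:
        return asdict(self)


def _paired(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"inputs must be 1-D of equal length, got {x.shape}, {y.shape}")
    return x, y


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population moments).

    2 cov(x,y) / (var(x) + var(y) + (mean(x) - mean(y))^2); identical
    constant vectors return 1 by convention.
    """
    x, y = _paired(x, y)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0.0:
        return 1.0
    return 2.0 * cov / denom


def nrmse(truth, est) -> float:
    """RMSE(truth, est) / population stdev(truth)."""
    truth, est = _paired(truth, est)
    sd = truth.std()
    if sd == 0.0:
        raise ValueError("truth vector is constant; NRMSE undefined")
    return float(np.sqrt(np.mean((est - truth) ** 2)) / sd)


def mrd(truth, est, expressed_only: bool = True, eps: float = 1e-9) -> float:
    """Median of |est - truth| / truth.

    With expressed_only (default), only transcripts with truth > 0 enter;
    otherwise zero-truth denominators are guarded with eps.
    """
    truth, est = _paired(truth, est)
    if expressed_only:
        mask = truth > 0
        if not mask.any():
            raise ValueError("no expressed transcripts")
        truth, est = truth[mask], est[mask]
    rel = np.abs(est - truth) / np.maximum(truth, eps)
    return float(np.median(rel))


def pet(truth, est, detect_threshold: float = 0.0) -> float:
    """Percent of truly expressed transcripts with est > detect_threshold."""
    truth, est = _paired(truth, est)
    expressed = truth > 0
    if not expressed.any():
        raise ValueError("no expressed transcripts")
    return float(100.0 * np.mean(est[expressed] > detect_threshold))


_TRANSFORMS = {
    "log2p1": lambda v: np.log2(v + 1.0),
    "identity": lambda v: v,
}

_UNIT_COLUMNS = {
    "tpm": (("true_tpm", "tpm"), ("tpm", "est_tpm")),
    "counts": (("true_counts", "counts"), ("est_counts", "counts")),
}


def _pick_column(frame: pd.DataFrame, candidates, role: str) -> str:
    for c in candidates:
        if c in frame.columns:
            return c
    raise ValueError(f"no {role} column among {candidates} in {list(frame.columns)}")


def evaluate(
    truth_table: pd.DataFrame,
    abundance_table: pd.DataFrame,
    transform: str = "log2p1",
    unit: str = "tpm",
) -> MetricReport:
    """Join two abundance tables on target_id and compute all metrics.

    The join is outer with zeros for missing ids; disjoint id sets are an
    error.  ccc/pearson/spearman/nrmse see transformed values; mrd and pet
    see raw values.
    """
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    if unit not in _UNIT_COLUMNS:
        raise ValueError(f"unknown unit {unit!r}")
    truth_candidates, est_candidates = _UNIT_COLUMNS[unit]
    tcol = _pick_column(truth_table, truth_candidates, "truth")
    ecol = _pick_column(abundance_table, est_candidates, "estimate")
    t = truth_table[["target_id", tcol]].rename(columns={tcol: "_truth"})
    e = abundance_table[["target_id", ecol]].rename(columns={ecol: "_est"})
    if not set(t["target_id"]) & set(e["target_id"]):
        raise ValueError("truth and estimate share no transcript ids")
    merged = t.merge(e, on="target_id", how="outer").fillna(0.0)
    merged = merged.sort_values("target_id", kind="stable").reset_index(drop=True)
    truth = merged["_truth"].to_numpy(float)
    est = merged["_est"].to_numpy(float)
    f = _TRANSFORMS[transform]
    tx, ex = f(truth), f(est)
    return MetricReport(
        ccc=ccc(tx, ex),
        pearson=float(stats.pearsonr(tx, ex).statistic),
        spearman=float(stats.spearmanr(tx, ex).statistic),
        nrmse=nrmse(tx, ex),
        mrd=mrd(truth, est),
        pet=pet(truth, est),
        n_transcripts=len(merged),
        transform=transform,
        unit=unit,
    )
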