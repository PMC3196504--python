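"""Evaluation of species-distribution-model output surfaces.

Operates on habitat-suitability probability surfaces (ESRI ASCII grids) and
presence/background cell lists: rank-based AUC, data-driven threshold
selection (equal sensitivity/specificity, or maximum of their sum), Cohen's
kappa, range-size cell counting at a threshold, hindcast validation against
fossil cells, and masking of non-analogous past climates (cells where any
variable falls outside the range observed anywhere in the current climate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .synthio import AsciiGrid

__all__ = [
    "ThresholdReport",
    "roc_auc",
    "find_threshold",
    "cohens_kappa",
    "count_range_cells",
    "nonanalog_mask",
    "fossil_validation",
]


@dataclass(frozen=True)
class ThresholdReport:
    criterion: str
    threshold: float
    sensitivity: float
    specificity: float
    kappa: float | None
    n_predicted_presence_cells: int


def roc_auc(presence_scores, background_scores) -> float:
    """Rank-based (Mann–Whitney) AUC with ties counted as one half.

    The probability that a random presence cell scores above a random
    background cell; 0.5 = no better than chance.
    """
    pres = np.asarray(presence_scores, float)
    back = np.asarray(background_scores, float)
    if pres.size == 0 or back.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = sstats.rankdata(np.concatenate([pres, back]))
    r_pres = ranks[: pres.size].sum()
    u = r_pres - pres.size * (pres.size + 1) / 2.0
    return float(u / (pres.size * back.size))


def _confusion(scores: np.ndarray, labels: np.ndarray, thr: float):
    pred = scores > thr
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())
    return tp, fp, fn, tn


def find_threshold(scores, labels, criterion: str) -> ThresholdReport:
    """Pick a presence/absence threshold from labelled scores.

    Candidate thresholds are midpoints between adjacent sorted unique scores
    plus values just below and above the data range.  ``equal_sens_spec``
    minimizes |sensitivity − specificity|; ``max_sens_plus_spec`` maximizes
    their sum.  Ties prefer the lower threshold.  Presence is predicted by
    strict exceedance (score > threshold).
    """
    if criterion not in ("equal_sens_spec", "max_sens_plus_spec"):
        raise ValueError(f"unknown criterion: {criterion!r}")
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    if len(set(labels.tolist())) < 2:
        raise ValueError("labels must contain both classes")
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    span = max(uniq[-1] - uniq[0], 1.0)
    cands = np.concatenate([[uniq[0] - 1e-9 * span], mids,
                            [uniq[-1] + 1e-9 * span]])
    best_thr = None
    best_key = None
    for thr in cands:  # ascending, so ties keep the lower threshold
        tp, fp, fn, tn = _confusion(scores, labels, thr)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        key = (
            abs(sens - spec) if criterion == "equal_sens_spec"
            else -(sens + spec)
        )
        if best_key is None or key < best_key:
            best_key = key
            best_thr = thr
    tp, fp, fn, tn = _confusion(scores, labels, best_thr)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    try:
        kap = cohens_kappa(tp, fp, fn, tn)
    except ValueError:
        kap = None
    return ThresholdReport(
        criterion=criterion,
        threshold=float(best_thr),
        sensitivity=sens,
        specificity=spec,
        kappa=kap,
        n_predicted_presence_cells=int((scores > best_thr).sum()),
    )


def cohens_kappa(tp: int, fp: int, fn: int, tn: int) -> float:
    """Chance-corrected agreement between predicted and observed presence.

    kappa = (p_o − p_e) / (1 − p_e) with p_e from the marginal products.
    """
    for v in (tp, fp, fn, tn):
        if v < 0:
            raise ValueError("counts must be non-negative")
    total = tp + fp + fn + tn
    if total == 0:
        raise ValueError("empty confusion table")
    p_o = (tp + tn) / total
    p_yes = ((tp + fp) / total) * ((tp + fn) / total)
    p_no = ((fn + tn) / total) * ((fp + tn) / total)
    p_e = p_yes + p_no
    if abs(1.0 - p_e) < 1e-15:
        raise ValueError("degenerate marginals: kappa undefined")
    return (p_o - p_e) / (1.0 - p_e)


def count_range_cells(surface: AsciiGrid, threshold: float) -> int:
    """Number of non-NODATA cells with suitability strictly above threshold."""
    vals = surface.values
    return int((vals[~np.isnan(vals)] > threshold).sum())


def nonanalog_mask(
    current_stack: list[AsciiGrid], past_stack: list[AsciiGrid]
) -> np.ndarray:
    """Flag past cells whose climate has no current analogue.

    For each variable the global min/max over all non-NODATA current cells is
    computed; a past cell is flagged when at least one variable lies outside
    that closed interval.  NODATA past cells are never flagged.
    """
    if len(current_stack) != len(past_stack) or not current_stack:
        raise ValueError("stacks must be non-empty and of equal length")
    shape = current_stack[0].values.shape
    for g in list(current_stack) + list(past_stack):
        if not g.same_geometry(current_stack[0]):
            raise ValueError("grid geometry mismatch within/between stacks")
    mask = np.zeros(shape, dtype=bool)
    for cur, pst in zip(current_stack, past_stack):
        cvals = cur.values[~np.isnan(cur.values)]
        if cvals.size == 0:
            raise ValueError("a current variable has no data cells")
        lo, hi = cvals.min(), cvals.max()
        p = pst.values
        with np.errstate(invalid="ignore"):
            mask |= np.where(np.isnan(p), False, (p < lo) | (p > hi))
    return mask


def _cells_to_scores(surface: AsciiGrid, cells) -> np.ndarray:
    vals = surface.values
    out = []
    for r, c in cells:
        v = vals[int(r), int(c)]
        if np.isnan(v):
            raise ValueError(f"cell ({r}, {c}) is NODATA")
        out.append(float(v))
    return np.asarray(out)


def fossil_validation(
    surface: AsciiGrid,
    fossil_cells,
    background_cells,
    threshold: float,
) -> tuple[float, float | None, int]:
    """Hindcast check against fossil occurrence cells.

    ``fossil_cells`` and ``background_cells`` are equal-length lists of
    (row, col); returns (AUC, kappa at the supplied threshold, number of
    fossil cells predicted present by strict exceedance).
    """
    if not fossil_cells or not background_cells:
        raise ValueError("cell sets must be non-empty")
    if len(fossil_cells) != len(background_cells):
        raise ValueError("background must match fossil cells in number")
    f_scores = _cells_to_scores(surface, fossil_cells)
    b_scores = _cells_to_scores(surface, background_cells)
    auc = roc_auc(f_scores, b_scores)
    tp = int((f_scores > threshold).sum())
    fn = len(f_scores) - tp
    fp = int((b_scores > threshold).sum())
    tn = len(b_scores) - fp
    try:
        kap = cohens_kappa(tp, fp, fn, tn)
    except ValueError:
        kap = None
    return auc, kap, tp
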