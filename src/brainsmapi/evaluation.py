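"""Multilevel quantitative assessment of registration quality.

Brain-region level: per-region 2D Dice scores over a fixed number of evenly
spaced slices.  Identifiable-nuclei level: multiple human raters' binary
segmentations are fused by STAPLE (EM estimation of a consensus together
with each rater's sensitivity/specificity); rater-vs-consensus Dice is the
human performance (HP) and atlas-vs-consensus Dice the registration
performance (RP), compared by a Mann-Whitney U-test.  Landmark distances
complete the toolbox.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from itertools import combinations
from math import comb, erfc, sqrt

import numpy as np

from .types import LabelVolume, ValidationError

__all__ = [
    "DiceReport",
    "StapleResult",
    "RaterStudy",
    "dice",
    "region_dice_report",
    "staple",
    "hp_rp",
    "mann_whitney_u",
    "landmark_distances",
]


def dice(I: np.ndarray, J: np.ndarray) -> float:
    """Dice score ``2|I n J| / (|I| + |J|)`` of two same-shape binary masks.

    Two empty masks are defined to score 1.0 (identical masks must score 1);
    a warning flags the degenerate case.
    """
    I = np.asarray(I, dtype=bool)
    J = np.asarray(J, dtype=bool)
    if I.shape != J.shape:
        raise ValidationError(f"mask shapes differ: {I.shape} vs {J.shape}")
    si, sj = int(I.sum()), int(J.sum())
    if si == 0 and sj == 0:
        warnings.warn("dice of two empty masks defined as 1.0", RuntimeWarning)
        return 1.0
    return 2.0 * int((I & J).sum()) / (si + sj)


@dataclass
class DiceReport:
    region: str
    slice_indices: list
    scores: list

    @property
    def median(self) -> float:
        return float(np.median(self.scores))

    @property
    def quartiles(self) -> tuple[float, float]:
        return tuple(np.percentile(self.scores, [25, 75]))


def _slice_indices(lo: int, hi: int, n: int) -> list[int]:
    """n evenly spaced slice indices within [lo, hi]; all slices if span < n."""
    span = hi - lo + 1
    if span <= n:
        return list(range(lo, hi + 1))
    return [int(round(v)) for v in np.linspace(lo, hi, n)]


def region_dice_report(registered: LabelVolume, reference: LabelVolume,
                       regions, n_slices: int = 50, axis: int = 2) -> list[DiceReport]:
    """Per-region 2D Dice on evenly spaced slices through the region's span.

    The span is taken along ``axis`` in the REFERENCE volume; regions absent
    from either volume are skipped with a warning.  If a region spans fewer
    than ``n_slices`` slices, every slice is used and the count reported.
    """
    if registered.shape != reference.shape:
        raise ValidationError("volumes must be aligned in the same space")
    name_to_id = {v: k for k, v in reference.names.items()}
    reports = []
    for r in regions:
        rid = name_to_id.get(r, r) if isinstance(r, str) else int(r)
        ref_mask = reference.labels == rid
        reg_mask = registered.labels == rid
        if not ref_mask.any() or not reg_mask.any():
            warnings.warn(f"region {r!r} absent from one volume; skipped", RuntimeWarning)
            continue
        proj = ref_mask.any(axis=tuple(a for a in range(3) if a != axis))
        present = np.flatnonzero(proj)
        idxs = _slice_indices(int(present[0]), int(present[-1]), n_slices)
        scores = []
        for k in idxs:
            sl = [slice(None)] * 3
            sl[axis] = k
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                scores.append(dice(reg_mask[tuple(sl)], ref_mask[tuple(sl)]))
        name = reference.names.get(rid, str(rid))
        reports.append(DiceReport(name, idxs, scores))
    return reports


# ---------------------------------------------------------------------------
# STAPLE

@dataclass
class StapleResult:
    consensus_prob: np.ndarray
    consensus_mask: np.ndarray
    sensitivity: np.ndarray   # p_j per rater
    specificity: np.ndarray   # q_j per rater
    iterations: int
    converged: bool


def staple(masks, tol: float = 1e-6, max_iter: int = 200, prior=None) -> StapleResult:
    """Simultaneous Truth and Performance Level Estimation (EM fusion).

    Estimates a per-pixel consensus probability together with each rater's
    sensitivity ``p_j`` and specificity ``q_j``.  Initialization is
    ``p_j = q_j = 0.99`` with a spatially uniform prior equal to the mean
    rater foreground fraction (an array prior may be supplied); both are
    fixed, so the result is deterministic.  The consensus mask thresholds
    the probability at 0.5 with ties counted as foreground.
    """
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if len(masks) < 2:
        raise ValidationError("STAPLE needs at least 2 rater masks")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValidationError("rater masks must share one shape")
    D = np.stack([m.ravel() for m in masks]).astype(np.float64)  # (J, N)
    J, N = D.shape
    if D.sum() == 0:
        raise ValidationError("all rater masks are empty")
    if prior is None:
        f = float(D.mean())
    else:
        prior = np.asarray(prior, dtype=np.float64)
        f = prior.ravel() if prior.size == N else float(prior)
    f = np.clip(f, 1e-8, 1 - 1e-8)
    p = np.full(J, 0.99)
    q = np.full(J, 0.99)
    W = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: posterior probability that the true label is foreground
        log_a = np.log(f) + (np.log(p)[:, None] * D + np.log1p(-p)[:, None] * (1 - D)).sum(axis=0)
        log_b = np.log1p(-f) + (np.log(q)[:, None] * (1 - D) + np.log1p(-q)[:, None] * D).sum(axis=0)
        m = np.maximum(log_a, log_b)
        a = np.exp(log_a - m)
        b = np.exp(log_b - m)
        W = a / (a + b)
        # M-step
        sw = W.sum()
        swc = (1.0 - W).sum()
        p_new = (D * W).sum(axis=1) / max(sw, 1e-12)
        q_new = ((1 - D) * (1 - W)).sum(axis=1) / max(swc, 1e-12)
        p_new = np.clip(p_new, 1e-8, 1 - 1e-8)
        q_new = np.clip(q_new, 1e-8, 1 - 1e-8)
        change = max(np.abs(p_new - p).max(), np.abs(q_new - q).max())
        p, q = p_new, q_new
        if change < tol:
            converged = True
            break
    prob = W.reshape(shape)
    return StapleResult(prob, prob >= 0.5, p, q, it, converged)


@dataclass
class RaterStudy:
    """Rater masks plus the registered-atlas mask for one evaluated nucleus."""

    rater_masks: list
    atlas_mask: np.ndarray
    staple_result: StapleResult | None = None

    def __post_init__(self):
        if len(self.rater_masks) < 2:
            raise ValidationError("need >= 2 raters")
        shape = np.asarray(self.atlas_mask).shape
        if any(np.asarray(m).shape != shape for m in self.rater_masks):
            raise ValidationError("rater and atlas masks must share one shape")


def hp_rp(study: RaterStudy) -> tuple[list[float], float]:
    """Human performance (per-rater Dice vs consensus) and registration performance.

    Runs STAPLE if the study does not carry a result yet.
    """
    if study.staple_result is None:
        study.staple_result = staple(study.rater_masks)
    consensus = study.staple_result.consensus_mask
    hp = [dice(m, consensus) for m in study.rater_masks]
    rp = dice(study.atlas_mask, consensus)
    return hp, rp


# ---------------------------------------------------------------------------
# Mann-Whitney

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: #(a > b) pairs + half ties."""
    a = np.asarray(a, dtype=float)[:, None]
    b = np.asarray(b, dtype=float)[None, :]
    return float((a > b).sum() + 0.5 * (a == b).sum())


def mann_whitney_u(a, b, alternative: str = "two-sided",
                   exact_limit: int = 12) -> tuple[float, float]:
    """Mann-Whitney U test of two independent samples.

    For ``n_a + n_b <= exact_limit`` the p-value is computed by exhaustive,
    tie-aware enumeration of all group assignments of the pooled sample; the
    two-sided p is twice the smaller tail (capped at 1).  Larger samples use
    the normal approximation with tie correction and a 0.5 continuity
    correction.  Returns ``(U, p)``.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    na, nb = len(a), len(b)
    U = _u_statistic(a, b)

    if na + nb <= exact_limit:
        pooled = np.concatenate([a, b])
        n = na + nb
        total = comb(n, na)
        le = ge = 0
        eps = 1e-12
        for ia in combinations(range(n), na):
            sel = np.zeros(n, dtype=bool)
            sel[list(ia)] = True
            u = _u_statistic(pooled[sel], pooled[~sel])
            if u <= U + eps:
                le += 1
            if u >= U - eps:
                ge += 1
        p_less, p_greater = le / total, ge / total
        if alternative == "greater":
            return U, p_greater
        if alternative == "less":
            return U, p_less
        return U, min(1.0, 2.0 * min(p_less, p_greater))

    # normal approximation with tie correction
    mu = na * nb / 2.0
    nt = na + nb
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (nt * (nt - 1.0))
    sigma2 = na * nb / 12.0 * ((nt + 1.0) - tie_term)
    sigma = sqrt(max(sigma2, 1e-300))

    def sf(u_shifted):
        return 0.5 * erfc(u_shifted / (sigma * sqrt(2.0)))

    p_greater = sf(U - mu - 0.5)
    p_less = sf(mu - U - 0.5)
    if alternative == "greater":
        return U, min(1.0, p_greater)
    if alternative == "less":
        return U, min(1.0, p_less)
    return U, min(1.0, 2.0 * min(p_less, p_greater))


def landmark_distances(pairs) -> tuple[np.ndarray, float]:
    """Euclidean distance per (fixed, moved) landmark pair, plus the median.

    ``pairs`` is a sequence of ``(fixed_point, moved_point)`` in um.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValidationError("no landmark pairs supplied")
    fixed = np.asarray([p[0] for p in pairs], dtype=float)
    moved = np.asarray([p[1] for p in pairs], dtype=float)
    if fixed.shape != moved.shape:
        raise ValidationError("fixed/moved landmark lists differ in shape")
    d = np.linalg.norm(fixed - moved, axis=1)
    return d, float(np.median(d))
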