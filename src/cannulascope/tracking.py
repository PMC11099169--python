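"""Cross-session field-of-view registration and longitudinal cell matching.

Sessions recorded weeks or months apart share a cell constellation but
differ by a translation (and possibly a zoom).  The alignment offset is
the peak of a high-pass-adjusted cross-correlogram: the plain 2D
cross-correlation of the two average fields of view minus the
cross-correlation of Gaussian-blurred (sigma 4 px) copies, which removes
the low-spatial-frequency component (slow illumination structure) so the
peak is driven by the high-frequency anatomy.  Cells are then matched by
mutual overlap: a pair is retained only if the overlap area exceeds 50%
of the area of each individual ROI.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.transform import rescale

__all__ = [
    "AlignmentResult",
    "rescale_to_common_zoom",
    "highpass_xcorr_align",
    "match_rois",
    "resolve_one_to_one",
    "match_metrics",
]


@dataclass
class AlignmentResult:
    """Offset of session B's content relative to session A, in px."""

    offset_px: tuple[float, float]      # (dy, dx)
    peak_score: float
    sigma_px: float = 4.0
    resize_factor: float = 1.0


def rescale_to_common_zoom(
    img_a: np.ndarray,
    img_b: np.ndarray,
    um_per_px_a: float,
    um_per_px_b: float,
    order: int = 1,
):
    """Upsample the coarser image so both share the finer um/px scale.

    Returns ``(img_a, img_b, resize_factor)`` where the factor is the
    upsampling applied (1.0 if the zooms already match).  ``order=0``
    (nearest) is appropriate for label/mask images.
    """
    if not (np.isfinite(um_per_px_a) and np.isfinite(um_per_px_b)):
        raise ValueError("non-finite zoom")
    if um_per_px_a <= 0 or um_per_px_b <= 0:
        raise ValueError("zoom must be positive")
    if um_per_px_a == um_per_px_b:
        return img_a, img_b, 1.0
    if um_per_px_a > um_per_px_b:  # a is coarser
        factor = um_per_px_a / um_per_px_b
        return rescale(img_a, factor, order=order, preserve_range=True), img_b, factor
    factor = um_per_px_b / um_per_px_a
    return img_a, rescale(img_b, factor, order=order, preserve_range=True), factor


def _xcorr2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Full zero-padded 2D cross-correlation of mean-subtracted images."""
    a = a - a.mean()
    b = b - b.mean()
    return fftconvolve(a, b[::-1, ::-1], mode="full")


def highpass_xcorr_align(
    img_a: np.ndarray, img_b: np.ndarray, sigma_px: float = 4.0
) -> AlignmentResult:
    """Offset of ``img_b`` relative to ``img_a`` from the adjusted correlogram.

    adjusted = xcorr(a, b) - xcorr(blur(a), blur(b)); the argmax is the
    alignment offset (ties break toward the smallest offset magnitude).
    With sigma = 0 the blur is the identity and the adjustment vanishes.
    """
    img_a = np.asarray(img_a, dtype=float)
    img_b = np.asarray(img_b, dtype=float)
    if img_a.shape != img_b.shape:
        raise ValueError("images must share a shape (rescale to a common zoom first)")
    if img_a.std() == 0 or img_b.std() == 0:
        raise ValueError("constant image has no correlation structure")
    cc = _xcorr2(img_a, img_b)
    if sigma_px > 0:
        cc = cc - _xcorr2(
            ndimage.gaussian_filter(img_a, sigma_px, mode="reflect"),
            ndimage.gaussian_filter(img_b, sigma_px, mode="reflect"),
        )
    h, w = img_a.shape
    peak = cc.max()
    ys, xs = np.where(cc == peak)
    # lag (h-1, w-1) is zero offset; positive lag means b's content sits
    # at larger indices in a, i.e. b = translate(a) by -offset
    offs = np.column_stack([ys - (h - 1), xs - (w - 1)])
    best = offs[np.argmin((offs**2).sum(axis=1))]
    return AlignmentResult(
        offset_px=(-float(best[0]), -float(best[1])),
        peak_score=float(peak),
        sigma_px=sigma_px,
    )


def _binarize(masks: np.ndarray) -> np.ndarray:
    m = np.asarray(masks)
    return m > 0 if m.dtype != bool else m


def _shift_masks(masks: np.ndarray, offset: tuple[int, int]) -> np.ndarray:
    """Integer-translate boolean masks (no resampling), zeros fill."""
    dy, dx = int(round(offset[0])), int(round(offset[1]))
    out = np.zeros_like(masks)
    h, w = masks.shape[1:]
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[:, ys, xs] = masks[:, ys_src, xs_src]
    return out


def match_rois(
    masks_a: np.ndarray,
    masks_b: np.ndarray,
    offset_px: tuple[float, float] = (0.0, 0.0),
    min_overlap_frac: float = 0.5,
) -> pd.DataFrame:
    """Candidate cell pairs across two sessions by mutual areal overlap.

    ``offset_px`` is the offset of B's content relative to A (as returned
    by :func:`highpass_xcorr_align` on (A, B)); masks_b are translated by
    ``-offset`` into A's frame.  All overlapping pairs are returned; the
    ``kept`` column marks pairs whose overlap exceeds ``min_overlap_frac``
    of the area of *each* ROI (strict).
    """
    a = _binarize(masks_a)
    b = _binarize(masks_b)
    cols = ["cell_id_A", "cell_id_B", "overlap_px", "frac_A", "frac_B", "kept"]
    if a.shape[0] == 0 or b.shape[0] == 0:
        return pd.DataFrame(columns=cols)
    b = _shift_masks(b, (-offset_px[0], -offset_px[1]))
    fa = a.reshape(a.shape[0], -1).astype(np.float32)
    fb = b.reshape(b.shape[0], -1).astype(np.float32)
    overlap = fa @ fb.T
    area_a = fa.sum(axis=1)
    area_b = fb.sum(axis=1)
    ia, ib = np.nonzero(overlap)
    frac_a = overlap[ia, ib] / area_a[ia]
    frac_b = overlap[ia, ib] / np.where(area_b[ib] > 0, area_b[ib], np.inf)
    df = pd.DataFrame(
        {
            "cell_id_A": ia,
            "cell_id_B": ib,
            "overlap_px": overlap[ia, ib].astype(int),
            "frac_A": frac_a,
            "frac_B": frac_b,
        }
    )
    df["kept"] = (df["frac_A"] > min_overlap_frac) & (df["frac_B"] > min_overlap_frac)
    return df


def resolve_one_to_one(match_table: pd.DataFrame) -> pd.DataFrame:
    """Greedy conflict resolution: take kept pairs in descending order of
    min(frac_A, frac_B); each cell appears at most once."""
    kept = match_table[match_table["kept"]].copy() if "kept" in match_table else match_table.copy()
    if kept.empty:
        return kept
    kept["min_frac"] = np.minimum(kept["frac_A"], kept["frac_B"])
    kept = kept.sort_values("min_frac", ascending=False, kind="stable")
    used_a: set = set()
    used_b: set = set()
    rows = []
    for _, row in kept.iterrows():
        if row["cell_id_A"] in used_a or row["cell_id_B"] in used_b:
            continue
        used_a.add(row["cell_id_A"])
        used_b.add(row["cell_id_B"])
        rows.append(row)
    return pd.DataFrame(rows).drop(columns="min_frac").reset_index(drop=True)


def best_assignment_by_total_min_frac(match_table: pd.DataFrame) -> set:
    """Exhaustive one-to-one assignment maximizing the summed min-frac.

    Exponential; intended as an oracle for small conflict graphs.
    """
    kept = match_table[match_table["kept"]] if "kept" in match_table else match_table
    pairs = list(
        zip(kept["cell_id_A"], kept["cell_id_B"], np.minimum(kept["frac_A"], kept["frac_B"]))
    )
    best_score = -1.0
    best_set: set = set()
    n = len(pairs)
    for order in permutations(range(n)):
        used_a: set = set()
        used_b: set = set()
        score = 0.0
        chosen = set()
        for i in order:
            a, b, s = pairs[i]
            if a in used_a or b in used_b:
                continue
            used_a.add(a)
            used_b.add(b)
            score += s
            chosen.add((a, b))
        if score > best_score:
            best_score = score
            best_set = chosen
    return best_set


def match_metrics(pred_pairs, true_pairs) -> tuple[float, float]:
    """Precision and recall of predicted pairings against ground truth."""
    pred = set(map(tuple, pred_pairs))
    true = set(map(tuple, true_pairs))
    tp = len(pred & true)
    precision = tp / len(pred) if pred else float("nan")
    recall = tp / len(true) if true else float("nan")
    return precision, recall
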