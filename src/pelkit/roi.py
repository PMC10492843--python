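"""ROI quantification and statistical comparisons.

Lesion regions of interest are labelled rasters (0 = background, k > 0 =
lesion k).  Visibility is quantified by the mean ROI intensity and the
Weber contrast C_W = (I_f - I_b) / I_b against the mean of the entire
non-ROI, non-excluded background.  Group comparisons follow the standard
workflow for this kind of lesion study: one-way ANOVA with Tukey HSD
post-hoc tests across imaging modalities, two-sample t-tests for
benign-vs-malignant contrasts, and Fisher's exact test for 2x2 detection
counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContrastRecord",
    "roi_means",
    "weber_contrast",
    "contrast_table",
    "anova_tukey",
    "ttest_two_sample",
    "fisher_exact_2x2",
]


@dataclass
class ContrastRecord:
    """Mean intensities and Weber contrast for one ROI under one modality."""

    roi_id: int
    modality: str  # WLL | PEL | mPEL
    I_f: float
    I_b: float
    C_W: float


def roi_means(
    image: np.ndarray,
    rois: np.ndarray,
    excluded_mask: np.ndarray | None = None,
) -> tuple[dict[int, float], float]:
    """Per-ROI mean intensity and the shared background mean.

    The background is every pixel outside *all* ROIs that is neither
    excluded nor non-finite.  Raises on an empty ROI or empty background.
    """
    image = np.asarray(image, dtype=float)
    rois = np.asarray(rois)
    if image.shape != rois.shape:
        raise ValueError("image and ROI label raster shapes differ")
    valid = np.isfinite(image)
    if excluded_mask is not None:
        valid &= ~np.asarray(excluded_mask, dtype=bool)
    bg = valid & (rois == 0)
    if not bg.any():
        raise ValueError("background is empty")
    i_b = float(image[bg].mean())
    means: dict[int, float] = {}
    for label in np.unique(rois):
        if label == 0:
            continue
        sel = valid & (rois == label)
        if not sel.any():
            raise ValueError(f"ROI {label} has no valid pixels")
        means[int(label)] = float(image[sel].mean())
    return means, i_b


def weber_contrast(i_f: float, i_b: float) -> float:
    """C_W = (I_f - I_b) / I_b; undefined for non-positive background."""
    if i_b <= 0:
        raise ValueError(f"Weber contrast undefined for background mean {i_b}")
    return (i_f - i_b) / i_b


def contrast_table(
    images: dict[str, np.ndarray],
    rois: np.ndarray,
    excluded_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """ContrastRecords for every ROI under every modality, as a DataFrame."""
    rows = []
    for modality, image in images.items():
        means, i_b = roi_means(image, rois, excluded_mask)
        for roi_id, i_f in means.items():
            rows.append(
                dict(roi_id=roi_id, modality=modality, I_f=i_f, I_b=i_b,
                     C_W=weber_contrast(i_f, i_b))
            )
    return pd.DataFrame(rows)


def anova_tukey(groups: list, labels: list[str] | None = None):
    """One-way ANOVA F/p plus Tukey HSD pairwise adjusted p-values.

    Degenerate case: if every observation in every group is the same
    constant there is no variance to test against; by convention the
    omnibus p is 1.0 and all pairwise p are 1.0.
    Returns (F, p, pairwise) with pairwise a dict {(i, j): p_adj}.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        pairs = {(i, j): 1.0 for i in range(len(groups)) for j in range(i + 1, len(groups))}
        return 0.0, 1.0, pairs
    f, p = stats.f_oneway(*groups)
    hsd = stats.tukey_hsd(*groups)
    pairwise = {
        (i, j): float(hsd.pvalue[i, j])
        for i in range(len(groups))
        for j in range(i + 1, len(groups))
    }
    return float(f), float(p), pairwise


def ttest_two_sample(a, b, welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test (pooled variance by default).

    Degenerate case: zero variance in both samples with equal means
    returns (0, 1) by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per sample")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Two-sidedness by the point-probability method: the sum of the
    probabilities of all tables (at fixed margins) no more probable than
    the observed one.
    """
    tab = np.asarray(table)
    if tab.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(tab < 0) or not np.issubdtype(tab.dtype, np.integer):
        if np.any(tab != np.floor(tab)) or np.any(tab < 0):
            raise ValueError("counts must be non-negative integers")
        tab = tab.astype(np.int64)
    return float(stats.fisher_exact(tab, alternative="two-sided")[1])
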