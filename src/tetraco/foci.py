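"""Immunofluorescence focus counting on meiotic chromosome spreads.

The pipeline mirrors standard practice for RAD51/DMC1 focus quantification:
the chromosome-axis channel (DAPI or ASY1) is binarised with the triangle
thresholding method and closed morphologically to yield a chromosome ROI;
the focus channel is enhanced with a white top-hat transform (image minus
its morphological opening), which flattens background and retains bright
spots smaller than the structuring element; significant local maxima inside
the ROI are counted as foci.

Group comparisons of per-cell focus counts use Fisher's protected LSD:
pairwise t-statistics on the pooled one-way-ANOVA error variance, with
unadjusted p-values (LSD applies no multiplicity correction).

Coordinates are (row, col), origin top-left, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage.feature import peak_local_max
from skimage.filters import threshold_triangle
from skimage.measure import label as label_components
from skimage.morphology import closing, disk, white_tophat

#: Default structuring-element radius for closing the binarised axis, px.
DEFAULT_CLOSING_RADIUS = 2
#: Default white-top-hat structuring-element radius, px.
DEFAULT_TOPHAT_RADIUS = 3
#: Default minimum separation between counted peaks, px.
DEFAULT_MIN_SEPARATION = 3
#: Default minimum connected-component area kept in the ROI, px.
DEFAULT_MIN_AREA = 50
#: Peak threshold, when not given, is background mean + this many SDs.
DEFAULT_THRESHOLD_SDS = 5.0


@dataclass(frozen=True)
class FociImage:
    """Two-channel meiocyte image: chromosome axis + focus channel."""

    axis_channel: np.ndarray
    foci_channel: np.ndarray
    cell_id: str = ""
    stage: str = ""  # leptotene / zygotene / pachytene, supplied as metadata

    def __post_init__(self):
        a = np.asarray(self.axis_channel)
        f = np.asarray(self.foci_channel)
        if a.ndim != 2 or f.ndim != 2:
            raise ValueError("channels must be 2-D intensity grids")
        if a.shape != f.shape:
            raise ValueError(f"channel shapes differ: {a.shape} vs {f.shape}")
        if (a < 0).any() or (f < 0).any():
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "axis_channel", a)
        object.__setattr__(self, "foci_channel", f)


@dataclass(frozen=True)
class ROIMask:
    """Binary chromosome region-of-interest mask."""

    mask: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        object.__setattr__(self, "mask", m)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class FociResult:
    """Focus count of one cell, with peak coordinates inside the ROI."""

    count: int
    peak_coordinates: tuple
    cell_id: str = ""
    stage: str = ""


def segment_chromosomes(
    axis: np.ndarray,
    closing_radius: int = DEFAULT_CLOSING_RADIUS,
    min_area: int = DEFAULT_MIN_AREA,
) -> ROIMask:
    """Segment the chromosome ROI from the axis (DAPI/ASY1) channel.

    Triangle-threshold binarisation (256-bin histogram over the observed
    intensity range), binary closing with a disk of ``closing_radius``
    pixels, then removal of connected components below ``min_area`` pixels
    (hot-pixel rejection).

    Raises
    ------
    ValueError
        If the image is constant (no foreground can be detected) or the
        resulting mask is empty.
    """
    axis = np.asarray(axis)
    if axis.ndim != 2 or axis.size == 0:
        raise ValueError("axis channel must be a non-empty 2-D grid")
    if axis.min() == axis.max():
        raise ValueError("no foreground detected: axis channel is constant")
    mask = axis > threshold_triangle(axis, nbins=256)
    if closing_radius > 0:
        mask = closing(mask, disk(closing_radius))
    labels = label_components(mask)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = (sizes >= min_area)[labels] & mask
    if not mask.any():
        raise ValueError("no foreground detected: segmented ROI is empty")
    return ROIMask(mask)


def enhance_foci(foci: np.ndarray, tophat_radius: int = DEFAULT_TOPHAT_RADIUS) -> np.ndarray:
    """White top-hat transform of the focus channel.

    Subtracts the morphological opening with a disk of ``tophat_radius``
    pixels, flattening any structure wider than the disk (background,
    gradients) while preserving diffraction-limited spots.
    """
    foci = np.asarray(foci)
    if foci.ndim != 2 or foci.size == 0:
        raise ValueError("focus channel must be a non-empty 2-D grid")
    if tophat_radius < 1:
        raise ValueError(f"tophat_radius must be >= 1, got {tophat_radius}")
    return white_tophat(foci, disk(tophat_radius))


def count_foci(
    enhanced: np.ndarray,
    roi: ROIMask,
    peak_threshold: Optional[float] = None,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    cell_id: str = "",
    stage: str = "",
) -> FociResult:
    """Count significant peaks of the enhanced focus channel inside the ROI.

    Local maxima with intensity >= ``peak_threshold`` and pairwise distance
    >= ``min_separation`` are detected over the whole frame and intersected
    with the ROI.  When ``peak_threshold`` is None it is estimated as
    mean + 5 SD of the enhanced image *outside* the ROI (the background).

    Raises
    ------
    ValueError
        If shapes mismatch or the ROI is empty.
    """
    enhanced = np.asarray(enhanced)
    if enhanced.shape != roi.mask.shape:
        raise ValueError("enhanced image and ROI shapes differ")
    if roi.area == 0:
        raise ValueError("ROI is empty")
    if peak_threshold is None:
        background = enhanced[~roi.mask]
        if background.size == 0:
            raise ValueError(
                "cannot estimate a background threshold: ROI covers the frame"
            )
        peak_threshold = float(background.mean()) + DEFAULT_THRESHOLD_SDS * float(
            background.std()
        )
    peaks = peak_local_max(
        enhanced.astype(float),
        min_distance=int(min_separation),
        threshold_abs=float(peak_threshold),
        exclude_border=False,
    )
    inside = [tuple(map(int, p)) for p in peaks if roi.mask[p[0], p[1]]]
    return FociResult(
        count=len(inside),
        peak_coordinates=tuple(inside),
        cell_id=cell_id,
        stage=stage,
    )


def compare_groups_lsd(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Fisher's LSD pairwise comparisons of per-cell focus counts.

    A one-way ANOVA pooled error variance (MSE with N - k df) feeds the
    pairwise t statistic

        t = (mean_i - mean_j) / sqrt(MSE * (1/n_i + 1/n_j))

    with unadjusted two-sided p-values.

    Parameters
    ----------
    groups : mapping
        Group label -> per-cell observations; at least two groups, each
        with at least two observations.

    Returns
    -------
    pandas.DataFrame
        One row per unordered pair: group1, group2, mean_diff, t, df, p.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than two observations")
    n_total = sum(v.size for v in arrays.values())
    k = len(arrays)
    df_error = n_total - k
    sse = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
    mse = sse / df_error
    rows = []
    for g1, g2 in combinations(arrays, 2):
        a, b = arrays[g1], arrays[g2]
        diff = a.mean() - b.mean()
        se = np.sqrt(mse * (1.0 / a.size + 1.0 / b.size))
        if se == 0.0:
            t = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
        else:
            t = diff / se
        p = 2.0 * sps.t.sf(abs(t), df_error) if np.isfinite(t) else 0.0
        rows.append(
            {"group1": g1, "group2": g2, "mean_diff": diff, "t": t,
             "df": df_error, "p": p}
        )
    return pd.DataFrame(rows)
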