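"""Synthetic meiocyte images with planted foci and known ground truth.

The generator emulates a chromosome spread: the axis channel contains a few
bright chromosome-like curves (thick random walks) over dark background,
and the focus channel contains diffraction-limited Gaussian spots at known
positions — some inside the chromosome region, optional distractors
strictly outside it — plus Gaussian read noise.  Both channels are 16-bit.

Every planted coordinate is returned, so detection recall and precision can
be scored exactly against the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

from .foci import FociImage, ROIMask

_AXIS_BACKGROUND = 1000.0
_AXIS_FOREGROUND = 20000.0
_AXIS_NOISE_SD = 200.0
_FOCI_BACKGROUND = 1000.0
_FOCI_NOISE_SD = 100.0
_CURVE_THICKNESS = 3  # dilation radius of the random-walk skeleton, px
_BORDER_MARGIN = 12  # keep planted spots away from the frame edge, px
_MIN_SPOT_SPACING = 8  # pairwise spacing of planted spots, px
_DISTRACTOR_CLEARANCE = 10  # distance of distractors from the ROI, px
_BACKGROUND_CORRELATION_SIGMA = 4.0  # autofluorescence correlation length, px
_BACKGROUND_NOISE_FRACTION = 0.866  # share of the noise sd in the smooth component
_PIXEL_NOISE_FRACTION = 0.5  # share in iid pixel (shot/read) noise; quadrature sum 1
_DEBRIS_DENSITY = 1.0 / 400.0  # granular off-cell debris, particles per px
_DEBRIS_MAX_AMPLITUDE_SDS = 4.0  # debris stays well below focus brightness


@dataclass(frozen=True)
class ImageSimParams:
    """Parameters of a synthetic meiocyte image.

    Parameters
    ----------
    image_size : (rows, cols)
        Frame size in pixels.
    n_foci_in_roi : int
        Gaussian spots planted inside the chromosome region.
    n_distractors_outside_roi : int
        Spots planted strictly outside the chromosome region (off-target
        signal that a correct pipeline must not count).
    focus_sigma : float
        PSF width of each spot, pixels (> 0).
    snr : float
        Peak spot amplitude divided by the noise standard deviation (> 0).
    seed : int
        Root seed; identical parameters yield bit-identical images.
    """

    image_size: Tuple[int, int] = (256, 256)
    n_foci_in_roi: int = 20
    n_distractors_outside_roi: int = 0
    focus_sigma: float = 1.5
    snr: float = 10.0
    seed: int = 0

    def __post_init__(self):
        rows, cols = self.image_size
        if rows < 8 * _BORDER_MARGIN // 2 or cols < 8 * _BORDER_MARGIN // 2:
            raise ValueError(f"image_size too small: {self.image_size}")
        if self.n_foci_in_roi < 0 or self.n_distractors_outside_roi < 0:
            raise ValueError("spot counts must be non-negative")
        if not (np.isfinite(self.focus_sigma) and self.focus_sigma > 0):
            raise ValueError(f"focus_sigma must be > 0, got {self.focus_sigma}")
        if not (np.isfinite(self.snr) and self.snr > 0):
            raise ValueError(f"snr must be > 0, got {self.snr}")


@dataclass(frozen=True)
class GroundTruth:
    """Planted-spot coordinates and the true chromosome mask."""

    peaks: pd.DataFrame  # columns: row, col, in_roi
    roi: ROIMask


def _draw_curves(shape, rng: np.random.Generator) -> np.ndarray:
    """Chromosome-like mask: 2-4 thick random-walk curves."""
    from skimage.morphology import dilation, disk

    rows, cols = shape
    lo, hi = _BORDER_MARGIN, None
    skeleton = np.zeros(shape, dtype=bool)
    n_curves = int(rng.integers(2, 5))
    n_steps = int(1.5 * min(rows, cols))
    for _ in range(n_curves):
        r = rng.uniform(rows * 0.25, rows * 0.75)
        c = rng.uniform(cols * 0.25, cols * 0.75)
        heading = rng.uniform(0.0, 2.0 * np.pi)
        for _ in range(n_steps):
            heading += rng.normal(0.0, 0.2)
            r = np.clip(r + np.sin(heading), lo, rows - 1 - _BORDER_MARGIN)
            c = np.clip(c + np.cos(heading), lo, cols - 1 - _BORDER_MARGIN)
            skeleton[int(round(r)), int(round(c))] = True
    return dilation(skeleton, disk(_CURVE_THICKNESS))


def _spaced_sample(candidates: np.ndarray, k: int, rng: np.random.Generator):
    """Pick k candidate coordinates with pairwise spacing >= _MIN_SPOT_SPACING."""
    if k == 0:
        return np.empty((0, 2), dtype=int)
    order = rng.permutation(len(candidates))
    chosen: list = []
    for idx in order:
        p = candidates[idx]
        if all(np.hypot(*(p - q)) >= _MIN_SPOT_SPACING for q in chosen):
            chosen.append(p)
            if len(chosen) == k:
                return np.array(chosen)
    raise ValueError(
        f"could not place {k} spots with {_MIN_SPOT_SPACING} px spacing; "
        "reduce the spot count or enlarge the image"
    )


def _noise_field(shape, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Two-component Gaussian noise with total standard deviation ``sd``.

    Mimics the noise budget of a real fluorescence micrograph: most of the
    variance sits in slowly varying autofluorescence background (smooth,
    correlation length well above the top-hat structuring element — the
    structure the top-hat transform exists to remove), the rest in
    pixel-independent shot/read noise.  The ``snr`` parameter is the peak
    amplitude over the *total* sd, as measured on a raw image.
    """
    from scipy.ndimage import gaussian_filter

    smooth = gaussian_filter(rng.normal(size=shape), _BACKGROUND_CORRELATION_SIGMA)
    smooth *= _BACKGROUND_NOISE_FRACTION * sd / smooth.std()
    grain = rng.normal(0.0, _PIXEL_NOISE_FRACTION * sd, size=shape)
    return smooth + grain


def _add_spots(image: np.ndarray, coords: np.ndarray, amplitude: float, sigma: float):
    half = int(np.ceil(4 * sigma))
    offsets = np.arange(-half, half + 1)
    kernel = np.exp(-(offsets[:, None] ** 2 + offsets[None, :] ** 2) / (2 * sigma**2))
    rows, cols = image.shape
    for r, c in coords:
        r0, r1 = max(r - half, 0), min(r + half + 1, rows)
        c0, c1 = max(c - half, 0), min(c + half + 1, cols)
        image[r0:r1, c0:c1] += amplitude * kernel[
            r0 - (r - half) : kernel.shape[0] - ((r + half + 1) - r1),
            c0 - (c - half) : kernel.shape[1] - ((c + half + 1) - c1),
        ]


def simulate_foci_image(params: ImageSimParams) -> Tuple[FociImage, GroundTruth]:
    """Generate a two-channel synthetic meiocyte image with ground truth.

    Returns
    -------
    image : FociImage
        16-bit axis and focus channels.
    truth : GroundTruth
        Planted peak coordinates (``in_roi`` flag per spot) and the true
        chromosome mask; the peak table has exactly
        ``n_foci_in_roi + n_distractors_outside_roi`` rows.
    """
    from skimage.morphology import dilation, disk, erosion

    rng = np.random.default_rng(params.seed)
    shape = tuple(int(s) for s in params.image_size)
    roi_mask = _draw_curves(shape, rng)

    # In-ROI spots sampled from the slightly eroded mask, so they stay
    # inside any reasonable re-segmentation of the axis channel.
    inner = erosion(roi_mask, disk(1))
    in_candidates = np.argwhere(inner)
    in_coords = _spaced_sample(in_candidates, params.n_foci_in_roi, rng)

    border = np.zeros(shape, dtype=bool)
    border[_BORDER_MARGIN:-_BORDER_MARGIN, _BORDER_MARGIN:-_BORDER_MARGIN] = True
    outside = border & ~dilation(roi_mask, disk(_DISTRACTOR_CLEARANCE))
    out_candidates = np.argwhere(outside)
    out_coords = _spaced_sample(
        out_candidates, params.n_distractors_outside_roi, rng
    )

    amplitude = params.snr * _FOCI_NOISE_SD
    foci = np.full(shape, _FOCI_BACKGROUND, dtype=float)
    _add_spots(foci, in_coords, amplitude, params.focus_sigma)
    _add_spots(foci, out_coords, amplitude, params.focus_sigma)

    # Granular autofluorescence debris outside the cell region: dim
    # sub-focus particles, as on real spread slides.  They never enter the
    # ROI (so they are background texture, not plantable spots) but they
    # keep the pipeline's background-derived significance threshold honest.
    if len(out_candidates):
        n_debris = rng.poisson(_DEBRIS_DENSITY * len(out_candidates))
        debris = out_candidates[rng.integers(0, len(out_candidates), n_debris)]
        for (r, c), amp in zip(
            debris,
            rng.uniform(1.0, _DEBRIS_MAX_AMPLITUDE_SDS, n_debris) * _FOCI_NOISE_SD,
        ):
            _add_spots(foci, np.array([[r, c]]), amp, params.focus_sigma)

    foci += _noise_field(shape, _FOCI_NOISE_SD, rng)

    axis = np.full(shape, _AXIS_BACKGROUND, dtype=float)
    axis[roi_mask] = _AXIS_FOREGROUND
    axis += rng.normal(0.0, _AXIS_NOISE_SD, size=shape)

    def to_u16(a):
        return np.clip(np.rint(a), 0, 65535).astype(np.uint16)

    image = FociImage(axis_channel=to_u16(axis), foci_channel=to_u16(foci))
    peaks = pd.DataFrame(
        {
            "row": np.concatenate([in_coords[:, 0], out_coords[:, 0]]).astype(int),
            "col": np.concatenate([in_coords[:, 1], out_coords[:, 1]]).astype(int),
            "in_roi": [True] * len(in_coords) + [False] * len(out_coords),
        }
    )
    return image, GroundTruth(peaks=peaks, roi=ROIMask(roi_mask))
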