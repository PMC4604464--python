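"""Single-molecule spot detection via the à-trous B3-spline wavelet transform.

The undecimated à-trous decomposition convolves the frame with an increasingly
dilated B3-spline kernel [1, 4, 6, 4, 1]/16 and takes differences of successive
smoothing levels as wavelet planes.  Spot-sized features concentrate in the
second plane, where candidates are taken as local maxima above a robust
(median-absolute-deviation) noise threshold.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

_B3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass(frozen=True)
class SpotCandidate:
    frame: int
    y_px: int
    x_px: int
    response: float
    window: tuple[int, int, int, int]   # y0, y1, x0, x1 (half-open)
    saturated: bool = False


def atrous_decompose(frame: np.ndarray, levels: int = 3) -> list[np.ndarray]:
    """Wavelet planes w_1..w_levels (``frame = sum(planes) + residual``)."""
    if levels < 2:
        raise ValueError("need at least 2 wavelet levels")
    c = np.asarray(frame, dtype=float)
    planes = []
    for j in range(levels):
        kernel = np.zeros(4 * 2 ** j + 1)
        kernel[:: 2 ** j] = _B3
        smoothed = ndimage.convolve1d(c, kernel, axis=0, mode="reflect")
        smoothed = ndimage.convolve1d(smoothed, kernel, axis=1, mode="reflect")
        planes.append(c - smoothed)
        c = smoothed
    return planes


def robust_noise_sigma(plane: np.ndarray) -> float:
    """Noise scale of a wavelet plane from the scaled median absolute deviation."""
    med = np.median(plane)
    return float(1.4826 * np.median(np.abs(plane - med)))


def detect_spots(frame: np.ndarray, frame_index: int = 0, levels: int = 3,
                 k: float = 3.0, detect_plane: int = 1,
                 merge_radius_px: float = 2.0, window_px: int = 9,
                 saturation_level: int = 65535) -> list[SpotCandidate]:
    """Detect candidate single molecules in one frame.

    Candidates are local maxima of the chosen wavelet plane exceeding
    ``k`` x the plane's robust noise estimate; maxima closer together than
    ``merge_radius_px`` are merged, keeping the brighter.  Saturated frames are
    flagged on their candidates, not rejected.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2 or min(frame.shape) < 8:
        raise ValueError("frame must be a 2D image of at least 8x8 px")
    planes = atrous_decompose(frame, levels)
    w = planes[detect_plane]
    # pixel noise concentrates in the first plane; its robust scale sets the
    # detection threshold applied to the spot-sized plane
    thr = k * robust_noise_sigma(planes[0])
    local_max = (w == ndimage.maximum_filter(w, size=3)) & (w > thr) & (w > 0)
    ys, xs = np.nonzero(local_max)
    if len(ys) == 0:
        return []
    order = np.argsort(w[ys, xs])[::-1]
    ys, xs = ys[order], xs[order]
    keep: list[int] = []
    for i in range(len(ys)):
        if all((ys[i] - ys[j]) ** 2 + (xs[i] - xs[j]) ** 2 > merge_radius_px ** 2
               for j in keep):
            keep.append(i)
    saturated = bool(np.any(frame >= saturation_level))
    half = window_px // 2
    ny, nx = frame.shape
    out = []
    for i in keep:
        y, x = int(ys[i]), int(xs[i])
        y0 = min(max(y - half, 0), ny - window_px)
        x0 = min(max(x - half, 0), nx - window_px)
        out.append(SpotCandidate(frame=frame_index, y_px=y, x_px=x,
                                 response=float(w[y, x]),
                                 window=(y0, y0 + window_px, x0, x0 + window_px),
                                 saturated=saturated))
    return out
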