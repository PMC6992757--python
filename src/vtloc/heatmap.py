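"""Gaussian heat-map encoding and argmax decoding of landmark coordinates.

The "heat-maps in channels" representation turns each landmark coordinate
into an image: channel ``l`` of the target stack holds an untruncated
Gaussian hat

    G_l(x, y) = exp(-((x - x_l)^2 + (y - y_l)^2) / (2 sigma^2))

with a maximum of 1 at the landmark location (sigma = 10 px by default).
A predicted landmark is recovered from channel ``l`` as the pixel of
maximal intensity:

    (x_p, y_p)_l = argmax_{x,y} H_l(x, y)

Ties are broken deterministically to the smallest row, then the smallest
column.  Decoding is pixel-resolution by design — no sub-pixel refinement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple
import warnings

import numpy as np

__all__ = ["CodecConfig", "HeatmapStack", "DecodedLandmarks",
           "encode_heatmaps", "decode_heatmaps"]


@dataclass(frozen=True)
class CodecConfig:
    """Parameters of the Gaussian heat-map codec.

    ``sigma_px`` controls the spatial extent of the hat; ``peak_value`` is
    the maximum of each target channel (1.0 — targets are normalised to
    peak 1, not to unit integral).
    """

    sigma_px: float = 10.0
    peak_value: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_px <= 0:
            raise ValueError("sigma_px must be positive")


@dataclass
class HeatmapStack:
    """``(rows, cols, L)`` tensor of per-landmark heat-maps.

    ``channel_landmarks`` names the landmark behind each channel, in
    channel order (which is schema order for full stacks).
    """

    values: np.ndarray
    channel_landmarks: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("heat-map stack must be 3-D (rows, cols, L)")
        if self.values.shape[2] != len(self.channel_landmarks):
            raise ValueError("channel count does not match channel_landmarks")
        if self.values.shape[2] < 1:
            raise ValueError("stack must hold at least one channel")

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]


class DecodedLandmarks(NamedTuple):
    coords: np.ndarray      # (L, 2) float, (x, y) per channel
    degenerate: np.ndarray  # (L,) bool — True where the channel was constant


def encode_heatmaps(landmarks: np.ndarray,
                    image_size: tuple[int, int],
                    config: CodecConfig | None = None,
                    channel_landmarks: tuple[str, ...] | None = None,
                    skip_out_of_frame: bool = False) -> HeatmapStack:
    """Encode landmark coordinates as a stack of Gaussian target heat-maps.

    Parameters
    ----------
    landmarks
        ``(L, 2)`` array of ``(x, y)`` coordinates; sub-pixel locations are
        honoured (the Gaussian is centred at the real-valued point, so the
        peak *pixel* then reads slightly below ``peak_value``).
    image_size
        ``(rows, cols)`` of the frame.
    skip_out_of_frame
        An out-of-frame landmark raises ``ValueError`` by default; with
        ``skip_out_of_frame=True`` its channel is encoded anyway (centre
        outside the frame) and a warning is emitted.

    Returns
    -------
    HeatmapStack with one channel per landmark; each channel is a full,
    untruncated Gaussian, strictly positive everywhere.
    """
    config = config or CodecConfig()
    landmarks = np.asarray(landmarks, dtype=float)
    if landmarks.ndim != 2 or landmarks.shape[1] != 2:
        raise ValueError("landmarks must have shape (L, 2)")
    rows, cols = image_size
    x_l, y_l = landmarks[:, 0], landmarks[:, 1]
    outside = (x_l < 0) | (x_l >= cols) | (y_l < 0) | (y_l >= rows)
    if np.any(outside):
        which = np.nonzero(outside)[0].tolist()
        if not skip_out_of_frame:
            raise ValueError(
                f"landmark(s) at channel index {which} lie outside the "
                f"{rows}x{cols} frame; pass skip_out_of_frame=True to encode anyway")
        warnings.warn(f"encoding out-of-frame landmark(s) at channel index {which}",
                      stacklevel=2)
    xs = np.arange(cols, dtype=float)
    ys = np.arange(rows, dtype=float)
    # (rows, cols, L) via broadcasting of squared distances
    dx2 = (xs[None, :, None] - x_l[None, None, :]) ** 2
    dy2 = (ys[:, None, None] - y_l[None, None, :]) ** 2
    values = config.peak_value * np.exp(-(dx2 + dy2) / (2.0 * config.sigma_px ** 2))
    if channel_landmarks is None:
        channel_landmarks = tuple(f"ch{i}" for i in range(landmarks.shape[0]))
    return HeatmapStack(values=values, channel_landmarks=tuple(channel_landmarks))


def decode_heatmaps(stack: HeatmapStack) -> DecodedLandmarks:
    """Decode each channel to the coordinates of its global maximum.

    Returns ``(x, y)`` per channel.  Ties break to the smallest row, then
    smallest column.  A constant channel carries no location information;
    it decodes to the tie-break winner (0, 0) with ``degenerate=True``.
    """
    v = stack.values
    flat = v.reshape(-1, v.shape[2])
    idx = np.argmax(flat, axis=0)  # first occurrence = row-major tie-break
    rows_i, cols_i = np.unravel_index(idx, v.shape[:2])
    coords = np.stack([cols_i, rows_i], axis=1).astype(float)
    degenerate = flat.max(axis=0) == flat.min(axis=0)
    return DecodedLandmarks(coords=coords, degenerate=degenerate)
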