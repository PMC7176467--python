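"""GREIT figures of merit for reconstructed small-target images.

Every metric derives from the quarter-amplitude set: the pixels whose
(sign-oriented) amplitude reaches at least one fourth of the image maximum.
With ``q`` the quarter set, ``CoG`` its amplitude-weighted center of
gravity and ``C`` the circle centered on the CoG with the same area as
``q``:

- AR  (amplitude response): total quarter-set amplitude x pixel area, per
  unit of true target strength (disc area x |contrast - 1|);
- PE  (position error): radial distance of the true center minus that of
  the CoG — positive when the target is reconstructed too centrally;
- RES (resolution): sqrt(quarter-set area / in-mask area);
- SD  (shape deformation): fraction of quarter-set amplitude outside C;
- RNG (ringing): opposite-sign amplitude outside C relative to the
  quarter-set amplitude.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from eitshape.recon import PixelGrid

__all__ = [
    "TargetSpec",
    "FoMRecord",
    "quarter_set",
    "amplitude_response",
    "position_error",
    "resolution",
    "shape_deformation",
    "ringing",
    "evaluate",
]


@dataclasses.dataclass(frozen=True)
class TargetSpec:
    """A small simulated disc target."""

    center: tuple[float, float]
    radius: float
    factor: float  # conductivity multiplier; > 1 conductive, < 1 resistive


@dataclasses.dataclass(frozen=True)
class FoMRecord:
    ar: float
    pe: float
    res: float
    sd: float
    rng: float
    target: TargetSpec
    valid: bool = True

    @classmethod
    def invalid(cls, target: TargetSpec) -> "FoMRecord":
        nan = float("nan")
        return cls(ar=nan, pe=nan, res=nan, sd=nan, rng=nan, target=target, valid=False)


def _oriented(image: np.ndarray, factor: float) -> np.ndarray:
    """Flip the image so the target's expected effect is positive."""
    return image if factor >= 1.0 else -image


def quarter_set(image: np.ndarray, factor: float = 2.0) -> np.ndarray:
    """Boolean mask of pixels with amplitude >= 1/4 of the oriented maximum."""
    img = _oriented(image, factor)
    peak = img.max()
    if peak <= 0:
        return np.zeros_like(img, dtype=bool)
    return img >= peak / 4.0


def _pixel_coords(grid: PixelGrid) -> tuple[np.ndarray, np.ndarray]:
    c = PixelGrid._centers(grid.n)
    return np.meshgrid(c, c)


def amplitude_response(image: np.ndarray, target: TargetSpec,
                       grid: PixelGrid) -> float:
    q = quarter_set(image, target.factor)
    if target.factor == 1.0:
        raise ValueError("target with factor 1 has no amplitude scale")
    amp = _oriented(image, target.factor)[q].sum() * grid.pixel_area
    return float(amp / (np.pi * target.radius ** 2 * abs(target.factor - 1.0)))


def position_error(image: np.ndarray, target: TargetSpec, grid: PixelGrid) -> float:
    """r_true - r_cog; positive when reconstructed closer to the center."""
    img = _oriented(image, target.factor)
    q = quarter_set(image, target.factor)
    if not q.any():
        raise ValueError("empty quarter set")
    X, Y = _pixel_coords(grid)
    w = img[q]
    cog = np.array([np.average(X[q], weights=w), np.average(Y[q], weights=w)])
    r_t = float(np.hypot(*target.center))
    r_q = float(np.hypot(*cog))
    return r_t - r_q


def resolution(image: np.ndarray, grid: PixelGrid, factor: float = 2.0) -> float:
    q = quarter_set(image, factor)
    if not q.any():
        raise ValueError("empty quarter set")
    return float(np.sqrt(np.count_nonzero(q) / grid.mask.sum()))


def _cog_circle(image: np.ndarray, factor: float,
                grid: PixelGrid) -> tuple[np.ndarray, np.ndarray, float]:
    img = _oriented(image, factor)
    q = quarter_set(image, factor)
    X, Y = _pixel_coords(grid)
    w = img[q]
    cog = np.array([np.average(X[q], weights=w), np.average(Y[q], weights=w)])
    area_q = np.count_nonzero(q) * grid.pixel_area
    radius_c = np.sqrt(area_q / np.pi)
    inside_c = (X - cog[0]) ** 2 + (Y - cog[1]) ** 2 <= radius_c ** 2
    return q, inside_c, radius_c


def shape_deformation(image: np.ndarray, grid: PixelGrid, factor: float = 2.0) -> float:
    """Quarter-set amplitude falling outside the equal-area CoG circle."""
    img = _oriented(image, factor)
    q, inside_c, _ = _cog_circle(image, factor, grid)
    if not q.any():
        raise ValueError("empty quarter set")
    total = img[q].sum()
    outside = img[q & ~inside_c].sum()
    return float(outside / total)


def ringing(image: np.ndarray, grid: PixelGrid, factor: float = 2.0) -> float:
    """Opposite-sign amplitude outside C, relative to the quarter-set amplitude."""
    img = _oriented(image, factor)
    q, inside_c, _ = _cog_circle(image, factor, grid)
    if not q.any():
        raise ValueError("empty quarter set")
    neg = img[(img < 0) & ~inside_c]
    return float(-neg.sum() / img[q].sum())


def evaluate(image: np.ndarray, target: TargetSpec, grid: PixelGrid) -> FoMRecord:
    """All five figures of merit; degenerate images yield an invalid record."""
    q = quarter_set(image, target.factor)
    if not q.any() or not np.all(np.isfinite(image)):
        return FoMRecord.invalid(target)
    return FoMRecord(
        ar=amplitude_response(image, target, grid),
        pe=position_error(image, target, grid),
        res=resolution(image, grid, target.factor),
        sd=shape_deformation(image, grid, target.factor),
        rng=ringing(image, grid, target.factor),
        target=target,
    )
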