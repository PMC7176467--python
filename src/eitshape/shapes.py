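"""Body-contour handling: normalization, Fourier smoothing, shape mismatch.

A body cross-section is represented as a closed planar polygon.  Families of
progressively circularized shapes are produced by truncating the discrete
Fourier transform of the complex boundary sequence ``x + iy`` two
coefficients (one conjugate pair) at a time, down to five terms and finally
to a single first-harmonic term, which is a circle.  Every family member is
rescaled to area ``pi`` so that the mismatch between two shapes can be
quantified as the area of their symmetric difference divided by ``pi``
(the ``ΔS`` metric).
"""

from __future__ import annotations

import dataclasses
import pathlib
from collections.abc import Sequence

import numpy as np
import shapely
import shapely.geometry as geom

__all__ = [
    "Contour",
    "ContourError",
    "Descriptor",
    "FamilyMember",
    "ShapeFamily",
    "normalize_contour",
    "fourier_descriptor",
    "smooth_to",
    "polygon_area",
    "symmetric_difference_area",
    "shape_family",
    "read_contour_csv",
    "write_contour_csv",
    "export_family",
]


class ContourError(ValueError):
    """Raised for degenerate or self-intersecting boundary polygons."""


@dataclasses.dataclass(frozen=True)
class Contour:
    """Closed, simple, counter-clockwise polygon (implicit closure).

    Parameters
    ----------
    points : (n, 2) array
        Vertex coordinates; the last vertex connects back to the first.
        Orientation is normalized to counter-clockwise on construction.
    """

    points: np.ndarray

    def __init__(self, points: np.ndarray | Sequence[Sequence[float]]):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ContourError(f"expected (n, 2) coordinates, got {pts.shape}")
        if len(pts) >= 2 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]  # drop duplicate closing vertex
        if len(pts) < 5:
            raise ContourError(f"need >= 5 vertices, got {len(pts)}")
        if not np.all(np.isfinite(pts)):
            raise ContourError("non-finite coordinates")
        if _shoelace(pts) < 0:
            pts = pts[::-1].copy()
        area = _shoelace(pts)
        if area <= 0:
            raise ContourError("degenerate polygon with zero area")
        ring = geom.LinearRing(pts)
        if not ring.is_simple:
            raise ContourError("self-intersecting polygon")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def area(self) -> float:
        return _shoelace(self.points)

    @property
    def centroid(self) -> np.ndarray:
        return np.asarray(self.polygon.centroid.coords[0])

    @property
    def perimeter(self) -> float:
        return float(np.sum(np.linalg.norm(np.roll(self.points, -1, axis=0) - self.points, axis=1)))

    @property
    def polygon(self) -> geom.Polygon:
        return geom.Polygon(self.points)

    def resample(self, n: int) -> "Contour":
        """Resample to ``n`` equidistant points along the perimeter.

        The first output vertex coincides with the first input vertex.
        """
        pts = self.points
        seg = np.roll(pts, -1, axis=0) - pts
        seglen = np.linalg.norm(seg, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        total = cum[-1]
        s = np.linspace(0.0, total, n, endpoint=False)
        idx = np.searchsorted(cum, s, side="right") - 1
        idx = np.clip(idx, 0, len(pts) - 1)
        frac = (s - cum[idx]) / np.where(seglen[idx] > 0, seglen[idx], 1.0)
        out = pts[idx] + frac[:, None] * seg[idx]
        return Contour(out)

    def point_at_arclength(self, s: np.ndarray) -> np.ndarray:
        """Boundary points at arc-length positions ``s`` (measured from vertex 0)."""
        pts = self.points
        seg = np.roll(pts, -1, axis=0) - pts
        seglen = np.linalg.norm(seg, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        s = np.mod(np.atleast_1d(np.asarray(s, dtype=float)), cum[-1])
        idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(pts) - 1)
        frac = (s - cum[idx]) / np.where(seglen[idx] > 0, seglen[idx], 1.0)
        return pts[idx] + frac[:, None] * seg[idx]

    def scaled_to_area(self, target: float = np.pi) -> "Contour":
        """Uniformly rescale about the centroid so the area equals ``target``."""
        c = self.centroid
        f = np.sqrt(target / self.area)
        return Contour(c + f * (self.points - c))


@dataclasses.dataclass(frozen=True)
class Descriptor:
    """Complex Fourier descriptor of a closed contour.

    ``coefficients[j]`` is the unnormalized DFT (numpy convention) of the
    boundary sequence ``x + iy``; index ``j`` carries signed frequency
    ``j`` for ``j <= n/2`` and ``j - n`` above.  The inverse transform of
    the full descriptor reproduces the source points.
    """

    coefficients: np.ndarray
    n_points: int

    def inverse(self, m: int | None = None) -> np.ndarray:
        """Inverse transform, optionally zero-padded/resampled to ``m`` points."""
        n = self.n_points
        if m is None or m == n:
            z = np.fft.ifft(self.coefficients)
        else:
            padded = np.zeros(m, dtype=complex)
            half = n // 2
            padded[: half + 1] = self.coefficients[: half + 1]
            padded[m - (n - half - 1):] = self.coefficients[half + 1:]
            # amplitude-preserving rescale: ifft divides by the new length
            z = np.fft.ifft(padded) * (m / n)
        return np.column_stack([z.real, z.imag])


@dataclasses.dataclass(frozen=True)
class FamilyMember:
    k: int
    contour: Contour
    delta_s: float


@dataclasses.dataclass(frozen=True)
class ShapeFamily:
    """Sequence of progressively smoothed shapes, all of area ``pi``."""

    members: tuple[FamilyMember, ...]

    def __iter__(self):
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def reference(self) -> FamilyMember:
        """The untruncated (largest-k) member."""
        return self.members[0]


def _shoelace(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_area(contour: Contour | np.ndarray) -> float:
    """Shoelace area of a simple polygon (positive for counter-clockwise)."""
    pts = contour.points if isinstance(contour, Contour) else np.asarray(contour, float)
    return _shoelace(pts)


def normalize_contour(points: np.ndarray | Sequence[Sequence[float]]) -> Contour:
    """Fit a raw point list into the square ``[-1, 1]^2``.

    Similarity transform only: the bounding-box center is translated to the
    origin and a single uniform scale makes the larger bounding-box extent
    exactly 2.  The starting vertex is rolled to the point of maximum x so
    descriptors of equivalent contours are comparable.
    """
    c = Contour(points)
    pts = c.points
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    center = (lo + hi) / 2.0
    extent = float((hi - lo).max())
    if extent <= 0:
        raise ContourError("degenerate contour: zero extent")
    pts = (pts - center) * (2.0 / extent)
    start = int(np.argmax(pts[:, 0]))
    return Contour(np.roll(pts, -start, axis=0))


def fourier_descriptor(contour: Contour) -> Descriptor:
    """DFT of the boundary interpreted as the complex sequence ``x + iy``."""
    z = contour.points[:, 0] + 1j * contour.points[:, 1]
    return Descriptor(np.fft.fft(z), len(z))


def smooth_to(descriptor: Descriptor, k: int, m: int = 48) -> Contour:
    """Truncate a descriptor to ``k`` coefficients and rebuild a contour.

    Retains frequencies ``{0, ±1, …, ±(k−1)/2}`` (``k`` odd), zero-pads the
    spectrum to ``m`` samples, inverse-transforms, and rescales the polygon
    to area ``pi`` about its centroid.  ``k = 1`` keeps only the dominant
    first-harmonic coefficient, which yields an origin-centered circle of
    radius 1 after the area rescale.
    """
    n = descriptor.n_points
    coeff = descriptor.coefficients
    if k == 1:
        kept = np.zeros(n, dtype=complex)
        pos, neg = coeff[1], coeff[-1]
        if abs(pos) >= abs(neg):
            kept[1] = pos
        else:
            kept[-1] = neg
    else:
        if k % 2 == 0 or k < 5 or k > n:
            raise ValueError(f"k must be odd with 5 <= k <= {n}, or 1; got {k}")
        half = (k - 1) // 2
        kept = np.zeros(n, dtype=complex)
        kept[: half + 1] = coeff[: half + 1]
        kept[n - half:] = coeff[n - half:]
    if m < max(k, 5):
        raise ValueError(f"m={m} too small for k={k}")
    pts = Descriptor(kept, n).inverse(m)
    try:
        c = Contour(pts)
    except ContourError as err:
        raise ContourError(f"truncation to k={k} produced an invalid polygon: {err}") from err
    return c.scaled_to_area(np.pi)


def symmetric_difference_area(a: Contour, b: Contour) -> float:
    """Shape mismatch ``ΔS``: area of the symmetric difference divided by pi.

    Computed with exact polygon boolean operations; symmetric in its
    arguments and zero for identical shapes.
    """
    pa, pb = a.polygon, b.polygon
    try:
        diff = pa.symmetric_difference(pb)
    except shapely.errors.GEOSException as err:  # pragma: no cover - degenerate overlap
        raise ContourError(f"polygon boolean operation failed: {err}") from err
    return float(diff.area) / np.pi


def shape_family(contour: Contour, step: int = 2, m: int = 48,
                 max_members: int | None = None) -> ShapeFamily:
    """Build the smoothing family ``k = N, N−2, …, 5`` plus the circle.

    The contour is resampled by arc length to an odd point count if needed.
    Each member is rescaled to area ``pi`` and annotated with its ``ΔS``
    against the untruncated (``k = N``) member.  ``max_members`` keeps only
    the first members of the descending-k list but always appends the
    ``k = 1`` circle.
    """
    n = len(contour)
    if n % 2 == 0:
        contour = contour.resample(n - 1)
        n = n - 1
    desc = fourier_descriptor(contour)
    ks = list(range(n, 4, -step))
    if max_members is not None and max_members >= 2:
        ks = ks[: max_members - 1]
    ks.append(1)
    members: list[FamilyMember] = []
    reference: Contour | None = None
    for k in ks:
        c = smooth_to(desc, k, m=max(m, k))
        if reference is None:
            reference = c
        members.append(FamilyMember(k=k, contour=c,
                                    delta_s=symmetric_difference_area(reference, c)))
    return ShapeFamily(tuple(members))


# ---------------------------------------------------------------------------
# I/O: one vertex per CSV row with an `x,y` header; implicit closure.

def read_contour_csv(path: str | pathlib.Path) -> Contour:
    data = np.genfromtxt(path, delimiter=",", names=True)
    pts = np.column_stack([data["x"], data["y"]])
    return Contour(pts)  # constructor silently drops a duplicate closing vertex


def write_contour_csv(contour: Contour, path: str | pathlib.Path) -> None:
    header = "x,y"
    np.savetxt(path, contour.points, delimiter=",", header=header, comments="", fmt="%.12g")


def export_family(family: ShapeFamily, out_dir: str | pathlib.Path) -> pathlib.Path:
    """Write each member contour plus a ``family.csv`` manifest (k, delta_s, filename)."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for mem in family:
        fname = f"contour_k{mem.k:03d}.csv"
        write_contour_csv(mem.contour, out / fname)
        rows.append(f"{mem.k},{mem.delta_s:.9g},{fname}")
    manifest = out / "family.csv"
    manifest.write_text("k,delta_s,filename\n" + "\n".join(rows) + "\n")
    return manifest
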