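"""Synthetic inputs: thorax-like contours, lung polygons, breathing frames.

The generators stand in for CT-derived anatomy: a star-shaped radius
function with a small set of low-order harmonics produces human-like
(eccentric, mildly flattened sternally) or pig-like (rounder, dorsally
flattened) cross sections, two mirrored super-ellipse "lungs" carry the
conductivity contrast, and a raised-cosine conductivity cycle between
end-expiration and end-inspiration emulates tidal breathing.  The presets
are stylized rather than anatomically fitted; the lung-to-background
conductivity ratio averages 0.1875 over the cycle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import pathlib

import numpy as np
import shapely
import yaml

from eitshape import fem
from eitshape.shapes import (Contour, ContourError, normalize_contour,
                             shape_family, export_family, write_contour_csv)

__all__ = [
    "ThoraxPreset",
    "LungSpec",
    "PRESETS",
    "gen_thorax_contour",
    "gen_lungs",
    "gen_breathing_sequence",
    "make_fixtures",
]


@dataclasses.dataclass(frozen=True)
class ThoraxPreset:
    """Harmonic recipe for a body contour radius function.

    ``harmonics`` maps harmonic order h to (amplitude, phase) of
    ``a_h * cos(h*theta + phi_h)`` added to the unit radius.
    """

    name: str
    harmonics: dict[int, tuple[float, float]]
    perturb_scale: float = 0.01


PRESETS: dict[str, ThoraxPreset] = {
    # lateral-to-anteroposterior extent ratio ~1.4, mild sternal flattening
    "human": ThoraxPreset("human", {2: (0.17, 0.0), 3: (0.04, np.pi / 2),
                                    4: (0.03, 0.0)}),
    # rounder (ratio ~1.15) with dorsal flattening
    "pig": ThoraxPreset("pig", {2: (0.07, 0.0), 3: (0.05, -np.pi / 2)}),
    "ellipse": ThoraxPreset("ellipse", {2: (0.17, 0.0)}, perturb_scale=0.0),
}


@dataclasses.dataclass(frozen=True)
class LungSpec:
    """Geometry and contrast of the two lung regions.

    Super-ellipse half-axes (a, b), exponent p, mirrored centers
    (+-cx, cy), and the lung-to-background conductivity ratio.
    """

    a: float = 0.34
    b: float = 0.55
    p: float = 2.2
    cx: float = 0.48
    cy: float = -0.05
    ratio: float = 0.1875
    n_points: int = 64


def gen_thorax_contour(preset: ThoraxPreset | str = "human", n_points: int = 48,
                       seed: int = 0) -> Contour:
    """Thorax-like star-shaped contour, normalized and area-scaled to pi.

    The radius function is ``1 + sum_h a_h cos(h theta + phi_h)`` plus a
    seeded low-amplitude perturbation on harmonics 5-8.  If a perturbation
    draw self-intersects (it essentially cannot for the default scales),
    the draw is repeated.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    if n_points < 16:
        raise ValueError("need at least 16 points")
    rng = np.random.default_rng(seed)
    th = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    for _ in range(10):
        r = np.ones_like(th)
        for h, (amp, phase) in preset.harmonics.items():
            r = r + amp * np.cos(h * th + phase)
        if preset.perturb_scale > 0:
            for h in range(5, 9):
                amp = preset.perturb_scale * rng.uniform(0, 1)
                phase = rng.uniform(0, 2 * np.pi)
                r = r + amp * np.cos(h * th + phase)
        if np.any(r <= 0):
            continue
        try:
            c = normalize_contour(np.column_stack([r * np.cos(th), r * np.sin(th)]))
        except ContourError:
            continue
        return c.scaled_to_area(np.pi)
    raise ContourError(f"could not draw a simple contour for preset {preset.name!r}")


def _superellipse(a: float, b: float, p: float, center, n: int) -> np.ndarray:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x = a * np.sign(np.cos(t)) * np.abs(np.cos(t)) ** (2.0 / p)
    y = b * np.sign(np.sin(t)) * np.abs(np.sin(t)) ** (2.0 / p)
    return np.column_stack([x + center[0], y + center[1]])


def gen_lungs(contour: Contour, spec: LungSpec | None = None,
              seed: int = 0) -> tuple[Contour, Contour]:
    """Two mirrored lung polygons strictly inside the contour.

    Both lungs are shrunk toward their own centroids (up to 40%) until they
    fit with a small safety margin; the mirror symmetry of the pair is
    preserved because both are shrunk together.
    """
    spec = spec or LungSpec()
    body = contour.polygon
    for shrink in np.linspace(1.0, 0.6, 9):
        pts_r = _superellipse(spec.a * shrink, spec.b * shrink, spec.p,
                              (spec.cx * contourscale(contour), spec.cy), spec.n_points)
        pts_l = pts_r * np.array([-1.0, 1.0])
        ok = True
        for pts in (pts_r, pts_l):
            if not np.all(shapely.contains_xy(body, pts[:, 0] * 1.02, pts[:, 1] * 1.02)):
                ok = False
                break
        if ok:
            left = Contour(pts_l)
            right = Contour(pts_r)
            if not left.polygon.intersects(right.polygon):
                return left, right
    raise ValueError("could not fit lungs inside the contour")


def contourscale(contour: Contour) -> float:
    """Half the lateral extent; sizes lung placement to the body width."""
    pts = contour.points
    return float(pts[:, 0].max() - pts[:, 0].min()) / 2.0


def breathing_ratio(phase: np.ndarray, end_expiration: float,
                    end_inspiration: float) -> np.ndarray:
    """Raised-cosine conductivity-ratio cycle; phase 0 is end-expiration."""
    return end_expiration + (end_inspiration - end_expiration) * \
        (1.0 - np.cos(2 * np.pi * phase)) / 2.0


def gen_breathing_sequence(model: fem.EITModel, lungs, n_frames: int = 10,
                           ratio_end_expiration: float = 0.25,
                           ratio_end_inspiration: float = 0.125,
                           snr: float | None = None, seed: int = 0,
                           spec: LungSpec | None = None
                           ) -> list[fem.MeasurementFrame]:
    """Forward-simulate one breath; frame 0 is the end-expiration reference.

    The lung conductivity ratio follows a raised cosine between the two
    endpoint ratios (defaults average to 0.1875 over the cycle); each frame
    is solved on the model and optionally noise-corrupted at the given SNR.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    polys = [l.polygon if isinstance(l, Contour) else shapely.geometry.Polygon(l)
             for l in lungs]
    cent = model.mesh.centroids
    mask = np.zeros(model.mesh.n_elements, dtype=bool)
    for p in polys:
        mask |= shapely.contains_xy(p, cent[:, 0], cent[:, 1])
    rng = np.random.default_rng(seed)
    phases = np.arange(n_frames) / n_frames
    frames = []
    for ph in phases:
        ratio = float(breathing_ratio(np.array([ph]), ratio_end_expiration,
                                      ratio_end_inspiration)[0])
        sigma = model.sigma_ref.copy()
        sigma[mask] *= ratio
        fr = fem.solve_forward(model, sigma)
        if snr is not None:
            fr = fem.add_noise(fr, snr, rng)
        frames.append(fr)
    return frames


# ---------------------------------------------------------------------------
# Deterministic fixture bundle for tests and examples


def make_fixtures(out_dir: str | pathlib.Path, seed: int = 0) -> pathlib.Path:
    """Write a small deterministic bundle of synthetic inputs.

    Contents: human and pig contours (48 points), their 12-member shape
    families, one coarse mesh (nodes/elements CSV), a 10-frame noiseless
    breathing sequence with its metadata, and a checksum manifest.
    Regeneration with the same seed is byte-identical.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[pathlib.Path] = []

    human = gen_thorax_contour("human", 48, seed=seed)
    pig = gen_thorax_contour("pig", 48, seed=seed)
    for name, c in (("human", human), ("pig", pig)):
        p = out / f"{name}.csv"
        write_contour_csv(c, p)
        written.append(p)
        fam_dir = out / f"family_{name}"
        manifest = export_family(shape_family(c, max_members=12), fam_dir)
        written.extend(sorted(fam_dir.iterdir()))

    model = fem.build_model(human, max_area=0.02)
    np.savetxt(out / "mesh_nodes.csv", model.mesh.nodes, delimiter=",",
               header="x,y", comments="", fmt="%.12g")
    np.savetxt(out / "mesh_elements.csv", model.mesh.elements, delimiter=",",
               header="n1,n2,n3", comments="", fmt="%d")
    written += [out / "mesh_nodes.csv", out / "mesh_elements.csv"]

    lungs = gen_lungs(human, seed=seed)
    frames = gen_breathing_sequence(model, lungs, n_frames=10, seed=seed)
    seq = np.column_stack([f.v for f in frames])
    np.savetxt(out / "breathing_frames.csv", seq, delimiter=",",
               header=",".join(f"frame{i}" for i in range(10)), comments="",
               fmt="%.12g")
    written.append(out / "breathing_frames.csv")
    meta = {"seed": seed, "n_frames": 10, "snr": None,
            "ratio_end_expiration": 0.25, "ratio_end_inspiration": 0.125,
            "pattern": "adjacent-16", "reference_frame": 0}
    (out / "breathing_meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    written.append(out / "breathing_meta.yaml")

    sums = []
    for p in sorted(set(written)):
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        sums.append(f"{digest}  {p.relative_to(out)}")
    (out / "checksums.txt").write_text("\n".join(sums) + "\n")
    return out
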