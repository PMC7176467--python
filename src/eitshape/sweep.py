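"""Study orchestration: figure-of-merit maps versus shape mismatch.

For every member of a shape-smoothing family, a homogeneous reconstruction
model with the (mis)matched shape is built and calibrated; measurements of
a regular lattice of small targets are simulated once on the true-shape
(optionally lung-heterogeneous) model and reconstructed with every
(shape, algorithm) pair.  Each figure of merit becomes a map with one
pixel per target position; maps are summarized by their mean and the
ratio of standard deviation to mean as a function of the mismatch ΔS.
"""

from __future__ import annotations

import dataclasses
import hashlib
import pathlib

import numpy as np
import pandas as pd
import shapely

from eitshape import fem, fom, recon
from eitshape.shapes import Contour, ShapeFamily

__all__ = [
    "FoMMap",
    "SweepConfig",
    "target_grid",
    "run_sweep",
    "summarize",
    "horizontal_cut",
    "save_maps",
]

METRICS = ("ar", "pe", "res", "sd", "rng")


@dataclasses.dataclass(frozen=True)
class FoMMap:
    """Per-target-position image of one figure of merit.

    ``values[iy, ix]`` corresponds to the target centered at
    ``(xs[ix], ys[iy])``; positions without a (valid) target are NaN.
    """

    metric: str
    shape_k: int
    delta_s: float
    algorithm: str
    xs: np.ndarray
    ys: np.ndarray
    values: np.ndarray

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]


@dataclasses.dataclass(frozen=True)
class SweepConfig:
    """Study conditions for one sweep."""

    spacing: float = 0.125
    target_radius: float = 0.05
    target_factor: float = 1.1
    lung_ratio: float = 0.1875
    nf_target: float = 0.5
    max_area: float = 0.004
    n_electrodes: int = 16
    coverage: float = 0.5
    contact_impedance: float = 0.01
    greit_n: int = 1500
    seed: int = 0


def target_grid(contour: Contour, spacing: float = 0.125, radius: float = 0.05,
                factor: float = 1.1) -> list[fom.TargetSpec]:
    """Square lattice of small-disc targets fully inside the contour."""
    poly = contour.polygon
    k = int(np.ceil(2.0 / spacing))
    coords = spacing * np.arange(-k, k + 1)
    coords = coords[np.abs(coords) <= 1.5]
    t = np.linspace(0, 2 * np.pi, 16, endpoint=False)
    ring = 1.05 * radius * np.column_stack([np.cos(t), np.sin(t)])
    targets = []
    for y in coords:
        for x in coords:
            pts = ring + [x, y]
            if np.all(shapely.contains_xy(poly, pts[:, 0], pts[:, 1])):
                targets.append(fom.TargetSpec(center=(float(x), float(y)),
                                              radius=radius, factor=factor))
    if not targets:
        raise ValueError("no target fits inside the contour at this spacing")
    return targets


def _simulate_targets(true_model: fem.EITModel, targets, config: SweepConfig,
                      lungs=None) -> tuple[np.ndarray, list[bool]]:
    """Normalized differences of every target on the true-shape model.

    The reference conductivity carries the lung contrast when lung polygons
    are given; the target disc multiplies the local (possibly lung)
    conductivity by the target factor.
    """
    sigma_base = true_model.sigma_ref.copy()
    if lungs is not None:
        cent = true_model.mesh.centroids
        mask = np.zeros(true_model.mesh.n_elements, dtype=bool)
        for l in lungs:
            poly = l.polygon if isinstance(l, Contour) else shapely.geometry.Polygon(l)
            mask |= shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
        sigma_base[mask] *= config.lung_ratio
    v_r = fem.solve_forward(true_model, sigma_base)
    Y = np.empty((len(targets), len(v_r.v)))
    ok = []
    for i, tgt in enumerate(targets):
        try:
            base_model = dataclasses.replace(true_model, sigma_ref=sigma_base)
            sigma = fem.target_sigma(base_model, tgt.center, tgt.radius, tgt.factor)
            v = fem.solve_forward(true_model, sigma)
            Y[i] = recon.normalized_difference(v, v_r)
            ok.append(True)
        except (ValueError, ZeroDivisionError):
            Y[i] = np.nan
            ok.append(False)
    return Y, ok


def _map_key(member, algorithm: str, targets, config: SweepConfig) -> str:
    h = hashlib.sha256()
    h.update(member.contour.points.tobytes())
    h.update(algorithm.encode())
    h.update(np.array([t.center + (t.radius, t.factor) for t in targets]).tobytes())
    h.update(repr(config).encode())
    return h.hexdigest()[:16]


def run_sweep(true_model: fem.EITModel, family: ShapeFamily,
              algorithms=recon.ALGORITHMS, targets=None,
              lungs=None, config: SweepConfig | None = None,
              cache_dir: str | pathlib.Path | None = None) -> list[FoMMap]:
    """Full study: maps of every metric per (family member, algorithm).

    Target measurements are simulated once on the true-shape model; every
    family member provides a homogeneous reconstruction model with the
    smoothed shape.  Per-(shape, algorithm) maps are cached as CSV bundles
    keyed by a content hash when ``cache_dir`` is given, so an interrupted
    sweep resumes where it stopped.
    """
    config = config or SweepConfig()
    if true_model.contour is None:
        raise ValueError("true model must carry its contour")
    if targets is None:
        targets = target_grid(true_model.contour, config.spacing,
                              config.target_radius, config.target_factor)
    xs = np.unique([t.center[0] for t in targets])
    ys = np.unique([t.center[1] for t in targets])
    pos_index = {t.center: (np.searchsorted(ys, t.center[1]),
                            np.searchsorted(xs, t.center[0])) for t in targets}
    Y, ok = _simulate_targets(true_model, targets, config, lungs=lungs)

    cache = pathlib.Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)
    maps: list[FoMMap] = []
    for member in family:
        shape_model = None
        for algo in algorithms:
            key = _map_key(member, algo, targets, config) if cache is not None else None
            if key is not None and (cache / f"{key}.npz").exists():
                data = np.load(cache / f"{key}.npz")
                for metric in METRICS:
                    maps.append(FoMMap(metric=metric, shape_k=member.k,
                                       delta_s=member.delta_s, algorithm=algo,
                                       xs=xs, ys=ys, values=data[metric]))
                continue
            if shape_model is None:
                shape_model = fem.build_model(
                    member.contour, n_elec=config.n_electrodes,
                    coverage=config.coverage,
                    contact_impedance=config.contact_impedance,
                    max_area=config.max_area, pattern=true_model.pattern)
            rm = recon.build_recon_model(
                shape_model, algorithm=algo, nf_target=config.nf_target,
                greit_n=config.greit_n, seed=config.seed)
            grids = {metric: np.full((len(ys), len(xs)), np.nan) for metric in METRICS}
            for i, tgt in enumerate(targets):
                if not ok[i]:
                    continue
                img = recon.reconstruct(rm, Y[i])
                rec = fom.evaluate(img, tgt, rm.grid)
                if not rec.valid:
                    continue
                iy, ix = pos_index[tgt.center]
                for metric in METRICS:
                    grids[metric][iy, ix] = getattr(rec, metric)
            if key is not None:
                np.savez(cache / f"{key}.npz", **grids)
            for metric in METRICS:
                maps.append(FoMMap(metric=metric, shape_k=member.k,
                                   delta_s=member.delta_s, algorithm=algo,
                                   xs=xs, ys=ys, values=grids[metric]))
    return maps


def summarize(maps: list[FoMMap]) -> pd.DataFrame:
    """Mean and sd/mean per map over valid targets (tidy long format)."""
    if not maps:
        raise ValueError("no maps to summarize")
    rows = []
    for m in maps:
        vals = m.valid_values
        if len(vals) == 0:
            import warnings
            warnings.warn(f"all-invalid map {m.metric}/{m.algorithm}/k={m.shape_k}",
                          RuntimeWarning, stacklevel=2)
            continue
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append({"shape_k": m.shape_k, "delta_s": m.delta_s,
                     "algorithm": m.algorithm, "metric": m.metric,
                     "mean": mean,
                     "sd_over_mean": sd / mean if mean != 0 else np.inf,
                     "n_valid": len(vals)})
    return pd.DataFrame(rows)


def horizontal_cut(m: FoMMap, y: float = 0.0) -> pd.DataFrame:
    """Profile of one map along the row of targets nearest ``y``."""
    iy = int(np.argmin(np.abs(m.ys - y)))
    row = m.values[iy]
    sel = np.isfinite(row)
    return pd.DataFrame({"x": m.xs[sel], "value": row[sel],
                         "y": np.full(sel.sum(), m.ys[iy])})


def save_maps(maps: list[FoMMap], out_dir: str | pathlib.Path,
              render: bool = False) -> pathlib.Path:
    """Write each map as a CSV grid plus the tidy summary table.

    With ``render=True`` a PNG rendering of each map is written alongside.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for m in maps:
        name = f"map_{m.metric}_k{m.shape_k:03d}_{m.algorithm}"
        np.savetxt(out / f"{name}.csv", m.values, delimiter=",", fmt="%.9g")
        if render:
            render_map(m, out / f"{name}.png")
    summarize(maps).to_csv(out / "summary.csv", index=False)
    return out


def render_map(m: FoMMap, path: str | pathlib.Path) -> None:
    """Render one figure-of-merit map to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4, 3.2))
    extent = (m.xs.min(), m.xs.max(), m.ys.min(), m.ys.max())
    im = ax.imshow(m.values, origin="lower", extent=extent, cmap="viridis")
    fig.colorbar(im, ax=ax, shrink=0.85)
    ax.set_title(f"{m.metric.upper()}  k={m.shape_k}  ΔS={m.delta_s:.3f}  "
                 f"{m.algorithm}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
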