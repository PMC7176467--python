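"""Linear difference-EIT reconstruction on a rectangular pixel grid.

Four algorithms build a reconstruction matrix ``R`` mapping normalized
voltage differences ``y`` to a conductivity-change image ``x_hat = R y``:

- TSVD: truncated pseudoinverse of the Jacobian;
- GREIT: trained from simulated point-target measurements and the
  corresponding desired images, ``R = X~ Y^T (J Sx J^T + lam Sn)^-1``;
- one-step Gauss-Newton, ``R = (J^T J + lam P)^-1 J^T``, with either the
  NOSER diagonal prior or a discrete-Laplace smoothness prior.

All use the dual-model approach: the Jacobian is computed on the fine
forward mesh and aggregated onto a coarse ``n x n`` pixel grid restricted
to pixels inside the reconstruction contour.  The hyperparameter of every
algorithm is calibrated so that the Noise Figure — the ratio of measurement
SNR to image SNR for a small central target — equals a common value
(0.5 by default), which makes the algorithms comparable.
"""

from __future__ import annotations

import dataclasses
import pathlib
import warnings

import numpy as np
import scipy.linalg as sla
import shapely
import yaml

from eitshape import fem
from eitshape.shapes import Contour

__all__ = [
    "PixelGrid",
    "ReconModel",
    "GreitTraining",
    "Prior",
    "normalized_difference",
    "tsvd_matrix",
    "gn_matrix",
    "noser_prior",
    "laplace_prior",
    "make_greit_training",
    "greit_matrix",
    "noise_figure",
    "calibrate_hyperparameter",
    "build_recon_model",
    "reconstruct",
    "save_recon",
    "load_recon",
]


@dataclasses.dataclass(frozen=True)
class PixelGrid:
    """``n x n`` reconstruction grid over [-1, 1]^2 masked to a contour.

    ``mask[iy, ix]`` is True where the pixel center lies inside the
    reconstruction contour; images use the same ``[iy, ix]`` layout with
    y increasing along rows.
    """

    n: int
    mask: np.ndarray   # (n, n) bool

    @classmethod
    def from_contour(cls, contour: Contour, n: int = 32) -> "PixelGrid":
        centers = cls._centers(n)
        X, Y = np.meshgrid(centers, centers)
        inside = shapely.contains_xy(contour.polygon, X.ravel(), Y.ravel())
        return cls(n=n, mask=inside.reshape(n, n))

    @staticmethod
    def _centers(n: int) -> np.ndarray:
        pitch = 2.0 / n
        return -1.0 + pitch * (np.arange(n) + 0.5)

    @property
    def pitch(self) -> float:
        return 2.0 / self.n

    @property
    def pixel_area(self) -> float:
        return self.pitch ** 2

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    @property
    def masked_centers(self) -> np.ndarray:
        """(n_masked, 2) coordinates of in-mask pixel centers (row-major order)."""
        c = self._centers(self.n)
        X, Y = np.meshgrid(c, c)
        return np.column_stack([X[self.mask], Y[self.mask]])

    def to_image(self, values: np.ndarray) -> np.ndarray:
        """Scatter a masked-pixel vector into a dense (n, n) image (zeros outside)."""
        img = np.zeros((self.n, self.n))
        img[self.mask] = values
        return img

    def from_image(self, img: np.ndarray) -> np.ndarray:
        return img[self.mask]

    def restrict(self, keep_masked: np.ndarray) -> "PixelGrid":
        """New grid keeping only the given subset of in-mask pixels."""
        mask = self.mask.copy()
        mask[self.mask] = keep_masked
        return PixelGrid(n=self.n, mask=mask)

    def aggregate_jacobian(self, J_elem: np.ndarray, mesh: fem.Mesh,
                           depth: int = 2) -> np.ndarray:
        """Sum element sensitivities into pixel columns (dual-model step).

        Approximate area-weighted overlap: each element is uniformly
        subdivided ``depth`` times (4^depth equal-area subtriangles) and
        each subtriangle's share is assigned to the pixel containing its
        centroid; shares landing on masked-out pixels go to the nearest
        in-mask pixel so no sensitivity is lost.
        """
        tris = mesh.nodes[mesh.elements]  # (M, 3, 2)
        for _ in range(depth):
            a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
            ab, bc, ca = (a + b) / 2, (b + c) / 2, (c + a) / 2
            tris = np.concatenate([
                np.stack([a, ab, ca], axis=1),
                np.stack([ab, b, bc], axis=1),
                np.stack([ca, bc, c], axis=1),
                np.stack([ab, bc, ca], axis=1)], axis=0)
        n_sub = 4 ** depth
        weights = np.tile(J_elem / n_sub, (1, n_sub))  # columns follow tiling order
        cent = tris.mean(axis=1)
        ix = np.clip(((cent[:, 0] + 1.0) / self.pitch).astype(int), 0, self.n - 1)
        iy = np.clip(((cent[:, 1] + 1.0) / self.pitch).astype(int), 0, self.n - 1)
        flat_idx = np.full(self.n * self.n, -1, dtype=int)
        flat_idx[np.flatnonzero(self.mask.ravel())] = np.arange(self.n_masked)
        pix = flat_idx[iy * self.n + ix]
        lost = pix < 0
        if lost.any():
            mc = self.masked_centers
            for e in np.flatnonzero(lost):
                pix[e] = np.argmin(np.sum((mc - cent[e]) ** 2, axis=1))
        Jp = np.zeros((J_elem.shape[0], self.n_masked))
        np.add.at(Jp.T, pix, weights.T)
        return Jp

    def render_disc(self, center, radius: float) -> np.ndarray:
        """Unit-amplitude disc on the masked pixels (desired-image shape)."""
        mc = self.masked_centers
        return (np.sum((mc - np.asarray(center)) ** 2, axis=1) <= radius ** 2).astype(float)


@dataclasses.dataclass(frozen=True)
class Prior:
    """Regularization prior matrix for one-step Gauss-Newton."""

    P: np.ndarray
    kind: str


@dataclasses.dataclass(frozen=True)
class GreitTraining:
    """Simulated training measurements and desired solutions.

    Columns of ``X_tilde`` (pixels x n) are desired images, columns of
    ``Y`` (channels x n) the corresponding simulated normalized
    differences; both carry the 1/n scaling of their defining concatenation.
    """

    X_tilde: np.ndarray
    Y: np.ndarray
    Sigma_x: np.ndarray | None
    Sigma_n: np.ndarray | None
    n: int
    seed: int
    centers: np.ndarray


@dataclasses.dataclass(frozen=True)
class ReconModel:
    """Reconstruction matrix with its grid, algorithm tag and hyperparameter."""

    R: np.ndarray          # (n_masked, channels)
    algorithm: str
    hyperparameter: float
    grid: PixelGrid
    achieved_nf: float | None = None
    meta: dict = dataclasses.field(default_factory=dict)


def normalized_difference(v: fem.MeasurementFrame | np.ndarray,
                          v_r: fem.MeasurementFrame | np.ndarray) -> np.ndarray:
    """Element-wise normalized difference y_i = (v_i - v_ri) / v_ri."""
    va = v.v if isinstance(v, fem.MeasurementFrame) else np.asarray(v, float)
    vr = v_r.v if isinstance(v_r, fem.MeasurementFrame) else np.asarray(v_r, float)
    if va.shape != vr.shape:
        raise ValueError(f"channel count mismatch: {va.shape} vs {vr.shape}")
    zero = np.flatnonzero(vr == 0)
    if len(zero):
        raise ZeroDivisionError(f"zero reference voltage in channel(s) {zero.tolist()}")
    return (va - vr) / vr


# ---------------------------------------------------------------------------
# Matrix builders


def tsvd_matrix(J: np.ndarray, t: float, grid: PixelGrid | None = None) -> ReconModel:
    """Truncated-pseudoinverse reconstruction matrix.

    Singular values below the threshold ``t`` are discarded from the
    reciprocal; ``t = 0`` gives the Moore-Penrose pseudoinverse.
    """
    if t < 0:
        raise ValueError("threshold must be nonnegative")
    U, s, Vt = np.linalg.svd(J, full_matrices=False)
    inv = np.where(s >= t, np.divide(1.0, s, out=np.zeros_like(s), where=s > 0), 0.0)
    R = (Vt.T * inv) @ U.T
    return ReconModel(R=R, algorithm="tsvd", hyperparameter=float(t),
                      grid=grid if grid is not None else _dummy_grid(J.shape[1]))


def _tsvd_fractional(svd, nu: float, grid: PixelGrid) -> ReconModel:
    """TSVD with a continuous effective component count ``nu``.

    Components ``0 .. floor(nu)-1`` enter at full weight and the marginal
    component at fractional weight ``nu - floor(nu)``; this makes the Noise
    Figure continuous in the truncation parameter so it can be calibrated
    by bisection.
    """
    U, s, Vt = svd
    m = len(s)
    nu = float(np.clip(nu, 0.0, m))
    k = int(np.floor(nu))
    w = np.zeros(m)
    w[:k] = 1.0
    if k < m:
        w[k] = nu - k
    inv = np.where(s > 0, w / np.where(s > 0, s, 1.0), 0.0)
    R = (Vt.T * inv) @ U.T
    t_equiv = s[min(k, m - 1)]
    return ReconModel(R=R, algorithm="tsvd", hyperparameter=float(t_equiv),
                      grid=grid, meta={"effective_components": nu})


def gn_matrix(J: np.ndarray, prior: Prior, lam: float,
              grid: PixelGrid | None = None) -> ReconModel:
    """One-step Gauss-Newton matrix R = (J^T J + lam P)^-1 J^T."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    A = J.T @ J + lam * prior.P
    try:
        R = sla.solve(A, J.T, assume_a="sym")
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"singular regularized system: {err}") from err
    return ReconModel(R=R, algorithm=f"gn-{prior.kind}", hyperparameter=float(lam),
                      grid=grid if grid is not None else _dummy_grid(J.shape[1]))


def noser_prior(J: np.ndarray, exponent: float = 0.5) -> Prior:
    """NOSER prior: diag(J^T J) raised to the given exponent."""
    if exponent < 0:
        raise ValueError("exponent must be nonnegative")
    d = np.einsum("ij,ij->j", J, J)
    if np.any(d == 0):
        warnings.warn("zero Jacobian column yields a zero NOSER diagonal entry",
                      RuntimeWarning, stacklevel=2)
    return Prior(P=np.diag(d ** exponent), kind="noser")


def laplace_prior(grid: PixelGrid) -> Prior:
    """Smoothness prior P = L^T L from the 4-neighbor discrete Laplacian.

    ``L`` has the in-mask neighbor count on the diagonal and -1 for each
    in-mask neighbor (Neumann-style at the mask edge), so constant images
    are in its null space.
    """
    n = grid.n
    idx = np.full((n, n), -1, dtype=int)
    idx[grid.mask] = np.arange(grid.n_masked)
    L = np.zeros((grid.n_masked, grid.n_masked))
    for iy, ix in zip(*np.nonzero(grid.mask)):
        i = idx[iy, ix]
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            jy, jx = iy + dy, ix + dx
            if 0 <= jy < n and 0 <= jx < n and idx[jy, jx] >= 0:
                L[i, i] += 1.0
                L[i, idx[jy, jx]] = -1.0
    return Prior(P=L.T @ L, kind="laplace")


def make_greit_training(model: fem.EITModel, grid: PixelGrid, n: int = 500,
                        target_radius: float = 0.05, desired_radius: float = 0.2,
                        factor: float = 1.1, seed: int = 0) -> GreitTraining:
    """Simulate GREIT training targets at uniform interior positions.

    Each training column pairs the normalized-difference measurement of a
    small conductive disc with the unit-amplitude desired image of radius
    ``desired_radius`` at the same center; both matrices carry the 1/n
    scaling of the defining concatenation.
    """
    if n < 1:
        raise ValueError("need at least one training target")
    rng = np.random.default_rng(seed)
    poly = model.contour.polygon if model.contour is not None else None
    lo = model.mesh.nodes.min(axis=0)
    hi = model.mesh.nodes.max(axis=0)
    centers = []
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > 1000 * n:
            raise RuntimeError("rejection sampling of training centers failed")
        c = rng.uniform(lo, hi)
        if poly is not None:
            t = np.linspace(0, 2 * np.pi, 16, endpoint=False)
            ring = c + 1.05 * target_radius * np.column_stack([np.cos(t), np.sin(t)])
            if not np.all(shapely.contains_xy(poly, ring[:, 0], ring[:, 1])):
                continue
        centers.append(c)
    centers = np.array(centers)
    v_r = fem.solve_forward(model)
    Y = np.empty((len(v_r.v), n))
    X = np.empty((grid.n_masked, n))
    for j, c in enumerate(centers):
        sig = fem.target_sigma(model, c, target_radius, factor)
        v = fem.solve_forward(model, sig)
        Y[:, j] = normalized_difference(v, v_r)
        X[:, j] = grid.render_disc(c, desired_radius)
    return GreitTraining(X_tilde=X / n, Y=Y / n, Sigma_x=None, Sigma_n=None,
                         n=n, seed=seed, centers=centers)


def greit_matrix(J: np.ndarray, training: GreitTraining, lam: float,
                 grid: PixelGrid | None = None) -> ReconModel:
    """GREIT matrix R = X~ Y^T (J Sx J^T + lam Sn)^-1.

    ``Sigma_x`` and ``Sigma_n`` default to identity.  (The defining product
    only makes dimensional sense with ``Y`` transposed; the training
    matrices are concatenations of column vectors.)
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    nch = J.shape[0]
    Sx = training.Sigma_x
    Sn = training.Sigma_n if training.Sigma_n is not None else np.eye(nch)
    JS = J if Sx is None else J @ Sx
    A = JS @ J.T + lam * Sn
    B = training.X_tilde @ training.Y.T
    try:
        R = sla.solve(A.T, B.T, assume_a="sym").T
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"singular GREIT bracket: {err}") from err
    return ReconModel(R=R, algorithm="greit", hyperparameter=float(lam),
                      grid=grid if grid is not None else _dummy_grid(J.shape[1]))


def _dummy_grid(n_pix: int) -> PixelGrid:
    """Full-mask placeholder grid for matrix-level use on toy dimensions."""
    n = int(np.ceil(np.sqrt(n_pix)))
    mask = np.zeros((n, n), dtype=bool)
    mask.ravel()[:n_pix] = True
    return PixelGrid(n=n, mask=mask)


# ---------------------------------------------------------------------------
# Noise figure and calibration


def _nf_closed_form(R: np.ndarray, y_signal: np.ndarray) -> float:
    """Deterministic Noise Figure for unit-variance channel noise.

    NF = [mean|y| / sd(y_noise)] / [mean|x_hat| / sd(x_noise)] with
    sd(y_noise) = 1 per channel and the image-noise sd taken as the RMS of
    per-pixel noise standard deviations, sqrt(mean diag(R R^T)).
    """
    x = R @ y_signal
    mean_x = np.mean(np.abs(x))
    if mean_x == 0:
        raise ValueError("zero image signal; cannot compute a noise figure")
    sd_img = np.sqrt(np.mean(np.einsum("ij,ij->i", R, R)))
    return float(np.mean(np.abs(y_signal)) * sd_img / mean_x)


def noise_figure(recon: ReconModel, model: fem.EITModel,
                 target_radius: float = 0.1, factor: float = 1.1) -> float:
    """Noise amplification of a reconstruction matrix for a central target.

    Signal is the simulated normalized difference of a small disc at the
    grid origin; noise is white with unit variance per channel.  The value
    is computed in closed form (no sampling) and is invariant to rescaling
    the reconstruction matrix or the data.
    """
    v_r, v = fem.simulate_target_frame(model, (0.0, 0.0), target_radius, factor)
    y = normalized_difference(v, v_r)
    return _nf_closed_form(recon.R, y)


def calibrate_hyperparameter(builder, nf_target: float = 0.5, tol: float = 1e-3,
                             y_signal: np.ndarray | None = None,
                             model: fem.EITModel | None = None,
                             bracket: tuple[float, float] = (1e-10, 1e6),
                             max_iter: int = 200) -> ReconModel:
    """Bisect a (log-scale) hyperparameter until the Noise Figure matches.

    ``builder`` maps a positive hyperparameter to a ReconModel whose NF is
    monotone in it (decreasing for regularization weights).  Either a
    precomputed central-target signal ``y_signal`` or a ``model`` to
    simulate it from must be given.
    """
    if y_signal is None:
        if model is None:
            raise ValueError("need y_signal or model")
        v_r, v = fem.simulate_target_frame(model, (0.0, 0.0), 0.1, 1.1)
        y_signal = normalized_difference(v, v_r)

    def nf_of(lam):
        return _nf_closed_form(builder(lam).R, y_signal)

    lo, hi = bracket
    nf_lo, nf_hi = nf_of(lo), nf_of(hi)
    sign = 1.0 if nf_lo >= nf_hi else -1.0  # sign=1: NF decreasing in lam
    if not min(nf_lo, nf_hi) <= nf_target <= max(nf_lo, nf_hi):
        raise ValueError(
            f"noise-figure target {nf_target} not bracketed: "
            f"NF({lo:g}) = {nf_lo:.4g}, NF({hi:g}) = {nf_hi:.4g}")
    llo, lhi = np.log10(lo), np.log10(hi)
    lam, nf = hi, nf_hi
    for _ in range(max_iter):
        lmid = 0.5 * (llo + lhi)
        lam = 10.0 ** lmid
        nf = nf_of(lam)
        if abs(nf - nf_target) <= tol:
            break
        if (nf > nf_target) == (sign > 0):
            llo = lmid
        else:
            lhi = lmid
    else:
        raise RuntimeError(f"calibration did not converge: NF = {nf:.4g}")
    out = builder(lam)
    return dataclasses.replace(out, achieved_nf=float(nf))


def _calibrate_tsvd(svd, grid: PixelGrid, y_signal: np.ndarray,
                    nf_target: float, tol: float, max_iter: int = 200) -> ReconModel:
    """Bisection on the continuous effective component count."""
    m = len(svd[1])

    def nf_of(nu):
        return _nf_closed_form(_tsvd_fractional(svd, nu, grid).R, y_signal)

    # NF is not monotone over the full range: it falls while the leading
    # singular vectors sharpen the target, then rises as noisy components
    # enter.  Calibrate on the physical rising branch (less truncation =
    # more noise) starting from the integer-scan minimum.
    coarse = [nf_of(float(k)) for k in range(1, m + 1)]
    lo = float(1 + int(np.argmin(coarse)))
    hi = float(m)
    nf_lo, nf_hi = coarse[int(lo) - 1], coarse[-1]
    if not nf_lo <= nf_target <= nf_hi:
        raise ValueError(
            f"noise-figure target {nf_target} not bracketed by TSVD: "
            f"NF({lo:g} comps) = {nf_lo:.4g}, NF({hi:g} comps) = {nf_hi:.4g}")
    nu, nf = hi, nf_hi
    for _ in range(max_iter):
        nu = 0.5 * (lo + hi)
        nf = nf_of(nu)
        if abs(nf - nf_target) <= tol:
            break
        if nf < nf_target:
            lo = nu
        else:
            hi = nu
    else:
        raise RuntimeError(f"TSVD calibration did not converge: NF = {nf:.4g}")
    out = _tsvd_fractional(svd, nu, grid)
    return dataclasses.replace(out, achieved_nf=float(nf))


ALGORITHMS = ("tsvd", "greit", "gn-noser", "gn-laplace")


def build_recon_model(model: fem.EITModel, grid: PixelGrid | None = None,
                      algorithm: str = "greit", nf_target: float = 0.5,
                      nf_tol: float = 1e-3, noser_exponent: float = 0.5,
                      greit_n: int = 1500, greit_target_radius: float = 0.05,
                      greit_desired_radius: float = 0.2, greit_factor: float = 1.1,
                      seed: int = 0) -> ReconModel:
    """Build and NF-calibrate a reconstruction matrix for a forward model.

    The Jacobian is computed on the model's mesh, aggregated onto the pixel
    grid (32 x 32 by default, masked to the model contour), and the chosen
    algorithm's hyperparameter is bisected to the target Noise Figure.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    if grid is None:
        if model.contour is None:
            raise ValueError("model has no contour; pass a PixelGrid explicitly")
        grid = PixelGrid.from_contour(model.contour)
    J_elem = fem.compute_jacobian(model).matrix
    J = grid.aggregate_jacobian(J_elem, model.mesh)
    # mask pixels the mesh does not reach (contour/mesh boundary slack)
    covered = np.abs(J).sum(axis=0) > 0
    if not covered.all():
        grid = grid.restrict(covered)
        J = J[:, covered]
    v_r, v = fem.simulate_target_frame(model, (0.0, 0.0), 0.1, 1.1)
    y_signal = normalized_difference(v, v_r)
    if algorithm == "tsvd":
        svd = np.linalg.svd(J, full_matrices=False)
        out = _calibrate_tsvd(svd, grid, y_signal, nf_target, nf_tol)
    elif algorithm == "greit":
        training = make_greit_training(model, grid, n=greit_n,
                                       target_radius=greit_target_radius,
                                       desired_radius=greit_desired_radius,
                                       factor=greit_factor, seed=seed)
        out = calibrate_hyperparameter(
            lambda lam: greit_matrix(J, training, lam, grid),
            nf_target=nf_target, tol=nf_tol, y_signal=y_signal)
    else:
        prior = (noser_prior(J, noser_exponent) if algorithm == "gn-noser"
                 else laplace_prior(grid))
        out = calibrate_hyperparameter(
            lambda lam: gn_matrix(J, prior, lam, grid),
            nf_target=nf_target, tol=nf_tol, y_signal=y_signal)
    meta = dict(out.meta)
    meta.update(algorithm=algorithm, seed=seed, nf_target=nf_target)
    return dataclasses.replace(out, algorithm=algorithm, meta=meta)


def reconstruct(recon: ReconModel, y: np.ndarray) -> np.ndarray:
    """Apply the reconstruction matrix; returns a dense masked image."""
    y = np.asarray(y, dtype=float)
    if y.shape != (recon.R.shape[1],):
        raise ValueError(f"expected {recon.R.shape[1]} channels, got {y.shape}")
    return recon.grid.to_image(recon.R @ y)


# ---------------------------------------------------------------------------
# Persistence: matrix in an .npz container plus a YAML sidecar.


def save_recon(recon: ReconModel, path: str | pathlib.Path) -> None:
    path = pathlib.Path(path)
    np.savez_compressed(path.with_suffix(".npz"), R=recon.R, mask=recon.grid.mask)
    sidecar = {
        "algorithm": recon.algorithm,
        "hyperparameter": float(recon.hyperparameter),
        "achieved_nf": None if recon.achieved_nf is None else float(recon.achieved_nf),
        "grid_n": int(recon.grid.n),
        "meta": {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                 for k, v in recon.meta.items()},
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))


def load_recon(path: str | pathlib.Path) -> ReconModel:
    path = pathlib.Path(path)
    data = np.load(path.with_suffix(".npz"))
    side = yaml.safe_load(path.with_suffix(".yaml").read_text())
    grid = PixelGrid(n=side["grid_n"], mask=data["mask"].astype(bool))
    return ReconModel(R=data["R"], algorithm=side["algorithm"],
                      hyperparameter=side["hyperparameter"], grid=grid,
                      achieved_nf=side["achieved_nf"], meta=side.get("meta", {}))
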