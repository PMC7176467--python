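"""2-D complete-electrode-model (CEM) finite-element forward solver.

The body cross-section is meshed with first-order triangles; electrodes are
boundary arcs with a contact impedance, modelled with the complete electrode
model (shunting + contact layer).  The solver returns electrode-pair
voltages under a stimulation pattern, and the measurement Jacobian is
computed by the adjoint (sensitivity-theorem) method:

    d(v_channel)/d(sigma_e) = - \\int_e grad(u_drive) . grad(u_meas) dx

where ``u_meas`` is the CEM solution driven through the measurement pair.
Meshing uses a graded boundary subdivision (finer under and near the
electrodes), an interior hexagonal lattice, Delaunay triangulation, and a
containment filter, giving a conforming boundary-fitted mesh without an
external mesh generator.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
import shapely
import shapely.geometry as geom
from scipy.spatial import Delaunay, cKDTree

from eitshape.shapes import Contour

__all__ = [
    "ElectrodeSet",
    "Mesh",
    "MeshError",
    "StimPattern",
    "EITModel",
    "MeasurementFrame",
    "Jacobian",
    "place_electrodes",
    "build_mesh",
    "adjacent_pattern",
    "build_model",
    "solve_forward",
    "compute_jacobian",
    "simulate_target_frame",
    "simulate_lung_frame",
    "add_noise",
]


class MeshError(RuntimeError):
    """Mesher failure; try changing the contour point count or max_area."""


@dataclasses.dataclass(frozen=True)
class ElectrodeSet:
    """Electrode arcs on a contour, in arc-length coordinates.

    ``arcs[l] = (start, end)`` along the boundary (measured from vertex 0,
    counter-clockwise); centers are equidistant along the perimeter and the
    first electrode is centered on the boundary point of maximum x.
    """

    count: int
    arcs: np.ndarray          # (count, 2) arc-length start/end
    contact_impedance: np.ndarray  # (count,)
    perimeter: float


@dataclasses.dataclass(frozen=True)
class StimPattern:
    """Current-drive pairs and, per drive, voltage-measurement pairs."""

    drive_pairs: tuple[tuple[int, int], ...]
    meas_pairs: tuple[tuple[tuple[int, int], ...], ...]  # per drive

    @property
    def n_channels(self) -> int:
        return sum(len(m) for m in self.meas_pairs)

    def channels(self) -> list[tuple[int, int, int]]:
        """Flattened (drive_index, plus_electrode, minus_electrode) list."""
        out = []
        for d, pairs in enumerate(self.meas_pairs):
            out.extend((d, p, q) for p, q in pairs)
        return out


@dataclasses.dataclass
class Mesh:
    """Conforming triangulation with labelled boundary edges.

    ``boundary_edges`` rows are ``(node_i, node_j, electrode_label)`` with
    label ``-1`` for inter-electrode gap edges.
    """

    nodes: np.ndarray       # (N, 2)
    elements: np.ndarray    # (M, 3) CCW triangles
    boundary_edges: np.ndarray  # (B, 3) int

    _areas: np.ndarray | None = dataclasses.field(default=None, repr=False)
    _grads: np.ndarray | None = dataclasses.field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def element_areas(self) -> np.ndarray:
        if self._areas is None:
            self._compute_geometry()
        return self._areas

    @property
    def element_grads(self) -> np.ndarray:
        """(M, 3, 2) gradients of the three nodal hat functions per element."""
        if self._grads is None:
            self._compute_geometry()
        return self._grads

    @property
    def centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def _compute_geometry(self) -> None:
        p = self.nodes[self.elements]  # (M, 3, 2)
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        det = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
        self._areas = 0.5 * det
        # grad of hat_i: rotate opposite edge by 90deg / (2A)
        e0 = p[:, 2] - p[:, 1]
        e1 = p[:, 0] - p[:, 2]
        e2 = p[:, 1] - p[:, 0]
        g = np.empty((len(p), 3, 2))
        for i, e in enumerate((e0, e1, e2)):
            g[:, i, 0] = -e[:, 1]
            g[:, i, 1] = e[:, 0]
        self._grads = g / (2.0 * self._areas)[:, None, None]


@dataclasses.dataclass(frozen=True)
class EITModel:
    """Mesh + electrodes + stimulation pattern + reference conductivity."""

    mesh: Mesh
    electrodes: ElectrodeSet
    pattern: StimPattern
    sigma_ref: np.ndarray
    contour: Contour | None = None

    def __post_init__(self):
        if np.any(self.sigma_ref <= 0):
            raise ValueError("sigma_ref must be positive elementwise")


@dataclasses.dataclass(frozen=True)
class MeasurementFrame:
    """One vector of electrode-pair voltages (one entry per channel)."""

    v: np.ndarray
    channels: tuple[tuple[int, int, int], ...]  # (drive, plus, minus)


@dataclasses.dataclass(frozen=True)
class Jacobian:
    """Channel x element sensitivity matrix J_ij = dy_i / dx_j.

    ``normalized=True`` means rows are divided by the reference voltage and
    columns multiplied by the reference conductivity, i.e. the Jacobian of
    the normalized difference y = (v - v_r)/v_r with respect to the
    fractional conductivity change x = d(sigma)/sigma_ref.
    """

    matrix: np.ndarray
    normalized: bool


# ---------------------------------------------------------------------------
# Electrode placement and meshing


def place_electrodes(contour: Contour, count: int = 16, coverage: float = 0.5,
                     contact_impedance: float = 0.01) -> ElectrodeSet:
    """Equidistant electrode arcs along the perimeter.

    Each electrode spans ``coverage`` of its share of the perimeter; the
    first electrode center sits at the boundary vertex of maximum x (which
    is vertex 0 for normalized contours).
    """
    if count < 2:
        raise ValueError("need at least 2 electrodes")
    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0, 1)")
    P = contour.perimeter
    pts = contour.points
    seglen = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    s0 = cum[int(np.argmax(pts[:, 0]))]
    pitch = P / count
    half = coverage * pitch / 2.0
    centers = np.mod(s0 + pitch * np.arange(count), P)
    arcs = np.column_stack([centers - half, centers + half])
    return ElectrodeSet(count=count, arcs=arcs,
                        contact_impedance=np.full(count, float(contact_impedance)),
                        perimeter=P)


def _graded_fill(length: float, h_end: float, h_max: float, growth: float = 1.4) -> np.ndarray:
    """Interior subdivision points of a gap of given length, graded from both ends."""
    if length <= max(h_end, 1e-12):
        return np.array([])
    left, s, h = [], 0.0, h_end
    while s + h < length / 2:
        s += h
        left.append(s)
        h = min(h * growth, h_max)
    right = [length - s for s in left][::-1]
    mid_lo = left[-1] if left else 0.0
    mid_hi = right[0] if right else length
    n_mid = max(int(np.floor((mid_hi - mid_lo) / h_max)), 1)
    mid = list(np.linspace(mid_lo, mid_hi, n_mid + 1)[1:-1])
    return np.array(left + mid + right)


def _boundary_nodes(contour: Contour, electrodes: ElectrodeSet,
                    h: float) -> tuple[np.ndarray, np.ndarray]:
    """Arc-length positions of boundary nodes and per-node positions array."""
    P = electrodes.perimeter
    arcs = np.mod(electrodes.arcs, P)
    h_e = h / 2.0
    positions = []
    # electrode arcs: endpoints plus >= 2 subdivisions at spacing <= h/2
    for (a, b) in arcs:
        length = (b - a) % P
        n_sub = max(2, int(np.ceil(length / h_e)))
        positions.extend(np.mod(a + length * np.arange(n_sub + 1) / n_sub, P))
    # gaps between consecutive electrodes, graded from the electrode edge size
    order = np.argsort(np.mod(arcs[:, 0], P))
    for i in range(electrodes.count):
        l0, l1 = order[i], order[(i + 1) % electrodes.count]
        gap_start, gap_end = arcs[l0, 1] % P, arcs[l1, 0] % P
        gap_len = (gap_end - gap_start) % P
        a_len = (arcs[l0, 1] - arcs[l0, 0]) % P
        h_end = min(h_e, a_len / 2.0)
        fill = _graded_fill(gap_len, h_end, h)
        positions.extend(np.mod(gap_start + fill, P))
    positions = np.sort(np.mod(np.asarray(positions), P))
    # dedupe near-coincident positions
    keep = np.concatenate([[True], np.diff(positions) > 1e-9 * P])
    positions = positions[keep]
    if (positions[0] + P - positions[-1]) <= 1e-9 * P:
        positions = positions[:-1]
    return positions, contour.point_at_arclength(positions)


def _interior_points(contour: Contour, boundary_xy: np.ndarray,
                     boundary_spacing: np.ndarray, h: float,
                     clearance_factor: float = 1.0) -> np.ndarray:
    """Inner offset ring + hexagonal lattice.

    An inner ring point sits one local boundary spacing inward of each
    boundary node; this guarantees an interior point near every boundary
    chord (Delaunay would otherwise span collinear boundary triples with
    zero-area slivers wherever the boundary is subdivided finer than the
    interior lattice, e.g. under small electrodes).
    """
    poly = contour.polygon
    bxy = boundary_xy
    nb = len(bxy)
    tang = bxy[(np.arange(nb) + 1) % nb] - bxy[(np.arange(nb) - 1) % nb]
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    inward = np.column_stack([-tang[:, 1], tang[:, 0]])  # CCW boundary
    depth = np.minimum(boundary_spacing, h) * 0.9
    ring = bxy + inward * depth[:, None]
    ok = shapely.contains_xy(poly, ring[:, 0], ring[:, 1])
    ring, ring_sp = ring[ok], np.minimum(boundary_spacing, h)[ok]
    # greedy thinning of the ring where it self-collides (concavities)
    keep = np.ones(len(ring), dtype=bool)
    tree_b = cKDTree(bxy)
    if len(ring):
        tree_r = cKDTree(ring)
        for i in range(len(ring)):
            if not keep[i]:
                continue
            for j in tree_r.query_ball_point(ring[i], 0.55 * ring_sp[i]):
                if j > i:
                    keep[j] = False
    ring, ring_sp = ring[keep], ring_sp[keep]

    lo = contour.points.min(axis=0)
    hi = contour.points.max(axis=0)
    dy = h * np.sqrt(3) / 2
    rows = np.arange(lo[1] - h, hi[1] + h, dy)
    pts = []
    for i, y in enumerate(rows):
        off = (h / 2) if i % 2 else 0.0
        xs = np.arange(lo[0] - h + off, hi[0] + h, h)
        pts.append(np.column_stack([xs, np.full_like(xs, y)]))
    pts = np.vstack(pts)
    pts = pts[shapely.contains_xy(poly, pts[:, 0], pts[:, 1])]
    d, _ = tree_b.query(pts)
    pts = pts[d > 0.75 * h * clearance_factor]
    if len(ring):
        d, _ = cKDTree(ring).query(pts)
        pts = pts[d > 0.65 * h * clearance_factor]
        pts = np.vstack([ring, pts])
    return pts


def _repair_slivers(nodes: np.ndarray, elems: np.ndarray,
                    tol: float = 1e-12) -> np.ndarray:
    """Remove (near-)zero-area triangles from collinear boundary triples.

    Three boundary nodes on one straight polygon segment can appear as a
    degenerate Delaunay triangle.  Each such sliver ``(a, b, c)`` (``b``
    the middle node) is dropped; if a kept triangle carries the long edge
    ``(a, c)``, it is split so ``b`` stays connected.
    """
    p = nodes[elems]
    two_a = np.abs((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                   - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0]))
    bad = two_a < tol
    if not bad.any():
        return elems
    slivers = elems[bad]
    out = [t for t in elems[~bad]]
    for tri_ in slivers:
        q = nodes[tri_]
        d01 = np.linalg.norm(q[0] - q[1])
        d12 = np.linalg.norm(q[1] - q[2])
        d02 = np.linalg.norm(q[0] - q[2])
        longest = int(np.argmax([d12, d02, d01]))  # index of opposite (middle) node
        b = tri_[longest]
        a, c = [v for i, v in enumerate(tri_) if i != longest]
        host = None
        for i, t in enumerate(out):
            s = set(t)
            if a in s and c in s:
                host = i
                break
        if host is None:
            continue
        r = [v for v in out[host] if v not in (a, c)][0]
        del out[host]
        out.append(np.array([a, b, r]))
        out.append(np.array([b, c, r]))
    return np.array(out)


def build_mesh(contour: Contour, electrodes: ElectrodeSet, max_area: float = 0.004) -> Mesh:
    """Boundary-fitted triangulation with electrode-conforming edges.

    Boundary vertices are placed at every electrode arc endpoint, arcs are
    subdivided to at least two edges at half the global target size, gaps
    are graded, and the interior is filled with a hexagonal lattice before
    Delaunay triangulation.  Triangles whose centroid falls outside the
    boundary-node polygon are discarded.
    """
    h = float(np.sqrt(4.0 * max_area / np.sqrt(3.0)))
    positions, bxy = _boundary_nodes(contour, electrodes, h)
    gaps = np.diff(np.concatenate([positions, [positions[0] + electrodes.perimeter]]))
    spacing = np.minimum(gaps, np.roll(gaps, 1))
    for attempt in range(3):
        ipts = _interior_points(contour, bxy, spacing, h,
                                clearance_factor=1.0 + 0.15 * attempt)
        nodes = np.vstack([bxy, ipts])
        tri = Delaunay(nodes)
        elems = tri.simplices
        cent = nodes[elems].mean(axis=1)
        node_poly = geom.Polygon(bxy)
        keep = shapely.contains_xy(node_poly, cent[:, 0], cent[:, 1])
        elems = _repair_slivers(nodes, elems[keep])
        # orient CCW
        p = nodes[elems]
        det = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
               - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0]))
        flip = det < 0
        elems[flip] = elems[flip][:, [0, 2, 1]]
        # every boundary chord must be an edge of some kept triangle
        edge_set = set()
        for t in elems:
            for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
                edge_set.add((min(a, b), max(a, b)))
        nb = len(bxy)
        chords = [(i, (i + 1) % nb) for i in range(nb)]
        if all((min(a, b), max(a, b)) in edge_set for a, b in chords):
            break
    else:
        raise MeshError(
            "could not recover the boundary in the triangulation; "
            "try a different contour point count or a smaller max_area")
    # label boundary edges by electrode membership of the edge midpoint arc
    P = electrodes.perimeter
    arcs = electrodes.arcs
    labels = np.full(nb, -1, dtype=int)
    mids = np.mod((positions + np.roll(positions, -1)) / 2.0, P)
    mids[-1] = np.mod((positions[-1] + positions[0] + P) / 2.0, P)
    for l, (a, b) in enumerate(arcs):
        rel = np.mod(mids - a, P)
        labels[rel < np.mod(b - a, P) - 1e-12] = l
    boundary_edges = np.column_stack(
        [np.arange(nb), np.roll(np.arange(nb), -1), labels]).astype(int)
    mesh = Mesh(nodes=nodes, elements=np.ascontiguousarray(elems),
                boundary_edges=boundary_edges)
    for l in range(electrodes.count):
        if np.count_nonzero(labels == l) < 2:
            raise MeshError(f"electrode {l} has fewer than 2 boundary edges")
    if np.any(mesh.element_areas <= 0):
        raise MeshError("degenerate (zero-area) element produced")
    return mesh


# ---------------------------------------------------------------------------
# Stimulation patterns


def adjacent_pattern(n_elec: int = 16, skip: int = 0) -> StimPattern:
    """Skip-m drive and measurement pattern, excluding driven electrodes.

    ``skip=0`` is the de-facto standard adjacent-adjacent pattern: for 16
    electrodes it yields 16 x 13 = 208 channels.
    """
    step = skip + 1
    drives = [(j, (j + step) % n_elec) for j in range(n_elec)]
    meas = []
    for a, b in drives:
        pairs = []
        for m in range(n_elec):
            p, q = m, (m + step) % n_elec
            if {p, q} & {a, b}:
                continue
            pairs.append((p, q))
        meas.append(tuple(pairs))
    return StimPattern(drive_pairs=tuple(drives), meas_pairs=tuple(meas))


def build_model(contour: Contour, n_elec: int = 16, coverage: float = 0.5,
                contact_impedance: float = 0.01, max_area: float = 0.004,
                pattern: StimPattern | None = None,
                sigma_ref: float | np.ndarray = 1.0) -> EITModel:
    """Convenience constructor: electrodes + mesh + pattern + reference sigma."""
    electrodes = place_electrodes(contour, n_elec, coverage, contact_impedance)
    mesh = build_mesh(contour, electrodes, max_area)
    if pattern is None:
        pattern = adjacent_pattern(n_elec)
    sig = np.broadcast_to(np.asarray(sigma_ref, dtype=float), (mesh.n_elements,)).copy()
    return EITModel(mesh=mesh, electrodes=electrodes, pattern=pattern,
                    sigma_ref=sig, contour=contour)


# ---------------------------------------------------------------------------
# CEM assembly and solution


def _assemble(model: EITModel, sigma: np.ndarray):
    """CEM system matrix with a zero-mean electrode-potential constraint.

    Unknowns: nodal potentials u (N), electrode potentials U (L), one
    Lagrange multiplier for sum(U) = 0.
    """
    mesh, elset = model.mesh, model.electrodes
    N, L = mesh.n_nodes, elset.count
    elems = mesh.elements
    A = mesh.element_areas
    G = mesh.element_grads  # (M, 3, 2)
    # stiffness: K_ab = sigma * area * g_a . g_b
    Ke = sigma[:, None, None] * A[:, None, None] * np.einsum("mad,mbd->mab", G, G)
    rows = np.repeat(elems, 3, axis=1).reshape(-1, 3, 3).transpose(0, 2, 1).ravel()
    cols = np.repeat(elems, 3, axis=1).reshape(-1, 3, 3).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(N, N))

    az_r, az_c, az_v = [], [], []
    w_r, w_c, w_v = [], [], []
    Dd = np.zeros(L)
    nodes = mesh.nodes
    for i, j, lab in mesh.boundary_edges:
        if lab < 0:
            continue
        z = elset.contact_impedance[lab]
        Le = np.linalg.norm(nodes[j] - nodes[i])
        f = Le / z
        az_r += [i, i, j, j]
        az_c += [i, j, i, j]
        az_v += [f / 3, f / 6, f / 6, f / 3]
        w_r += [i, j]
        w_c += [lab, lab]
        w_v += [f / 2, f / 2]
        Dd[lab] += f
    AZ = sp.coo_matrix((az_v, (az_r, az_c)), shape=(N, N))
    W = sp.coo_matrix((w_v, (w_r, w_c)), shape=(N, L))
    D = sp.diags(Dd)
    ones = sp.coo_matrix((np.ones(L), (np.arange(L), np.zeros(L, int))), shape=(L, 1))
    zeroN = sp.coo_matrix((N, 1))
    S = sp.bmat([[K + AZ, -W, zeroN],
                 [-W.T, D, ones],
                 [zeroN.T, ones.T, None]], format="csc")
    return S, N, L


def _solve_fields(model: EITModel, sigma: np.ndarray,
                  pairs: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Solve the CEM for unit-current injection through each electrode pair.

    Returns nodal potentials (N, n_pairs) and electrode potentials
    (L, n_pairs).
    """
    S, N, L = _assemble(model, sigma)
    rhs = np.zeros((N + L + 1, len(pairs)))
    for c, (a, b) in enumerate(pairs):
        rhs[N + a, c] = 1.0
        rhs[N + b, c] = -1.0
    try:
        lu = spla.splu(S)
    except RuntimeError as err:  # pragma: no cover - disconnected mesh
        raise RuntimeError(f"singular CEM system (disconnected mesh?): {err}") from err
    sol = lu.solve(rhs)
    return sol[:N], sol[N:N + L]


def solve_forward(model: EITModel, sigma: np.ndarray | None = None) -> MeasurementFrame:
    """Electrode-pair voltages for the model's stimulation pattern.

    The system is grounded by constraining the electrode potentials to zero
    mean; measured channels are potential differences, so the gauge choice
    does not affect them.  Voltages scale as 1/c when sigma is scaled by c.
    """
    if sigma is None:
        sigma = model.sigma_ref
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive elementwise")
    _, U = _solve_fields(model, sigma, list(model.pattern.drive_pairs))
    chans = model.pattern.channels()
    v = np.array([U[p, d] - U[q, d] for d, p, q in chans])
    return MeasurementFrame(v=v, channels=tuple(chans))


def compute_jacobian(model: EITModel, normalized: bool = True) -> Jacobian:
    """Adjoint-method sensitivity of every channel to every element.

    Drive and measurement fields are CEM solutions with unit current through
    the respective pairs; the raw sensitivity of channel (d; p, q) to
    element e is ``-area_e * grad(u_d) . grad(u_pq)`` evaluated at
    ``sigma_ref``.  With ``normalized=True`` (the default, matching
    element-wise normalized difference imaging) rows are divided by the
    reference channel voltage and columns multiplied by the reference
    conductivity.
    """
    pairs = list(model.pattern.drive_pairs)
    pair_index = {p: i for i, p in enumerate(pairs)}
    chans = model.pattern.channels()
    for _, p, q in chans:
        if (p, q) not in pair_index and (q, p) not in pair_index:
            pairs.append((p, q))
            pair_index[(p, q)] = len(pairs) - 1
    u, U = _solve_fields(model, model.sigma_ref, pairs)
    mesh = model.mesh
    # per-element gradient of each field: (n_pairs, M, 2)
    ue = u[mesh.elements]  # (M, 3, n_pairs)
    grads = np.einsum("mad,maf->fmd", mesh.element_grads, ue)
    J = np.empty((len(chans), mesh.n_elements))
    A = mesh.element_areas
    for i, (d, p, q) in enumerate(chans):
        if (p, q) in pair_index:
            gm = grads[pair_index[(p, q)]]
            sign = 1.0
        else:
            gm = grads[pair_index[(q, p)]]
            sign = -1.0
        J[i] = -sign * A * np.einsum("md,md->m", grads[d], gm)
    if normalized:
        drv = model.pattern.drive_pairs
        v_r = np.array([U[p, pair_index[drv[d]]] - U[q, pair_index[drv[d]]]
                        for d, p, q in chans])
        if np.any(v_r == 0):
            raise ZeroDivisionError("zero reference channel; cannot normalize Jacobian")
        J = (J * model.sigma_ref[None, :]) / v_r[:, None]
    return Jacobian(matrix=J, normalized=normalized)


# ---------------------------------------------------------------------------
# Simulation helpers


def _require_inside(model: EITModel, pts: np.ndarray, what: str) -> None:
    if model.contour is None:
        return
    poly = model.contour.polygon
    if not np.all(shapely.contains_xy(poly, pts[:, 0], pts[:, 1])):
        raise ValueError(f"{what} extends outside the body contour")


def target_sigma(model: EITModel, center, radius: float, factor: float) -> np.ndarray:
    """sigma_ref with elements whose centroid lies in the disc scaled by factor.

    If the disc is smaller than the local mesh and captures no centroid, the
    single nearest element is perturbed instead.
    """
    center = np.asarray(center, dtype=float)
    ring = center + radius * np.column_stack(
        [np.cos(np.linspace(0, 2 * np.pi, 16, endpoint=False)),
         np.sin(np.linspace(0, 2 * np.pi, 16, endpoint=False))])
    _require_inside(model, ring, "target disc")
    cent = model.mesh.centroids
    mask = np.linalg.norm(cent - center, axis=1) <= radius
    if not mask.any():
        mask = np.zeros(len(cent), dtype=bool)
        mask[np.argmin(np.linalg.norm(cent - center, axis=1))] = True
    sigma = model.sigma_ref.copy()
    sigma[mask] *= factor
    return sigma


def simulate_target_frame(model: EITModel, center, radius: float,
                          factor: float) -> tuple[MeasurementFrame, MeasurementFrame]:
    """(v_r, v): homogeneous reference and small-disc-perturbed frames."""
    v_r = solve_forward(model, model.sigma_ref)
    v = solve_forward(model, target_sigma(model, center, radius, factor))
    return v_r, v


def simulate_lung_frame(model: EITModel, lungs, ratio: float = 0.1875
                        ) -> tuple[MeasurementFrame, MeasurementFrame]:
    """(v_r, v) with lung-region conductivity = ratio x background.

    ``lungs`` is an iterable of polygons (Contour or shapely Polygon);
    elements are assigned by centroid membership.
    """
    polys = [l.polygon if isinstance(l, Contour) else geom.Polygon(l) for l in lungs]
    for p in polys:
        _require_inside(model, np.asarray(p.exterior.coords), "lung polygon")
    cent = model.mesh.centroids
    mask = np.zeros(model.mesh.n_elements, dtype=bool)
    for p in polys:
        mask |= shapely.contains_xy(p, cent[:, 0], cent[:, 1])
    sigma = model.sigma_ref.copy()
    sigma[mask] *= ratio
    v_r = solve_forward(model, model.sigma_ref)
    v = solve_forward(model, sigma)
    return v_r, v


def write_frame_csv(frame: MeasurementFrame, path) -> None:
    """One measurement channel per row: ``channel,value``."""
    rows = np.column_stack([np.arange(len(frame.v)), frame.v])
    np.savetxt(path, rows, delimiter=",", header="channel,value", comments="",
               fmt=("%d", "%.12g"))


def read_frame_csv(path, pattern: StimPattern | None = None) -> MeasurementFrame:
    data = np.genfromtxt(path, delimiter=",", names=True)
    v = np.atleast_1d(data["value"])
    chans = tuple(pattern.channels()) if pattern is not None else \
        tuple((-1, -1, -1) for _ in v)
    if pattern is not None and len(v) != pattern.n_channels:
        raise ValueError(f"frame has {len(v)} channels, pattern expects "
                         f"{pattern.n_channels}")
    return MeasurementFrame(v=v, channels=chans)


def export_mesh_csv(mesh: Mesh, nodes_path, elements_path) -> None:
    np.savetxt(nodes_path, mesh.nodes, delimiter=",", header="x,y",
               comments="", fmt="%.12g")
    np.savetxt(elements_path, mesh.elements, delimiter=",", header="n1,n2,n3",
               comments="", fmt="%d")


def write_msh22(mesh: Mesh, path) -> None:
    """Gmsh MSH 2.2 ASCII export (triangles; boundary edges with their labels)."""
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes", str(mesh.n_nodes)]
    for i, (x, y) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {x:.12g} {y:.12g} 0")
    lines += ["$EndNodes", "$Elements",
              str(mesh.n_elements + len(mesh.boundary_edges))]
    eid = 1
    for i, j, lab in mesh.boundary_edges:
        # element type 1 = 2-node line; physical tag = electrode label + 1 (0 = gap)
        lines.append(f"{eid} 1 2 {lab + 1} {lab + 1} {i + 1} {j + 1}")
        eid += 1
    for a, b, c in mesh.elements:
        lines.append(f"{eid} 2 2 0 0 {a + 1} {b + 1} {c + 1}")
        eid += 1
    lines.append("$EndElements")
    import pathlib
    pathlib.Path(path).write_text("\n".join(lines) + "\n")


def add_noise(frame: MeasurementFrame, snr: float,
              seed: int | np.random.Generator) -> MeasurementFrame:
    """Additive white Gaussian noise at the given signal-to-noise ratio.

    Noise standard deviation is ``norm(v) / (sqrt(n_channels) * snr)``, i.e.
    snr is the ratio of RMS signal to RMS noise.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = np.linalg.norm(frame.v) / (np.sqrt(len(frame.v)) * snr)
    return MeasurementFrame(v=frame.v + rng.normal(0.0, sd, size=len(frame.v)),
                            channels=frame.channels)
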