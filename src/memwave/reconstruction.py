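"""Membrane reconstruction: locate the cell surface in a 4D fluorescence stack,
triangulate it, and pull per-node signal time series off the voxel data.

The cell is assumed immobile (actin polymerization inhibited), so a single
triangulated mesh represents the membrane for all time points.  The membrane is
found per ray direction as the radial argmax of the temporal standard deviation
of the fluorescence — the membrane-bound reporter fluctuates, the cytosol much
less.  The resulting star-shaped point cloud is triangulated in direction space
(spherical Delaunay via the convex hull of the unit ray directions) and
resampled so the mean area per node is ~0.3 um^2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import ConvexHull, QhullError, cKDTree

__all__ = [
    "CellMesh",
    "SignalField",
    "StackMetadata",
    "ReconstructionError",
    "TriangulationError",
    "fibonacci_directions",
    "locate_membrane",
    "triangulate_surface",
    "smooth_nodes",
    "sample_signal",
    "detect_contact_perimeter",
    "save_cell",
    "load_cell",
]

DEFAULT_NODE_AREA = 0.3  # um^2, mesh-resolution contract


class ReconstructionError(RuntimeError):
    """Membrane could not be located reliably in the stack."""


class TriangulationError(RuntimeError):
    """Point cloud is not a star-shaped surface."""


# ---------------------------------------------------------------------------
# stack metadata
# ---------------------------------------------------------------------------

@dataclass
class StackMetadata:
    """Voxel geometry of a 4D (t, z, y, x) fluorescence stack.

    Defaults follow spinning-disc confocal acquisition of small adherent
    cells: lateral sampling 0.2666 um, axial 0.5 um, one volume per 10 s.
    """

    dx: float = 0.2666
    dy: float = 0.2666
    dz: float = 0.5
    dt: float = 10.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (x, y, z) of voxel (0,0,0), um
    shape: tuple[int, ...] | None = None  # (nz, ny, nx) if prescribed

    def __post_init__(self) -> None:
        if min(self.dx, self.dy, self.dz) <= 0 or self.dt <= 0:
            raise ValueError("voxel spacings and dt must be strictly positive")

    @property
    def spacing(self) -> np.ndarray:
        """(dz, dy, dx) in um, matching stack axis order."""
        return np.array([self.dz, self.dy, self.dx])


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------

@dataclass
class CellMesh:
    """Closed triangulated membrane surface with spherical node coordinates.

    ``theta`` is the latitude in [-pi/2, pi/2] with -pi/2 at the ventral
    center; ``phi`` the azimuth in [-pi, pi].  Nodes on the substrate-adhered
    ventral disc are flagged ``adherent``; ``theta_adh`` is the latitude of
    the contact perimeter (NaN when the cell does not touch the substrate).
    """

    nodes: np.ndarray           # (N, 3) positions, um
    triangles: np.ndarray       # (M, 3) int node indices, outward-oriented
    center: np.ndarray          # (3,)
    theta: np.ndarray           # (N,) latitude, rad
    phi: np.ndarray             # (N,) azimuth, rad
    adherent: np.ndarray        # (N,) bool
    theta_adh: float = float("nan")
    node_areas: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, float)
        self.triangles = np.asarray(self.triangles, int)
        self.center = np.asarray(self.center, float)
        self.adherent = np.asarray(self.adherent, bool)
        if self.node_areas is None:
            self.node_areas = self._compute_node_areas()

    # -- geometry ----------------------------------------------------------

    def triangle_areas(self) -> np.ndarray:
        a, b, c = (self.nodes[self.triangles[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def _compute_node_areas(self) -> np.ndarray:
        # barycentric lumping: one third of each incident triangle
        areas = np.zeros(len(self.nodes))
        ta = self.triangle_areas()
        for i in range(3):
            np.add.at(areas, self.triangles[:, i], ta / 3.0)
        return areas

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def area_total(self) -> float:
        """Total membrane area A_mem (um^2)."""
        return float(self.triangle_areas().sum())

    @property
    def area_adherent(self) -> float:
        """Ventral (adhered) membrane area A_adh (um^2).

        Summed area of triangles all of whose vertices are adherent; with the
        contact-perimeter ring flagged adherent this tiles the ventral disc
        exactly, without leaking the mixed rim-band triangles that straddle
        the perimeter.
        """
        if not self.adherent.any():
            return 0.0
        full = self.adherent[self.triangles].all(axis=1)
        return float(self.triangle_areas()[full].sum())

    @property
    def mean_node_area(self) -> float:
        return self.area_total / self.n_nodes

    @property
    def effective_radius(self) -> float:
        """Mean node distance from the center (um)."""
        return float(np.linalg.norm(self.nodes - self.center, axis=1).mean())

    def edges(self) -> np.ndarray:
        e = np.vstack([self.triangles[:, [0, 1]], self.triangles[:, [1, 2]],
                       self.triangles[:, [2, 0]]])
        return np.unique(np.sort(e, axis=1), axis=0)

    def mean_edge_length(self) -> float:
        e = self.edges()
        return float(np.linalg.norm(self.nodes[e[:, 0]] - self.nodes[e[:, 1]], axis=1).mean())

    def euler_characteristic(self) -> int:
        return self.n_nodes - len(self.edges()) + len(self.triangles)

    def neighbors(self) -> list[np.ndarray]:
        """1-ring neighbor indices per node."""
        nbr: list[set[int]] = [set() for _ in range(self.n_nodes)]
        for i, j, k in self.triangles:
            nbr[i].update((j, k)); nbr[j].update((i, k)); nbr[k].update((i, j))
        return [np.fromiter(s, int) for s in nbr]

    def perimeter_ring(self) -> np.ndarray:
        """Indices of adherent nodes that border a free node (the contact perimeter)."""
        if not self.adherent.any():
            return np.empty(0, int)
        nbr = self.neighbors()
        ring = [i for i in np.flatnonzero(self.adherent)
                if not self.adherent[nbr[i]].all()]
        return np.asarray(ring, int)

    def validate(self, strict_node_area: bool = True) -> None:
        """Assert closure, orientability and the mesh-resolution contract."""
        chi = self.euler_characteristic()
        if chi != 2:
            raise TriangulationError(f"surface not a closed sphere topology (chi={chi})")
        na, ta = self.node_areas.sum(), self.area_total
        if abs(na - ta) > 1e-6 * max(ta, 1e-12):
            raise TriangulationError("node areas do not partition the surface area")
        if strict_node_area and not (0.2 <= self.mean_node_area <= 0.4):
            raise TriangulationError(
                f"mean node area {self.mean_node_area:.3f} um^2 outside [0.2, 0.4]")

    def replace(self, **kw) -> "CellMesh":
        d = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}
        d.update(kw)
        if "nodes" in kw and "node_areas" not in kw:
            d["node_areas"] = None
        return CellMesh(**d)


@dataclass
class SignalField:
    """Per-node fluorescence (or synthetic activity) time series on a mesh."""

    values: np.ndarray  # (N_nodes, N_t)
    dt: float = 10.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValueError("values must be a (nodes, time) matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("signal contains non-finite values")

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_times)


# ---------------------------------------------------------------------------
# ray directions
# ---------------------------------------------------------------------------

def fibonacci_directions(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (Fibonacci sphere lattice)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    ga = np.pi * (3.0 - np.sqrt(5.0))
    az = ga * i
    return np.column_stack([r * np.cos(az), r * np.sin(az), z])


def _latitude_azimuth(vec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    r = np.linalg.norm(vec, axis=-1)
    with np.errstate(invalid="ignore"):
        lat = np.arcsin(np.clip(vec[..., 2] / np.where(r > 0, r, 1.0), -1, 1))
    return lat, np.arctan2(vec[..., 1], vec[..., 0])


# ---------------------------------------------------------------------------
# membrane localization
# ---------------------------------------------------------------------------

def locate_membrane(stack: np.ndarray, meta: StackMetadata,
                    n_directions: int = 1000,
                    max_flagged_frac: float = 0.2) -> np.ndarray:
    """Find one membrane point per ray direction from the cell center.

    For every quasi-uniform ray the radial profile of the per-voxel temporal
    standard deviation is sampled by trilinear interpolation; the membrane
    radius is the profile's interior argmax, refined to subvoxel precision by
    a local quadratic fit.  Rays whose argmax falls on the profile boundary
    (no interior membrane peak) are flagged and filled from the nearest
    unflagged direction; if more than ``max_flagged_frac`` of rays are
    flagged the reconstruction fails.

    Returns an (n_directions, 3) point cloud in um.
    """
    stack = np.asarray(stack, float)
    if stack.ndim != 4 or stack.shape[0] < 3:
        raise ValueError("stack must be (t, z, y, x) with >= 3 time points")
    sd = stack.std(axis=0)                       # (z, y, x) temporal SD
    mean_img = stack.mean(axis=0)
    if sd.max() <= 0:
        raise ReconstructionError("stack has no temporal variation; no membrane found")

    nz, ny, nx = sd.shape
    sp = meta.spacing                            # (dz, dy, dx)
    # intensity centroid of the time-mean image, in um (x, y, z)
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
    w = mean_img / mean_img.sum()
    center = np.array([ (w * xx).sum() * meta.dx,
                        (w * yy).sum() * meta.dy,
                        (w * zz).sum() * meta.dz ]) + np.asarray(meta.origin)

    dirs = fibonacci_directions(n_directions)
    r_max = 0.5 * min(nx * meta.dx, ny * meta.dy, nz * meta.dz)
    n_r = max(32, int(np.ceil(2 * r_max / min(sp))))
    radii = np.linspace(0.25 * min(sp), r_max, n_r)
    dr = radii[1] - radii[0]

    # sample SD along every ray at once
    pts = center[None, None, :] + radii[None, :, None] * dirs[:, None, :]  # (D, R, 3)
    orig = np.asarray(meta.origin)
    idx = np.empty((3, n_directions, n_r))
    idx[0] = (pts[..., 2] - orig[2]) / meta.dz   # z index
    idx[1] = (pts[..., 1] - orig[1]) / meta.dy
    idx[2] = (pts[..., 0] - orig[0]) / meta.dx
    prof = map_coordinates(sd, idx.reshape(3, -1), order=1, mode="constant",
                           cval=0.0).reshape(n_directions, n_r)

    # interior argmax; ties broken toward the larger radius (outer shell)
    rev = prof[:, ::-1]
    am = n_r - 1 - np.argmax(rev, axis=1)
    flagged = (am <= 0) | (am >= n_r - 1) | (prof[np.arange(n_directions), am] <= 0)

    # subvoxel quadratic refinement around the argmax
    r_membrane = radii[np.clip(am, 1, n_r - 2)].copy()
    ok = ~flagged
    i0 = am[ok]
    y0, y1, y2 = prof[ok, i0 - 1], prof[ok, i0], prof[ok, i0 + 1]
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / np.where(denom == 0, 1, denom), 0.0)
    r_membrane[ok] = radii[i0] + np.clip(shift, -1, 1) * dr

    if flagged.mean() > max_flagged_frac:
        raise ReconstructionError(
            f"{flagged.mean():.0%} of rays found no interior membrane peak")
    if flagged.any():
        tree = cKDTree(dirs[ok])
        _, nn = tree.query(dirs[flagged])
        r_membrane[flagged] = r_membrane[ok][nn]

    return center[None, :] + r_membrane[:, None] * dirs


# ---------------------------------------------------------------------------
# triangulation
# ---------------------------------------------------------------------------

def _hull_triangulation(dirs: np.ndarray, center_local: np.ndarray | None = None) -> np.ndarray:
    """Spherical Delaunay triangulation of unit directions via the convex hull."""
    try:
        hull = ConvexHull(dirs)
    except QhullError as exc:  # degenerate / planar cloud
        raise TriangulationError(f"directions are not full-dimensional: {exc}") from exc
    tris = hull.simplices.copy()
    # orient all triangles outward (positive volume with the origin)
    a, b, c = dirs[tris[:, 0]], dirs[tris[:, 1]], dirs[tris[:, 2]]
    inward = np.einsum("ij,ij->i", np.cross(b - a, c - a), a) < 0
    tris[inward] = tris[inward][:, [0, 2, 1]]
    return tris


def _mesh_from_points(points: np.ndarray, center: np.ndarray) -> CellMesh:
    rel = points - center
    r = np.linalg.norm(rel, axis=1)
    if (r <= 0).any():
        raise TriangulationError("point coincides with the center")
    dirs = rel / r[:, None]
    tris = _hull_triangulation(dirs)
    lat, az = _latitude_azimuth(rel)
    return CellMesh(nodes=points, triangles=tris, center=center.copy(),
                    theta=lat, phi=az,
                    adherent=np.zeros(len(points), bool))


def triangulate_surface(points: np.ndarray,
                        target_node_area: float = DEFAULT_NODE_AREA,
                        center: np.ndarray | None = None,
                        smooth: bool = True) -> CellMesh:
    """Triangulate a star-shaped membrane point cloud at ~target node area.

    The cloud is first triangulated as-is to measure the total surface area;
    the node count is then chosen as area / target_node_area and the surface
    resampled on that many Fibonacci directions (radius by inverse-distance
    interpolation of the nearest cloud rays), re-triangulated, and smoothed by
    one pass of the 1-ring Gaussian kernel.
    """
    points = np.asarray(points, float)
    if len(points) < 100:
        raise TriangulationError("need >= 100 points for a surface")
    c = points.mean(axis=0) if center is None else np.asarray(center, float)
    raw = _mesh_from_points(points, c)

    rel = points - c
    r = np.linalg.norm(rel, axis=1)
    dirs = rel / r[:, None]
    tree = cKDTree(dirs)

    def build(n: int) -> CellMesh:
        new_dirs = fibonacci_directions(n)
        dist, nn = tree.query(new_dirs, k=min(4, len(points)))
        wgt = 1.0 / np.maximum(dist, 1e-9)
        new_r = (wgt * r[nn]).sum(axis=1) / wgt.sum(axis=1)
        m = _mesh_from_points(c + new_r[:, None] * new_dirs, c)
        if smooth:
            a0 = m.area_total
            m = smooth_nodes(m)
            # undo the Laplacian shrinkage so the surface area is conserved
            f = np.sqrt(a0 / m.area_total)
            m = m.replace(nodes=c + f * (m.nodes - c))
        return m

    n_target = max(64, int(round(raw.area_total / target_node_area)))
    mesh = build(n_target)
    # one corrective pass: smoothing shrinks the surface a few percent, so
    # re-pick the node count from the realized (smoothed) area
    n_corr = max(64, int(round(mesh.area_total / target_node_area)))
    if abs(n_corr - n_target) > 0.02 * n_target:
        mesh = build(n_corr)
    mesh.validate(strict_node_area=False)
    return mesh


def smooth_nodes(mesh: CellMesh, kernel_sd: float | None = None) -> CellMesh:
    """One pass of 1-ring Gaussian-weighted node position smoothing.

    Each node is replaced by the Gaussian-weighted average of itself and its
    1-ring neighbors, weights exp(-d^2 / 2 sd^2) from inter-node distance.
    Width defaults to the mean edge length.  kernel_sd = 0 is the identity.
    Topology is unchanged.
    """
    if kernel_sd is None:
        kernel_sd = mesh.mean_edge_length()
    if kernel_sd <= 0:
        return mesh.replace(nodes=mesh.nodes.copy())
    new = np.empty_like(mesh.nodes)
    for i, nb in enumerate(mesh.neighbors()):
        pts = np.vstack([mesh.nodes[i], mesh.nodes[nb]])
        d2 = ((pts - mesh.nodes[i]) ** 2).sum(axis=1)
        w = np.exp(-0.5 * d2 / kernel_sd**2)
        new[i] = (w[:, None] * pts).sum(axis=0) / w.sum()
    return mesh.replace(nodes=new)


# ---------------------------------------------------------------------------
# signal sampling
# ---------------------------------------------------------------------------

def sample_signal(stack: np.ndarray, mesh: CellMesh, meta: StackMetadata) -> SignalField:
    """Per-node intensity time series from a 4D stack.

    Each node's intensity is the mean of trilinear samples taken at the node
    position and one radial step inward/outward along the node's ray (a +/- 1
    voxel radial window).  Deterministic.
    """
    stack = np.asarray(stack, float)
    nt = stack.shape[0]
    orig = np.asarray(meta.origin)
    rel = mesh.nodes - mesh.center
    u = rel / np.linalg.norm(rel, axis=1)[:, None]
    dr = min(meta.dx, meta.dy, meta.dz)
    samples = np.concatenate([mesh.nodes + s * dr * u for s in (-1.0, 0.0, 1.0)])
    idx = np.empty((3, len(samples)))
    idx[0] = (samples[:, 2] - orig[2]) / meta.dz
    idx[1] = (samples[:, 1] - orig[1]) / meta.dy
    idx[2] = (samples[:, 0] - orig[0]) / meta.dx
    nzyx = stack.shape[1:]
    if ((idx[0] < -1) | (idx[0] > nzyx[0]) | (idx[1] < -1) | (idx[1] > nzyx[1])
            | (idx[2] < -1) | (idx[2] > nzyx[2])).any():
        raise ValueError("mesh node outside the stack bounds")
    values = np.empty((mesh.n_nodes, nt))
    for t in range(nt):
        v = map_coordinates(stack[t], idx, order=1, mode="nearest")
        values[:, t] = v.reshape(3, mesh.n_nodes).mean(axis=0)
    return SignalField(values=values, dt=meta.dt)


# ---------------------------------------------------------------------------
# contact perimeter
# ---------------------------------------------------------------------------

def detect_contact_perimeter(mesh: CellMesh, flatness_tol: float = 0.5) -> CellMesh:
    """Flag adherent (ventral) nodes and locate the contact perimeter.

    Nodes within ``flatness_tol`` (um) of the lowest supporting plane
    (minimum z, the coverslip) are adherent.  theta_adh is the area-weighted
    mean latitude of the perimeter ring between adherent and free nodes, and
    ventral-disc nodes are re-assigned latitude linearly in radial position
    from -pi/2 at the disc center to theta_adh at the rim, so maps cover the
    whole closed surface.
    """
    z = mesh.nodes[:, 2]
    adherent = z - z.min() <= flatness_tol
    if adherent.all():
        raise ValueError("flatness_tol flags every node adherent; no free membrane")
    out = mesh.replace(adherent=adherent)
    if not adherent.any():
        return out.replace(theta_adh=float("nan"))
    ring = out.perimeter_ring()
    if len(ring) == 0:  # isolated adherent specks only
        return out.replace(theta_adh=float("nan"))
    w = out.node_areas[ring]
    theta_adh = float((w * out.theta[ring]).sum() / w.sum())
    # re-parameterize the ventral disc in latitude
    theta = out.theta.copy()
    adh_idx = np.flatnonzero(adherent)
    rho = np.linalg.norm(mesh.nodes[adh_idx, :2] - mesh.center[None, :2], axis=1)
    rho_max = rho.max()
    if rho_max > 0:
        theta[adh_idx] = -np.pi / 2 + (rho / rho_max) * (theta_adh + np.pi / 2)
    return out.replace(theta=theta, theta_adh=theta_adh)


# ---------------------------------------------------------------------------
# persistence (HDF5 + PLY/OFF)
# ---------------------------------------------------------------------------

def save_cell(path, mesh: CellMesh, signal: SignalField | None = None) -> None:
    """Write a mesh (and optional signal) to a single HDF5 file."""
    with h5py.File(path, "w") as f:
        f["/nodes"] = mesh.nodes
        f["/triangles"] = mesh.triangles
        f["/theta"] = mesh.theta
        f["/phi"] = mesh.phi
        f["/adherent"] = mesh.adherent
        f["/center"] = mesh.center
        f.attrs["theta_adh"] = mesh.theta_adh
        if signal is not None:
            f["/signal"] = signal.values
            f["/time"] = signal.times
            f.attrs["dt"] = signal.dt


def load_cell(path) -> tuple[CellMesh, SignalField | None]:
    with h5py.File(path, "r") as f:
        mesh = CellMesh(nodes=f["/nodes"][:], triangles=f["/triangles"][:],
                        center=f["/center"][:], theta=f["/theta"][:],
                        phi=f["/phi"][:], adherent=f["/adherent"][:],
                        theta_adh=float(f.attrs["theta_adh"]))
        signal = None
        if "signal" in f:
            t = f["/time"][:]
            signal = SignalField(values=f["/signal"][:], dt=float(f.attrs["dt"]),
                                 t0=float(t[0]) if len(t) else 0.0)
    return mesh, signal


def export_mesh(mesh: CellMesh, ply_path=None, off_path=None) -> None:
    """Export the surface as binary little-endian PLY and/or OFF."""
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.nodes, faces=mesh.triangles, process=False)
    if ply_path is not None:
        tm.export(ply_path, file_type="ply", encoding="binary")
    if off_path is not None:
        tm.export(off_path, file_type="off")
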