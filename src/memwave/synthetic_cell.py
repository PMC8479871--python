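"""Ground-truth synthetic cells: truncated-sphere geometry, prototypical
membrane signal patterns, and rendered 4D voxel stacks.

Actin-inhibited amoeboid cells adhered to a coverslip are well described by a
sphere of radius R truncated at the substrate, parameterized by the contact
angle Omega in [0, pi/2]: Omega = 0 is a free-floating sphere, larger Omega a
larger flat ventral disc (radius R sin Omega) whose rim — the contact
perimeter at latitude theta_adh = -pi/2 + Omega — carries the largest membrane
curvature.  The signal patterns emulate the three prototypical classes of
membrane lipid-signaling dynamics (horizontal waves running parallel to the
contact perimeter, vertical waves crossing it, transient spots above it) plus
a spiral wave pinned at the contact perimeter, pure white noise, and a quiet
control.  Oscillation periods default to the 2-5 minute band observed in
vivo; frames are 10 s apart.

Every stochastic draw is governed by a single integer seed through a
counter-based (Philox) generator, so identical specs give bit-identical
signals.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .reconstruction import (
    CellMesh,
    SignalField,
    StackMetadata,
    _hull_triangulation,
    save_cell,
)

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "StackMetadata",
    "ConfigurationError",
    "PATTERNS",
    "make_geometry",
    "make_signal",
    "make_scene",
    "voxelize",
]

PATTERNS = (
    "horizontal_wave",
    "vertical_wave",
    "transient_spots",
    "pinned_spiral",
    "white_noise",
    "quiet",
    "isotropic_domain",
)


class ConfigurationError(ValueError):
    """Pattern/geometry combination is inconsistent."""


@dataclass
class SceneSpec:
    """Parameters of one synthetic cell scene.

    radius          sphere radius R (um); 1-3 um-scale cells, volumes ~0.5 pL
    contact_angle   Omega (rad) in [0, pi/2]; 0 means no ventral disc
    pattern         one of PATTERNS
    period          oscillation/rotation period T (s); 2-5 min band typical
    wave_width      angular half-width of the active domain (rad)
    theta_band      latitude of the horizontal-wave band center (rad)
    amplitude       activity amplitude above baseline (intensity units)
    noise_sd        additive Gaussian noise SD (intensity units)
    baseline        constant background intensity
    duration        total simulated time (s)
    dt              frame interval (s); >= 34 frames needed for phase analysis
    spot_rate       transient-spot birth rate (1/s)
    spot_lifetime   transient-spot lifetime (s)
    node_area       target mean mesh node area (um^2)
    seed            single integer governing all stochastic draws
    """

    radius: float = 3.0
    contact_angle: float = 0.0
    pattern: str = "horizontal_wave"
    period: float = 200.0
    wave_width: float = 0.5
    theta_band: float = 0.0
    amplitude: float = 1.0
    noise_sd: float = 0.2
    baseline: float = 1.0
    duration: float = 1800.0
    dt: float = 10.0
    spot_rate: float = 1.0 / 60.0
    spot_lifetime: float = 60.0
    node_area: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not 0.0 <= self.contact_angle <= np.pi / 2 + 1e-12:
            raise ValueError("contact_angle must lie in [0, pi/2]")
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("duration and dt must be positive")

    @property
    def theta_adh(self) -> float:
        """Latitude of the contact perimeter, -pi/2 + Omega."""
        return -np.pi / 2 + self.contact_angle

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(self.n_frames)


@dataclass
class GroundTruth:
    """Realized pattern parameters and noiseless per-node activity."""

    pattern: str
    theta_adh: float
    params: dict = field(default_factory=dict)
    noiseless: np.ndarray | None = None        # (nodes, time)
    phase: np.ndarray | None = None            # (nodes,) prescribed phase at t=0 (spiral)
    peak_path: np.ndarray | None = None        # (time, 3) domain-peak positions, um

    def to_json(self, path) -> None:
        """Persist the scalar/parameter part (arrays live in the HDF5 file)."""
        doc = {"pattern": self.pattern, "theta_adh": self.theta_adh,
               "params": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                          for k, v in self.params.items()}}
        with open(path, "w") as f:
            json.dump(doc, f, indent=1)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def make_geometry(spec: SceneSpec) -> CellMesh:
    """Triangulated truncated-sphere cell: spherical cap above theta_adh closed
    by a flat ventral disc of radius R sin(Omega).

    Nodes are laid out at near-uniform area density (target ``spec.node_area``)
    with a Fibonacci lattice on the cap and a sunflower lattice on the disc,
    then joined by a spherical Delaunay triangulation in direction space.
    Disc nodes are flagged adherent and assigned latitude linearly in radial
    position from -pi/2 (disc center) to theta_adh (rim).
    """
    R, omega = spec.radius, spec.contact_angle
    theta_adh = spec.theta_adh
    ga = np.pi * (3.0 - np.sqrt(5.0))                   # golden angle
    # hexagonal-lattice spacing giving the target area per node
    ell = np.sqrt(2.0 * spec.node_area / np.sqrt(3.0))

    rim_rho = R * np.sin(omega)
    z_disc = -R * np.cos(omega)
    if omega > 0:
        # explicit ring of nodes on the contact perimeter itself; twice the
        # lattice density so the polygonal rim tracks the circle closely
        n_rim = max(12, int(round(2 * np.pi * rim_rho / (0.5 * ell))))
        az_r = np.linspace(-np.pi, np.pi, n_rim, endpoint=False)
        # place ring nodes on the circle of equal polygon area so the disc
        # tiling does not suffer the inscribed-polygon chord deficit
        rho_r = rim_rho * np.sqrt(2 * np.pi / (n_rim * np.sin(2 * np.pi / n_rim)))
        rim = np.column_stack([rho_r * np.cos(az_r), rho_r * np.sin(az_r),
                               np.full(n_rim, z_disc)])
        # cap lattice starts half a spacing above the rim, disc lattice half
        # a spacing inside it, so rim triangles stay near-equilateral
        lat_lo = min(theta_adh + 0.5 * ell / R, np.pi / 2 - 1e-3)
    else:
        n_rim = 0
        rim = np.empty((0, 3))
        lat_lo = -np.pi / 2

    sin_lo = np.sin(lat_lo)
    a_cap = 2 * np.pi * R**2 * (1.0 - sin_lo)
    n_cap = max(16, int(round(a_cap / spec.node_area)))
    i = np.arange(n_cap) + 0.5
    s = sin_lo + (1.0 - sin_lo) * i / n_cap             # uniform in sin(latitude)
    lat_cap = np.arcsin(np.clip(s, -1, 1))
    az_cap = (ga * i + np.pi) % (2 * np.pi) - np.pi
    # a piecewise-flat triangulation underestimates the spherical area by
    # ~0.21 (ell/R)^2; inflating cap radii by half that keeps the mesh area
    # at the analytic value so the r_a contract holds at coarse resolution
    R_cap = R * (1.0 + 0.1075 * (ell / R) ** 2)
    cap = R_cap * np.column_stack([np.cos(lat_cap) * np.cos(az_cap),
                                   np.cos(lat_cap) * np.sin(az_cap),
                                   np.sin(lat_cap)])

    if omega > 0:
        rho_max = max(rim_rho - 0.5 * ell, 0.25 * rim_rho)
        n_disc = max(4, int(round(np.pi * rho_max**2 / spec.node_area)))
        j = np.arange(n_disc) + 0.5
        rho = rho_max * np.sqrt(j / n_disc)
        az_d = (ga * j + np.pi) % (2 * np.pi) - np.pi
        disc = np.column_stack([rho * np.cos(az_d), rho * np.sin(az_d),
                                np.full(n_disc, z_disc)])
        nodes = np.vstack([cap, rim, disc])
        adherent = np.r_[np.zeros(n_cap, bool), np.ones(n_rim + n_disc, bool)]
        lat_rim = np.full(n_rim, theta_adh)
        lat_disc = -np.pi / 2 + (rho / rim_rho) * omega
        theta = np.r_[lat_cap, lat_rim, lat_disc]
        phi = np.r_[az_cap, az_r, az_d]
    else:
        nodes = cap
        adherent = np.zeros(n_cap, bool)
        theta, phi = lat_cap, az_cap
        theta_adh = float("nan")

    center = np.zeros(3)
    # the truncated sphere is star-shaped about any interior point; view the
    # directions from a point safely inside even when the disc plane passes
    # through the sphere center (omega -> pi/2)
    view = np.array([0.0, 0.0, 0.5 * (z_disc + R)]) if omega > 0 else center
    rel_v = nodes - view
    dirs = rel_v / np.linalg.norm(rel_v, axis=1)[:, None]
    tris = _hull_triangulation(dirs)
    mesh = CellMesh(nodes=nodes, triangles=tris, center=center,
                    theta=theta, phi=phi, adherent=adherent, theta_adh=theta_adh)
    mesh.validate(strict_node_area=False)
    return mesh


# ---------------------------------------------------------------------------
# signal patterns
# ---------------------------------------------------------------------------

def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return np.pi - np.mod(np.pi - a, 2 * np.pi)


def _unit_dirs(mesh: CellMesh) -> np.ndarray:
    rel = mesh.nodes - mesh.center
    return rel / np.linalg.norm(rel, axis=1)[:, None]


def _gauss_bump(angular_dist: np.ndarray, width: float) -> np.ndarray:
    return np.exp(-0.5 * (angular_dist / width) ** 2)


def _horizontal_wave(mesh: CellMesh, spec: SceneSpec) -> tuple[np.ndarray, dict, np.ndarray]:
    t = spec.times
    phi_c = 2 * np.pi * t / spec.period                  # domain azimuth over time
    dth = mesh.theta[:, None] - spec.theta_band
    dph = _wrap_angle(mesh.phi[:, None] - phi_c[None, :])
    act = spec.amplitude * _gauss_bump(dth, spec.wave_width) * _gauss_bump(dph, spec.wave_width)
    R = spec.radius
    path = R * np.column_stack([np.cos(spec.theta_band) * np.cos(phi_c),
                                np.cos(spec.theta_band) * np.sin(phi_c),
                                np.full(len(t), np.sin(spec.theta_band))])
    return act, {"axis": [0.0, 0.0, 1.0], "angular_speed": 2 * np.pi / spec.period}, path


def _vertical_wave(mesh: CellMesh, spec: SceneSpec) -> tuple[np.ndarray, dict, np.ndarray]:
    # domain center rotates about the x axis, starting at the ventral pole,
    # so it periodically crosses the contact perimeter
    t = spec.times
    beta = 2 * np.pi * t / spec.period
    m = np.column_stack([np.zeros_like(beta), np.sin(beta), -np.cos(beta)])  # (T, 3)
    u = _unit_dirs(mesh)
    cosd = np.clip(u @ m.T, -1, 1)
    act = spec.amplitude * _gauss_bump(np.arccos(cosd), spec.wave_width)
    return act, {"axis": [1.0, 0.0, 0.0], "angular_speed": 2 * np.pi / spec.period}, spec.radius * m


def _transient_spots(mesh: CellMesh, spec: SceneSpec,
                     rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    t = spec.times
    n_births = rng.poisson(spec.spot_rate * spec.duration)
    birth_t = np.sort(rng.uniform(0, spec.duration, n_births))
    free = ~mesh.adherent if mesh.adherent.any() else np.ones(mesh.n_nodes, bool)
    if mesh.adherent.any():
        free &= mesh.theta > mesh.theta_adh
    free_idx = np.flatnonzero(free)
    p = mesh.node_areas[free_idx] / mesh.node_areas[free_idx].sum()
    centers = rng.choice(free_idx, size=n_births, p=p)
    u = _unit_dirs(mesh)
    act = np.zeros((mesh.n_nodes, len(t)))
    tau_r = min(10.0, spec.spot_lifetime / 4)
    for tb, ci in zip(birth_t, centers):
        age = t - tb
        live = (age >= 0) & (age <= spec.spot_lifetime)
        if not live.any():
            continue
        # exponential-shoulder temporal profile: fast rise, exponential decay
        prof = np.zeros(len(t))
        a = age[live]
        prof[live] = (1.0 - np.exp(-a / tau_r)) * np.exp(-a / (spec.spot_lifetime / 2.0))
        d = np.arccos(np.clip(u @ u[ci], -1, 1))
        act += spec.amplitude * _gauss_bump(d, spec.wave_width)[:, None] * prof[None, :]
    return act, {"birth_times": birth_t, "center_nodes": centers.astype(int)}


def _pinned_spiral(mesh: CellMesh, spec: SceneSpec) -> tuple[np.ndarray, dict, np.ndarray]:
    if not mesh.adherent.any() or not np.isfinite(mesh.theta_adh):
        raise ConfigurationError("pinned_spiral requires a cell with a contact perimeter")
    theta_adh = -np.pi / 2 + spec.contact_angle
    # singular axis pierces the contact perimeter at azimuth 0; the
    # topologically required counter-singularity sits at the antipode
    axis = np.array([np.cos(theta_adh), 0.0, np.sin(theta_adh)])
    e1 = np.array([-np.sin(theta_adh), 0.0, np.cos(theta_adh)])
    e2 = np.cross(axis, e1)
    u = _unit_dirs(mesh)
    phi_p = np.arctan2(u @ e2, u @ e1)                 # azimuth about the axis
    theta_p = np.arccos(np.clip(u @ axis, -1, 1))      # colatitude from the axis
    t = spec.times
    chi = phi_p[:, None] - 2 * np.pi * t[None, :] / spec.period
    # amplitude floor keeps phase well-defined away from the exact poles
    amp = spec.amplitude * (0.3 + 0.7 * np.sin(theta_p))
    act = amp[:, None] * np.cos(chi)
    params = {
        "axis": axis, "period": spec.period,
        "pinned_position": spec.radius * axis,
        "counter_position": -spec.radius * axis,
    }
    return act, params, phi_p


def _isotropic_domain(mesh: CellMesh, spec: SceneSpec,
                      rng: np.random.Generator) -> tuple[np.ndarray, dict, np.ndarray]:
    """Domain rotating a fixed angular step per frame about a fresh random
    axis each step: step directions are isotropic on the sphere, the baseline
    condition under which the azimuthal/polar speed ratio is unity."""
    t = spec.times
    step = 2 * np.pi * spec.dt / spec.period           # angular step per frame
    u = _unit_dirs(mesh)
    c = np.empty((len(t), 3))
    v = rng.normal(size=3)
    c[0] = v / np.linalg.norm(v)
    for k in range(1, len(t)):
        # random tangent direction at the current position
        h = rng.normal(size=3)
        tang = h - (h @ c[k - 1]) * c[k - 1]
        tang /= np.linalg.norm(tang)
        c[k] = np.cos(step) * c[k - 1] + np.sin(step) * tang
    cosd = np.clip(u @ c.T, -1, 1)
    act = spec.amplitude * _gauss_bump(np.arccos(cosd), spec.wave_width)
    return act, {"angular_step": step}, spec.radius * c


def make_signal(mesh: CellMesh, spec: SceneSpec) -> tuple[SignalField, GroundTruth]:
    """Per-node activity time series: baseline + pattern + Gaussian noise.

    Deterministic given ``spec.seed`` (counter-based Philox generator).
    """
    rng = np.random.Generator(np.random.Philox(key=spec.seed))
    phase0 = None
    path = None
    if spec.pattern == "horizontal_wave":
        act, params, path = _horizontal_wave(mesh, spec)
    elif spec.pattern == "vertical_wave":
        act, params, path = _vertical_wave(mesh, spec)
    elif spec.pattern == "transient_spots":
        act, params = _transient_spots(mesh, spec, rng)
    elif spec.pattern == "pinned_spiral":
        act, params, phase0 = _pinned_spiral(mesh, spec)
    elif spec.pattern == "isotropic_domain":
        act, params, path = _isotropic_domain(mesh, spec, rng)
    elif spec.pattern in ("white_noise", "quiet"):
        act, params = np.zeros((mesh.n_nodes, spec.n_frames)), {}
    else:  # pragma: no cover - guarded in SceneSpec
        raise ConfigurationError(spec.pattern)

    noiseless = spec.baseline + act
    values = noiseless.copy()
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    signal = SignalField(values=values, dt=spec.dt)
    truth = GroundTruth(pattern=spec.pattern, theta_adh=spec.theta_adh,
                        params=params, noiseless=noiseless,
                        phase=phase0, peak_path=path)
    return signal, truth


def make_scene(spec: SceneSpec) -> tuple[CellMesh, SignalField, GroundTruth]:
    """Convenience: geometry + signal in one call."""
    mesh = make_geometry(spec)
    signal, truth = make_signal(mesh, spec)
    return mesh, signal, truth


# ---------------------------------------------------------------------------
# voxel rendering
# ---------------------------------------------------------------------------

def voxelize(mesh: CellMesh, signal: SignalField, meta: StackMetadata,
             psf_sd: float = 0.3, cytosol_frac: float = 0.15,
             margin: float | None = None) -> tuple[np.ndarray, StackMetadata]:
    """Render a (t, z, y, x) fluorescence stack from a mesh + signal.

    Membrane intensity is splatted onto the voxel nearest each node, blurred
    with an isotropic Gaussian point-spread function of width ``psf_sd`` (um),
    and a dimmer uniform cytosolic interior component (``cytosol_frac`` of the
    median membrane intensity) is added.  Returns the stack and the metadata
    with the realized grid origin/shape.
    """
    if margin is None:
        margin = max(3.0 * psf_sd, 1.0)
    lo = mesh.nodes.min(axis=0) - margin
    hi = mesh.nodes.max(axis=0) + margin
    if meta.shape is not None:
        nz, ny, nx = meta.shape
        ext = np.array([nx * meta.dx, ny * meta.dy, nz * meta.dz])
        if ((hi - lo) > ext).any():
            raise ValueError("mesh (plus 3 psf_sd margin) exceeds the prescribed stack bounds")
        origin = tuple(lo)
    else:
        nx = int(np.ceil((hi[0] - lo[0]) / meta.dx))
        ny = int(np.ceil((hi[1] - lo[1]) / meta.dy))
        nz = int(np.ceil((hi[2] - lo[2]) / meta.dz))
        origin = tuple(lo)
    out_meta = StackMetadata(dx=meta.dx, dy=meta.dy, dz=meta.dz, dt=meta.dt,
                             origin=origin, shape=(nz, ny, nx))

    sp = np.array([meta.dx, meta.dy, meta.dz])
    vox = np.round((mesh.nodes - np.asarray(origin)) / sp).astype(int)   # (N, 3) x,y,z
    vox[:, 0] = np.clip(vox[:, 0], 0, nx - 1)
    vox[:, 1] = np.clip(vox[:, 1], 0, ny - 1)
    vox[:, 2] = np.clip(vox[:, 2], 0, nz - 1)
    flat = np.ravel_multi_index((vox[:, 2], vox[:, 1], vox[:, 0]), (nz, ny, nx))
    count = np.bincount(flat, minlength=nz * ny * nx)

    # interior mask from the star-shaped surface: a voxel is cytosol when its
    # distance from the center is below the interpolated membrane radius
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
    centers = np.column_stack([xx.ravel() * meta.dx + origin[0],
                               yy.ravel() * meta.dy + origin[1],
                               zz.ravel() * meta.dz + origin[2]])
    rel = centers - mesh.center
    r_vox = np.linalg.norm(rel, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dirs_vox = rel / np.where(r_vox[:, None] > 0, r_vox[:, None], 1.0)
    node_rel = mesh.nodes - mesh.center
    node_r = np.linalg.norm(node_rel, axis=1)
    tree = cKDTree(node_rel / node_r[:, None])
    dist, nn = tree.query(dirs_vox, k=3)
    w = 1.0 / np.maximum(dist, 1e-9)
    r_surf = (w * node_r[nn]).sum(axis=1) / w.sum(axis=1)
    interior = (r_vox < r_surf - max(psf_sd, min(sp))).reshape(nz, ny, nx)

    med_int = float(np.median(signal.values))
    sigma_vox = (psf_sd / meta.dz, psf_sd / meta.dy, psf_sd / meta.dx)
    stack = np.empty((signal.n_times, nz, ny, nx), np.float32)
    for t in range(signal.n_times):
        acc = np.bincount(flat, weights=signal.values[:, t], minlength=nz * ny * nx)
        frame = np.zeros(nz * ny * nx)
        occ = count > 0
        frame[occ] = acc[occ] / count[occ]
        frame = frame.reshape(nz, ny, nx)
        frame[interior] = np.maximum(frame[interior], cytosol_frac * med_int)
        stack[t] = gaussian_filter(frame, sigma_vox)
    return stack, out_meta


def write_stack(path, stack: np.ndarray, meta: StackMetadata) -> None:
    """Write a stack as a multi-page TIFF (TZYX order)."""
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, np.float32),
                     metadata={"axes": "TZYX", "dx_um": meta.dx, "dy_um": meta.dy,
                               "dz_um": meta.dz, "dt_s": meta.dt})


def read_stack(path) -> np.ndarray:
    import tifffile

    arr = tifffile.imread(path)
    return np.asarray(arr, float)


def save_scene(outdir, spec: SceneSpec, mesh: CellMesh, signal: SignalField,
               truth: GroundTruth) -> None:
    """Persist a scene: HDF5 cell, PLY/OFF mesh, JSON ground truth + spec."""
    from pathlib import Path

    from .reconstruction import export_mesh

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    save_cell(out / "cell.h5", mesh, signal)
    if truth.noiseless is not None:
        with __import__("h5py").File(out / "cell.h5", "a") as f:
            f["/noiseless"] = truth.noiseless
    export_mesh(mesh, ply_path=out / "mesh.ply", off_path=out / "mesh.off")
    truth.to_json(out / "ground_truth.json")
    with open(out / "scene_spec.json", "w") as f:
        json.dump(asdict(spec), f, indent=1)
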