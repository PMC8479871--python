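"""Cell-shape descriptors, spherical-harmonic domain tracking, velocity
decomposition, and population-level linear relations.

The adhered cell is modeled as a sphere of radius R truncated by the
substrate at contact angle Omega.  The dimensionless adhesion area ratio

    r_a = A_adh / A_mem = sin^2(Omega) / (3 + cos(Omega))

links the measurable areas to Omega (R cancels); it rises monotonically from
0 at Omega = 0 to 1/3 at Omega = pi/2 and is inverted numerically to recover
Omega from a reconstructed mesh.  Signal domains are tracked by projecting
each frame onto real spherical harmonics up to degree 3 (the octupole
moment), which smooths the intensity field for peak detection; successive
peak positions give the domain speed v (chord distance per frame, um/min)
and its polar/azimuthal split (v_theta, v_phi), summarized per cell by the
speed ratio v_a = <v_phi> / <v_theta> (unity for isotropic propagation).
Population tables of (delta_alpha, r_a, v_a) are reduced to the linear law
v_a = m * r_a + n_0 by fitting binned medians against delta_alpha and
eliminating delta_alpha between the two fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .reconstruction import CellMesh, SignalField, TriangulationError

__all__ = [
    "CellGeometry",
    "DomainTrack",
    "PopulationFit",
    "FitError",
    "area_ratio",
    "contact_angle",
    "contact_angle_closed_form",
    "shape_descriptors",
    "track_domain",
    "decompose_velocity",
    "population_fits",
]

R_A_MAX = 1.0 / 3.0  # area ratio at Omega = pi/2


class FitError(RuntimeError):
    """Population fit impossible (insufficient spread)."""


# ---------------------------------------------------------------------------
# contact-angle geometry
# ---------------------------------------------------------------------------

def area_ratio(omega) -> float | np.ndarray:
    """Adhesion area ratio r_a = sin^2(Omega) / (3 + cos(Omega)).

    The denominator is the truncated-sphere membrane area 4 pi R^2 -
    pi R^2 (1 - cos Omega) over pi R^2; R cancels.  0 at Omega = 0, 1/3 at
    Omega = pi/2.
    """
    om = np.asarray(omega, float)
    if np.any((om < -1e-12) | (om > np.pi / 2 + 1e-12)):
        raise ValueError("Omega must lie in [0, pi/2]")
    r = np.sin(om) ** 2 / (3.0 + np.cos(om))
    return float(r) if np.ndim(omega) == 0 else r


def area_ratio_exact(omega) -> float | np.ndarray:
    """Exact truncated-sphere ratio: closing disc / (free spherical zone + disc).

    Differs from :func:`area_ratio` at intermediate Omega (they agree at the
    endpoints); provided for documenting the model-vs-geometry discrepancy.
    """
    om = np.asarray(omega, float)
    disc = np.pi * np.sin(om) ** 2
    zone = 2 * np.pi * (1.0 + np.cos(om))
    r = disc / (zone + disc)
    return float(r) if np.ndim(omega) == 0 else r


def contact_angle(r_a: float, tol: float = 1e-10) -> float:
    """Invert the area ratio: Omega such that area_ratio(Omega) = r_a.

    Bisection (brentq) on [0, pi/2]; the model's range is r_a in [0, 1/3].
    """
    if not 0.0 <= r_a <= R_A_MAX + 1e-9:
        raise ValueError(f"r_a = {r_a} outside the model range [0, 1/3]")
    if r_a <= 0:
        return 0.0
    if r_a >= R_A_MAX:
        return np.pi / 2
    return brentq(lambda om: area_ratio(om) - r_a, 0.0, np.pi / 2, xtol=tol)


def contact_angle_closed_form(r_a: float) -> float:
    """Algebraic inverse of the area ratio.

    Writing c = cos(Omega), the ratio becomes the quadratic
    c^2 + r_a c + 3 r_a - 1 = 0 with root c = (-r_a + sqrt(r_a^2 - 12 r_a + 4))/2,
    so Omega = arccos(c).  Cross-checks the numerical inversion exactly.
    """
    if not 0.0 <= r_a <= R_A_MAX + 1e-9:
        raise ValueError(f"r_a = {r_a} outside the model range [0, 1/3]")
    c = 0.5 * (-r_a + np.sqrt(max(r_a * r_a - 12.0 * r_a + 4.0, 0.0)))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


# ---------------------------------------------------------------------------
# shape descriptors
# ---------------------------------------------------------------------------

@dataclass
class CellGeometry:
    """Shape summary of one cell.

    volume_pl in picoliters (1 pL = 1000 um^3); kappa_max is the maximal
    discrete mean curvature over contact-perimeter ring nodes (1/um), NaN for
    a free-floating cell.
    """

    volume_pl: float
    area_adherent: float
    area_total: float
    r_a: float
    omega: float
    radius: float
    kappa_max: float

    def as_dict(self) -> dict:
        return {"V_pL": self.volume_pl, "A_adh_um2": self.area_adherent,
                "A_mem_um2": self.area_total, "r_a": self.r_a,
                "omega_rad": self.omega, "R_um": self.radius,
                "kappa_max_per_um": self.kappa_max}


def _mesh_volume(mesh: CellMesh) -> float:
    """Volume from the tetrahedral decomposition about the center (um^3)."""
    a = mesh.nodes[mesh.triangles[:, 0]] - mesh.center
    b = mesh.nodes[mesh.triangles[:, 1]] - mesh.center
    c = mesh.nodes[mesh.triangles[:, 2]] - mesh.center
    return float(np.abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)


def _mean_curvature(mesh: CellMesh, node_idx: np.ndarray) -> np.ndarray:
    """Discrete mean curvature (cotangent Laplacian) at selected nodes, 1/um."""
    nodes, tris = mesh.nodes, mesh.triangles
    lap = np.zeros_like(nodes)
    wsum_area = mesh.node_areas
    for roll in range(3):
        i = tris[:, roll]
        j = tris[:, (roll + 1) % 3]
        k = tris[:, (roll + 2) % 3]
        # cotangent at vertex k of angle opposite edge (i, j)
        u = nodes[i] - nodes[k]
        v = nodes[j] - nodes[k]
        cross = np.linalg.norm(np.cross(u, v), axis=1)
        cot = np.einsum("ij,ij->i", u, v) / np.maximum(cross, 1e-12)
        d = nodes[j] - nodes[i]
        np.add.at(lap, i, 0.5 * cot[:, None] * d)
        np.add.at(lap, j, -0.5 * cot[:, None] * d)
    H = np.linalg.norm(lap, axis=1) / (2.0 * np.maximum(wsum_area, 1e-12))
    return H[node_idx]


def shape_descriptors(mesh: CellMesh) -> CellGeometry:
    """A_adh, A_mem, V, r_a, Omega and kappa_max from a closed mesh.

    Omega is recovered by numerically inverting the area-ratio relation; for
    mesh ratios above the model's 1/3 ceiling (possible for strongly adhered
    reconstructions) Omega saturates at pi/2.  kappa_max is NaN when the cell
    has no contact perimeter.
    """
    if mesh.euler_characteristic() != 2:
        raise TriangulationError("shape descriptors require a closed surface")
    a_mem = mesh.area_total
    a_adh = mesh.area_adherent
    r_a = a_adh / a_mem
    omega = contact_angle(min(r_a, R_A_MAX))
    vol = _mesh_volume(mesh)
    ring = mesh.perimeter_ring()
    kappa = float(_mean_curvature(mesh, ring).max()) if len(ring) else float("nan")
    return CellGeometry(volume_pl=vol / 1000.0, area_adherent=a_adh,
                        area_total=a_mem, r_a=r_a, omega=omega,
                        radius=mesh.effective_radius, kappa_max=kappa)


# ---------------------------------------------------------------------------
# domain tracking (spherical harmonics)
# ---------------------------------------------------------------------------

def _real_sh_basis(dirs: np.ndarray, lmax: int = 3) -> np.ndarray:
    """Real spherical harmonics up to degree lmax on unit directions, (N, (lmax+1)^2)."""
    from scipy.special import sph_harm_y

    colat = np.arccos(np.clip(dirs[:, 2], -1, 1))
    az = np.arctan2(dirs[:, 1], dirs[:, 0])
    cols = []
    for l in range(lmax + 1):
        for m in range(-l, l + 1):
            y = sph_harm_y(l, abs(m), colat, az)
            if m == 0:
                cols.append(y.real)
            elif m > 0:
                cols.append(np.sqrt(2) * (-1) ** m * y.real)
            else:
                cols.append(np.sqrt(2) * (-1) ** m * y.imag)
    return np.column_stack(cols)


@dataclass
class DomainTrack:
    """Domain-peak trajectory on the membrane."""

    times: np.ndarray        # (T,) seconds (all frames)
    positions: np.ndarray    # (T, 3) um, NaN rows where skipped
    valid: np.ndarray        # (T,) bool
    ambiguous: np.ndarray    # (T,) bool (tied / degenerate peaks)
    dt: float

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def track_domain(signal: SignalField, mesh: CellMesh, lmax: int = 3,
                 contrast_floor: float = 0.05) -> DomainTrack:
    """Track the dominant signal domain frame by frame.

    Each frame is least-squares projected onto real spherical harmonics up to
    degree ``lmax`` on the node directions; the reconstruction's peak gives
    the domain position, refined by an intensity-weighted centroid of the
    nodes within the top 20% of the reconstructed range (projected back to
    the membrane radius).  Frames whose reconstructed contrast (max - min)
    falls below ``contrast_floor`` times the best frame's contrast are
    skipped.  Frames whose weighted centroid collapses toward the cell center
    (e.g. two equal antipodal domains) fall back to the first-index argmax
    node and are flagged ambiguous.
    """
    rel = mesh.nodes - mesh.center
    rad = np.linalg.norm(rel, axis=1)
    dirs = rel / rad[:, None]
    B = _real_sh_basis(dirs, lmax)
    coef = np.linalg.pinv(B) @ signal.values          # (n_coef, T)
    recon = B @ coef                                  # (N, T)
    contrast = recon.max(axis=0) - recon.min(axis=0)
    # absolute epsilon guards flat fields whose contrast is pure round-off
    eps = 1e-9 * max(1.0, float(np.abs(signal.values).max()))
    floor = max(contrast_floor * contrast.max(), eps) if contrast.max() > eps else np.inf
    nt = signal.n_times
    pos = np.full((nt, 3), np.nan)
    valid = np.zeros(nt, bool)
    ambiguous = np.zeros(nt, bool)
    for t in range(nt):
        if contrast[t] < floor or contrast[t] <= 0:
            continue
        r = recon[:, t]
        thresh = r.max() - 0.2 * contrast[t]
        w = np.clip(r - thresh, 0.0, None)
        p = (w[:, None] * mesh.nodes).sum(axis=0) / w.sum()
        d = p - mesh.center
        nd = np.linalg.norm(d)
        r_local = (w * rad).sum() / w.sum()
        if nd < 0.5 * r_local:
            # degenerate: antipodal tie or ring-like domain
            ambiguous[t] = True
            pos[t] = mesh.nodes[int(np.argmax(r))]
        else:
            pos[t] = mesh.center + d / nd * r_local
        valid[t] = True
    return DomainTrack(times=signal.times, positions=pos, valid=valid,
                       ambiguous=ambiguous, dt=signal.dt)


# ---------------------------------------------------------------------------
# velocity decomposition
# ---------------------------------------------------------------------------

@dataclass
class VelocitySummary:
    v_mean: float        # <v>, um/min
    v_theta: float       # <|v_theta|>, um/min
    v_phi: float         # <|v_phi|>, um/min
    v_a: float           # <v_phi> / <v_theta>; inf flagged when v_theta ~ 0
    n_steps: int
    v_a_flagged: bool

    def as_dict(self) -> dict:
        return {"v_mean": self.v_mean, "v_theta": self.v_theta,
                "v_phi": self.v_phi, "v_a": self.v_a, "n_steps": self.n_steps}


def decompose_velocity(track: DomainTrack, mesh: CellMesh) -> VelocitySummary:
    """Step speeds and their polar/azimuthal decomposition, in um/min.

    Each step is the straight-line chord between successive valid peaks over
    one frame interval; it is decomposed onto the local unit vectors along
    latitude (e_theta) and azimuth (e_phi) at the step midpoint, and absolute
    component values are averaged.  v_a = <v_phi>/<v_theta>; when <v_theta>
    is ~0 (purely azimuthal motion) v_a is flagged infinite.
    """
    idx = np.flatnonzero(track.valid)
    steps = [(i, j) for i, j in zip(idx[:-1], idx[1:]) if j == i + 1]
    if len(steps) < 5:
        raise ValueError("need at least 5 consecutive tracked steps")
    per_min = 60.0 / track.dt
    v, vth, vph = [], [], []
    for i, j in steps:
        d = track.positions[j] - track.positions[i]
        mid = 0.5 * (track.positions[i] + track.positions[j]) - mesh.center
        u = mid / np.linalg.norm(mid)
        horiz = np.array([-u[1], u[0], 0.0])
        nh = np.linalg.norm(horiz)
        if nh < 1e-9:          # midpoint at a pole: azimuth direction undefined
            continue
        e_phi = horiz / nh
        e_theta = np.cross(e_phi, u)   # points toward increasing latitude
        e_theta /= np.linalg.norm(e_theta)
        v.append(np.linalg.norm(d) * per_min)
        vth.append(abs(d @ e_theta) * per_min)
        vph.append(abs(d @ e_phi) * per_min)
    if len(v) < 5:
        raise ValueError("need at least 5 decomposable steps")
    v_mean, v_theta, v_phi = map(lambda a: float(np.mean(a)), (v, vth, vph))
    flagged = v_theta < 1e-9 * max(v_mean, 1.0)
    v_a = float("inf") if flagged else v_phi / v_theta
    return VelocitySummary(v_mean=v_mean, v_theta=v_theta, v_phi=v_phi,
                           v_a=v_a, n_steps=len(v), v_a_flagged=flagged)


# ---------------------------------------------------------------------------
# population fits
# ---------------------------------------------------------------------------

@dataclass
class PopulationFit:
    """Linear law v_a = m * r_a + n_0 derived from binned-median fits."""

    slope: float                    # m
    intercept: float                # n_0
    ra_fit: tuple[float, float]     # (slope, intercept) of median r_a vs delta_alpha
    va_fit: tuple[float, float]     # (slope, intercept) of median v_a vs delta_alpha
    n_cells: int
    n_bins: int

    def predict(self, r_a) -> np.ndarray:
        return self.slope * np.asarray(r_a) + self.intercept


def population_fits(table: pd.DataFrame, n_bins: int = 8) -> PopulationFit:
    """Reduce a per-cell table to the v_a = m r_a + n_0 law.

    ``table`` needs columns delta_alpha, r_a, v_a (flagged-infinite v_a rows
    are excluded).  delta_alpha is binned; per-bin medians of r_a and v_a are
    each fit linearly against the bin-center delta_alpha; eliminating
    delta_alpha between the two fits yields m and n_0.
    """
    need = {"delta_alpha", "r_a", "v_a"}
    if not need.issubset(table.columns):
        raise ValueError(f"table must contain columns {sorted(need)}")
    df = table.replace([np.inf, -np.inf], np.nan).dropna(subset=["delta_alpha", "r_a", "v_a"])
    if len(df) < 8:
        raise FitError(f"population fit needs >= 8 cells, got {len(df)}")
    da = df["delta_alpha"].to_numpy()
    edges = np.linspace(da.min(), da.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(da, edges) - 1, 0, n_bins - 1)
    centers, med_ra, med_va = [], [], []
    for b in range(n_bins):
        m = which == b
        if m.any():
            centers.append(np.median(da[m]))
            med_ra.append(df["r_a"].to_numpy()[m])
            med_va.append(df["v_a"].to_numpy()[m])
    if len(centers) < 3:
        raise FitError(f"only {len(centers)} occupied delta_alpha bins; need >= 3")
    x = np.asarray(centers)
    ra_med = np.array([np.median(v) for v in med_ra])
    va_med = np.array([np.median(v) for v in med_va])
    a_ra, b_ra = np.polyfit(x, ra_med, 1)
    a_va, b_va = np.polyfit(x, va_med, 1)
    if abs(a_ra) < 1e-12:
        raise FitError("no delta_alpha dependence of r_a; cannot eliminate delta_alpha")
    m = a_va / a_ra
    n0 = b_va - m * b_ra
    return PopulationFit(slope=float(m), intercept=float(n0),
                         ra_fit=(float(a_ra), float(b_ra)),
                         va_fit=(float(a_va), float(b_va)),
                         n_cells=len(df), n_bins=len(centers))
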