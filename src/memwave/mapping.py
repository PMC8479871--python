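"""Mollweide equal-area projection of per-node membrane fields, plus
azimuth-time kymographs of latitude bands.

The Mollweide projection maps the sphere onto a 2:1 ellipse while preserving
area: x = (2 sqrt(2) / pi) * lon * cos(gamma), y = sqrt(2) * sin(gamma), with
the auxiliary angle gamma solving 2 gamma + sin(2 gamma) = pi sin(lat) by
Newton-Raphson.  Maps are drawn with the azimuth phi horizontal and the
latitude theta vertical, the contact perimeter theta_adh as a dashed line.
"""

from __future__ import annotations

import numpy as np

from .reconstruction import CellMesh, SignalField

__all__ = [
    "solve_gamma",
    "mollweide_project",
    "mollweide_invert",
    "render_map",
    "extract_kymograph",
]

_SQRT2 = np.sqrt(2.0)


def solve_gamma(latitude, tol: float = 1e-10, max_iter: int = 100):
    """Auxiliary Mollweide angle: the root of 2g + sin(2g) = pi sin(latitude).

    Newton-Raphson from g0 = latitude; the poles (|lat| = pi/2) are returned
    analytically since the Newton derivative vanishes there.  Accepts scalars
    or arrays.
    """
    lat = np.asarray(latitude, float)
    if np.any(np.abs(lat) > np.pi / 2 + 1e-12):
        raise ValueError("|latitude| must not exceed pi/2")
    scalar = lat.ndim == 0
    lat = np.atleast_1d(lat)
    g = lat.copy()
    target = np.pi * np.sin(lat)
    pole = np.abs(np.abs(lat) - np.pi / 2) < 1e-12
    g[pole] = np.sign(lat[pole]) * np.pi / 2
    active = ~pole
    for _ in range(max_iter):
        if not active.any():
            break
        f = 2 * g[active] + np.sin(2 * g[active]) - target[active]
        df = 2 + 2 * np.cos(2 * g[active])
        step = f / np.maximum(df, 1e-12)
        g[active] -= step
        done = np.abs(f) < tol
        idx = np.flatnonzero(active)
        active[idx[done]] = False
    else:
        if active.any():
            raise RuntimeError("Newton-Raphson failed to converge for gamma")
    return float(g[0]) if scalar else g


def mollweide_project(longitude, latitude, tol: float = 1e-10):
    """Project (longitude, latitude) in radians to Mollweide (x, y).

    |x| <= 2 sqrt(2), |y| <= sqrt(2); area on the map equals solid angle on
    the unit sphere (total ellipse area 4 pi).
    """
    lon = np.asarray(longitude, float)
    g = solve_gamma(latitude, tol=tol)
    x = (2 * _SQRT2 / np.pi) * lon * np.cos(g)
    y = _SQRT2 * np.sin(g)
    return x, y


def mollweide_invert(x, y):
    """Inverse projection; returns (longitude, latitude), NaN outside the ellipse."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    with np.errstate(invalid="ignore"):
        g = np.arcsin(np.clip(y / _SQRT2, -1, 1))
        lat = np.arcsin(np.clip((2 * g + np.sin(2 * g)) / np.pi, -1, 1))
        cosg = np.cos(g)
        lon = np.where(cosg > 1e-12, np.pi * x / (2 * _SQRT2 * np.maximum(cosg, 1e-12)), 0.0)
    bad = (x / (2 * _SQRT2)) ** 2 + (y / _SQRT2) ** 2 > 1.0 + 1e-9
    bad |= np.abs(lon) > np.pi + 1e-9
    lon = np.where(bad, np.nan, lon)
    lat = np.where(bad, np.nan, lat)
    return lon, lat


# ---------------------------------------------------------------------------
# rasterized maps
# ---------------------------------------------------------------------------

def _seam_interpolator(mesh: CellMesh, node_values: np.ndarray):
    """Barycentric interpolant of node values over the (phi, theta) plane.

    Nodes are duplicated at phi +/- 2 pi so the interpolant covers the full
    longitude range without a seam; the plane is re-triangulated by Delaunay
    (the surface parameterization is injective, so plane triangulation is a
    faithful support for value interpolation).
    """
    from scipy.interpolate import LinearNDInterpolator

    pts = np.column_stack([
        np.concatenate([mesh.phi, mesh.phi + 2 * np.pi, mesh.phi - 2 * np.pi]),
        np.tile(mesh.theta, 3),
    ])
    vals = np.tile(node_values, 3)
    return LinearNDInterpolator(pts, vals)


def render_map(mesh: CellMesh, node_values: np.ndarray, n_x: int = 400,
               png_path=None, cmap: str = "viridis", title: str | None = None):
    """Rasterize a per-node scalar onto the Mollweide ellipse.

    Values are interpolated barycentrically on the (phi, theta) triangulation
    (with seam handling), evaluated at every map pixel via the analytic
    inverse projection.  Returns (map_matrix, extent); pixels outside the
    ellipse are NaN.  The contact perimeter is drawn as a dashed line when a
    PNG is written.
    """
    node_values = np.asarray(node_values, float)
    if node_values.shape != (mesh.n_nodes,):
        raise ValueError("need one value per mesh node")
    interp = _seam_interpolator(mesh, node_values)

    n_y = n_x // 2
    xs = np.linspace(-2 * _SQRT2, 2 * _SQRT2, n_x)
    ys = np.linspace(-_SQRT2, _SQRT2, n_y)
    gx, gy = np.meshgrid(xs, ys)
    lon, lat = mollweide_invert(gx, gy)
    grid = np.full(gx.shape, np.nan)
    ok = np.isfinite(lon)
    grid[ok] = interp(lon[ok], lat[ok])
    # fill pinholes inside the ellipse (pixels the triangulation misses near
    # the seam/poles) with the nearest node value
    hole = ok & ~np.isfinite(grid)
    if hole.any():
        from scipy.spatial import cKDTree

        tree = cKDTree(np.column_stack([mesh.phi, mesh.theta]))
        _, nn = tree.query(np.column_stack([lon[hole], lat[hole]]))
        grid[hole] = node_values[nn]
    extent = (-2 * _SQRT2, 2 * _SQRT2, -_SQRT2, _SQRT2)

    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 4))
        im = ax.imshow(grid, origin="lower", extent=extent, cmap=cmap, aspect="equal")
        if np.isfinite(mesh.theta_adh):
            lon_line = np.linspace(-np.pi, np.pi, 200)
            bx, by = mollweide_project(lon_line, np.full_like(lon_line, mesh.theta_adh))
            ax.plot(bx, by, "w--", lw=1.2)
        fig.colorbar(im, ax=ax, shrink=0.8)
        if title:
            ax.set_title(title)
        ax.set_xlabel("phi (Mollweide x)")
        ax.set_ylabel("theta (Mollweide y)")
        fig.savefig(png_path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return grid, extent


# ---------------------------------------------------------------------------
# kymographs
# ---------------------------------------------------------------------------

SECTIONS = ("bottom", "center", "top")


def extract_kymograph(signal: SignalField, mesh: CellMesh, section: str = "center",
                      n_phi: int = 60, band_width: float = 0.35) -> np.ndarray:
    """Azimuth x time matrix of the band-mean signal.

    Bands in latitude theta: "bottom" is the ventral membrane below theta_adh,
    "center" the equatorial band |theta| <= band_width/2, "top" the upper cap
    theta >= pi/2 - band_width.  Bin means are node-area weighted; azimuth is
    periodic.  Returns an (n_phi, n_t) array (NaN for empty azimuth bins).
    """
    if section not in SECTIONS:
        raise ValueError(f"section must be one of {SECTIONS}")
    if section == "bottom":
        if not np.isfinite(mesh.theta_adh) or not mesh.adherent.any():
            raise ValueError("bottom section undefined: cell has no contact area")
        sel = mesh.theta < mesh.theta_adh
    elif section == "center":
        sel = np.abs(mesh.theta) <= band_width / 2
    else:
        sel = mesh.theta >= np.pi / 2 - band_width
    if not sel.any():
        raise ValueError(f"no nodes in the {section!r} band")
    phi = mesh.phi[sel]
    w = mesh.node_areas[sel]
    vals = signal.values[sel]
    bins = np.floor((phi + np.pi) / (2 * np.pi) * n_phi).astype(int) % n_phi
    kymo = np.full((n_phi, signal.n_times), np.nan)
    for b in range(n_phi):
        m = bins == b
        if m.any():
            kymo[b] = (w[m, None] * vals[m]).sum(axis=0) / w[m].sum()
    return kymo
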