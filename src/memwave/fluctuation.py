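"""Detrended fluctuation analysis (DFA) of per-node membrane signals.

DFA quantifies the self-affinity of a time series s(t_i): the mean-removed
series is cumulated, S_i = sum_{k<=i} (s_k - mean(s)); within non-overlapping
windows of length tau samples the best least-squares polynomial P (order 1 by
default) is removed; the fluctuation function is the RMS residual,
F^2(tau) = <(S - P)^2>.  For a self-affine series F(tau) ~ tau^alpha, and the
scaling exponent alpha is the slope of log F vs log tau.  alpha ~ 0.5 marks
uncorrelated noise, alpha > 1 an underlying deterministic signal, alpha ~ 2 a
noise-free smooth oscillation sampled well below its period.

The default window set probes every integer tau from 4 samples up to
T_max / dt = 18 samples (T_max = 180 s at 10-s frames), the time scales on
which membrane signaling is stationary.  Mapping alpha node-by-node over the
membrane separates signal-dominant from noise-dominant regions; its latitude
profile is summarized by a weighted polynomial fit evaluated at the ventral
center (alpha_min, theta = -pi/2) and the contact perimeter (alpha_adh),
whose difference Delta-alpha = alpha_adh - alpha_min is the headline summary:
negative for an oscillatory ventral membrane, positive for a noise-dominated
one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reconstruction import CellMesh, SignalField

__all__ = [
    "DfaConfig",
    "AlphaMap",
    "AlphaProfile",
    "UndefinedAlphaError",
    "cumulate",
    "fluctuation_function",
    "dfa_alpha",
    "alpha_map",
    "alpha_profile",
]


class UndefinedAlphaError(ValueError):
    """The series is constant: F(tau) vanishes at every scale."""


@dataclass
class DfaConfig:
    """DFA parameters.

    t_max   largest window length in seconds (default 180 s)
    order   polynomial detrend order (1 = classic DFA1)
    tau_set explicit window lengths in samples; default all integers from
            order + 3 (>= 4 for DFA1) to floor(t_max / dt)
    """

    t_max: float = 180.0
    order: int = 1
    tau_set: np.ndarray | None = None

    def taus(self, dt: float, n_samples: int) -> np.ndarray:
        if self.tau_set is not None:
            taus = np.asarray(self.tau_set, int)
        else:
            lo = max(4, self.order + 2)
            hi = int(np.floor(self.t_max / dt))
            taus = np.arange(lo, hi + 1)
        taus = taus[taus <= n_samples]
        if len(taus) < 2:
            raise ValueError("need at least two window lengths <= series length")
        if (taus < self.order + 2).any():
            raise ValueError("window length must be >= order + 2 samples")
        return taus


@dataclass
class AlphaMap:
    """Per-node DFA exponents with fit quality."""

    alpha: np.ndarray       # (N,) exponent, NaN where undefined
    r_squared: np.ndarray   # (N,) log-log fit quality
    flagged: np.ndarray     # (N,) bool, True where alpha undefined

    @property
    def n_defined(self) -> int:
        return int((~self.flagged).sum())


@dataclass
class AlphaProfile:
    """Latitude profile of alpha and its polynomial summary."""

    bin_centers: np.ndarray
    bin_median: np.ndarray
    bin_weight: np.ndarray
    coefficients: np.ndarray          # np.polyval convention (highest first)
    alpha_min: float
    alpha_adh: float
    theta_adh: float

    @property
    def delta_alpha(self) -> float:
        """alpha_adh - alpha_min; NaN when the cell has no contact perimeter."""
        return self.alpha_adh - self.alpha_min

    def __call__(self, theta) -> np.ndarray:
        return np.polyval(self.coefficients, theta)


# ---------------------------------------------------------------------------
# core DFA
# ---------------------------------------------------------------------------

def cumulate(series: np.ndarray) -> np.ndarray:
    """Cumulated mean-removed sum S_i = sum_{k<=i} (s_k - mean(s)).

    Works on (..., time) arrays; the final entry is ~0 by construction.
    """
    s = np.asarray(series, float)
    if s.shape[-1] < 4:
        raise ValueError("series must have at least 4 samples")
    return np.cumsum(s - s.mean(axis=-1, keepdims=True), axis=-1)


def _segment_residuals(S: np.ndarray, tau: int, order: int) -> np.ndarray:
    """Squared residuals after per-segment polynomial detrending.

    S has shape (..., N); the leading floor(N/tau)*tau samples are split into
    non-overlapping segments of tau samples (the short tail is discarded) and
    the best least-squares polynomial of the given order is removed from each.
    Returns squared residuals of shape (..., n_seg, tau).
    """
    n = S.shape[-1]
    n_seg = n // tau
    if n_seg < 1:
        raise ValueError(f"window of {tau} samples exceeds series length {n}")
    seg = S[..., : n_seg * tau].reshape(*S.shape[:-1], n_seg, tau)
    x = np.arange(tau, dtype=float)
    # shared design matrix: hat matrix H projects each segment onto the
    # polynomial space, residual = (I - H) seg
    X = np.vander(x, order + 1, increasing=True)
    H = X @ np.linalg.pinv(X)
    resid = seg - seg @ H.T
    return resid**2


def fluctuation_function(S: np.ndarray, tau: int, order: int = 1) -> float | np.ndarray:
    """RMS fluctuation F(tau) of a cumulated series after detrending.

    F^2 is the mean squared residual over all samples covered by complete
    segments.  Accepts (..., time) arrays and returns F per leading index.
    """
    if tau < order + 2:
        raise ValueError("tau must be at least order + 2 samples")
    r2 = _segment_residuals(np.asarray(S, float), int(tau), order)
    F = np.sqrt(r2.mean(axis=(-2, -1)))
    return float(F) if np.ndim(F) == 0 else F


def dfa_alpha(series: np.ndarray, dt: float, config: DfaConfig | None = None):
    """DFA scaling exponent: slope of log F(tau) vs log tau.

    Returns (alpha, r_squared).  Raises UndefinedAlphaError for a constant
    series.  ``series`` may be (..., time); alpha is computed per row.
    """
    config = config or DfaConfig()
    s = np.asarray(series, float)
    taus = config.taus(dt, s.shape[-1])
    S = cumulate(s)
    F = np.stack([fluctuation_function(S, int(t), config.order) for t in taus], axis=-1)
    scalar = F.ndim == 1
    F2d = np.atleast_2d(F)
    bad = (F2d <= 0).any(axis=-1)
    if scalar and bad[0]:
        raise UndefinedAlphaError("constant series: F(tau) = 0, alpha undefined")
    logt = np.log(taus)
    lt = logt - logt.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        logF = np.log(F2d)
        alpha = (logF * lt).sum(axis=-1) / (lt**2).sum()
        fit = logF.mean(axis=-1, keepdims=True) + alpha[..., None] * lt
        ss_res = ((logF - fit) ** 2).sum(axis=-1)
        ss_tot = ((logF - logF.mean(axis=-1, keepdims=True)) ** 2).sum(axis=-1)
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
    alpha = np.where(bad, np.nan, alpha)
    r2 = np.where(bad, np.nan, r2)
    if scalar:
        return float(alpha[0]), float(r2[0])
    return alpha.reshape(F.shape[:-1]), r2.reshape(F.shape[:-1])


# ---------------------------------------------------------------------------
# whole-membrane maps and latitude profiles
# ---------------------------------------------------------------------------

def alpha_map(signal: SignalField, mesh: CellMesh,
              config: DfaConfig | None = None) -> AlphaMap:
    """DFA exponent at every mesh node (vectorized over nodes).

    Nodes with a constant series get alpha = NaN and are flagged; a flagged
    node never aborts the map.
    """
    if signal.values.shape[0] != mesh.n_nodes:
        raise ValueError("signal rows must match mesh nodes")
    alpha, r2 = dfa_alpha(signal.values, signal.dt, config)
    flagged = ~np.isfinite(alpha)
    return AlphaMap(alpha=alpha, r_squared=r2, flagged=flagged)


def alpha_profile(amap: AlphaMap, mesh: CellMesh, poly_order: int = 4,
                  n_bins: int = 24) -> AlphaProfile:
    """Latitude profile of alpha with a weighted polynomial summary.

    alpha values are binned by node latitude; each bin is summarized by its
    median, and a polynomial of ``poly_order`` is fit to the bin medians with
    weights = bin occupancy (summed node area).  The fit is evaluated at the
    ventral center (theta = -pi/2, alpha_min) and at the contact perimeter
    (theta_adh, alpha_adh); their difference is delta_alpha.  For a cell with
    no contact area alpha_adh (and hence delta_alpha) is NaN.
    """
    ok = ~amap.flagged
    if not ok.any():
        raise UndefinedAlphaError("no node has a defined alpha")
    theta = mesh.theta[ok]
    alpha = amap.alpha[ok]
    area = mesh.node_areas[ok]
    edges = np.linspace(-np.pi / 2, np.pi / 2, n_bins + 1)
    which = np.clip(np.digitize(theta, edges) - 1, 0, n_bins - 1)
    centers, med, wgt = [], [], []
    for b in range(n_bins):
        m = which == b
        if m.any():
            centers.append(0.5 * (edges[b] + edges[b + 1]))
            med.append(np.median(alpha[m]))
            wgt.append(area[m].sum())
    if len(centers) < max(10, poly_order + 1):
        raise ValueError(f"only {len(centers)} populated latitude bins; need >= 10")
    centers = np.asarray(centers)
    med = np.asarray(med)
    wgt = np.asarray(wgt)
    # np.polyfit weights multiply residuals, i.e. minimizes sum (w (y - f))^2
    coeff = np.polyfit(centers, med, poly_order, w=np.sqrt(wgt))
    alpha_min = float(np.polyval(coeff, -np.pi / 2))
    if np.isfinite(mesh.theta_adh):
        alpha_adh = float(np.polyval(coeff, mesh.theta_adh))
    else:
        alpha_adh = float("nan")
    return AlphaProfile(bin_centers=centers, bin_median=med, bin_weight=wgt,
                        coefficients=coeff, alpha_min=alpha_min,
                        alpha_adh=alpha_adh, theta_adh=mesh.theta_adh)
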