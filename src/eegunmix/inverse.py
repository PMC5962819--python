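"""Linear inverse operators, the resolution matrix, and resolution diagnostics.

A linear inverse solution estimates sources as ``jhat = A v``.  Composed with
the forward map this gives ``jhat = R j`` with ``R = A K`` the resolution
matrix; how far R sits from the identity quantifies the leakage that the
unmixing step corrects.  Besides the minimum-norm and sLORETA operators this
module provides the two diagnostics used to characterize an operator on a
grid: per-voxel localization error and the minimum inter-source distance at
which a two-point unmixing system is still invertible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .headmodel import LeadField, SourceSpace

__all__ = [
    "InverseOperator",
    "ResolutionMatrix",
    "default_alpha",
    "mne_operator",
    "sloreta_operator",
    "custom_operator",
    "resolution_matrix",
    "localization_error",
    "min_unmixing_distance",
]

_PINV_RTOL = 1e-12


@dataclass(frozen=True)
class InverseOperator:
    A: np.ndarray  # (p, d)
    method: str  # "mne" | "sloreta" | "custom"
    alpha: float
    orientation_mode: str  # "free" | "fixed"

    def __post_init__(self):
        A = np.asarray(self.A, float)
        object.__setattr__(self, "A", A)
        if A.ndim != 2:
            raise ValueError("A must be a 2-D matrix")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.orientation_mode not in ("free", "fixed"):
            raise ValueError("orientation_mode must be 'free' or 'fixed'")

    def apply(self, v: np.ndarray) -> np.ndarray:
        """Source estimate(s) from voltage vector or (d, T) matrix."""
        return self.A @ np.asarray(v, float)


@dataclass(frozen=True)
class ResolutionMatrix:
    R: np.ndarray  # (p, p)
    orientation_mode: str
    source_space: SourceSpace | None = field(default=None, compare=False)

    def __post_init__(self):
        R = np.asarray(self.R, float)
        object.__setattr__(self, "R", R)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("R must be square")
        if self.orientation_mode not in ("free", "fixed"):
            raise ValueError("orientation_mode must be 'free' or 'fixed'")

    @property
    def n_voxels(self) -> int:
        p = self.R.shape[0]
        return p // 3 if self.orientation_mode == "free" else p

    def block(self, u: int, w: int) -> np.ndarray:
        """The (3x3 or scalar) block coupling true source w into estimate u."""
        if self.orientation_mode == "fixed":
            return self.R[u, w]
        return self.R[3 * u : 3 * u + 3, 3 * w : 3 * w + 3]

    def collapse(self, directions: np.ndarray) -> "ResolutionMatrix":
        """Scalar resolution matrix d(u)^T R(u,w) d(w) along given directions."""
        if self.orientation_mode == "fixed":
            return self
        N = self.n_voxels
        D = np.asarray(directions, float)
        if D.shape != (N, 3):
            raise ValueError(f"directions must be ({N}, 3)")
        Rr = self.R.reshape(N, 3, N, 3)
        Rd = np.einsum("ua,uawb,wb->uw", D, Rr, D)
        return ResolutionMatrix(Rd, "fixed", self.source_space)


def _centering(d: int) -> np.ndarray:
    return np.eye(d) - np.ones((d, d)) / d


def _psd_pinv(M: np.ndarray, rtol: float = _PINV_RTOL) -> np.ndarray:
    """Moore-Penrose pseudo-inverse of a symmetric PSD matrix via eigh."""
    lam, U = np.linalg.eigh((M + M.T) / 2)
    lam_max = lam[-1]
    inv = np.where(lam > rtol * lam_max, 1.0 / np.where(lam > 0, lam, 1.0), 0.0)
    return (U * inv) @ U.T


def default_alpha(K: LeadField) -> float:
    """Default Tikhonov weight: 1e-5 * trace(K K^T) / d."""
    G = K.gain
    return 1e-5 * float(np.einsum("ij,ij->", G, G)) / K.n_electrodes


def _require_average(K: LeadField):
    if K.reference_state != "average":
        raise ValueError("inverse operators require an average-referenced lead field")


def mne_operator(K: LeadField, alpha: float = 0.0) -> InverseOperator:
    """Minimum-norm operator A = K^T (K K^T + alpha H)^+."""
    _require_average(K)
    G = K.gain
    d = K.n_electrodes
    M = G @ G.T + alpha * _centering(d)
    return InverseOperator(G.T @ _psd_pinv(M), "mne", alpha, K.orientation_mode)


def sloreta_operator(K: LeadField, alpha: float = 0.0) -> InverseOperator:
    """Standardized minimum-norm (sLORETA) operator.

    With T = K^T (K K^T + alpha H)^+ and S = T K, the row block of A for
    voxel u is S(u,u)^(-1/2) T(u,:) — a symmetric 3x3 inverse square root in
    free mode, the scalar 1/sqrt(S(u,u)) in fixed mode.  The standardization
    is what gives the operator its zero localization error for noiseless
    single dipoles.
    """
    _require_average(K)
    G = K.gain
    d = K.n_electrodes
    Tmat = G.T @ _psd_pinv(G @ G.T + alpha * _centering(d))
    S = Tmat @ G
    N = K.n_voxels
    A = np.empty_like(Tmat)
    if K.orientation_mode == "fixed":
        diag = np.diag(S)
        if np.any(diag <= 0):
            u = int(np.argmin(diag))
            raise ArithmeticError(f"singular standardization at voxel {u}")
        A = Tmat / np.sqrt(diag)[:, None]
    else:
        for u in range(N):
            blk = S[3 * u : 3 * u + 3, 3 * u : 3 * u + 3]
            lam, U = np.linalg.eigh((blk + blk.T) / 2)
            good = lam > 1e-12 * max(lam[-1], 0.0)
            if not np.any(good):
                raise ArithmeticError(f"singular standardization at voxel {u}")
            inv_sqrt = (U[:, good] / np.sqrt(lam[good])) @ U[:, good].T
            A[3 * u : 3 * u + 3] = inv_sqrt @ Tmat[3 * u : 3 * u + 3]
    return InverseOperator(A, "sloreta", alpha, K.orientation_mode)


def custom_operator(A: np.ndarray, orientation_mode: str, alpha: float = 0.0) -> InverseOperator:
    """Wrap an externally built operator (e.g., eLORETA) for use downstream.

    Everything past the inverse step consumes only the resolution matrix, so
    any linear operator can be injected here.
    """
    return InverseOperator(A, "custom", alpha, orientation_mode)


def resolution_matrix(op: InverseOperator, K: LeadField) -> ResolutionMatrix:
    """R = A K; in the noiseless case jhat = R j for any source j."""
    if op.orientation_mode != K.orientation_mode:
        raise ValueError("operator and lead field orientation modes differ")
    if op.A.shape[1] != K.n_electrodes or op.A.shape[0] != K.gain.shape[1]:
        raise ValueError("operator and lead field dimensions do not match")
    return ResolutionMatrix(op.A @ K.gain, K.orientation_mode, K.source_space)


def _estimate_power(op: InverseOperator, est: np.ndarray) -> np.ndarray:
    """Per-voxel power of source estimates, columns = simulated sources."""
    if op.orientation_mode == "fixed":
        return est**2
    N = est.shape[0] // 3
    return (est.reshape(N, 3, -1) ** 2).sum(axis=1)


def localization_error(
    op: InverseOperator,
    K: LeadField,
    src: SourceSpace,
    directions: np.ndarray | None = None,
) -> np.ndarray:
    """Distance from each voxel to the power peak of its noiseless estimate.

    A unit point source is simulated at every voxel (along ``directions`` in
    free mode, defaulting to the grid normals) and located at the voxel whose
    estimated (standardized, for sLORETA) power is maximal; ties break to the
    lowest voxel index.
    """
    if K.orientation_mode == "free":
        if directions is None:
            directions = src.normals
        if directions is None:
            raise ValueError("free-orientation localization needs dipole directions")
        blocks = K.gain.reshape(K.n_electrodes, src.n_voxels, 3)
        V = np.einsum("dua,ua->du", blocks, np.asarray(directions, float))
    else:
        V = K.gain  # column u is already the unit source at voxel u
    est = op.apply(V)  # (p, N) estimates, one column per simulated source
    power = _estimate_power(op, est)  # (N, N)
    peak = np.argmax(power, axis=0)  # first-occurrence = lowest index
    return np.linalg.norm(src.positions[peak] - src.positions, axis=1)


def _cond_2x2(a, b, c, d):
    """2-norm condition numbers of [[a, b], [c, d]], vectorized."""
    t = a * a + b * b + c * c + d * d
    det = a * d - b * c
    disc = np.sqrt(np.maximum(0.0, t * t - 4 * det * det))
    s1 = np.sqrt((t + disc) / 2)
    s2sq = np.maximum(0.0, (t - disc) / 2)
    s2 = np.sqrt(s2sq)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(s2 > 0, s1 / np.where(s2 > 0, s2, 1.0), np.inf)


def min_unmixing_distance(
    R: ResolutionMatrix,
    src: SourceSpace,
    directions: np.ndarray | None = None,
    cond_threshold: float = 1e8,
) -> np.ndarray:
    """Smallest separation at which every farther voxel pair can be unmixed.

    For each voxel u, the two-point directional unmixing system for {u, w}
    is the 2x2 matrix [[R_uu, R_uw], [R_wu, R_ww]]; the result is the
    smallest distance r such that this system has condition number below
    ``cond_threshold`` for every w at distance >= r.  Scanning is over grid
    distances: if no pair fails, r is the nearest-neighbor distance; if some
    pair at distance delta fails, r is the smallest grid distance beyond
    delta (inf when the farthest pair fails).
    """
    Rs = R.collapse(directions).R if R.orientation_mode == "free" else R.R
    if R.orientation_mode == "free" and directions is None:
        raise ValueError("free-orientation R needs directions to collapse")
    N = Rs.shape[0]
    if src.n_voxels != N:
        raise ValueError("source space does not match R")
    diff = src.positions[:, None, :] - src.positions[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    diag = np.diag(Rs)
    out = np.empty(N)
    for u in range(N):
        others = np.arange(N) != u
        cond = _cond_2x2(
            np.full(N, diag[u]), Rs[u, :], Rs[:, u], diag
        )
        bad = others & ~(cond < cond_threshold)
        du = dist[u]
        if not np.any(bad):
            out[u] = du[others].min()
        else:
            dmax_bad = du[bad].max()
            beyond = others & (du > dmax_bad)
            out[u] = du[beyond].min() if np.any(beyond) else np.inf
    return out
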