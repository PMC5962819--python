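"""MAR source simulators, scenario builders, and the noisy forward solver.

All validation scenarios share the same skeleton: a small stable MAR(2)
system drives a handful of source voxels or regions on a synthetic cortical
shell; the forward model maps the source field to scalp voltages (optionally
with measurement noise); the inverse/unmixing/connectivity stack then has to
recover the directed interaction pattern.

The three-node system is fully specified (coefficients and unit innovation
covariance); the larger 5- and 17-node systems fix the connection topology
exactly and draw coupling magnitudes from the same small palette of values,
with an automatic down-scaling rescue if a draw lands outside the stability
region — a reconstruction of the published setup, not a value-for-value
reproduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .headmodel import ElectrodeMontage, LeadField, SourceSpace, average_reference
from .unmix import Parcellation

__all__ = [
    "MARModel",
    "TimeSeriesSet",
    "three_node_mar_model",
    "five_node_mar_model",
    "extended_17node_model",
    "true_edge_set",
    "mar_simulate",
    "region_spatial_profile",
    "nearest_voxels_to_electrodes",
    "scenario_point_sources",
    "scenario_surface_regions",
    "forward",
]


@dataclass(frozen=True)
class MARModel:
    """Multivariate autoregressive model X(t) = sum_k A(k) X(t-k) + e(t)."""

    coeffs: np.ndarray  # (P, n, n)
    cov: np.ndarray  # (n, n) innovation covariance, symmetric PSD
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        A = np.asarray(self.coeffs, float)
        V = np.asarray(self.cov, float)
        object.__setattr__(self, "coeffs", A)
        object.__setattr__(self, "cov", V)
        if A.ndim != 3 or A.shape[1] != A.shape[2]:
            raise ValueError("coeffs must be (P, n, n)")
        n = A.shape[1]
        if V.shape != (n, n):
            raise ValueError("cov must be (n, n)")
        if not np.allclose(V, V.T, atol=1e-10):
            raise ValueError("cov must be symmetric")
        if np.linalg.eigvalsh((V + V.T) / 2).min() < -1e-10:
            raise ValueError("cov must be positive semi-definite")
        if self.labels is not None:
            labels = tuple(self.labels)
            if len(labels) != n:
                raise ValueError("labels must match the model dimension")
            object.__setattr__(self, "labels", labels)

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_vars(self) -> int:
        return self.coeffs.shape[1]

    def companion(self) -> np.ndarray:
        """The (nP x nP) companion matrix of the lag polynomial."""
        P, n = self.order, self.n_vars
        C = np.zeros((n * P, n * P))
        C[:n] = self.coeffs.transpose(1, 0, 2).reshape(n, n * P)
        if P > 1:
            C[n:, :-n] = np.eye(n * (P - 1))
        return C

    @property
    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.companion())).max())

    @property
    def is_stable(self) -> bool:
        return self.spectral_radius < 1.0


@dataclass(frozen=True)
class TimeSeriesSet:
    """Channels x samples array with labels; sampling rate 1 by convention,
    so frequencies are fractions of the sampling rate."""

    values: np.ndarray  # (n, T)
    labels: tuple[str, ...] | None = None
    sfreq: float = 1.0

    def __post_init__(self):
        vals = np.atleast_2d(np.asarray(self.values, float))
        object.__setattr__(self, "values", vals)
        if not np.all(np.isfinite(vals)):
            raise ValueError("time series must be finite")
        if vals.shape[1] < 1:
            raise ValueError("need at least one sample")
        if self.labels is not None:
            labels = tuple(self.labels)
            if len(labels) != vals.shape[0]:
                raise ValueError("labels must match the number of channels")
            object.__setattr__(self, "labels", labels)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def three_node_mar_model() -> MARModel:
    """The fully specified three-variable MAR(2) reference system.

    X1 and X2 drive each other, X2 drives X3, X3 drives nothing; innovations
    are unit-variance white noise.
    """
    A1 = np.array(
        [
            [1.5, -0.25, 0.0],
            [-0.25, 1.8, 0.0],
            [0.0, 0.5, 1.3],
        ]
    )
    A2 = np.diag([-0.95, -0.96, -0.95])
    return MARModel(np.stack([A1, A2]), np.eye(3), ("X1", "X2", "X3"))


# Directed interaction topologies for the larger systems.  Bidirectional
# Fp1<->Fp2; every other link is unidirectional; O1/O2 receive nothing.
_FIVE_NODE_LABELS = ("Fp1", "Fp2", "F3", "F4", "O1")
_FIVE_NODE_EDGES = (
    ("Fp1", "Fp2"),
    ("Fp2", "Fp1"),
    ("F3", "Fp1"),
    ("F3", "F4"),
    ("F4", "Fp2"),
    ("O1", "F3"),
)

_SEVENTEEN_LABELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3",
    "C4", "T4", "T5", "P3", "P4", "T6", "O1", "O2",
)
_SEVENTEEN_EDGES = (
    ("Fp1", "Fp2"), ("Fp2", "Fp1"),
    ("F3", "Fp1"), ("F4", "Fp2"),
    ("C3", "F3"), ("C4", "F4"),
    ("P3", "C3"), ("P4", "C4"),
    ("T5", "P3"), ("T6", "P4"),
    ("O1", "T5"), ("O2", "T6"),
    ("T5", "F7"), ("F7", "Fz"), ("F7", "T3"),
    ("T3", "T4"), ("Fz", "F8"),
)

_DIAG_A1 = (1.5, 1.8, 1.3)
_DIAG_A2 = (-0.95, -0.96, -0.95)
_COUPLINGS = (-0.25, 0.5)


def _mar_from_topology(labels, edges, seed, radius_limit=0.98) -> MARModel:
    """Seeded MAR(2) with the given directed topology.

    Apart from bidirectional pairs the edge set forms a DAG, so the lag
    matrices are block-triangular over strongly connected components and the
    one-way couplings cannot move eigenvalues; each bidirectional pair is
    pinned to the reference feedback block of the three-node system.  The
    model is therefore stable by construction whenever the per-node AR(2)
    modules are; a shrink-couplings rescue remains as a safety net.
    """
    rng = np.random.default_rng(seed)
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    edge_set_ = set(edges)
    bidir = {
        tuple(sorted((a, b))) for a, b in edges if (b, a) in edge_set_
    }
    A1 = np.diag(rng.choice(_DIAG_A1, size=n))
    A2 = np.diag(rng.choice(_DIAG_A2, size=n))
    C = np.zeros((n, n))
    for src_lab, dst_lab in edges:
        C[idx[dst_lab], idx[src_lab]] = rng.choice(_COUPLINGS)
    for a, b in bidir:
        ia, ib = idx[a], idx[b]
        A1[ia, ia], A2[ia, ia] = 1.5, -0.95
        A1[ib, ib], A2[ib, ib] = 1.8, -0.96
        C[ia, ib] = C[ib, ia] = -0.25
    scale = 1.0  # couplings enter A(1) off-diagonally only; shrink until stable
    for _ in range(60):
        model = MARModel(np.stack([A1 + scale * C, A2]), np.eye(n), tuple(labels))
        if model.spectral_radius < radius_limit:
            return model
        scale *= 0.8
    raise ArithmeticError("could not stabilize the MAR topology")


def five_node_mar_model(seed: int = 0) -> MARModel:
    """Five frontal/occipital sources with the fixed 6-edge topology
    (Fp1<->Fp2, F3->Fp1, F3->F4, F4->Fp2, O1->F3)."""
    return _mar_from_topology(_FIVE_NODE_LABELS, _FIVE_NODE_EDGES, seed)


def extended_17node_model(seed: int = 0) -> MARModel:
    """Seventeen sources named after 10-20 electrodes with a fixed complex
    topology: Fp1<->Fp2 bidirectional, all other links unidirectional,
    O1/O2 pure senders.  Coupling magnitudes are seeded draws from the
    three-node palette with a stability rescue."""
    return _mar_from_topology(_SEVENTEEN_LABELS, _SEVENTEEN_EDGES, seed)


def true_edge_set(model: MARModel) -> set[tuple[str, str]]:
    """Directed (source, target) pairs with any nonzero off-diagonal lag
    coefficient."""
    labels = model.labels or tuple(str(i + 1) for i in range(model.n_vars))
    nz = np.any(model.coeffs != 0.0, axis=0)
    return {
        (labels[j], labels[i])
        for i in range(model.n_vars)
        for j in range(model.n_vars)
        if i != j and nz[i, j]
    }


def mar_simulate(
    model: MARModel,
    T: int,
    burnin: int = 1000,
    seed: int = 0,
) -> TimeSeriesSet:
    """Simulate a stable MAR model with Gaussian innovations.

    State starts at zero; the first ``burnin`` samples are discarded so the
    retained segment is effectively stationary.  Refuses unstable models.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rho = model.spectral_radius
    if rho >= 1.0:
        raise ValueError(f"model is unstable (companion spectral radius {rho:.4f})")
    rng = np.random.default_rng(seed)
    n, P = model.n_vars, model.order
    lam, U = np.linalg.eigh(model.cov)
    Lfac = U * np.sqrt(np.clip(lam, 0.0, None))
    E = (Lfac @ rng.standard_normal((n, T + burnin)))
    X = np.zeros((n, T + burnin + P))
    A = model.coeffs
    for t in range(T + burnin):
        acc = E[:, t].copy()
        for k in range(P):
            acc += A[k] @ X[:, P + t - 1 - k]
        X[:, P + t] = acc
    return TimeSeriesSet(X[:, P + burnin :], model.labels)


def nearest_voxels_to_electrodes(
    src: SourceSpace,
    montage: ElectrodeMontage,
    labels,
) -> np.ndarray:
    """Grid voxel nearest to each electrode's radial projection.

    The projection point is the electrode direction scaled to the voxel's
    shell radius, so this picks the voxel "under" the electrode.  Raises if
    two labels collapse onto the same voxel.
    """
    unit = src.positions / np.maximum(src.depth, 1e-300)[:, None]
    out = []
    for lab in labels:
        e = montage.positions[montage.index(lab)]
        out.append(int(np.argmax(unit @ e)))
    if len(set(out)) != len(out):
        raise ValueError("two electrode labels map to the same nearest voxel")
    return np.asarray(out, int)


def scenario_point_sources(
    series: TimeSeriesSet,
    src: SourceSpace,
    montage: ElectrodeMontage,
    target_labels,
    background_sd: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Point-source scenario: each series channel becomes the intensity of
    the voxel nearest its named electrode (oriented along the voxel normal),
    and independent Gaussian noise of ``background_sd`` is added at every
    voxel.  Returns the (N, T) normal-intensity field; expand against a
    free-orientation lead field via the grid normals if needed."""
    target_labels = list(target_labels)
    if series.n_channels != len(target_labels):
        raise ValueError("one series channel is needed per target label")
    vox = nearest_voxels_to_electrodes(src, montage, target_labels)
    rng = np.random.default_rng(seed)
    X = np.zeros((src.n_voxels, series.n_samples))
    if background_sd > 0:
        X += background_sd * rng.standard_normal(X.shape)
    X[vox] += series.values
    return X


def region_spatial_profile(src: SourceSpace, region: np.ndarray, width: float | None = None):
    """Gaussian spatial weight over a region, equal to 1 at the voxel closest
    to the region centroid; default width is half the centroid-to-edge
    distance."""
    pos = src.positions[region]
    centroid = pos.mean(axis=0)
    center_vox = region[int(np.argmin(np.linalg.norm(pos - centroid, axis=1)))]
    dist = np.linalg.norm(pos - src.positions[center_vox], axis=1)
    if width is None:
        width = max(dist.max() / 2, 1e-12)
    return np.exp(-(dist**2) / (2 * width**2))


def scenario_surface_regions(
    series: TimeSeriesSet,
    src: SourceSpace,
    parc: Parcellation,
    region_targets,
    sd_within: float = 0.1,
    seed: int = 0,
    profile_width: float | None = None,
) -> np.ndarray:
    """Surface-region scenario: every voxel of a target region carries its
    region's series scaled by a Gaussian spatial profile centered on the
    region centroid, plus independent per-voxel noise; all remaining voxels
    are white noise of the same sd.  Returns the (N, T) intensity field."""
    region_targets = list(region_targets)
    if series.n_channels != len(region_targets):
        raise ValueError("one series channel is needed per target region")
    for l in region_targets:
        if not 0 <= l < parc.n_regions:
            raise ValueError(f"unknown region id {l}")
    rng = np.random.default_rng(seed)
    X = np.zeros((src.n_voxels, series.n_samples))
    if sd_within > 0:
        X += sd_within * rng.standard_normal(X.shape)
    for ch, l in enumerate(region_targets):
        region = parc.regions[l]
        w = region_spatial_profile(src, region, profile_width)
        X[region] += w[:, None] * series.values[ch][None, :]
    return X


def forward(
    K: LeadField,
    J: np.ndarray,
    measurement_sd: float = 0.0,
    seed: int = 0,
) -> TimeSeriesSet:
    """Scalp voltages v(t) = K j(t) + noise, re-centered to average reference.

    ``J`` is (p,) or (p, T) in the lead field's orientation mode (intensity
    per voxel for fixed mode, stacked 3-vectors for free mode).
    """
    if K.reference_state != "average":
        raise ValueError("forward projection expects an average-referenced lead field")
    J = np.asarray(J, float)
    V = K.gain @ (J[:, None] if J.ndim == 1 else J)
    if measurement_sd > 0:
        rng = np.random.default_rng(seed)
        V = V + measurement_sd * rng.standard_normal(V.shape)
    V = average_reference(V)
    return TimeSeriesSet(V if J.ndim > 1 else V, labels=None)
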