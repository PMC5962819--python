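"""Head geometry, electrode montages and the three-concentric-spheres forward model.

The head is a dimensionless three-shell sphere (brain, skull, scalp; scalp
radius 1 by convention).  Sources are current dipoles on synthetic spherical
grids strictly inside the brain shell.  The forward map is the analytic
Legendre-series solution for a dipole in three concentric homogeneous
spheres; its output is the lead field matrix ``K`` that sends a stacked
source vector to scalp potentials, ``v = K j``.

Only ratios and spatial patterns of the gain matter for everything built on
top (inverse operators, resolution matrices, unmixing), so gain units are
arbitrary-but-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

__all__ = [
    "ElectrodeMontage",
    "SphereHeadModel",
    "SourceSpace",
    "LeadField",
    "DEFAULT_HEAD",
    "standard_1020_montage",
    "spherical_cortex_grid",
    "three_sphere_leadfield",
    "average_reference",
    "project_to_directions",
    "leadfield_rank",
]

_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class ElectrodeMontage:
    """Named electrode positions on the unit scalp sphere."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (d, 3), unit vectors

    def __post_init__(self):
        positions = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) < 2:
            raise ValueError("a montage needs at least 2 electrodes")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("electrode labels must be unique")
        if positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (d, 3)")
        norms = np.linalg.norm(positions, axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError("electrode positions must lie on the unit sphere")

    @property
    def n_electrodes(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass(frozen=True)
class SphereHeadModel:
    """Three concentric homogeneous shells: brain, skull, scalp.

    Radii are strictly increasing with scalp = 1 by convention; the default
    conductivities use the classical 80:1 scalp-to-skull ratio.  All units
    are relative.
    """

    radii: tuple[float, float, float] = (0.87, 0.92, 1.0)
    conductivities: tuple[float, float, float] = (1.0, 0.0125, 1.0)

    def __post_init__(self):
        r = np.asarray(self.radii, float)
        c = np.asarray(self.conductivities, float)
        if r.shape != (3,) or c.shape != (3,):
            raise ValueError("expected 3 radii and 3 conductivities")
        if not (0 < r[0] < r[1] < r[2]):
            raise ValueError("radii must be strictly increasing and positive")
        if np.any(c <= 0):
            raise ValueError("conductivities must be positive")

    @property
    def brain_radius(self) -> float:
        return self.radii[0]

    @property
    def scalp_radius(self) -> float:
        return self.radii[2]


DEFAULT_HEAD = SphereHeadModel()


@dataclass(frozen=True)
class SourceSpace:
    """Grid of voxel positions (strictly inside the brain shell) with
    optional unit normals; ``depth[u]`` is the distance to the head center."""

    positions: np.ndarray  # (N, 3)
    normals: np.ndarray | None = None  # (N, 3) unit vectors

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, float))
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if self.normals is not None:
            nor = np.atleast_2d(np.asarray(self.normals, float))
            if nor.shape != pos.shape:
                raise ValueError("normals must match positions in shape")
            if np.any(np.abs(np.linalg.norm(nor, axis=1) - 1.0) > _UNIT_TOL):
                raise ValueError("normals must be unit-length")
            object.__setattr__(self, "normals", nor)

    @property
    def n_voxels(self) -> int:
        return self.positions.shape[0]

    @property
    def depth(self) -> np.ndarray:
        return np.linalg.norm(self.positions, axis=1)


@dataclass(frozen=True)
class LeadField:
    """Electrode x source gain matrix.

    ``orientation_mode`` is ``"free"`` (3 columns per voxel, stacked x,y,z
    voxel-major, p = 3 N) or ``"fixed"`` (one column per voxel, p = N).
    ``reference_state`` records whether the rows have been centered to the
    average reference; centered columns sum to zero.
    """

    gain: np.ndarray  # (d, p)
    orientation_mode: str  # "free" | "fixed"
    reference_state: str = "raw"  # "raw" | "average"
    source_space: SourceSpace | None = field(default=None, compare=False)

    def __post_init__(self):
        gain = np.asarray(self.gain, float)
        object.__setattr__(self, "gain", gain)
        if gain.ndim != 2:
            raise ValueError("gain must be a 2-D matrix")
        if self.orientation_mode not in ("free", "fixed"):
            raise ValueError("orientation_mode must be 'free' or 'fixed'")
        if self.reference_state not in ("raw", "average"):
            raise ValueError("reference_state must be 'raw' or 'average'")
        if self.orientation_mode == "free" and gain.shape[1] % 3:
            raise ValueError("free-orientation gain needs p divisible by 3")
        if self.reference_state == "average":
            col = np.abs(gain.sum(axis=0))
            scale = np.linalg.norm(gain, axis=0)
            if np.any(col > _UNIT_TOL * np.maximum(scale, 1.0)):
                raise ValueError("average-referenced gain columns must sum to 0")

    @property
    def n_electrodes(self) -> int:
        return self.gain.shape[0]

    @property
    def n_voxels(self) -> int:
        p = self.gain.shape[1]
        return p // 3 if self.orientation_mode == "free" else p


def standard_1020_montage() -> ElectrodeMontage:
    """The 19-channel 10-20 montage on the unit sphere.

    Coordinates ship with the package (``data/montage_1020.txt``); the file
    documents the angular construction.
    """
    text = resources.files("eegunmix").joinpath("data/montage_1020.txt").read_text()
    labels, rows = [], []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        labels.append(parts[0])
        rows.append([float(v) for v in parts[1:4]])
    pos = np.asarray(rows)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return ElectrodeMontage(tuple(labels), pos)


def spherical_cortex_grid(
    n_voxels: int,
    radius: float,
    seed: int = 0,
    *,
    head: SphereHeadModel = DEFAULT_HEAD,
    inner_offset: float | None = None,
) -> SourceSpace:
    """Quasi-uniform (Fibonacci lattice) shell of voxels with radial normals.

    The lattice is rotated by a seeded random rotation so distinct seeds give
    distinct (but equally uniform) grids; a fixed seed is fully deterministic.
    With ``inner_offset`` a second concentric shell at ``radius - inner_offset``
    is appended (same angular positions), giving a two-layer grid whose first
    ``n_voxels`` entries are the superficial layer.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    if not 0 < radius < head.brain_radius:
        raise ValueError(
            f"grid radius must lie in (0, {head.brain_radius}) (brain shell); got {radius}"
        )
    if inner_offset is not None and not 0 < inner_offset < radius:
        raise ValueError("inner_offset must lie in (0, radius)")

    i = np.arange(n_voxels)
    golden = (1 + 5**0.5) / 2
    z = 1 - (2 * i + 1) / n_voxels
    theta = 2 * np.pi * i / golden
    s = np.sqrt(1 - z**2)
    unit = np.column_stack([s * np.cos(theta), s * np.sin(theta), z])

    # seeded random rotation (QR of a Gaussian matrix, det corrected)
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    unit = unit @ q.T

    radii = [radius] if inner_offset is None else [radius, radius - inner_offset]
    pos = np.vstack([r_ * unit for r_ in radii])
    normals = np.vstack([unit for _ in radii])
    return SourceSpace(pos, normals)


def _shell_gain_factors(head: SphereHeadModel, n_terms: int) -> np.ndarray:
    """Per-harmonic transmission through the three shells.

    For each degree n, the potential in the shells is a combination of r^n and
    r^-(n+1) harmonics; continuity of potential and radial current at the two
    interfaces plus the insulating scalp boundary give a 5x5 linear system per
    degree.  ``T[n]`` is the scalp-surface coefficient produced by a unit
    dipole-source coefficient in the brain shell.
    """
    r1, r2, r3 = head.radii
    s1, s2, s3 = head.conductivities
    T = np.zeros(n_terms + 1)
    for n in range(1, n_terms + 1):
        M = np.array(
            [
                [r1**n, -(r1**n), -(r1 ** -(n + 1)), 0.0, 0.0],
                [
                    s1 * n * r1 ** (n - 1),
                    -s2 * n * r1 ** (n - 1),
                    s2 * (n + 1) * r1 ** -(n + 2),
                    0.0,
                    0.0,
                ],
                [0.0, r2**n, r2 ** -(n + 1), -(r2**n), -(r2 ** -(n + 1))],
                [
                    0.0,
                    s2 * n * r2 ** (n - 1),
                    -s2 * (n + 1) * r2 ** -(n + 2),
                    -s3 * n * r2 ** (n - 1),
                    s3 * (n + 1) * r2 ** -(n + 2),
                ],
                [0.0, 0.0, 0.0, n * r3 ** (n - 1), -(n + 1) * r3 ** -(n + 2)],
            ]
        )
        rhs = np.array(
            [-(r1 ** -(n + 1)), s1 * (n + 1) * r1 ** -(n + 2), 0.0, 0.0, 0.0]
        )
        # column equilibration keeps the solve well-scaled at high degree
        cs = np.abs(M).max(axis=0)
        x = np.linalg.solve(M / cs, rhs) / cs
        T[n] = x[3] * r3**n + x[4] * r3 ** -(n + 1)
    return T


def three_sphere_leadfield(
    montage: ElectrodeMontage,
    head: SphereHeadModel = DEFAULT_HEAD,
    src: SourceSpace | None = None,
    *,
    series_tol: float = 1e-10,
    max_terms: int = 200,
) -> LeadField:
    """Free-orientation lead field from the three-sphere Legendre series.

    The series over spherical-harmonic degree is truncated once the bound on
    the next term falls below ``series_tol`` relative to the leading term
    (hard cap ``max_terms``); non-convergence raises with the offending voxel.
    Output is raw-referenced.
    """
    if src is None:
        raise ValueError("a SourceSpace is required")
    pos = src.positions
    b = np.linalg.norm(pos, axis=1)
    if np.any(b >= head.brain_radius):
        bad = int(np.argmax(b >= head.brain_radius))
        raise ValueError(
            f"voxel {bad} lies on/outside the brain shell (|r|={b[bad]:.4f})"
        )

    T = _shell_gain_factors(head, max_terms)
    bmax = b.max()
    Rscalp = head.scalp_radius
    sigma_in = head.conductivities[0]

    # choose the truncation degree from the worst-case (shallowest) voxel:
    # |term_n| <= |T_n| * b^(n-1) * n * (n+1)  (P_n <= 1, |P_n^1| <= n(n+1)/2)
    scale = abs(T[1])
    n_max = max_terms
    for n in range(2, max_terms + 1):
        bound = abs(T[n]) * bmax ** (n - 1) * n * (n + 1)
        if bound < series_tol * scale:
            n_max = n
            break
    else:
        raise ArithmeticError(
            f"three-sphere series did not converge within {max_terms} terms "
            f"for voxel {int(np.argmax(b))}"
        )

    E = montage.positions  # unit vectors; electrodes on the scalp sphere
    N = src.n_voxels
    d = montage.n_electrodes

    tiny = b < 1e-12
    rhat = np.where(tiny[:, None], np.array([0.0, 0.0, 1.0]), pos / np.maximum(b, 1e-300)[:, None])
    x = rhat @ E.T  # (N, d) cosines between voxel and electrode directions
    x = np.clip(x, -1.0, 1.0)
    sin = np.sqrt(np.maximum(0.0, 1.0 - x**2))
    # unit tangent (at the voxel direction, toward the electrode)
    tvec = E[None, :, :] - x[:, :, None] * rhat[:, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        tvec = np.where(sin[:, :, None] > 1e-12, tvec / np.maximum(sin, 1e-300)[:, :, None], 0.0)

    # Legendre recurrences on (N, d) arrays
    P_nm1 = np.ones_like(x)  # P_0
    P_n = x.copy()  # P_1
    P1_nm1 = np.zeros_like(x)  # P_0^1
    P1_n = sin.copy()  # P_1^1
    t_pow = np.ones(N)  # b^(n-1)

    Vrad = np.zeros((N, d))
    Vtan = np.zeros((N, d))
    for n in range(1, n_max + 1):
        Tn = T[n]
        Vrad += Tn * n * (t_pow[:, None] * P_n)
        Vtan += Tn * (t_pow[:, None] * P1_n)
        # advance to degree n+1
        P_np1 = ((2 * n + 1) * x * P_n - n * P_nm1) / (n + 1)
        P1_np1 = ((2 * n + 1) * x * P1_n - (n + 1) * P1_nm1) / n
        P_nm1, P_n = P_n, P_np1
        P1_nm1, P1_n = P1_n, P1_np1
        t_pow = t_pow * b

    # potentials for unit dipole moments along x, y, z at each voxel;
    # the shell factors T_n already carry the full radial dependence
    # (they are evaluated at the scalp radius), so only the 1/(4 pi sigma)
    # source normalization remains.
    del Rscalp
    coef = 1.0 / (4 * np.pi * sigma_in)
    gain3 = coef * (
        Vrad[:, :, None] * rhat[:, None, :] + Vtan[:, :, None] * tvec
    )  # (N, d, 3)
    gain = gain3.transpose(1, 0, 2).reshape(d, 3 * N)
    return LeadField(gain, "free", "raw", source_space=src)


def average_reference(x):
    """Center the electrode dimension: apply H = I - (1/d) 1 1^T.

    Accepts a LeadField (raw-referenced) or a voltage vector/matrix whose
    first axis is electrodes; returns the same type.
    """
    if isinstance(x, LeadField):
        if x.reference_state != "raw":
            raise ValueError("lead field is already average-referenced")
        gain = x.gain - x.gain.mean(axis=0, keepdims=True)
        return replace(x, gain=gain, reference_state="average")
    arr = np.asarray(x, float)
    return arr - arr.mean(axis=0, keepdims=True)


def project_to_directions(K: LeadField, directions: np.ndarray) -> LeadField:
    """Collapse a free-orientation lead field onto one direction per voxel.

    Column ``u`` of the result is the voxel's 3-column block times
    ``directions[u]``; the output has one column per voxel (fixed mode).
    """
    if K.orientation_mode != "free":
        raise ValueError("projection requires a free-orientation lead field")
    dirs = np.asarray(directions, float)
    N = K.n_voxels
    if dirs.shape != (N, 3):
        raise ValueError(f"directions must be ({N}, 3)")
    if np.any(np.abs(np.linalg.norm(dirs, axis=1) - 1.0) > 1e-6):
        raise ValueError("directions must be unit-length")
    blocks = K.gain.reshape(K.n_electrodes, N, 3)
    gain = np.einsum("dua,ua->du", blocks, dirs)
    return LeadField(gain, "fixed", K.reference_state, source_space=K.source_space)


def leadfield_rank(K: LeadField, rtol: float = 1e-8) -> int:
    """Numerical rank by singular-value thresholding at ``rtol * sigma_max``."""
    s = np.linalg.svd(K.gain, compute_uv=False)
    return int(np.sum(s > rtol * s[0]))
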