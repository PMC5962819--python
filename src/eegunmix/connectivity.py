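"""MVAR estimation and the isolated effective coherence (iCoh) statistic.

iCoh is a directed, frequency-resolved influence measure: for an ordered
pair j -> i it is the partial coherence of the MVAR model *pruned* to keep
only the j -> i lag coefficients and the self (diagonal) coefficients, all
other off-diagonal associations being set to zero.  With the spectral lag
polynomial Abar(w) = I - sum_k A(k) exp(-i 2 pi w k) and precision weights
w_i = [V^-1]_ii this reduces to the closed form

    iCoh_{i<-j}(w) = w_i |Abar_ij|^2 / (w_i |Abar_ij|^2 + w_j |Abar_jj|^2),

which is asymmetric by construction, lies in [0, 1], and vanishes
identically whenever every lag coefficient from j to i is zero.  The closed
form agrees exactly with a numerically computed partial coherence of the
pruned spectral model when the innovation covariance is diagonal (the
setting of every scenario here); the test suite carries that brute-force
cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import MARModel, TimeSeriesSet

__all__ = [
    "ICohResult",
    "mvar_fit",
    "icoh",
    "edge_summary",
    "edge_set",
]


@dataclass(frozen=True)
class ICohResult:
    """iCoh over a frequency grid; ``values[i, j, f]`` is the influence of
    node j toward node i at ``frequencies[f]`` (fractions of the sampling
    rate); the diagonal is 0 by definition."""

    frequencies: np.ndarray  # (F,) in (0, 0.5]
    values: np.ndarray  # (n, n, F) in [0, 1]
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        f = np.asarray(self.frequencies, float)
        v = np.asarray(self.values, float)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "values", v)
        if v.ndim != 3 or v.shape[0] != v.shape[1] or v.shape[2] != f.size:
            raise ValueError("values must be (n, n, F)")
        if self.labels is not None:
            object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def peak(self, i: int, j: int) -> tuple[float, float]:
        """(peak frequency, peak value) of the j -> i influence."""
        k = int(np.argmax(self.values[i, j]))
        return float(self.frequencies[k]), float(self.values[i, j, k])


def mvar_fit(X, order: int) -> MARModel:
    """Equationwise ordinary least squares on the lagged regression.

    ``X`` is a TimeSeriesSet or an (n, T) array.  The innovation covariance
    uses the degrees-of-freedom denominator T - P - n P (samples lost to
    initialization and n P regression coefficients per equation).
    """
    if isinstance(X, TimeSeriesSet):
        labels = X.labels
        X = X.values
    else:
        labels = None
        X = np.atleast_2d(np.asarray(X, float))
    n, T = X.shape
    P = int(order)
    if P < 1:
        raise ValueError("order must be >= 1")
    if T <= n * P + 10:
        raise ValueError(f"need T > n*order + 10 samples (got T={T}, n={n}, P={P})")
    Y = X[:, P:]  # (n, T-P)
    Z = np.vstack([X[:, P - k : T - k] for k in range(1, P + 1)])  # (nP, T-P)
    sv = np.linalg.svd(Z, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        raise np.linalg.LinAlgError("rank-deficient lag regressor matrix")
    B, *_ = np.linalg.lstsq(Z.T, Y.T, rcond=None)  # (nP, n)
    coeffs = B.T.reshape(n, P, n).transpose(1, 0, 2)
    resid = Y - B.T @ Z
    dof = T - P - n * P
    V = (resid @ resid.T) / dof
    return MARModel(coeffs, V, labels)


def icoh(model: MARModel, frequencies: np.ndarray | None = None) -> ICohResult:
    """iCoh for every ordered node pair of an MVAR model.

    Pruning leaves the (i, j) and diagonal lag coefficients untouched and
    zeroes the rest, so only Abar_ij and Abar_jj of the full model enter the
    closed form; the computation vectorizes over the frequency grid (default
    128 points uniform in (0, 0.5]).
    """
    n = model.n_vars
    if n < 2:
        raise ValueError("iCoh needs at least 2 variables")
    if frequencies is None:
        frequencies = np.arange(1, 129) / 256.0
    freqs = np.asarray(frequencies, float)
    Vinv = np.linalg.inv(model.cov)  # raises LinAlgError when singular
    w = np.diag(Vinv)

    P = model.order
    # Abar(w) = I - sum_k A(k) e^{-2 pi i w k}, shape (F, n, n)
    phase = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, P + 1)))  # (F, P)
    Abar = np.eye(n)[None] - np.einsum("fk,kij->fij", phase, model.coeffs)

    Aij2 = np.abs(Abar) ** 2  # (F, n, n)
    diag2 = np.abs(np.einsum("fii->fi", Abar)) ** 2  # (F, n)
    num = w[None, :, None] * Aij2  # w_i |Abar_ij|^2
    den = num + w[None, None, :] * diag2[:, None, :]  # + w_j |Abar_jj|^2
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    vals = vals.transpose(1, 2, 0)  # (n, n, F)
    idx = np.arange(n)
    vals[idx, idx, :] = 0.0
    return ICohResult(freqs, vals, model.labels)


def edge_summary(result: ICohResult, threshold: float):
    """Directed edges whose peak iCoh reaches ``threshold``.

    Returns a list of dicts (source, target, peak_frequency, peak_value)
    sorted by descending peak value.
    """
    labels = result.labels or tuple(str(i + 1) for i in range(result.n_nodes))
    edges = []
    for i in range(result.n_nodes):
        for j in range(result.n_nodes):
            if i == j:
                continue
            f, v = result.peak(i, j)
            if v >= threshold:
                edges.append(
                    {
                        "source": labels[j],
                        "target": labels[i],
                        "peak_frequency": f,
                        "peak_value": v,
                    }
                )
    return sorted(edges, key=lambda e: -e["peak_value"])


def edge_set(result: ICohResult, threshold: float) -> set[tuple[str, str]]:
    """The {(source, target)} pairs at or above the peak threshold."""
    return {(e["source"], e["target"]) for e in edge_summary(result, threshold)}
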