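"""Independent reference implementations used only by the test suite.

Each oracle derives its expected values by a route different from the
package code it checks: closed-form formulas, naive loops, or numerical
linear algebra on explicitly constructed objects.
"""

import numpy as np


def single_sphere_potential(electrode, dipole_pos, moment, radius=1.0, sigma=1.0):
    """Closed-form scalp potential of a current dipole in a homogeneous
    conducting sphere with an insulating boundary.

    Summation of the Legendre series in closed form: with t = b/R the ratio
    of dipole depth to sphere radius, x the cosine between dipole and
    electrode directions and g = sqrt(1 - 2 t x + t^2),

        V = [q_r (2(x - t)/g^3 + (1/t)(1/g - 1))
             + q_t sqrt(1-x^2) (2/g^3 + (g+1)/(g (1 - t x + g)))]
            / (4 pi sigma R^2),

    where q_r / q_t are the radial / tangential moment components.
    """
    b = np.linalg.norm(dipole_pos)
    ehat = electrode / np.linalg.norm(electrode)
    if b < 1e-14:
        return 3.0 * float(moment @ ehat) / (4 * np.pi * sigma * radius**2)
    rhat = dipole_pos / b
    t = b / radius
    x = float(np.clip(rhat @ ehat, -1.0, 1.0))
    g = np.sqrt(1 - 2 * t * x + t * t)
    s = np.sqrt(max(0.0, 1 - x * x))
    S_rad = 2 * (x - t) / g**3 + (1 / t) * (1 / g - 1)
    S_tan = s * (2 / g**3 + (g + 1) / (g * (1 - t * x + g)))
    q_r = float(moment @ rhat)
    if s > 1e-12:
        that = (ehat - x * rhat) / s
        q_t = float(moment @ that)
    else:
        q_t = 0.0
    return (q_r * S_rad + q_t * S_tan) / (4 * np.pi * sigma * radius**2)


def q_general_bruteforce(R_free, regions):
    """Naive double-loop assembly of the general 3L x 3L unmixing system."""
    L = len(regions)
    Q = np.zeros((3 * L, 3 * L))
    for l, Bl in enumerate(regions):
        for s, Bs in enumerate(regions):
            acc = np.zeros((3, 3))
            for u in Bl:
                for w in Bs:
                    acc += R_free[3 * u : 3 * u + 3, 3 * w : 3 * w + 3]
            Q[3 * l : 3 * l + 3, 3 * s : 3 * s + 3] = acc
    return Q


def q_directional_bruteforce(R_free, regions, dirs):
    """Naive double-loop assembly of the directional L x L system."""
    L = len(regions)
    Q = np.zeros((L, L))
    for l, Bl in enumerate(regions):
        for s, Bs in enumerate(regions):
            acc = 0.0
            for u in Bl:
                for w in Bs:
                    blk = R_free[3 * u : 3 * u + 3, 3 * w : 3 * w + 3]
                    acc += dirs[u] @ blk @ dirs[w]
            Q[l, s] = acc
    return Q


def icoh_pruned_model_bruteforce(model, i, j, freqs):
    """Partial coherence of the explicitly pruned spectral model.

    Builds the pruned MVAR (keep the i<-j and all self lag coefficients),
    forms its spectral density S = Abar^-1 V Abar^-H, inverts to the
    precision, and returns |P_ij|^2 / (P_ii P_jj) per frequency.
    """
    n, P = model.n_vars, model.order
    out = []
    for f in freqs:
        Abar = np.eye(n, dtype=complex)
        for k in range(P):
            Ak = np.zeros((n, n), dtype=complex)
            np.fill_diagonal(Ak, np.diag(model.coeffs[k]))
            Ak[i, j] = model.coeffs[k][i, j]
            Abar -= np.exp(-2j * np.pi * f * (k + 1)) * Ak
        H = np.linalg.inv(Abar)
        S = H @ model.cov @ H.conj().T
        Pm = np.linalg.inv(S)
        out.append(abs(Pm[i, j]) ** 2 / (Pm[i, i].real * Pm[j, j].real))
    return np.array(out)


def mar_autocovariance(model, max_lag):
    """Stationary autocovariances Gamma(0..max_lag) via the companion-form
    discrete Lyapunov equation (the Yule-Walker route)."""
    from scipy.linalg import solve_discrete_lyapunov

    n, P = model.n_vars, model.order
    C = model.companion()
    Vc = np.zeros((n * P, n * P))
    Vc[:n, :n] = model.cov
    Sigma = solve_discrete_lyapunov(C, Vc)
    gammas = [Sigma[:n, :n]]
    # Gamma(k) = C-propagated blocks of the companion covariance
    state_cov = Sigma
    for _ in range(max_lag):
        state_cov = C @ state_cov
        gammas.append(state_cov[:n, :n])
    return gammas


def min_unmix_distance_bruteforce(R_fixed, positions, cond_threshold):
    """Exhaustive scan over all voxel pairs for the two-point unmixing
    distance (same definition as the library, independent loops)."""
    N = R_fixed.shape[0]
    out = np.empty(N)
    for u in range(N):
        dists, conds = [], []
        for w in range(N):
            if w == u:
                continue
            Q = np.array(
                [[R_fixed[u, u], R_fixed[u, w]], [R_fixed[w, u], R_fixed[w, w]]]
            )
            s = np.linalg.svd(Q, compute_uv=False)
            conds.append(np.inf if s[1] == 0 else s[0] / s[1])
            dists.append(np.linalg.norm(positions[u] - positions[w]))
        dists, conds = np.array(dists), np.array(conds)
        bad = ~(conds < cond_threshold)
        if not bad.any():
            out[u] = dists.min()
        else:
            dmax_bad = dists[bad].max()
            beyond = dists > dmax_bad
            out[u] = dists[beyond].min() if beyond.any() else np.inf
    return out
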