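"""Metropolis annealing kernel for maximal-repulsion simulation in a ball.

Compiled with numba: the kernel is called tens of thousands of times by the
Monte-Carlo goodness-of-fit machinery (each conditioned simulation of a
maximal-repulsion model is one annealing run), so the inner loop must be
cheap.  Positions are expressed relative to the sphere center; the generic
(mesh / voxel-mask) path lives in :mod:`sdi3d.models` in plain Python.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _energy_with_row(D, di, i, N):
    """Energy after replacing row/col i of the distance matrix with di."""
    total = 0.0
    for k in range(N):
        m = np.inf
        if k == i:
            for j in range(N):
                if j != i and di[j] < m:
                    m = di[j]
        else:
            for j in range(N):
                if j == k:
                    continue
                d = di[k] if j == i else D[k, j]
                if d < m:
                    m = d
        total += m
    return -total / N


@njit(cache=True)
def _energy(D, N):
    total = 0.0
    for k in range(N):
        m = np.inf
        for j in range(N):
            if j != k and D[k, j] < m:
                m = D[k, j]
        total += m
    return -total / N


@njit(cache=True)
def anneal_in_ball(pos0, radii, R, rho, on_orbits, beta_growth, delta0,
                   conv_tol, window_sweeps, max_sweeps, seed):
    """Minimize E = −mean nearest-neighbour distance by Metropolis annealing.

    pos0 : (N, 3) initial centroids relative to the sphere center.
    rho  : fixed centroid radii for the orbit-constrained variant
           (ignored when on_orbits is False).
    Returns (best_pos, window_moves, window_E, window_bestE, accepted_frac,
    converged, moves_used, beta0).
    """
    np.random.seed(seed)
    N = pos0.shape[0]
    pos = pos0.copy()
    D = np.empty((N, N))
    for a in range(N):
        D[a, a] = np.inf
        for b in range(a + 1, N):
            d = np.sqrt((pos[a, 0] - pos[b, 0]) ** 2
                        + (pos[a, 1] - pos[b, 1]) ** 2
                        + (pos[a, 2] - pos[b, 2]) ** 2)
            D[a, b] = d
            D[b, a] = d
    E = _energy(D, N)
    best_E = E
    best_pos = pos.copy()

    delta = delta0
    di = np.empty(N)
    cand = np.empty(3)

    # --- calibrate beta0 so initial uphill acceptance ~ 0.5 ----------------
    probe_up = np.empty(100)
    n_up = 0
    for _p in range(100):
        i = np.random.randint(N)
        for axis in range(3):
            cand[axis] = pos[i, axis] + delta * (2.0 * np.random.random() - 1.0)
        if on_orbits:
            nrm = np.sqrt(cand[0] ** 2 + cand[1] ** 2 + cand[2] ** 2)
            if nrm < 1e-12:
                continue
            for axis in range(3):
                cand[axis] *= rho[i] / nrm
        ok = True
        if not on_orbits:
            nrm = np.sqrt(cand[0] ** 2 + cand[1] ** 2 + cand[2] ** 2)
            if nrm > R - radii[i]:
                ok = False
        if ok:
            for j in range(N):
                if j == i:
                    di[j] = np.inf
                    continue
                di[j] = np.sqrt((cand[0] - pos[j, 0]) ** 2
                                + (cand[1] - pos[j, 1]) ** 2
                                + (cand[2] - pos[j, 2]) ** 2)
                if di[j] < radii[i] + radii[j]:
                    ok = False
                    break
        if ok:
            dE = _energy_with_row(D, di, i, N) - E
            if dE > 0 and n_up < 100:
                probe_up[n_up] = dE
                n_up += 1
    if n_up > 0:
        med = np.median(probe_up[:n_up])
        beta0 = np.log(2.0) / med if med > 0 else 1.0
    else:
        beta0 = 1.0
    beta = beta0

    window = window_sweeps * N
    max_moves = max_sweeps * N
    n_windows = max_moves // window + 1
    w_moves = np.zeros(n_windows, dtype=np.int64)
    w_E = np.zeros(n_windows)
    w_best = np.zeros(n_windows)
    n_w = 0
    accepted_total = 0
    moves = 0
    prev_best = best_E
    stable = 0  # consecutive windows with stabilized best energy
    converged = False

    while moves < max_moves and not converged:
        acc_in_window = 0
        for _k in range(window):
            moves += 1
            i = np.random.randint(N)
            # uniform proposal in a ball of radius delta (rejection from cube)
            for _t in range(64):
                dx = delta * (2.0 * np.random.random() - 1.0)
                dy = delta * (2.0 * np.random.random() - 1.0)
                dz = delta * (2.0 * np.random.random() - 1.0)
                if dx * dx + dy * dy + dz * dz <= delta * delta:
                    break
            cand[0] = pos[i, 0] + dx
            cand[1] = pos[i, 1] + dy
            cand[2] = pos[i, 2] + dz
            if on_orbits:
                nrm = np.sqrt(cand[0] ** 2 + cand[1] ** 2 + cand[2] ** 2)
                if nrm < 1e-12:
                    continue
                for axis in range(3):
                    cand[axis] *= rho[i] / nrm
            else:
                nrm = np.sqrt(cand[0] ** 2 + cand[1] ** 2 + cand[2] ** 2)
                if nrm > R - radii[i]:
                    continue  # leaves the domain: rejected
            ok = True
            for j in range(N):
                if j == i:
                    di[j] = np.inf
                    continue
                di[j] = np.sqrt((cand[0] - pos[j, 0]) ** 2
                                + (cand[1] - pos[j, 1]) ** 2
                                + (cand[2] - pos[j, 2]) ** 2)
                if di[j] < radii[i] + radii[j]:
                    ok = False
                    break
            if not ok:
                continue
            newE = _energy_with_row(D, di, i, N)
            dE = newE - E
            accept = dE < 0
            if not accept:
                arg = beta * dE
                if arg < 50.0 and np.random.random() < np.exp(-arg):
                    accept = True
            if accept:
                for j in range(N):
                    D[i, j] = di[j]
                    D[j, i] = di[j]
                D[i, i] = np.inf
                pos[i, 0] = cand[0]
                pos[i, 1] = cand[1]
                pos[i, 2] = cand[2]
                E = newE
                acc_in_window += 1
                if E < best_E:
                    best_E = E
                    for a in range(N):
                        for axis in range(3):
                            best_pos[a, axis] = pos[a, axis]
        accepted_total += acc_in_window
        w_moves[n_w] = moves
        w_E[n_w] = E
        w_best[n_w] = best_E
        n_w += 1
        # geometric annealing: beta grows 'beta_growth' per sweep (N moves)
        beta *= beta_growth ** window_sweeps
        # adapt step size toward ~30% acceptance
        if acc_in_window > 0.3 * window:
            delta /= 0.9
        else:
            delta *= 0.9
        if delta > R:
            delta = R
        if delta < 1e-9 * R:
            delta = 1e-9 * R
        if abs(prev_best - best_E) / max(abs(best_E), 1e-300) < conv_tol:
            stable += 1
            if stable >= 3:  # three consecutive stable windows
                converged = True
        else:
            stable = 0
        prev_best = best_E

    return (best_pos, w_moves[:n_w], w_E[:n_w], w_best[:n_w],
            accepted_total / max(moves, 1), converged, moves, beta0)
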