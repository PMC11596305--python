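"""Independent reference implementations used only to cross-check results.

These deliberately avoid the package's code paths: superposition is done
by Horn's quaternion eigenvector method, sensograms by numerical ODE
integration, KS p-values by brute-force label enumeration, and register
scans / nearest-neighbor assignments by direct exhaustive loops.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import solve_ivp


def quaternion_superpose(mobile: np.ndarray, target: np.ndarray):
    """Horn's closed-form absolute orientation: returns (R, t, rmsd)."""
    p = np.asarray(mobile, dtype=float)
    q = np.asarray(target, dtype=float)
    cp, cq = p.mean(axis=0), q.mean(axis=0)
    pc, qc = p - cp, q - cq
    s = pc.T @ qc
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(k)
    lam = eigvals[-1]
    w, x, y, z = eigvecs[:, -1]
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    msd = (np.sum(pc * pc) + np.sum(qc * qc) - 2.0 * lam) / p.shape[0]
    rmsd = float(np.sqrt(max(msd, 0.0)))
    tra = cq - rot @ cp
    return rot, tra, rmsd


def ode_sensogram(ka, kd, rmax, conc, time, t_assoc):
    """Integrate dR/dt = ka C (Rmax - R) - kd R with C switched off at t_assoc."""

    def rhs(t, r):
        c = conc if t <= t_assoc else 0.0
        return ka * c * (rmax - r[0]) - kd * r[0]

    sol = solve_ivp(
        rhs, (time[0], time[-1]), [0.0], t_eval=time,
        max_step=0.25, rtol=1e-10, atol=1e-12,
    )
    return sol.y[0]


def ks_statistic(a, b):
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    grid = np.concatenate([a, b])
    fa = np.searchsorted(a, grid, side="right") / a.size
    fb = np.searchsorted(b, grid, side="right") / b.size
    return float(np.max(np.abs(fa - fb)))


def ks_permutation_pvalue(a, b):
    """Exact permutation p-value by enumerating label assignments."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d_obs = ks_statistic(a, b)
    pooled = np.concatenate([a, b])
    n = a.size
    idx = range(pooled.size)
    hits = total = 0
    for combo in itertools.combinations(idx, n):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(combo)] = True
        total += 1
        if ks_statistic(pooled[mask], pooled[~mask]) >= d_obs - 1e-12:
            hits += 1
    return d_obs, hits / total


def nearest_neighbor_assignment(moved: np.ndarray, targets: np.ndarray):
    """Brute-force nearest-target index for every moved point."""
    out = []
    for p in moved:
        d = np.sqrt(((targets - p) ** 2).sum(axis=1))
        out.append(int(np.argmin(d)))
    return out


def direct_rmsd_after_superposition(p: np.ndarray, q: np.ndarray) -> float:
    """RMSD from explicitly transformed coordinates (Horn transform)."""
    rot, tra, _ = quaternion_superpose(p, q)
    moved = p @ rot.T + tra
    return float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
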