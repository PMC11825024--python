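"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own likelihood/conditional code
paths: probabilities come from scipy pmfs and literal enumeration, patches
from a hand-written flood fill.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import binom


def enumerate_richness_posterior(
    y: np.ndarray, K: int, Omega: float, psi: float, p: float
) -> np.ndarray:
    """P(N = k | y) for one region by summing the joint over all (omega, z).

    ``y`` is the augmented (M, J) count matrix; all species share psi and p.
    Only feasible for tiny M * J.
    """
    M, J = y.shape
    post = np.zeros(M + 1)
    for om in itertools.product([0, 1], repeat=M):
        for zf in itertools.product([0, 1], repeat=M * J):
            z = np.array(zf).reshape(M, J)
            pr = 1.0
            for i in range(M):
                pr *= Omega if om[i] else 1.0 - Omega
                for j in range(J):
                    pz1 = psi * om[i]
                    pr *= pz1 if z[i, j] else 1.0 - pz1
                    pr *= binom.pmf(y[i, j], K, p * z[i, j])
            post[sum(om)] += pr
    return post / post.sum()


def enumerate_omega_conditional(
    y_row: np.ndarray, K, Omega: float, psi: float, p_row
) -> float:
    """P(omega = 1 | y_row) for one species by enumerating (omega, z_row)."""
    J = len(y_row)
    K = np.broadcast_to(np.asarray(K), (J,))
    p_row = np.broadcast_to(np.asarray(p_row, dtype=float), (J,))
    mass = {0: 0.0, 1: 0.0}
    for om in (0, 1):
        for zf in itertools.product([0, 1], repeat=J):
            pr = Omega if om else 1.0 - Omega
            for j in range(J):
                pz1 = psi * om
                pr *= pz1 if zf[j] else 1.0 - pz1
                pr *= binom.pmf(y_row[j], K[j], p_row[j] * zf[j])
            mass[om] += pr
    tot = mass[0] + mass[1]
    return mass[1] / tot if tot > 0 else 0.0


def enumerate_z_conditional(y: int, K: int, psi: float, p: float, omega: int) -> float:
    """P(z = 1 | y, omega) for one species-site by enumerating z."""
    mass = {}
    for zv in (0, 1):
        pz1 = psi * omega
        pr = pz1 if zv else 1.0 - pz1
        pr *= binom.pmf(y, K, p * zv)
        mass[zv] = pr
    tot = mass[0] + mass[1]
    return mass[1] / tot if tot > 0 else 0.0


def flood_fill_patches(cells: np.ndarray, connectivity: int = 8) -> int:
    """Number of connected components of 1-cells by explicit flood fill."""
    cells = np.asarray(cells)
    seen = np.zeros_like(cells, dtype=bool)
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    n = 0
    for si in range(cells.shape[0]):
        for sj in range(cells.shape[1]):
            if cells[si, sj] != 1 or seen[si, sj]:
                continue
            n += 1
            stack = [(si, sj)]
            seen[si, sj] = True
            while stack:
                i, j = stack.pop()
                for di, dj in nbrs:
                    a, b = i + di, j + dj
                    if (
                        0 <= a < cells.shape[0]
                        and 0 <= b < cells.shape[1]
                        and cells[a, b] == 1
                        and not seen[a, b]
                    ):
                        seen[a, b] = True
                        stack.append((a, b))
    return n


def gyration_direct(points: np.ndarray) -> float:
    """Mean distance of points (k, 2) from their centroid, by direct sums."""
    c = points.mean(axis=0)
    return float(np.mean(np.sqrt(((points - c) ** 2).sum(axis=1))))
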