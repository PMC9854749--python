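"""Slow, independent brute-force reference implementations used as test
oracles. Everything here is written as plain loops over definitions and
deliberately shares no code path with the package."""

from __future__ import annotations

import itertools

import numpy as np

ALL_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
DIRS_13 = [d for d in ALL_26 if d > (0, 0, 0)]


def tv_norm_bruteforce(u: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Triple-loop sum of |forward differences| between in-mask pairs."""
    if mask is None:
        mask = np.ones(u.shape, bool)
    total = 0.0
    nx, ny, nz = u.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                for d in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
                    q = (x + d[0], y + d[1], z + d[2])
                    if (q[0] < nx and q[1] < ny and q[2] < nz
                            and mask[q]):
                        total += abs(u[q] - u[x, y, z])
    return total


def rof_admm_oracle(
    g: np.ndarray,
    weight: float,
    mask: np.ndarray | None = None,
    rho: float = 1.0,
    iters: int = 5000,
) -> np.ndarray:
    """Dense-matrix ADMM solve of the anisotropic ROF problem.

    Builds the masked forward-difference operator K explicitly, solves the
    quadratic u-subproblem with a dense inverse, and applies soft
    shrinkage to the split gradient variable. Small volumes only.
    """
    if mask is None:
        mask = np.ones(g.shape, bool)
    mask = np.asarray(mask, bool)
    shape = g.shape
    n = g.size
    rows = []
    flat = lambda idx: int(np.ravel_multi_index(idx, shape))
    for d in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
        for idx in itertools.product(*(range(s) for s in shape)):
            q = tuple(i + o for i, o in zip(idx, d))
            if all(qq < s for qq, s in zip(q, shape)) and mask[idx] and mask[q]:
                row = np.zeros(n)
                row[flat(q)] = 1.0
                row[flat(idx)] = -1.0
                rows.append(row)
    gm = np.where(mask, g, 0.0).ravel()
    if not rows:
        return g.copy()
    K = np.array(rows)
    Minv = np.linalg.inv(np.eye(n) + rho * K.T @ K)
    z = np.zeros(K.shape[0])
    y = np.zeros(K.shape[0])
    u = gm.copy()
    for _ in range(iters):
        u = Minv @ (gm + rho * K.T @ (z - y))
        Ku = K @ u
        v = Ku + y
        z = np.sign(v) * np.maximum(np.abs(v) - weight / rho, 0.0)
        y += Ku - z
    out = g.astype(float).copy()
    out[mask] = u.reshape(shape)[mask]
    return out


def adc_loglinear_oracle(signal, b) -> float:
    """Ordinary least squares on log-signal (the closed-form ADC fit)."""
    s = np.asarray(signal, float)
    bv = np.asarray(b, float)
    A = np.vstack([bv, np.ones_like(bv)]).T
    slope = np.linalg.lstsq(A, np.log(s), rcond=None)[0][0]
    return -slope


# ---------------------------------------------------------------------------
# texture oracles


def glcm_matrix_bruteforce(q: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Normalized symmetric GLCM from exhaustive ordered pair enumeration
    over all 26 neighbor offsets."""
    nmax = int(q[mask].max())
    mat = np.zeros((nmax, nmax))
    nx, ny, nz = q.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                for d in ALL_26:
                    p = (x + d[0], y + d[1], z + d[2])
                    if (0 <= p[0] < nx and 0 <= p[1] < ny and 0 <= p[2] < nz
                            and mask[p]):
                        mat[q[x, y, z] - 1, q[p] - 1] += 1
    return mat / mat.sum()


def glcm_features_bruteforce(q: np.ndarray, mask: np.ndarray) -> np.ndarray:
    p = glcm_matrix_bruteforce(q, mask)
    n = p.shape[0]
    mu = sum((i + 1) * p[i, j] for i in range(n) for j in range(n))
    sig = np.sqrt(sum((i + 1 - mu) ** 2 * p[i, j]
                      for i in range(n) for j in range(n)))
    energy = contrast = entropy = homog = 0.0
    corr = sumavg = var = dissim = autoc = 0.0
    for i in range(n):
        for j in range(n):
            pij = p[i, j]
            gi, gj = i + 1, j + 1
            energy += pij ** 2
            contrast += (gi - gj) ** 2 * pij
            if pij > 0:
                entropy -= pij * np.log2(pij)
            homog += pij / (1 + abs(gi - gj))
            if sig > 0:
                corr += (gi - mu) * (gj - mu) * pij / (sig * sig)
            sumavg += 0.5 * (gi + gj) * pij
            var += 0.5 * ((gi - mu) ** 2 + (gj - mu) ** 2) * pij
            dissim += abs(gi - gj) * pij
            autoc += gi * gj * pij
    return np.array([energy, contrast, entropy, homog, corr,
                     sumavg, var, dissim, autoc])


def glrlm_runs_bruteforce(q: np.ndarray, mask: np.ndarray):
    """All (level, length) runs, enumerated by walking complete grid lines
    along each of the 13 directions."""
    shape = q.shape
    runs = []
    for d in DIRS_13:
        starts = []
        for idx in itertools.product(*(range(s) for s in shape)):
            prev = tuple(i - o for i, o in zip(idx, d))
            inside = all(0 <= p < s for p, s in zip(prev, shape))
            if not inside:
                starts.append(idx)
        for s0 in starts:
            line = []
            pos = s0
            while all(0 <= p < s for p, s in zip(pos, shape)):
                line.append(pos)
                pos = tuple(i + o for i, o in zip(pos, d))
            cur_level, cur_len = None, 0
            for v in line:
                if mask[v]:
                    lev = int(q[v])
                    if lev == cur_level:
                        cur_len += 1
                    else:
                        if cur_level is not None:
                            runs.append((cur_level, cur_len))
                        cur_level, cur_len = lev, 1
                else:
                    if cur_level is not None:
                        runs.append((cur_level, cur_len))
                    cur_level, cur_len = None, 0
            if cur_level is not None:
                runs.append((cur_level, cur_len))
    return runs


def glrlm_features_bruteforce(q: np.ndarray, mask: np.ndarray) -> np.ndarray:
    runs = glrlm_runs_bruteforce(q, mask)
    nr = len(runs)
    tot_len = sum(l for _, l in runs)
    sre = sum(1.0 / l ** 2 for _, l in runs) / nr
    lre = sum(l ** 2 for _, l in runs) / nr
    from collections import Counter
    by_level = Counter(g for g, _ in runs)
    by_len = Counter(l for _, l in runs)
    gln = sum(c ** 2 for c in by_level.values()) / nr
    rln = sum(c ** 2 for c in by_len.values()) / nr
    rp = nr / tot_len
    lgre = sum(1.0 / g ** 2 for g, _ in runs) / nr
    hgre = sum(g ** 2 for g, _ in runs) / nr
    srlge = sum(1.0 / (g ** 2 * l ** 2) for g, l in runs) / nr
    srhge = sum(g ** 2 / l ** 2 for g, l in runs) / nr
    lrlge = sum(l ** 2 / g ** 2 for g, l in runs) / nr
    lrhge = sum(g ** 2 * l ** 2 for g, l in runs) / nr
    mu_g = sum(g for g, _ in runs) / nr
    glv = sum((g - mu_g) ** 2 for g, _ in runs) / nr
    mu_l = sum(l for _, l in runs) / nr
    rlv = sum((l - mu_l) ** 2 for _, l in runs) / nr
    return np.array([sre, lre, gln, rln, rp, lgre, hgre,
                     srlge, srhge, lrlge, lrhge, glv, rlv])


def global_features_bruteforce(q: np.ndarray, mask: np.ndarray) -> np.ndarray:
    v = q[mask].astype(float)
    n = v.size
    mean = v.sum() / n
    var_s = sum((x - mean) ** 2 for x in v) / (n - 1)
    m2 = sum((x - mean) ** 2 for x in v) / n
    if m2 == 0:
        return np.array([0.0, 0.0, 0.0])
    m3 = sum((x - mean) ** 3 for x in v) / n
    m4 = sum((x - mean) ** 4 for x in v) / n
    return np.array([var_s, m3 / m2 ** 1.5, m4 / m2 ** 2])


def ngtdm_features_bruteforce(q: np.ndarray, mask: np.ndarray,
                              cap: float = 1e6) -> np.ndarray:
    nx, ny, nz = q.shape
    nmax = int(q[mask].max())
    s = np.zeros(nmax)
    counts = np.zeros(nmax)
    n_valid = 0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                nb = []
                for d in ALL_26:
                    p = (x + d[0], y + d[1], z + d[2])
                    if (0 <= p[0] < nx and 0 <= p[1] < ny
                            and 0 <= p[2] < nz and mask[p]):
                        nb.append(q[p])
                if not nb:
                    continue
                n_valid += 1
                lev = int(q[x, y, z])
                counts[lev - 1] += 1
                s[lev - 1] += abs(lev - sum(nb) / len(nb))
    p = counts / n_valid
    levels = np.arange(1, nmax + 1, dtype=float)
    nzl = p > 0
    ngp = int(nzl.sum())
    denom = float((p * s).sum())
    coarseness = min(1.0 / denom, cap) if denom > 0 else cap
    contrast = 0.0
    if ngp > 1:
        acc = sum(p[i] * p[j] * (levels[i] - levels[j]) ** 2
                  for i in range(nmax) for j in range(nmax))
        contrast = acc / (ngp * (ngp - 1)) * s.sum() / n_valid
    busy_den = sum(abs(levels[i] * p[i] - levels[j] * p[j])
                   for i in range(nmax) for j in range(nmax)
                   if p[i] > 0 and p[j] > 0)
    busyness = denom / busy_den if busy_den > 0 else 0.0
    complexity = 0.0
    strength_num = 0.0
    for i in range(nmax):
        for j in range(nmax):
            if p[i] > 0 and p[j] > 0:
                complexity += (abs(levels[i] - levels[j])
                               * (p[i] * s[i] + p[j] * s[j])
                               / (n_valid * (p[i] + p[j])))
                strength_num += (p[i] + p[j]) * (levels[i] - levels[j]) ** 2
    strength = strength_num / s.sum() if s.sum() > 0 else 0.0
    return np.array([coarseness, contrast, busyness, complexity, strength])


def quantize_equalized_bruteforce(values: np.ndarray, ng: int) -> np.ndarray:
    """Sort-and-split equal-frequency levels (stable tie-break)."""
    n = values.size
    order = sorted(range(n), key=lambda i: (values[i], i))
    levels = np.empty(n, dtype=int)
    for rank, i in enumerate(order):
        levels[i] = rank * ng // n + 1
    return levels


def auc_pair_counting(scores, labels) -> float:
    """AUC by exhaustive concordant/discordant pair counting."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum(1.0 if a > b else 0.5 if a == b else 0.0
               for a in pos for b in neg)
    return wins / (len(pos) * len(neg))
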