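"""Independent brute-force oracles for texture matrices and features.

Everything here is written as plain Python loops over voxels and matrix
entries, deliberately sharing no code with the package implementation, so it
can serve as an enumeration oracle on small grids.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
OFFSETS_13 = [d for d in OFFSETS_26 if d > (0, 0, 0)]


def _inside(shape, v):
    return all(0 <= v[i] < shape[i] for i in range(3))


def naive_glcm(levels: np.ndarray) -> dict[tuple[int, int], int]:
    """Directed co-occurrence counts over all 26 neighbour offsets
    (equivalent to symmetrized counts over the 13 unique directions)."""
    shape = levels.shape
    counts: dict[tuple[int, int], int] = defaultdict(int)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                a = levels[x, y, z]
                if a == 0:
                    continue
                for d in OFFSETS_26:
                    v = (x + d[0], y + d[1], z + d[2])
                    if _inside(shape, v):
                        b = levels[v]
                        if b != 0:
                            counts[(int(a), int(b))] += 1
    return dict(counts)


def naive_glrlm(levels: np.ndarray) -> dict[tuple[int, int], int]:
    """Run counts (level, run length) merged over the 13 directions."""
    shape = levels.shape
    counts: dict[tuple[int, int], int] = defaultdict(int)
    for d in OFFSETS_13:
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    a = levels[x, y, z]
                    if a == 0:
                        continue
                    prev = (x - d[0], y - d[1], z - d[2])
                    if _inside(shape, prev) and levels[prev] == a:
                        continue  # not a run start
                    length = 1
                    nxt = (x + d[0], y + d[1], z + d[2])
                    while _inside(shape, nxt) and levels[nxt] == a:
                        length += 1
                        nxt = (nxt[0] + d[0], nxt[1] + d[1], nxt[2] + d[2])
                    counts[(int(a), length)] += 1
    return dict(counts)


def naive_glszm(levels: np.ndarray) -> dict[tuple[int, int], int]:
    """Zone counts (level, zone size) under 26-connectivity."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    counts: dict[tuple[int, int], int] = defaultdict(int)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                a = levels[x, y, z]
                if a == 0 or seen[x, y, z]:
                    continue
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    v = stack.pop()
                    size += 1
                    for d in OFFSETS_26:
                        w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                        if _inside(shape, w) and not seen[w] and levels[w] == a:
                            seen[w] = True
                            stack.append(w)
                counts[(int(a), size)] += 1
    return dict(counts)


def naive_ngtdm(levels: np.ndarray) -> dict[int, tuple[int, float]]:
    """Per level: (n_i, s_i) over 26-neighbourhoods restricted to the ROI."""
    shape = levels.shape
    out: dict[int, list] = defaultdict(lambda: [0, 0.0])
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                a = levels[x, y, z]
                if a == 0:
                    continue
                nb = []
                for d in OFFSETS_26:
                    v = (x + d[0], y + d[1], z + d[2])
                    if _inside(shape, v) and levels[v] != 0:
                        nb.append(int(levels[v]))
                if not nb:
                    continue
                out[int(a)][0] += 1
                out[int(a)][1] += abs(a - sum(nb) / len(nb))
    return {k: (v[0], v[1]) for k, v in out.items()}


# ---------------------------------------------------------------------------
# feature formulas as explicit sums over the sparse matrices


def _entropy(ps):
    return -sum(p * math.log2(p) for p in ps if p > 0)


def naive_glcm_features(levels: np.ndarray) -> dict[str, float]:
    counts = naive_glcm(levels)
    total = sum(counts.values())
    p = {k: v / total for k, v in counts.items()}
    gray = sorted({i for i, _ in p} | {j for _, j in p})
    ng = len(gray)
    px = {i: sum(p.get((i, j), 0.0) for j in gray) for i in gray}
    py = {j: sum(p.get((i, j), 0.0) for i in gray) for j in gray}
    mu_x = sum(i * px[i] for i in gray)
    mu_y = sum(j * py[j] for j in gray)
    sig_x = math.sqrt(sum(px[i] * (i - mu_x) ** 2 for i in gray))
    sig_y = math.sqrt(sum(py[j] * (j - mu_y) ** 2 for j in gray))
    p_sum: dict[int, float] = defaultdict(float)
    p_diff: dict[int, float] = defaultdict(float)
    for (i, j), v in p.items():
        p_sum[i + j] += v
        p_diff[abs(i - j)] += v
    diff_avg = sum(k * v for k, v in p_diff.items())
    hx = _entropy(px.values())
    hxy = _entropy(p.values())
    hxy1 = -sum(
        v * math.log2(px[i] * py[j]) for (i, j), v in p.items() if px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j])
        for i in gray for j in gray if px[i] * py[j] > 0
    )
    if sig_x > 0 and sig_y > 0:
        corr = (sum(v * i * j for (i, j), v in p.items()) - mu_x * mu_y) / (sig_x * sig_y)
    else:
        corr = 1.0
    # MCC via the Q matrix
    q = np.zeros((ng, ng))
    gi = {g: a for a, g in enumerate(gray)}
    for i in gray:
        for j in gray:
            s = 0.0
            for k in gray:
                if px[i] > 0 and py[k] > 0:
                    s += p.get((i, k), 0.0) * p.get((j, k), 0.0) / (px[i] * py[k])
            q[gi[i], gi[j]] = s
    if ng > 1:
        eig = sorted(abs(np.linalg.eigvals(q)))
        mcc = math.sqrt(max(0.0, eig[-2].real))
    else:
        mcc = 1.0
    return {
        "autocorrelation": sum(v * i * j for (i, j), v in p.items()),
        "joint_average": mu_x,
        "cluster_prominence": sum(v * (i + j - mu_x - mu_y) ** 4 for (i, j), v in p.items()),
        "cluster_shade": sum(v * (i + j - mu_x - mu_y) ** 3 for (i, j), v in p.items()),
        "cluster_tendency": sum(v * (i + j - mu_x - mu_y) ** 2 for (i, j), v in p.items()),
        "contrast": sum(v * (i - j) ** 2 for (i, j), v in p.items()),
        "correlation": corr,
        "difference_average": diff_avg,
        "difference_entropy": _entropy(p_diff.values()),
        "difference_variance": sum((k - diff_avg) ** 2 * v for k, v in p_diff.items()),
        "joint_energy": sum(v * v for v in p.values()),
        "joint_entropy": hxy,
        "imc1": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "imc2": math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))),
        "idm": sum(v / (1.0 + (i - j) ** 2) for (i, j), v in p.items()),
        "idmn": sum(v / (1.0 + (i - j) ** 2 / ng**2) for (i, j), v in p.items()),
        "id": sum(v / (1.0 + abs(i - j)) for (i, j), v in p.items()),
        "idn": sum(v / (1.0 + abs(i - j) / ng) for (i, j), v in p.items()),
        "inverse_variance": sum(v / (i - j) ** 2 for (i, j), v in p.items() if i != j),
        "maximum_probability": max(p.values()),
        "mcc": mcc,
        "sum_average": sum(k * v for k, v in p_sum.items()),
        "sum_entropy": _entropy(p_sum.values()),
        "sum_squares": sum(v * (i - mu_x) ** 2 for (i, j), v in p.items()),
    }


def _naive_run_zone(counts: dict[tuple[int, int], int], n_norm: int, names):
    nr = sum(counts.values())
    p = {k: v / nr for k, v in counts.items()}
    mu_i = sum(i * v for (i, _), v in p.items())
    mu_j = sum(j * v for (_, j), v in p.items())
    row: dict[int, float] = defaultdict(float)
    col: dict[int, float] = defaultdict(float)
    for (i, j), v in counts.items():
        row[i] += v
        col[j] += v
    vals = [
        sum(v / j**2 for (_, j), v in counts.items()) / nr,
        sum(v * j**2 for (_, j), v in counts.items()) / nr,
        sum(v**2 for v in row.values()) / nr,
        sum(v**2 for v in row.values()) / nr**2,
        sum(v**2 for v in col.values()) / nr,
        sum(v**2 for v in col.values()) / nr**2,
        nr / n_norm,
        sum(v * (i - mu_i) ** 2 for (i, _), v in p.items()),
        sum(v * (j - mu_j) ** 2 for (_, j), v in p.items()),
        _entropy(p.values()),
        sum(v / i**2 for (i, _), v in counts.items()) / nr,
        sum(v * i**2 for (i, _), v in counts.items()) / nr,
        sum(v / (i**2 * j**2) for (i, j), v in counts.items()) / nr,
        sum(v * i**2 / j**2 for (i, j), v in counts.items()) / nr,
        sum(v * j**2 / i**2 for (i, j), v in counts.items()) / nr,
        sum(v * i**2 * j**2 for (i, j), v in counts.items()) / nr,
    ]
    return dict(zip(names, vals))


def naive_glrlm_features(levels: np.ndarray, names) -> dict[str, float]:
    n_vox = int((levels > 0).sum())
    return _naive_run_zone(naive_glrlm(levels), 13 * n_vox, names)


def naive_glszm_features(levels: np.ndarray, names) -> dict[str, float]:
    n_vox = int((levels > 0).sum())
    return _naive_run_zone(naive_glszm(levels), n_vox, names)


def naive_ngtdm_features(levels: np.ndarray) -> dict[str, float]:
    table = naive_ngtdm(levels)
    grays = sorted(table)
    nvp = sum(n for n, _ in table.values())
    pi = {g: table[g][0] / nvp for g in grays}
    si = {g: table[g][1] for g in grays}
    ngp = len(grays)
    ps = sum(pi[g] * si[g] for g in grays)
    coarseness = 1.0 / ps if ps > 0 else 1e6
    if ngp > 1:
        contrast = (
            sum(pi[a] * pi[b] * (a - b) ** 2 for a in grays for b in grays)
            / (ngp * (ngp - 1))
            * sum(si.values()) / nvp
        )
        busy_den = sum(abs(a * pi[a] - b * pi[b]) for a in grays for b in grays)
        busyness = ps / busy_den if busy_den > 0 else 0.0
        complexity = sum(
            abs(a - b) * (pi[a] * si[a] + pi[b] * si[b]) / (pi[a] + pi[b])
            for a in grays for b in grays
        ) / nvp
        s_tot = sum(si.values())
        strength = (
            sum((pi[a] + pi[b]) * (a - b) ** 2 for a in grays for b in grays) / s_tot
            if s_tot > 0 else 0.0
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }
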