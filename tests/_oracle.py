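"""Independent brute-force landscape-metric oracle.

Everything here is computed from first principles with explicit Python
loops: patches by flood fill, adjacencies by enumerating every cell pair,
metrics by directly evaluating their defining formulas.  It shares no code
with the package's vectorized engine and exists solely to cross-check it
on small rasters.
"""

from __future__ import annotations

import math


def flood_patches(values, connectivity=8, background=(0, -1)):
    """List of (class_code, [(r, c), ...]) maximal connected components."""
    nr, nc = len(values), len(values[0])
    bg = set(background)
    seen = [[False] * nc for _ in range(nr)]
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    patches = []
    for r in range(nr):
        for c in range(nc):
            if seen[r][c] or values[r][c] in bg:
                continue
            code = values[r][c]
            stack = [(r, c)]
            seen[r][c] = True
            cells = []
            while stack:
                rr, cc = stack.pop()
                cells.append((rr, cc))
                for dr, dc in nbrs:
                    r2, c2 = rr + dr, cc + dc
                    if 0 <= r2 < nr and 0 <= c2 < nc and not seen[r2][c2] and values[r2][c2] == code:
                        seen[r2][c2] = True
                        stack.append((r2, c2))
            patches.append((code, cells))
    return patches


def rook_pairs(values, background=(0, -1)):
    """Every unordered pair of edge-sharing foreground cells, with their codes."""
    nr, nc = len(values), len(values[0])
    bg = set(background)
    pairs = []
    for r in range(nr):
        for c in range(nc):
            a = values[r][c]
            if a in bg:
                continue
            for r2, c2 in ((r, c + 1), (r + 1, c)):
                if r2 < nr and c2 < nc:
                    b = values[r2][c2]
                    if b not in bg:
                        pairs.append((a, b))
    return pairs


def max_like_adj(a):
    n = int(math.isqrt(a))
    m = a - n * n
    if m == 0:
        return 2 * n * (n - 1)
    if m <= n:
        return 2 * n * (n - 1) + 2 * m - 1
    return 2 * n * (n - 1) + 2 * m - 2


def oracle_metrics(values, cell_size_m=30.0, connectivity=8, background=(0, -1), contrast=None):
    """(class metrics dict-of-dicts, landscape metrics dict) by brute force.

    ``contrast`` maps unordered class pairs ``(i, k)`` (i < k) to
    dissimilarity weights in [0, 1].
    """
    patches = flood_patches(values, connectivity, background)
    cell_ha = cell_size_m * cell_size_m / 1e4
    if not patches:
        return {}, {}
    classes = sorted({code for code, _ in patches})
    A = sum(len(cells) for _, cells in patches) * cell_ha

    pairs = rook_pairs(values, background)
    S = {}
    for a, b in pairs:
        key = (min(a, b), max(a, b))
        S[key] = S.get(key, 0) + 1

    per_patch = []  # (code, n_cells, area, gyrate_m, cells)
    for code, cells in patches:
        n = len(cells)
        cr = sum(r for r, _ in cells) / n
        cc = sum(c for _, c in cells) / n
        gy = sum(math.hypot(r - cr, c - cc) for r, c in cells) / n * cell_size_m
        per_patch.append((code, n, n * cell_ha, gy, cells))

    cls = {}
    for code in classes:
        mine = [p for p in per_patch if p[0] == code]
        areas = [p[2] for p in mine]
        a_i = sum(areas)
        cells_i = sum(p[1] for p in mine)
        # ENN: min cell-centre distance between each patch and its nearest sibling
        enns = []
        if len(mine) >= 2:
            for i, p in enumerate(mine):
                best = math.inf
                for j, q in enumerate(mine):
                    if i == j:
                        continue
                    for r1, c1 in p[4]:
                        for r2, c2 in q[4]:
                            d = math.hypot(r1 - r2, c1 - c2)
                            if d < best:
                                best = d
                enns.append(best * cell_size_m)
        gii = S.get((code, code), 0)
        mgii = max_like_adj(cells_i)
        unlike = sum(v for (a, b), v in S.items() if (a == code) != (b == code))
        cls[code] = {
            "PLAND": 100.0 * a_i / A,
            "NP": len(mine),
            "LPI": 100.0 * max(areas) / A,
            "TE": unlike * cell_size_m,
            "AREA_MN": a_i / len(mine),
            "AREA_AM": sum(a * a for a in areas) / a_i,
            "GYRATE_MN": sum(p[3] for p in mine) / len(mine),
            "GYRATE_AM": sum(p[3] * p[2] for p in mine) / a_i,
            "ENN_MN": sum(enns) / len(enns) if enns else math.nan,
            "ENN_AM": sum(e * p[2] for e, p in zip(enns, mine)) / a_i if enns else math.nan,
            "AI": 100.0 * gii / mgii if mgii > 0 else math.nan,
            "MESH": sum(a * a for a in areas) / A,
        }

    m = len(classes)
    P = {c: sum(p[2] for p in per_patch if p[0] == c) / A for c in classes}

    if m == 1:
        contag = 100.0
    else:
        # double-count adjacency matrix
        D = {(i, k): 0.0 for i in classes for k in classes}
        for (a, b), v in S.items():
            if a == b:
                D[(a, b)] += 2 * v
            else:
                D[(a, b)] += v
                D[(b, a)] += v
        acc = 0.0
        for i in classes:
            row = sum(D[(i, k)] for k in classes)
            if row <= 0:
                continue
            for k in classes:
                if D[(i, k)] > 0:
                    q = P[i] * D[(i, k)] / row
                    acc += q * math.log(q)
        contag = 100.0 * (1.0 + acc / (2.0 * math.log(m)))

    unlike_edges = {k: v for k, v in S.items() if k[0] != k[1]}
    E = sum(unlike_edges.values())
    if m < 3 or E == 0:
        iji = math.nan
    else:
        acc = 0.0
        for v in unlike_edges.values():
            q = v / E
            acc -= q * math.log(q)
        iji = 100.0 * acc / math.log(m * (m - 1) / 2.0)

    if contrast is None or E == 0:
        teci = math.nan
    else:
        teci = 100.0 * sum(v * contrast.get(k, 0.0) for k, v in unlike_edges.items()) / E

    shdi = -sum(P[c] * math.log(P[c]) for c in classes)
    shei = shdi / math.log(m) if m > 1 else 0.0
    ai_terms = [(P[c], cls[c]["AI"]) for c in classes if not math.isnan(cls[c]["AI"])]
    ai = sum(p * v for p, v in ai_terms) if ai_terms else math.nan

    land = {
        "NP": float(len(per_patch)),
        "LPI": 100.0 * max(p[2] for p in per_patch) / A,
        "TE": float(E * cell_size_m),
        "AI": ai,
        "MESH": sum(p[2] ** 2 for p in per_patch) / A,
        "CONTAG": contag,
        "IJI": iji,
        "TECI": teci,
        "SHDI": shdi,
        "SHEI": shei,
        "PR": float(m),
    }
    return cls, land
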