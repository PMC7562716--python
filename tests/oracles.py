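"""Independent brute-force oracles used to cross-check the library.

Everything here is deliberately written as plain loops over Python
scalars, sharing no code path with the package implementation.
"""

from __future__ import annotations

import math


def otsu_exhaustive(histogram) -> int:
    """Exhaustive 256-candidate search maximizing between-class variance;
    ties resolved to the smallest threshold."""
    hist = [float(c) for c in histogram]
    total = sum(hist)
    best_t, best_var = None, -1.0
    for t in range(256):
        w0 = sum(hist[: t + 1])
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = sum(i * hist[i] for i in range(t + 1)) / w0
        mu1 = sum(i * hist[i] for i in range(t + 1, 256)) / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var + 1e-9:
            best_var = var
            best_t = t
    return best_t


def heatmap_bruteforce(predictions, canvas_size, cell_size):
    """Per-cell max over all rectangles containing the cell center.

    ``predictions`` is a list of (x, y, w, h, probability); returns a list
    of rows, each a list of floats or None (no-data).
    """
    cw, ch = canvas_size
    nx = math.ceil(cw / cell_size)
    ny = math.ceil(ch / cell_size)
    grid = [[None] * nx for _ in range(ny)]
    for j in range(ny):
        for i in range(nx):
            px = (i + 0.5) * cell_size
            py = (j + 0.5) * cell_size
            best = None
            for (x, y, w, h, p) in predictions:
                if x <= px < x + w and y <= py < y + h:
                    best = p if best is None else max(best, p)
            grid[j][i] = best
    return grid


def _label_regions(binary):
    """8-connected component labels of a list-of-lists boolean mask."""
    ny = len(binary)
    nx = len(binary[0]) if ny else 0
    labels = [[0] * nx for _ in range(ny)]
    current = 0
    for j0 in range(ny):
        for i0 in range(nx):
            if not binary[j0][i0] or labels[j0][i0]:
                continue
            current += 1
            stack = [(j0, i0)]
            labels[j0][i0] = current
            while stack:
                j, i = stack.pop()
                for dj in (-1, 0, 1):
                    for di in (-1, 0, 1):
                        jj, ii = j + dj, i + di
                        if 0 <= jj < ny and 0 <= ii < nx:
                            if binary[jj][ii] and not labels[jj][ii]:
                                labels[jj][ii] = current
                                stack.append((jj, ii))
    return labels, current


def region_props_bruteforce(binary, values):
    """Per-region properties of an 8-connected boolean mask.

    Returns a list of dicts with area, perimeter (exposed 4-neighbor cell
    edges), eccentricity and major-axis length (equivalent-ellipse second
    central moments), extent, and mean of ``values`` over the region.
    """
    ny = len(binary)
    nx = len(binary[0]) if ny else 0
    labels, n = _label_regions(binary)
    out = []
    for lbl in range(1, n + 1):
        cells = [
            (j, i) for j in range(ny) for i in range(nx) if labels[j][i] == lbl
        ]
        area = len(cells)
        perim = 0
        for (j, i) in cells:
            for (dj, di) in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                jj, ii = j + dj, i + di
                if not (0 <= jj < ny and 0 <= ii < nx) or labels[jj][ii] != lbl:
                    perim += 1
        cy = sum(j for j, _ in cells) / area
        cx = sum(i for _, i in cells) / area
        mu20 = sum((i - cx) ** 2 for _, i in cells) / area
        mu02 = sum((j - cy) ** 2 for j, _ in cells) / area
        mu11 = sum((i - cx) * (j - cy) for j, i in cells) / area
        disc = math.sqrt((mu20 - mu02) ** 2 + 4 * mu11**2)
        l1 = (mu20 + mu02 + disc) / 2
        l2 = (mu20 + mu02 - disc) / 2
        if l1 > 0:
            ecc = math.sqrt(max(0.0, 1.0 - l2 / l1))
            major = 4.0 * math.sqrt(l1)
        else:
            ecc, major = 0.0, 0.0
        js = [j for j, _ in cells]
        iis = [i for _, i in cells]
        bbox = (max(js) - min(js) + 1) * (max(iis) - min(iis) + 1)
        out.append(
            {
                "area": area,
                "perimeter": perim,
                "eccentricity": ecc,
                "major_axis_length": major,
                "extent": area / bbox,
                "mean_probability": sum(values[j][i] for j, i in cells) / area,
            }
        )
    return out


def _stats(vals):
    """(max, mean, population variance, skewness, Pearson kurtosis) with
    empty -> zeros and zero variance -> zero skew/kurtosis."""
    if not vals:
        return [0.0] * 5
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / n
    if var <= 0:
        return [max(vals), mean, 0.0, 0.0, 0.0]
    m3 = sum((v - mean) ** 3 for v in vals) / n
    m4 = sum((v - mean) ** 4 for v in vals) / n
    return [max(vals), mean, var, m3 / var**1.5, m4 / var**2]


def features_bruteforce(values, tissue):
    """The 44-feature vector, computed from scratch with loops.

    ``values`` is a list of rows of floats-or-None (None = no-data),
    ``tissue`` a parallel boolean mask.  Mirrors the documented feature
    conventions exactly.
    """
    ny = len(values)
    nx = len(values[0]) if ny else 0

    def cell_ok(j, i):
        return tissue[j][i] and values[j][i] is not None

    probs = [values[j][i] for j in range(ny) for i in range(nx) if cell_ok(j, i)]
    n_tissue = len(probs)
    assert n_tissue > 0

    def regions_at(thr):
        binary = [
            [cell_ok(j, i) and values[j][i] >= thr for i in range(nx)]
            for j in range(ny)
        ]
        vals = [[values[j][i] or 0.0 for i in range(nx)] for j in range(ny)]
        return region_props_bruteforce(binary, vals)

    r90 = regions_at(0.90)
    r50 = regions_at(0.50)

    out = []
    out.append(float(sum(1 for r in r90 if r["area"] >= 0.05 * n_tissue)))
    n_hot = sum(1 for p in probs if p >= 0.90)
    out.append(n_hot / n_tissue)
    if r50:
        largest = max(r50, key=lambda r: r["area"])
        out.append(float(largest["area"]))
        out.append(largest["major_axis_length"])
    else:
        out.extend([0.0, 0.0])
    out.append(n_hot / n_tissue)
    hot = [p for p in probs if p >= 0.90]
    out.append(sum(hot) / len(hot) if hot else 0.0)
    out.extend(_stats([r["area"] for r in r90]))
    out.extend(_stats([r["perimeter"] for r in r90]))
    out.extend(_stats([r["eccentricity"] for r in r90]))
    out.extend(_stats([r["extent"] for r in r50]))

    n = len(probs)
    mean = sum(probs) / n
    var = sum((p - mean) ** 2 for p in probs) / n
    ordered = sorted(probs)
    if n % 2:
        median = ordered[n // 2]
    else:
        median = (ordered[n // 2 - 1] + ordered[n // 2]) / 2
    counts = [0] * 100
    for p in probs:
        b = min(int(p * 100), 99)
        counts[b] += 1
    mode_bin = counts.index(max(counts))
    in_bin = [p for p in probs if min(int(p * 100), 99) == mode_bin]
    out.extend(
        [
            mean,
            var,
            math.sqrt(var),
            median,
            sum(in_bin) / len(in_bin),
            min(probs),
            max(probs),
            max(probs) - min(probs),
            sum(probs),
            mean,
        ]
    )
    bins = [
        (0.999, None), (0.99, 0.999), (0.95, 0.99), (0.9, 0.95),
        (0.8, 0.9), (0.7, 0.8), (0.6, 0.7), (0.5, 0.6),
    ]
    for lo, hi in bins:
        if hi is None:
            frac = sum(1 for p in probs if p > lo) / n
        else:
            frac = sum(1 for p in probs if lo < p <= hi) / n
        out.append(frac)
    return out
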