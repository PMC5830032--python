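"""Brute-force reference implementations used as independent oracles.

Everything here is a literal per-cell double loop in Python, kept free of
the package's vectorized machinery. Accumulations iterate kernel offsets in
the same sorted order the package documents, so floating-point results are
comparable bit-for-bit.
"""

from __future__ import annotations

import math

import numpy as np


def window_values(values, valid, kernel, r, c):
    """Qualifying values seen from focal cell (r, c), in sorted-offset order."""
    nr, nc = values.shape
    out = []
    for di, dj in kernel.offsets:
        i, j = r + int(di), c + int(dj)
        if 0 <= i < nr and 0 <= j < nc and valid[i, j]:
            out.append(float(values[i, j]))
    return out


def brute_focal(values, valid, kernel, statistic):
    """Per-cell loop version of every moving-window statistic.

    Returns (result, empty_mask); result cells under empty_mask are 0.
    """
    nr, nc = values.shape
    out = np.zeros((nr, nc), dtype=np.float64)
    empty = np.zeros((nr, nc), dtype=bool)
    for r in range(nr):
        for c in range(nc):
            vals = window_values(values, valid, kernel, r, c)
            if not vals:
                empty[r, c] = True
                continue
            n = len(vals)
            if statistic == "count":
                out[r, c] = float(n)
            elif statistic == "min":
                out[r, c] = min(vals)
            elif statistic == "max":
                out[r, c] = max(vals)
            elif statistic in ("sum", "mean", "sd"):
                s = 0.0
                for v in vals:
                    s += v
                if statistic == "sum":
                    out[r, c] = s
                else:
                    mean = s / n
                    if statistic == "mean":
                        out[r, c] = mean
                    else:
                        ssd = 0.0
                        for v in vals:
                            dev = v - mean
                            ssd += dev * dev
                        out[r, c] = math.sqrt(ssd / n)
            else:
                raise ValueError(statistic)
    return out, empty


def brute_relief_hydro(elevation, hydro, valid, kernel, cell_area):
    """Per-cell sum of (e - window min) over hydro-network target cells."""
    nr, nc = elevation.shape
    out = np.zeros((nr, nc), dtype=np.float64)
    empty = np.zeros((nr, nc), dtype=bool)
    for r in range(nr):
        for c in range(nc):
            cells = []
            for di, dj in kernel.offsets:
                i, j = r + int(di), c + int(dj)
                if 0 <= i < nr and 0 <= j < nc and valid[i, j]:
                    cells.append((float(elevation[i, j]), bool(hydro[i, j])))
            if not cells:
                empty[r, c] = True
                continue
            minv = min(e for e, _ in cells)
            total = 0.0
            for e, on_net in cells:
                if on_net:
                    total += e - minv
            out[r, c] = total * cell_area
    return out, empty


def brute_velocity(now, future, years, valid, kernel, floor):
    """Per-cell |mean rate| / (population sd of baseline + floor)."""
    rate = (future - now) / years
    nr, nc = now.shape
    out = np.zeros((nr, nc), dtype=np.float64)
    empty = np.zeros((nr, nc), dtype=bool)
    for r in range(nr):
        for c in range(nc):
            rates = window_values(rate, valid, kernel, r, c)
            if not rates:
                empty[r, c] = True
                continue
            n = len(rates)
            s = 0.0
            for v in rates:
                s += v
            num = abs(s / n)
            base = window_values(now, valid, kernel, r, c)
            sb = 0.0
            for v in base:
                sb += v
            mb = sb / n
            ssd = 0.0
            for v in base:
                dev = v - mb
                ssd += dev * dev
            out[r, c] = num / (math.sqrt(ssd / n) + floor)
    return out, empty


def brute_d8_accumulation(elevation):
    """Independent D8 accumulation on pit-free terrain.

    Direction is steepest drop per unit distance on the tie-broken surface;
    accumulation is propagated by repeated relaxation until stable.
    """
    elevation = np.asarray(elevation, dtype=np.float64)
    nr, nc = elevation.shape
    z = elevation + 1e-6 * (np.arange(nr)[:, None] * nc + np.arange(nc)[None, :])
    neighbors = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    down = {}
    for r in range(nr):
        for c in range(nc):
            best, best_grad = None, 0.0
            for dr, dc in neighbors:
                i, j = r + dr, c + dc
                if 0 <= i < nr and 0 <= j < nc:
                    dist = math.sqrt(dr * dr + dc * dc)
                    grad = (z[r, c] - z[i, j]) / dist
                    if grad > best_grad:
                        best, best_grad = (i, j), grad
            if best is not None:
                down[(r, c)] = best
    acc = np.ones((nr, nc), dtype=np.int64)
    order = sorted(((z[r, c], r, c) for r in range(nr) for c in range(nc)),
                   reverse=True)
    for _, r, c in order:
        if (r, c) in down:
            i, j = down[(r, c)]
            acc[i, j] += acc[r, c]
    return acc
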