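"""Independent brute-force oracles used by the tests.

These deliberately share no code with the package: plain Python loops over
the topology table, scalar minimum-image arithmetic, and textbook formulas.
"""

from __future__ import annotations

import math

import numpy as np


def min_image_dist(a, b, box) -> float:
    """3-D distance with minimum image applied in x and y only."""
    dx = a[0] - b[0]
    dx -= box[0] * round(dx / box[0])
    dy = a[1] - b[1]
    dy -= box[1] * round(dy / box[1])
    dz = a[2] - b[2]
    return math.sqrt(dx * dx + dy * dy + dz * dz)


def brute_force_contacts(coords, box, table, cutoff=0.55) -> dict[int, int]:
    """Exhaustive nearest-lipid contact rule: for every residue scan every
    lipid and every (residue bead, headgroup bead) pair."""
    prot = table[table.role == "protein"]
    heads = table[table.role == "headgroup"]
    out = {}
    for rid, rgrp in prot.groupby("residue_id"):
        best_lid, best_d = None, None
        for lid, lgrp in sorted(heads.groupby("molecule_id"), key=lambda kv: kv[0]):
            d = min(
                min_image_dist(coords[i], coords[j], box)
                for i in rgrp.index
                for j in lgrp.index
            )
            if best_d is None or d < best_d:
                best_d, best_lid = d, lid
        if best_d is not None and best_d <= cutoff:
            out[int(rid)] = int(best_lid)
    return out


def ols_slope(t, y) -> float:
    """Covariance-formula least-squares slope."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    tm, ym = t.mean(), y.mean()
    return float(np.sum((t - tm) * (y - ym)) / np.sum((t - tm) ** 2))


def anova_f(groups) -> float:
    """Textbook between/within sum-of-squares F statistic."""
    all_vals = np.concatenate([np.asarray(g, float) for g in groups])
    grand = all_vals.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return float((ss_between / df_b) / (ss_within / df_w))


def best_rotation_by_grid(mobile, target, n=60) -> float:
    """Brute-force search over z-rotations + centroid match; returns the best
    RMSD found (upper bound on the optimum for in-plane rotations)."""
    best = np.inf
    pm, tm = mobile - mobile.mean(0), target - target.mean(0)
    for ang in np.linspace(0, 2 * np.pi, n, endpoint=False):
        c, s = np.cos(ang), np.sin(ang)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        rmsd = np.sqrt(np.mean(np.sum((pm @ R.T - tm) ** 2, axis=1)))
        best = min(best, rmsd)
    return float(best)
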