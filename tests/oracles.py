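"""Independent brute-force oracles used to cross-check the fast implementations.

Deliberately naive: per-voxel loops, explicit sorting and closed-form t
distributions, sharing no code with the package.
"""

import math

import numpy as np
from scipy.special import stdtr


def brute_mean(doses) -> float:
    vals = [float(v) for v in doses]
    return math.fsum(vals) / len(vals)


def brute_overlap_fraction(oar_occ, target_occ) -> float:
    oar = np.asarray(oar_occ).ravel()
    tgt = np.asarray(target_occ).ravel()
    inter = sum(1 for a, b in zip(oar, tgt) if a and b)
    denom = sum(1 for a in oar if a)
    return inter / denom


def brute_dose_at_volume(doses, p: float) -> float:
    """Minimum dose of the hottest p% of voxels (sort-and-index)."""
    vals = sorted((float(v) for v in doses), reverse=True)
    k = max(1, math.ceil(p / 100.0 * len(vals)))
    return vals[k - 1]


def brute_volume_at_dose(doses, d: float) -> float:
    vals = [float(v) for v in doses]
    return sum(1 for v in vals if v >= d) / len(vals)


def brute_conformity_index(dose_arr, target_occ, iso: float) -> float:
    dose_flat = np.asarray(dose_arr).ravel()
    tgt = np.asarray(target_occ).ravel()
    region = [v >= iso for v in dose_flat]
    n_iso = sum(region)
    inter = sum(1 for r, t in zip(region, tgt) if r and t)
    return inter / n_iso


def brute_ring_voxels(occ, spacing, margin_mm):
    """Ring membership by explicit pairwise distances to occupied centres."""
    occ = np.asarray(occ)
    sx, sy, sz = spacing
    occupied = np.argwhere(occ) * np.array([sx, sy, sz])
    ring = np.zeros(occ.shape, dtype=bool)
    for idx in np.ndindex(occ.shape):
        if occ[idx]:
            continue
        pos = np.array(idx) * np.array([sx, sy, sz])
        d2 = np.sum((occupied - pos) ** 2, axis=1)
        if d2.min() <= margin_mm**2 + 1e-9:
            ring[idx] = True
    return ring


def welch_oracle(a, b) -> tuple[float, float]:
    """Hand-computed Welch two-sample two-tailed t-test."""
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    na, nb = len(a), len(b)
    ma, mb = math.fsum(a) / na, math.fsum(b) / nb
    va = math.fsum((x - ma) ** 2 for x in a) / (na - 1)
    vb = math.fsum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stdtr(df, -abs(t))
    return t, p


def paired_oracle_less(x, y) -> tuple[float, float]:
    """Hand-computed paired t-test of H1: x < y (one-tailed)."""
    d = [float(a) - float(b) for a, b in zip(x, y)]
    n = len(d)
    md = math.fsum(d) / n
    vd = math.fsum((v - md) ** 2 for v in d) / (n - 1)
    t = md / math.sqrt(vd / n)
    p = stdtr(n - 1, t)
    return t, p
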