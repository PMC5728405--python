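"""Brute-force / formula-level oracles, independent of the library code paths.

Each oracle re-derives an expected result from the definition (per-pixel
loops, step-up definition, closed-form statistics, full translation) so the
tests never compare the implementation against itself.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import t as t_dist


def brute_erode_chebyshev(mask: np.ndarray, erosion_px: int) -> np.ndarray:
    """Per-pixel Chebyshev erosion: keep a pixel iff every pixel within
    Chebyshev distance <= erosion_px lies inside the mask (outside the image
    counts as background)."""
    mask = mask.astype(bool)
    out = np.zeros_like(mask)
    rows, cols = mask.shape
    e = erosion_px
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            keep = True
            for dr in range(-e, e + 1):
                for dc in range(-e, e + 1):
                    rr, cc = r + dr, c + dc
                    if rr < 0 or cc < 0 or rr >= rows or cc >= cols or not mask[rr, cc]:
                        keep = False
                        break
                if not keep:
                    break
            out[r, c] = keep
    return out


def brute_rings(mask: np.ndarray, gap: float, width: float) -> dict[int, np.ndarray]:
    """Exhaustive distance-band rings: for every background pixel, compute the
    Euclidean distance to every nucleus pixel set; assign the pixel to the
    nearest nucleus (ties to the lowest label) and include it in that
    nucleus's ring iff gap < distance <= gap + width."""
    labels = sorted(set(mask.ravel().tolist()) - {0})
    pix = {k: np.argwhere(mask == k) for k in labels}
    rings = {k: np.zeros(mask.shape, dtype=bool) for k in labels}
    rows, cols = mask.shape
    for r in range(rows):
        for c in range(cols):
            if mask[r, c]:
                continue
            best = (math.inf, 0)
            for k in labels:
                d2 = ((pix[k][:, 0] - r) ** 2 + (pix[k][:, 1] - c) ** 2).min()
                d = math.sqrt(float(d2))
                if (d, k) < best:
                    best = (d, k)
            d, k = best
            if gap < d <= gap + width:
                rings[k][r, c] = True
    return rings


def bh_stepup(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values straight from the step-up
    definition: sort, multiply p_(i) by m/i, take the running minimum from
    the largest rank down, cap at 1, restore input order."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = math.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        adj[order[rank - 1]] = min(running, 1.0)
    return adj


def student_t_p(a, b) -> float:
    """Two-sided pooled-variance t-test p from the textbook formulas."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return 2.0 * t_dist.sf(abs(t), na + nb - 2)


def welch_t_p(a, b) -> float:
    """Two-sided Welch t-test p with the Welch-Satterthwaite df formula."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return 2.0 * t_dist.sf(abs(t), df)


def translate_consequence(ref_cds: str, position: int, alt: str) -> str:
    """Consequence by full translation of both sequences (Biopython)."""
    from Bio.Seq import Seq

    alt_cds = ref_cds[: position - 1] + alt + ref_cds[position:]
    ref_prot = str(Seq(ref_cds).translate())
    alt_prot = str(Seq(alt_cds).translate())
    idx = (position - 1) // 3
    if ref_prot == alt_prot:
        return "silent"
    if alt_prot[idx] == "*" and ref_prot[idx] != "*":
        return "nonsense"
    if ref_prot[idx] == "*" and alt_prot[idx] != "*":
        return "stop_lost"
    return "missense"


def exact_presence_probability(motif: str, length: int, probs: dict[str, float]) -> float:
    """Exact P(>= 1 motif occurrence) in an i.i.d. sequence, by enumerating
    every sequence of the given length (feasible only for tiny lengths)."""
    import itertools

    total = 0.0
    k = len(motif)
    for seq in itertools.product("ACGT", repeat=length):
        s = "".join(seq)
        if motif in s:
            pr = 1.0
            for b in s:
                pr *= probs[b]
            total += pr
    return total
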