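"""Exhaustive k-mer over-representation scan for 3'-UTR sequence sets.

A deliberately simple, fully specified motif finder: every k-mer of widths
``k_min``..``k_max`` occurring in the sequences is scored for
over-representation against an order-0 background model.  The statistic is
a one-sided binomial tail on the number of sequences containing at least
one occurrence, with the per-sequence occurrence probability approximated
as ``1 - (1 - p_kmer)^(L - k + 1)``.  Significance is Bonferroni-corrected
across every distinct k-mer enumerated (the full tested universe across
all widths, not only those above the support floor — correcting only over
the high-support survivors would be a selection-biased universe).  Hits
are ranked by score (ties broken lexicographically) and nesting of a
shorter hit inside a longer one is annotated.

The scan treats sequences as single-stranded mRNA: reverse complements are
NOT collapsed.  Ambiguity codes break k-mer windows rather than matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
from scipy.special import gammaln, logsumexp

from .exceptions import ParameterError

__all__ = ["MotifHit", "background_model", "scan_kmers"]

_VALID = set("ACGT")
_LOG10 = math.log(10.0)


@dataclass
class MotifHit:
    kmer: str
    width: int
    observed: int  # sequences with >= 1 occurrence
    expected: float  # expected sequence count under the background
    score: float  # -log10 one-sided binomial tail (uncorrected)
    p_value: float
    p_bonferroni: float
    rank: int = 0
    nested_in: str | None = None  # a longer, also-significant hit containing this one


def binom_log_tail(observed: int, n: int, p: float) -> float:
    """log P(X >= observed) for X ~ Binomial(n, p), stable for extreme tails.

    Computed by log-sum-exp over the upper-tail terms, so enrichment scores
    do not underflow to -inf the way exponent-space survival functions do.
    """
    if observed <= 0:
        return 0.0
    if observed > n:
        return -math.inf
    if p <= 0:
        return -math.inf
    if p >= 1:
        return 0.0
    x = np.arange(observed, n + 1)
    log_terms = (
        gammaln(n + 1)
        - gammaln(x + 1)
        - gammaln(n - x + 1)
        + x * math.log(p)
        + (n - x) * math.log1p(-p)
    )
    return float(min(0.0, logsumexp(log_terms)))


def _as_strings(seqs) -> list[str]:
    out = []
    for s in seqs:
        out.append(str(getattr(s, "seq", s)).upper())
    return out


def background_model(seqs, pseudocount: float = 1.0) -> dict[str, float]:
    """Order-0 nucleotide frequencies with a pseudocount, summing to 1."""
    strings = _as_strings(seqs)
    if not strings:
        raise ParameterError("empty sequence set")
    counts = {b: pseudocount for b in "ACGT"}
    for s in strings:
        for b in s:
            if b in _VALID:
                counts[b] += 1
    total = sum(counts.values())
    return {b: counts[b] / total for b in "ACGT"}


def _windows(seq: str, k: int):
    """Valid k-mer windows of ``seq``; windows containing non-ACGT break."""
    n = len(seq)
    i = 0
    while i <= n - k:
        window = seq[i : i + k]
        bad = -1
        for j in range(k - 1, -1, -1):
            if window[j] not in _VALID:
                bad = j
                break
        if bad >= 0:
            i += bad + 1  # restart after the offending symbol
            continue
        yield window
        i += 1


def presence_probability(p_kmer: float, length: int, k: int) -> float:
    """P(>= 1 occurrence in a length-``length`` i.i.d. background sequence).

    Uses the independence approximation 1 - (1 - p_kmer)^(L - k + 1); the
    exact value (enumeration over all windows with overlap structure) is
    used as a test oracle on short sequences.
    """
    n_windows = length - k + 1
    if n_windows <= 0:
        return 0.0
    return 1.0 - (1.0 - p_kmer) ** n_windows


def scan_kmers(
    seqs,
    k_min: int = 8,
    k_max: int = 20,
    background: dict[str, float] | None = None,
    min_support: int = 5,
    alpha: float = 0.01,
) -> list[MotifHit]:
    """Rank over-represented k-mers of widths ``k_min``..``k_max``.

    Returns hits present in at least ``min_support`` sequences whose
    Bonferroni-corrected binomial tail falls below ``alpha``, ranked by
    score (descending) with lexicographic tie-break.
    """
    strings = _as_strings(seqs)
    if not strings:
        raise ParameterError("empty sequence set")
    if k_min > k_max:
        raise ParameterError("k_min must be <= k_max")
    if k_max > min(len(s) for s in strings):
        raise ParameterError("k_max exceeds the shortest sequence length")
    if background is None:
        background = background_model(strings)
    log_bg = {b: math.log(background[b]) for b in "ACGT"}
    lengths = [len(s) for s in strings]
    n_seq = len(strings)

    support: dict[str, int] = {}
    n_tested = 0
    for k in range(k_min, k_max + 1):
        seen_this_width: set[str] = set()
        for s in strings:
            present = set(_windows(s, k))
            seen_this_width.update(present)
            for kmer in present:
                support[kmer] = support.get(kmer, 0) + 1
        n_tested += len(seen_this_width)

    candidates = [(kmer, obs) for kmer, obs in support.items() if obs >= min_support]
    hits: list[MotifHit] = []
    for kmer, obs in candidates:
        k = len(kmer)
        p_kmer = math.exp(sum(log_bg[b] for b in kmer))
        p_seq = [presence_probability(p_kmer, L, k) for L in lengths]
        p_mean = float(np.mean(p_seq))
        expected = float(np.sum(p_seq))
        # one-sided tail P(X >= obs) for X ~ Binomial(n_seq, p_mean),
        # in log space so extreme enrichment does not underflow
        logp = binom_log_tail(obs, n_seq, p_mean)
        p_value = math.exp(logp) if logp > -700 else 0.0
        log_bonf = logp + math.log(n_tested)
        p_bonf = min(1.0, math.exp(log_bonf)) if log_bonf > -700 else 0.0
        if log_bonf >= math.log(alpha):
            continue
        hits.append(
            MotifHit(
                kmer=kmer,
                width=k,
                observed=obs,
                expected=expected,
                score=-logp / _LOG10,
                p_value=p_value,
                p_bonferroni=p_bonf,
            )
        )

    hits.sort(key=lambda h: (-h.score, h.kmer))
    for rank, hit in enumerate(hits, start=1):
        hit.rank = rank
    # annotate nesting: a shorter hit contained in a longer (higher-width) hit
    for hit in hits:
        for other in hits:
            if other.width > hit.width and hit.kmer in other.kmer:
                hit.nested_in = other.kmer
                break
    return hits
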