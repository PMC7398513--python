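"""Sequence-diversity statistics: Hd, Pi and Hudson-style pairwise Fst.

All sequence-based quantities use pairwise deletion (columns with a gap or
ambiguity code in either member of a pair are excluded for that pair only)
and count substitutions only, so indel-rich intron alignments keep their
information content.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiversityStats:
    """Per-population summary: n sequences, N distinct haplotypes,
    haplotype diversity and per-site nucleotide diversity (each with a
    standard deviation)."""

    n: int
    N: int
    Hd: float
    Hd_sd: float
    Pi: float
    Pi_sd: float


@dataclass(frozen=True)
class FstResult:
    pop_a: str
    pop_b: str
    fst: float | None  # None when pi_between == 0 (undefined)
    pi_within: float
    pi_between: float


def haplotype_diversity(haplotype_counts: Mapping[str, int] | Sequence[int],
                        ) -> tuple[float, float]:
    """Haplotype (gene) diversity with its sampling standard deviation.

    Hd = n/(n-1) * (1 - sum p_i^2).  The variance follows Nei (1987,
    eq. 8.12):

        V(Hd) = 2/(n(n-1)) * [ 2(n-2) * (sum p_i^3 - (sum p_i^2)^2)
                               + sum p_i^2 - (sum p_i^2)^2 ]
    """
    counts = (list(haplotype_counts.values())
              if isinstance(haplotype_counts, Mapping) else list(haplotype_counts))
    counts = [c for c in counts if c > 0]
    n = sum(counts)
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2 sequences")
    p = np.asarray(counts, dtype=float) / n
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    hd = n / (n - 1) * (1.0 - s2)
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (s3 - s2**2) + s2 - s2**2)
    return hd, math.sqrt(max(var, 0.0))


# -- sequence encoding -------------------------------------------------------

_ENC = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i


def encode_alignment(seqs: Sequence[str]) -> np.ndarray:
    """Encode equal-length sequences as an (n, L) int8 matrix; anything
    other than A/C/G/T (gaps, ambiguity codes) becomes -1 and is excluded
    pairwise downstream."""
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must have equal aligned length")
    mat = np.frombuffer("".join(s.upper() for s in seqs).encode("ascii"),
                        dtype=np.uint8).reshape(len(seqs), L)
    return _ENC[mat]


def _pair_diffs(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (diffs, compared) matrices over all sequence pairs."""
    n = mat.shape[0]
    valid = mat >= 0
    diffs = np.zeros((n, n))
    compared = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        diffs[i, i + 1 :] = np.sum(both & (mat[i] != mat[i + 1 :]), axis=1)
        compared[i, i + 1 :] = np.sum(both, axis=1)
    diffs += diffs.T
    compared += compared.T
    return diffs, compared


def nucleotide_diversity(aligned_seqs: Sequence[str]) -> tuple[float, float]:
    """Per-site nucleotide diversity Pi with its standard deviation.

    Pi is the mean over unordered pairs of (pairwise differences /
    pairwise-comparable sites); pairs with no comparable sites are dropped
    with a warning.  The variance uses the no-recombination sampling form
    (Nei 1987, eq. 10.7):

        V(Pi) = (n+1)/(3(n-1)L) * Pi + 2(n^2+n+3)/(9n(n-1)) * Pi^2

    with L the mean number of comparable sites per pair.
    """
    mat = encode_alignment(aligned_seqs)
    n = mat.shape[0]
    diffs, compared = _pair_diffs(mat)
    iu = np.triu_indices(n, k=1)
    d, c = diffs[iu], compared[iu]
    usable = c > 0
    if np.count_nonzero(~usable):
        logger.warning("%d sequence pair(s) had no comparable sites and were dropped",
                       int(np.count_nonzero(~usable)))
    if np.count_nonzero(usable) < 1:
        raise ValueError("no usable sequence pairs")
    pi = float(np.mean(d[usable] / c[usable]))
    L = float(np.mean(c[usable]))
    var = (n + 1) / (3.0 * (n - 1) * L) * pi + \
        2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1)) * pi**2
    return pi, math.sqrt(max(var, 0.0))


def diversity_stats(aligned_seqs: Sequence[str]) -> DiversityStats:
    """Table-style per-population summary over an aligned sequence set."""
    haps: dict[str, int] = {}
    for s in aligned_seqs:
        haps[s.upper()] = haps.get(s.upper(), 0) + 1
    hd, hd_sd = haplotype_diversity(haps)
    pi, pi_sd = nucleotide_diversity(aligned_seqs)
    return DiversityStats(n=len(aligned_seqs), N=len(haps),
                          Hd=hd, Hd_sd=hd_sd, Pi=pi, Pi_sd=pi_sd)


def _mean_pairwise_pi(mat: np.ndarray, rows_a: np.ndarray, rows_b: np.ndarray,
                      within: bool) -> float:
    valid = mat >= 0
    total = 0.0
    count = 0
    for ia in rows_a:
        rows = rows_b[rows_b > ia] if within else rows_b
        if rows.size == 0:
            continue
        both = valid[ia] & valid[rows]
        c = np.sum(both, axis=1)
        d = np.sum(both & (mat[ia] != mat[rows]), axis=1)
        ok = c > 0
        total += float(np.sum(d[ok] / c[ok]))
        count += int(np.count_nonzero(ok))
    if count == 0:
        raise ValueError("no comparable sequence pairs")
    return total / count


def pairwise_fst(
    seqs_a: Sequence[str],
    seqs_b: Sequence[str],
    pop_a: str = "A",
    pop_b: str = "B",
) -> FstResult:
    """Hudson/Slatkin/Maddison-style Fst: 1 - pi_within / pi_between.

    pi_within averages the two populations' mean pairwise diversities with
    equal weight; pi_between is the mean over all cross-population pairs.
    Sampling noise can make the estimate slightly negative; negative values
    are reported as computed.  When pi_between is zero the statistic is
    undefined and ``fst`` is None.
    """
    if len(seqs_a) < 2 or len(seqs_b) < 2:
        raise ValueError("each population needs >= 2 sequences")
    mat = encode_alignment(list(seqs_a) + list(seqs_b))
    ia = np.arange(len(seqs_a))
    ib = np.arange(len(seqs_a), len(seqs_a) + len(seqs_b))
    pi_a = _mean_pairwise_pi(mat, ia, ia, within=True)
    pi_b = _mean_pairwise_pi(mat, ib, ib, within=True)
    pi_between = _mean_pairwise_pi(mat, ia, ib, within=False)
    pi_within = 0.5 * (pi_a + pi_b)
    if pi_between == 0.0:
        logger.warning("pi_between = 0 for %s/%s: Fst undefined", pop_a, pop_b)
        return FstResult(pop_a, pop_b, None, pi_within, pi_between)
    return FstResult(pop_a, pop_b, 1.0 - pi_within / pi_between,
                     pi_within, pi_between)


def fst_matrix(populations: Mapping[str, Sequence[str]],
               focal: str | None = None) -> list[FstResult]:
    """Pairwise Fst over named populations.

    With ``focal`` set, only comparisons against that population are
    computed (the table-style presentation); otherwise all pairs.
    """
    names = list(populations)
    results = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if focal is not None and focal not in (a, b):
                continue
            results.append(pairwise_fst(populations[a], populations[b], a, b))
    return results
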