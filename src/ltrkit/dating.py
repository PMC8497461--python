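"""Insertion-time estimation and family phylogeny.

At insertion the two LTRs of a retrotransposon are identical; they then
accumulate substitutions independently, so the Kimura 2-parameter distance
K between the aligned 5' and 3' LTRs, divided by twice the per-site
substitution rate mu (default 1.3e-8 /site/year), estimates the insertion
age: T = K / (2*mu).  The divisor is configurable because some studies
divide by mu alone.

The family phylogeny is an UPGMA tree over p-distances from pairwise
global alignments, yielding an ultrametric tree serializable as newick.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .alignment import dna_aligner
from .density import DensityResult, density_modes
from .mining import LtrElement

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class SaturationError(ValueError):
    """K2P distance undefined: substitution proportions too high."""


@dataclass(frozen=True)
class AgeEstimate:
    element_id: str
    P: float  # transition proportion
    Q: float  # transversion proportion
    K: float  # Kimura 2-parameter distance
    mu: float
    age_years: float

    def __post_init__(self) -> None:
        if self.P < 0 or self.Q < 0 or self.P + self.Q > 1:
            raise ValueError("invalid substitution proportions")
        if self.K < 0:
            raise ValueError("negative distance")


# ---------------------------------------------------------------------------
# pairwise LTR alignment and K2P distance
# ---------------------------------------------------------------------------

def align_ltr_pair(ltr5: str, ltr3: str) -> Align.Alignment:
    """Global alignment of the two LTR copies (match +1, mismatch -1,
    gap open -4, gap extend -1)."""
    if len(ltr5) < 50 or len(ltr3) < 50:
        raise ValueError("LTR sequences must be at least 50 bp")
    return dna_aligner("global").align(ltr5.upper(), ltr3.upper())[0]


def kimura2p(alignment: Align.Alignment) -> tuple[float, float, float]:
    """(P, Q, K) over the gap-free columns of a pairwise alignment.

    K = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).
    """
    a, b = alignment[0], alignment[1]
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-" or x == "N" or y == "N":
            continue
        n += 1
        if x != y:
            if (x, y) in TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise ValueError("no gap-free columns")
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"saturated alignment: P={P:.3f}, Q={Q:.3f}")
    K = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return P, Q, K


def estimate_age(K: float, mu: float = 1.3e-8, divisor: float = 2.0) -> float:
    """Insertion age in years: T = K / (divisor * mu)."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if K < 0:
        raise ValueError("K must be >= 0")
    return K / (divisor * mu)


def date_element(element: LtrElement, mu: float = 1.3e-8,
                 divisor: float = 2.0) -> AgeEstimate:
    """K2P-date one mined element from its two LTR sequences."""
    aln = align_ltr_pair(element.ltr5_seq, element.ltr3_seq)
    P, Q, K = kimura2p(aln)
    age = estimate_age(K, mu, divisor)
    element.age_years = age
    return AgeEstimate(element_id=element.element_id, P=P, Q=Q, K=K,
                       mu=mu, age_years=age)


def date_ltr_pairs(pairs: list[tuple[str, str]], mu: float = 1.3e-8,
                   divisor: float = 2.0) -> list[AgeEstimate]:
    """Date bare (ltr5, ltr3) pairs, skipping saturated ones."""
    out = []
    for i, (l5, l3) in enumerate(pairs):
        try:
            P, Q, K = kimura2p(align_ltr_pair(l5, l3))
        except SaturationError:
            continue
        out.append(AgeEstimate(element_id=f"pair{i + 1}", P=P, Q=Q, K=K,
                               mu=mu, age_years=estimate_age(K, mu, divisor)))
    return out


def age_distribution(ages_years, grid_points: int = 512) -> DensityResult:
    """Age density (Gaussian KDE, Silverman bandwidth) with modes.

    Ages are non-negative, so the evaluation grid is clipped at zero.
    """
    return density_modes(ages_years, grid_points=grid_points, lower_bound=0.0)


# ---------------------------------------------------------------------------
# p-distance matrix and UPGMA
# ---------------------------------------------------------------------------

def pdistance_matrix(seqs: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """p-distances (mismatches over gap-free columns) from pairwise global
    alignments, for all sequence pairs."""
    ids = sorted(seqs)
    n = len(ids)
    mat = np.zeros((n, n))
    aligner = dna_aligner("global")
    for i, j in itertools.combinations(range(n), 2):
        aln = aligner.align(seqs[ids[i]].upper(), seqs[ids[j]].upper())[0]
        a, b = aln[0], aln[1]
        cols = diff = 0
        for x, y in zip(a, b):
            if x == "-" or y == "-":
                continue
            cols += 1
            if x != y:
                diff += 1
        d = diff / cols if cols else 1.0
        mat[i, j] = mat[j, i] = d
    return ids, mat


@dataclass
class UltrametricTree:
    newick: str
    leaves: list[str]
    root_height: float
    #: heights of all internal nodes, in merge order
    node_heights: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.leaves)) != len(self.leaves):
            raise ValueError("duplicate leaf ids")


def upgma_tree(ids: list[str], matrix: np.ndarray) -> UltrametricTree:
    """UPGMA agglomeration of a symmetric distance matrix.

    The minimum-distance pair is joined at height d/2; distances to the
    merged cluster are size-weighted averages.  Ties are broken by the
    lexicographically smallest pair of cluster leaf-id minima, making the
    output deterministic.  The result is ultrametric by construction.
    """
    n = len(ids)
    if matrix.shape != (n, n):
        raise ValueError("matrix shape does not match ids")
    if not np.allclose(matrix, matrix.T):
        raise ValueError("matrix must be symmetric")
    if (matrix < 0).any():
        raise ValueError("matrix must be non-negative")
    if n == 0:
        raise ValueError("empty input")
    if n == 1:
        return UltrametricTree(newick=f"{ids[0]}:0.0;", leaves=list(ids),
                               root_height=0.0)

    # cluster state: (min leaf id, size, height, newick)
    clusters: dict[int, tuple[str, int, float, str]] = {
        i: (ids[i], 1, 0.0, ids[i]) for i in range(n)
    }
    dist = {(i, j): float(matrix[i, j])
            for i, j in itertools.combinations(range(n), 2)}
    next_id = n
    heights: list[float] = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for a, b in itertools.combinations(keys, 2):
            d = dist[(min(a, b), max(a, b))]
            tiekey = tuple(sorted((clusters[a][0], clusters[b][0])))
            cand = (d, tiekey, a, b)
            if best is None or cand < best:
                best = cand
        d, _tie, a, b = best
        name_a, size_a, h_a, nwk_a = clusters[a]
        name_b, size_b, h_b, nwk_b = clusters[b]
        height = d / 2.0
        heights.append(height)
        nwk = (f"({nwk_a}:{max(0.0, height - h_a):.10g},"
               f"{nwk_b}:{max(0.0, height - h_b):.10g})")
        for k in keys:
            if k in (a, b):
                continue
            d_ak = dist[(min(a, k), max(a, k))]
            d_bk = dist[(min(b, k), max(b, k))]
            d_new = (size_a * d_ak + size_b * d_bk) / (size_a + size_b)
            dist[(min(next_id, k), max(next_id, k))] = d_new
        del clusters[a], clusters[b]
        clusters[next_id] = (min(name_a, name_b), size_a + size_b, height, nwk)
        next_id += 1
    (_, _, root_height, newick) = next(iter(clusters.values()))
    return UltrametricTree(newick=newick + ";", leaves=list(ids),
                           root_height=root_height, node_heights=heights)
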