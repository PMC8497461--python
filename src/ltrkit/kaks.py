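"""Codon-aware Ka/Ks by the Nei-Gojobori (1986) counting method.

Synonymous (S) and nonsynonymous (N) site counts are obtained per codon by
enumerating the three single-nucleotide neighbors at each position: a
position contributes (number of synonymous sense changes)/3 to S and the
remainder (including changes to stop codons) to N, so S + N = 3 per
ungapped codon exactly.  Differences between codon pairs are averaged over
all minimal mutation pathways, excluding pathways that pass through a stop
codon (all pathways are used when every one is blocked).  Proportions are
Jukes-Cantor corrected: d = -3/4 ln(1 - 4p/3); p >= 3/4 is flagged as
saturated.

Ks distributions over pair cohorts are summarized by the shared KDE/mode
machinery, with Ks > 3 excluded as saturated noise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

from Bio.Seq import Seq

from .alignment import protein_aligner
from .density import DensityResult, density_modes

_BASES = "ACGT"
KS_MAX = 3.0


@lru_cache(maxsize=None)
def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


@lru_cache(maxsize=None)
def _site_counts(codon: str) -> tuple[float, float]:
    """(S, N) site counts for one sense codon; S + N = 3."""
    aa = _translate(codon)
    if aa == "*":
        raise ValueError(f"stop codon {codon}")
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if _translate(alt) == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _pathway_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) difference counts between two sense codons, averaged over
    all minimal mutation pathways; stop-crossing pathways excluded."""
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not positions:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(positions):
        current = codon_a
        steps = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if _translate(nxt) == "*":
                blocked = True
            steps.append((current, nxt))
            current = nxt
        pathways.append((blocked, steps))
    usable = [steps for blocked, steps in pathways if not blocked]
    if not usable:  # all pathways cross a stop: fall back to every pathway
        usable = [steps for _, steps in pathways]
    sd = nd = 0.0
    for steps in usable:
        for before, after in steps:
            if _translate(before) == _translate(after):
                sd += 1.0
            else:
                nd += 1.0
    return sd / len(usable), nd / len(usable)


@dataclass
class CodingPair:
    id_a: str
    id_b: str
    codon_columns: int  # ungapped codon columns
    S: float
    N: float
    Sd: float
    Nd: float
    Ks: float  # nan when saturated
    Ka: float
    saturated_s: bool
    saturated_n: bool
    method: str = "NG86-JC"

    def __post_init__(self) -> None:
        if abs((self.S + self.N) - 3 * self.codon_columns) > 1e-6:
            raise ValueError("site counts must sum to 3 per ungapped codon")


def _jc_correct(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return math.nan, True
    if p == 0.0:
        return 0.0, False
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0), False


# ---------------------------------------------------------------------------
# codon-aware alignment
# ---------------------------------------------------------------------------

def _check_cds(cds: str, label: str) -> str:
    cds = cds.upper()
    cds = cds[: 3 * (len(cds) // 3)]  # trim an incomplete final codon
    if len(cds) < 3:
        raise ValueError(f"{label}: fewer than one codon")
    aa = str(Seq(cds).translate())
    body = aa[:-1] if aa.endswith("*") else aa
    if "*" in body:
        raise ValueError(f"{label}: internal stop codon")
    return cds


def codon_align(cds_a: str, cds_b: str) -> list[tuple[str, str]]:
    """Codon alignment via a global amino-acid alignment back-threaded to
    nucleotides.  Returns (codon_a, codon_b) columns; gaps appear as '---'.
    Trailing stop codons are trimmed before alignment."""
    cds_a = _check_cds(cds_a, "cds_a")
    cds_b = _check_cds(cds_b, "cds_b")
    aa_a = str(Seq(cds_a).translate()).rstrip("*")
    aa_b = str(Seq(cds_b).translate()).rstrip("*")
    aligner = protein_aligner("global")
    aln = aligner.align(aa_a, aa_b)[0]
    row_a, row_b = aln[0], aln[1]
    out: list[tuple[str, str]] = []
    ia = ib = 0
    for ca, cb in zip(row_a, row_b):
        if ca == "-":
            cod_a = "---"
        else:
            cod_a = cds_a[3 * ia : 3 * ia + 3]
            ia += 1
        if cb == "-":
            cod_b = "---"
        else:
            cod_b = cds_b[3 * ib : 3 * ib + 3]
            ib += 1
        out.append((cod_a, cod_b))
    return out


def ng86(codon_alignment: list[tuple[str, str]], id_a: str = "A",
         id_b: str = "B") -> CodingPair:
    """Nei-Gojobori site/difference counts and JC-corrected Ka, Ks."""
    S = N = Sd = Nd = 0.0
    columns = 0
    for cod_a, cod_b in codon_alignment:
        if "-" in cod_a or "-" in cod_b:
            continue
        s_a, n_a = _site_counts(cod_a)
        s_b, n_b = _site_counts(cod_b)
        S += (s_a + s_b) / 2.0
        N += (n_a + n_b) / 2.0
        sd, nd = _pathway_diffs(cod_a, cod_b)
        Sd += sd
        Nd += nd
        columns += 1
    if columns == 0:
        raise ValueError("no ungapped codon columns")
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ks, sat_s = _jc_correct(ps)
    ka, sat_n = _jc_correct(pn)
    return CodingPair(id_a=id_a, id_b=id_b, codon_columns=columns,
                      S=S, N=N, Sd=Sd, Nd=Nd, Ks=ks, Ka=ka,
                      saturated_s=sat_s, saturated_n=sat_n)


def kaks_pair(cds_a: str, cds_b: str, id_a: str = "A", id_b: str = "B") -> CodingPair:
    """codon_align + ng86 in one step."""
    return ng86(codon_align(cds_a, cds_b), id_a, id_b)


def ks_distribution(ks_values, mode: str = "self",
                    grid_points: int = 512) -> DensityResult:
    """Ks density and modes; Ks > 3 and non-finite values are excluded.

    ``mode`` records whether the cohort is a within-genome paralog
    (self) or between-set ortholog (cross) comparison; the estimator is
    identical for both.
    """
    if mode not in ("self", "cross"):
        raise ValueError("mode must be 'self' or 'cross'")
    finite = [k for k in ks_values
              if isinstance(k, (int, float)) and math.isfinite(k) and k <= KS_MAX]
    if len(finite) < 5:
        raise ValueError("fewer than 5 finite Ks values")
    return density_modes(finite, grid_points=grid_points, lower_bound=0.0)
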