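"""Shared pairwise-alignment helpers.

Thin wrappers around :class:`Bio.Align.PairwiseAligner` that return the
quantities the rest of the package consumes: percent identity, aligned
query coverage, and per-column match/mismatch tallies.  Scoring defaults
(match +1, mismatch -1, gap open -4, gap extend -1) follow common DNA
alignment practice for low-divergence repeat copies.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

DNA_MATCH = 1.0
DNA_MISMATCH = -1.0
DNA_GAP_OPEN = -4.0
DNA_GAP_EXTEND = -1.0


def dna_aligner(mode: str = "global", *, free_end_gaps: bool = False) -> Align.PairwiseAligner:
    """Return a DNA aligner with the package's standard scoring."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global" if mode == "semiglobal" else mode
    aligner.match_score = DNA_MATCH
    aligner.mismatch_score = DNA_MISMATCH
    aligner.open_gap_score = DNA_GAP_OPEN
    aligner.extend_gap_score = DNA_GAP_EXTEND
    if mode == "semiglobal" or free_end_gaps:
        if hasattr(aligner, "end_insertion_score"):
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        else:  # older Biopython attribute names
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    return aligner


def protein_aligner(mode: str = "local") -> Align.PairwiseAligner:
    """BLOSUM62 protein aligner (gap open -11, extend -1, BLAST-like)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


@dataclass(frozen=True)
class AlignmentStats:
    """Column tallies of one pairwise alignment.

    ``columns`` counts every alignment column inside the aligned span;
    ``matches``/``mismatches`` count gap-free columns only.
    """

    score: float
    matches: int
    mismatches: int
    gap_columns: int
    target_start: int
    target_end: int
    query_start: int
    query_end: int

    @property
    def columns(self) -> int:
        return self.matches + self.mismatches + self.gap_columns

    @property
    def identity(self) -> float:
        """Identity over all aligned columns; gap columns count as mismatches."""
        if self.columns == 0:
            return 0.0
        return self.matches / self.columns

    @property
    def gap_free_identity(self) -> float:
        """Identity over gap-free columns only."""
        n = self.matches + self.mismatches
        return self.matches / n if n else 0.0


def alignment_stats(alignment: Align.Alignment) -> AlignmentStats:
    """Tally matches, mismatches and gaps for one alignment."""
    t_aln = alignment[0]
    q_aln = alignment[1]
    matches = mismatches = gaps = 0
    for a, b in zip(t_aln, q_aln):
        if a == "-" or b == "-":
            gaps += 1
        elif a == b:
            matches += 1
        else:
            mismatches += 1
    blocks_t, blocks_q = alignment.aligned
    if len(blocks_t):
        t0, t1 = int(blocks_t[0][0]), int(blocks_t[-1][1])
        q0, q1 = int(blocks_q[0][0]), int(blocks_q[-1][1])
    else:  # degenerate: no aligned block
        t0 = t1 = q0 = q1 = 0
    return AlignmentStats(
        score=float(alignment.score),
        matches=matches,
        mismatches=mismatches,
        gap_columns=gaps,
        target_start=t0,
        target_end=t1,
        query_start=q0,
        query_end=q1,
    )


def align_pair(seq_a: str, seq_b: str, mode: str = "global") -> Align.Alignment:
    """Best pairwise DNA alignment of two sequences."""
    aligner = dna_aligner(mode)
    return aligner.align(seq_a, seq_b)[0]


def pairwise_stats(seq_a: str, seq_b: str, mode: str = "global") -> AlignmentStats:
    return alignment_stats(align_pair(seq_a, seq_b, mode))


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")
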