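"""Element classification: autonomy class, sequence group, family, regions.

Mined elements are sorted into four classes, following the logic used for
young Copia families whose nonautonomous copies carry a conserved
noncoding internal sequence ("nis") in place of the ORF:

* ``orf_full``    — the longest ORF carries all four canonical domains
                    (GAG, GAG-pre-integrase, integrase core, RT);
* ``orf_partial`` — the longest ORF carries some but not all domains;
* ``nis``         — no domain evidence, but the internal region matches
                    the family nis reference;
* ``other``       — none of the above (degenerate copies).

ORF-bearing elements are assigned to sequence group 1 or 2 by which group
reference their internal region aligns to more identically (the two
references differ by a single-nucleotide insertion that truncates the
group-2 N-terminus).  Family assignment follows the domain-majority rule:
the clade label carried by more than half of the domain hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from Bio.Seq import Seq

from .alignment import alignment_stats, dna_aligner, protein_aligner, reverse_complement
from .family import DOMAIN_NAMES, FamilyReference
from .mining import LtrElement


@dataclass
class ClassifyThresholds:
    #: local-alignment score against a domain motif, normalized by the
    #: motif's self-score, required to call the domain present
    min_domain_score: float = 0.60
    nis_min_identity: float = 0.80
    nis_min_coverage: float = 0.50
    min_orf_codons: int = 30

    def __post_init__(self) -> None:
        for name in ("min_domain_score", "nis_min_identity", "nis_min_coverage"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class DomainHit:
    domain_name: str
    orf_start: int  # amino-acid coordinates within the ORF
    orf_end: int
    score: float  # normalized to [0, 1]
    clade_label: str
    threshold: float

    def __post_init__(self) -> None:
        if self.domain_name not in DOMAIN_NAMES:
            raise ValueError(f"unknown domain {self.domain_name}")
        if self.orf_start < 0 or self.orf_end < self.orf_start:
            raise ValueError("bad domain coordinates")


class OrfResult(NamedTuple):
    frame: int
    strand: str
    nt_seq: str  # ATG..stop inclusive
    aa_seq: str  # stop excluded


# ---------------------------------------------------------------------------
# ORF finding
# ---------------------------------------------------------------------------

def longest_orf(internal: str, min_codons: int = 30) -> OrfResult | None:
    """Longest ATG-to-stop reading frame over both strands and all frames.

    Ties are broken toward the 5'-most start on the plus strand (plus
    strand preferred over minus, then smaller start offset).  Returns None
    when no complete ORF reaches ``min_codons`` codons (stop included).
    """
    if len(internal) < 3:
        raise ValueError("internal sequence shorter than one codon")
    internal = internal.upper()
    best: tuple[int, int, int, int, str] | None = None  # (-len, strand_rank, start, frame, nt)
    for strand_rank, (strand, seq) in enumerate(
        [("+", internal), ("-", reverse_complement(internal))]
    ):
        for frame in range(3):
            trimmed = seq[frame : frame + 3 * ((len(seq) - frame) // 3)]
            aa = str(Seq(trimmed).translate())
            start_codon: int | None = None
            for i, ch in enumerate(aa):
                if ch == "M" and start_codon is None:
                    start_codon = i
                elif ch == "*" and start_codon is not None:
                    n_codons = i - start_codon + 1  # stop included
                    if n_codons >= min_codons:
                        nt = trimmed[3 * start_codon : 3 * (i + 1)]
                        key = (-n_codons, strand_rank, frame + 3 * start_codon, frame, nt)
                        if best is None or key < best:
                            best = key
                    start_codon = None
    if best is None:
        return None
    n_codons, strand_rank, _start, frame, nt = best
    strand = "+" if strand_rank == 0 else "-"
    return OrfResult(frame=frame, strand=strand, nt_seq=nt,
                     aa_seq=str(Seq(nt).translate()).rstrip("*"))


# ---------------------------------------------------------------------------
# domain scanning
# ---------------------------------------------------------------------------

def scan_domains(aa_seq: str, family: FamilyReference,
                 th: ClassifyThresholds | None = None) -> list[DomainHit]:
    """Locally align each consensus motif against the ORF protein.

    At most one hit (the best) is reported per domain; a hit requires a
    normalized score of at least ``min_domain_score``.
    """
    th = th or ClassifyThresholds()
    if not aa_seq:
        raise ValueError("empty amino-acid sequence")
    aligner = protein_aligner("local")
    hits: list[DomainHit] = []
    for name in DOMAIN_NAMES:
        motif = family.domain_motifs[name]
        self_score = aligner.align(motif, motif)[0].score
        alns = aligner.align(aa_seq, motif)
        if len(alns) == 0:
            continue
        aln = alns[0]
        norm = float(aln.score) / float(self_score)
        if norm >= th.min_domain_score:
            stats = alignment_stats(aln)
            hits.append(DomainHit(
                domain_name=name,
                orf_start=stats.target_start,
                orf_end=stats.target_end,
                score=min(1.0, norm),
                clade_label=family.domain_clades.get(name, "unknown"),
                threshold=th.min_domain_score,
            ))
    hits.sort(key=lambda h: h.orf_start)
    return hits


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _local_identity_and_coverage(query: str, target: str) -> tuple[float, float]:
    """Local alignment of ``query`` within ``target``: identity over aligned
    columns and fraction of the query covered."""
    aligner = dna_aligner("local")
    alns = aligner.align(target, query)
    if len(alns) == 0:
        return 0.0, 0.0
    stats = alignment_stats(alns[0])
    coverage = (stats.query_end - stats.query_start) / len(query)
    return stats.identity, coverage


def _group_distance(internal: str, ref: str) -> int:
    """Edit distance of a group reference aligned inside the internal region
    (infix / semi-global mode)."""
    import edlib

    return edlib.align(ref, internal, mode="HW", task="distance")["editDistance"]


def _analyze(element: LtrElement, family: FamilyReference,
             th: ClassifyThresholds) -> tuple[OrfResult | None, list[DomainHit], str]:
    """Oriented internal sequence, longest ORF and its domain hits."""
    internal = element.internal_seq
    if not internal:
        raise ValueError("element has no extracted internal sequence")
    if element.strand == "-":
        internal = reverse_complement(internal)
    orf = longest_orf(internal, th.min_orf_codons) if len(internal) >= 3 else None
    hits = scan_domains(orf.aa_seq, family, th) if orf else []
    return orf, hits, internal


def classify_element(element: LtrElement, family: FamilyReference,
                     th: ClassifyThresholds | None = None) -> tuple[str, int | None]:
    """Assign (class_label, group) to one element; total and deterministic."""
    th = th or ClassifyThresholds()
    _orf, hits, internal = _analyze(element, family, th)
    if hits:
        label = "orf_full" if len(hits) == len(DOMAIN_NAMES) else "orf_partial"
        d1 = _group_distance(internal, family.orf_group1_ref)
        d2 = _group_distance(internal, family.orf_group2_ref)
        group = 1 if d1 <= d2 else 2
        element.class_label, element.group = label, group
        return label, group
    identity, coverage = _local_identity_and_coverage(family.nis_seq, internal)
    if identity >= th.nis_min_identity and coverage >= th.nis_min_coverage:
        element.class_label, element.group = "nis", None
        return "nis", None
    element.class_label, element.group = "other", None
    return "other", None


def assign_family(domain_hits: list[DomainHit]) -> str:
    """Majority clade label among domain hits (frequency strictly > 0.5)."""
    if not domain_hits:
        return "unknown"
    counts: dict[str, int] = {}
    for hit in domain_hits:
        counts[hit.clade_label] = counts.get(hit.clade_label, 0) + 1
    label, n = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    if n / len(domain_hits) > 0.5:
        return label
    return "unknown"


# ---------------------------------------------------------------------------
# inter-copy region identity
# ---------------------------------------------------------------------------

class RegionNotLocatedError(ValueError):
    """The canonical region could not be located in one of the elements."""


def _locate_region(element_seq: str, region_ref: str) -> str:
    aligner = dna_aligner("local")
    alns = aligner.align(element_seq, region_ref)
    if len(alns) == 0:
        raise RegionNotLocatedError("no alignment for region")
    stats = alignment_stats(alns[0])
    coverage = (stats.query_end - stats.query_start) / len(region_ref)
    # spurious short local matches have high identity, so demand that at
    # least half the canonical region aligned as well
    if stats.identity < 0.30 or coverage < 0.50:
        raise RegionNotLocatedError("region not located (identity < 30%)")
    return element_seq[stats.target_start : stats.target_end]


def region_identity(elem_a: LtrElement, elem_b: LtrElement, region_name: str,
                    family: FamilyReference) -> float:
    """Percent identity of one conserved region between two copies.

    The region is located in each element by local alignment against the
    canonical region sequence; the two located segments are then globally
    aligned, with gap columns counted as mismatches.
    """
    if region_name not in ("PBS_ATG", "3_ATrich", "3_cons"):
        raise ValueError(f"unsupported region {region_name}")
    ref = family.region_seq(region_name)
    seg_a = _locate_region(elem_a.oriented_seq, ref)
    seg_b = _locate_region(elem_b.oriented_seq, ref)
    aligner = dna_aligner("global")
    stats = alignment_stats(aligner.align(seg_a, seg_b)[0])
    return 100.0 * stats.matches / stats.columns


def classify_catalog(elements: list[LtrElement], family: FamilyReference,
                     th: ClassifyThresholds | None = None) -> list[LtrElement]:
    """Classify every element in place and assign domain-majority families."""
    th = th or ClassifyThresholds()
    for element in elements:
        classify_element(element, family, th)
        _orf, hits, _internal = _analyze(element, family, th)
        element.family = assign_family(hits)
    return elements
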