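"""Evidence-threshold gene triage: HC / LC / TE assignment.

Genes are classified from pre-computed evidence tables (similarity hits,
protein-domain hits, expression) by four criteria:

1. UniProt/NR similarity: E-value <= 1e-80 and identity >= 80%;
2. congeneric proteome similarity: E-value <= 1e-80, identity >= 90%,
   and 60% <= length coverage <= 140%;
3. protein-domain hit: E-value <= 1e-50;
4. expression: TPM > 0.

TE calls take precedence: a TE-library similarity or a TE-related product
name classifies the gene as TE regardless of the other criteria.  The
remaining genes satisfying the criterion conjunction are HC, all others
LC.  LC genes can subsequently be rescued to HC by an Araport-style
reference-proteome hit (E-value <= 1e-10, identity >= 25%, length coverage
within 60-140%).  A transcript-model filter implements the companion
long-read model selection rules (mapped length 95-105%, length >= 99 nt,
sense splice orientation, one model per locus with long-read support
preferred over length).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

SIMILARITY_DATABASES = ("uniprot", "nr", "cse_r1.1", "cnank_v2", "araport")

DEFAULT_TE_KEYWORDS = (
    "transposon",
    "retrotransposon",
    "transposase",
    "retrovirus-related",
    "gag protein",
    "gag-pol",
    "polyprotein",
    "reverse transcriptase",
    "integrase",
    "copia",
    "gypsy",
    "ty1",
    "ty3",
)


@dataclass(frozen=True)
class SimilarityHit:
    database: str  # one of SIMILARITY_DATABASES
    evalue: float
    identity: float  # percent, 0-100
    length_coverage: float  # percent of subject length covered

    def __post_init__(self) -> None:
        if self.database not in SIMILARITY_DATABASES:
            raise ValueError(f"unknown database tag {self.database}")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not 0 <= self.identity <= 100:
            raise ValueError("identity must be a percentage")
        if self.length_coverage < 0:
            raise ValueError("length coverage must be >= 0")


@dataclass(frozen=True)
class DomainEvidence:
    accession: str
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass
class EvidenceRecord:
    gene_id: str
    similarity_hits: list[SimilarityHit] = field(default_factory=list)
    domain_hits: list[DomainEvidence] = field(default_factory=list)
    tpm: float = 0.0
    product_names: list[str] = field(default_factory=list)
    #: similarity to a transposable-element library
    te_similarity: bool = False

    def __post_init__(self) -> None:
        if self.tpm < 0:
            raise ValueError("tpm must be >= 0")


ConjunctionMode = Literal["all", "any_similarity_plus_expression"]


@dataclass(frozen=True)
class TriagePolicy:
    crit1_evalue: float = 1e-80
    crit1_identity: float = 80.0
    crit2_evalue: float = 1e-80
    crit2_identity: float = 90.0
    crit2_coverage_min: float = 60.0
    crit2_coverage_max: float = 140.0
    crit3_evalue: float = 1e-50
    crit4_tpm: float = 0.0  # expressed means TPM strictly greater
    rescue_evalue: float = 1e-10
    rescue_identity: float = 25.0
    rescue_coverage_min: float = 60.0
    rescue_coverage_max: float = 140.0
    te_keywords: tuple[str, ...] = DEFAULT_TE_KEYWORDS
    conjunction: ConjunctionMode = "all"


def criterion1(ev: EvidenceRecord, policy: TriagePolicy = TriagePolicy()) -> bool:
    """General-proteome similarity (UniProt / NR)."""
    return any(
        h.database in ("uniprot", "nr")
        and h.evalue <= policy.crit1_evalue
        and h.identity >= policy.crit1_identity
        for h in ev.similarity_hits
    )


def criterion2(ev: EvidenceRecord, policy: TriagePolicy = TriagePolicy()) -> bool:
    """Congeneric-proteome similarity with a length-coverage window."""
    return any(
        h.database in ("cse_r1.1", "cnank_v2")
        and h.evalue <= policy.crit2_evalue
        and h.identity >= policy.crit2_identity
        and policy.crit2_coverage_min <= h.length_coverage <= policy.crit2_coverage_max
        for h in ev.similarity_hits
    )


def criterion3(ev: EvidenceRecord, policy: TriagePolicy = TriagePolicy()) -> bool:
    """Protein-family domain evidence."""
    return any(h.evalue <= policy.crit3_evalue for h in ev.domain_hits)


def criterion4(ev: EvidenceRecord, policy: TriagePolicy = TriagePolicy()) -> bool:
    """Expression evidence (TPM strictly positive)."""
    return ev.tpm > policy.crit4_tpm


def is_te(ev: EvidenceRecord, policy: TriagePolicy = TriagePolicy()) -> bool:
    if ev.te_similarity:
        return True
    for name in ev.product_names:
        lowered = name.lower()
        if any(kw in lowered for kw in policy.te_keywords):
            return True
    return False


def classify_gene(ev: EvidenceRecord,
                  policy: TriagePolicy = TriagePolicy()) -> str:
    """Total, deterministic HC/LC/TE call with TE precedence."""
    if is_te(ev, policy):
        return "TE"
    c = (criterion1(ev, policy), criterion2(ev, policy),
         criterion3(ev, policy), criterion4(ev, policy))
    if policy.conjunction == "all":
        hc = all(c)
    else:  # any evidence criterion (1)-(3) plus expression (4)
        hc = (c[0] or c[1] or c[2]) and c[3]
    return "HC" if hc else "LC"


def rescue_lc(ev: EvidenceRecord,
              policy: TriagePolicy = TriagePolicy()) -> str:
    """Araport-style rescue of an LC gene to HC; idempotent."""
    rescued = any(
        h.database == "araport"
        and h.evalue <= policy.rescue_evalue
        and h.identity >= policy.rescue_identity
        and policy.rescue_coverage_min <= h.length_coverage <= policy.rescue_coverage_max
        for h in ev.similarity_hits
    )
    return "HC" if rescued else "LC"


def triage_genes(records: Sequence[EvidenceRecord],
                 policy: TriagePolicy = TriagePolicy(),
                 apply_rescue: bool = True) -> dict[str, str]:
    """Classify a gene set, applying the LC->HC rescue pass."""
    out: dict[str, str] = {}
    for ev in records:
        cls = classify_gene(ev, policy)
        if cls == "LC" and apply_rescue:
            cls = rescue_lc(ev, policy)
        out[ev.gene_id] = cls
    return out


# ---------------------------------------------------------------------------
# transcript-model filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptModel:
    model_id: str
    locus: str
    mapped_length_pct: float
    length_nt: int
    splice_sense: bool
    source: str  # "isoseq" | "abinitio"

    def __post_init__(self) -> None:
        if self.source not in ("isoseq", "abinitio"):
            raise ValueError("source must be 'isoseq' or 'abinitio'")


def filter_transcript_models(
    records: Sequence[TranscriptModel],
    mapped_min: float = 95.0,
    mapped_max: float = 105.0,
    min_length_nt: int = 99,
) -> list[TranscriptModel]:
    """Keep sense-oriented models mapped at 95-105% of their length and at
    least 99 nt long, then resolve each locus to a single model: long-read
    (isoseq) support outranks length, length breaks ties within a source."""
    passing = [
        r for r in records
        if r.splice_sense
        and mapped_min <= r.mapped_length_pct <= mapped_max
        and r.length_nt >= min_length_nt
    ]
    by_locus: dict[str, list[TranscriptModel]] = {}
    for r in passing:
        by_locus.setdefault(r.locus, []).append(r)
    kept = []
    for locus in sorted(by_locus):
        winner = min(
            by_locus[locus],
            key=lambda r: (r.source != "isoseq", -r.length_nt, r.model_id),
        )
        kept.append(winner)
    return kept
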