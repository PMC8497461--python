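"""Synthetic gene-bearing genomes with planted LTR retrotransposon copies.

The generator emulates the statistical structure the downstream analysis
assumes: a random background genome carrying simple gene models, into
which family elements of known class (autonomous ORF-bearing, nonautonomous
nis-bearing, or degenerate) are inserted with target-site duplications.
Each planted copy is aged by a two-rate (transition-biased) substitution
process applied independently to the two LTRs and to the internal region,
so that a copy inserted T years ago shows an expected per-site LTR-LTR
divergence of 2*mu*T — the quantity the K2P dating stage inverts.

Every planted element is recorded in a machine-readable truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .family import FamilyReference, plus_strand_longest_orf_span, random_dna

ELEMENT_CLASSES = ("orf_full", "orf_partial", "nis", "degenerate")

_PURINES = {"A", "G"}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}
_STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class GenomeAssembly:
    """Ordered named chromosome sequences (uppercase DNA over ACGTN)."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.records]
        if len(set(ids)) != len(ids) or any(not cid for cid in ids):
            raise ValueError("chromosome ids must be unique and non-empty")
        for cid, seq in self.records:
            if not seq:
                raise ValueError(f"empty sequence for {cid}")
            if set(seq) - set("ACGTN"):
                raise ValueError(f"sequence for {cid} contains non-ACGTN symbols")

    def __len__(self) -> int:
        return sum(len(seq) for _, seq in self.records)

    def get(self, chrom: str) -> str:
        for cid, seq in self.records:
            if cid == chrom:
                return seq
        raise KeyError(chrom)

    @property
    def chrom_ids(self) -> list[str]:
        return [cid for cid, _ in self.records]


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted element (coordinates exclude the TSDs)."""

    element_id: str
    chrom: str
    start: int
    end: int
    strand: str
    true_class: str
    true_group: int | None
    true_age_years: float
    tsd_seq: str
    genic_context: str  # inside_gene | flank | intergenic

    def __post_init__(self) -> None:
        if self.true_class not in ELEMENT_CLASSES:
            raise ValueError(f"unknown class {self.true_class}")
        if self.start < 0 or self.end <= self.start:
            raise ValueError("bad coordinates")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str


AgeSpec = float | tuple[float, float]


@dataclass
class SimConfig:
    """Simulation parameters.

    Element counts default to a 1:10 scale-down of a young nonautonomous-
    dominated family census (67 fully coding, 94 partially coding, 190
    nis-bearing, 9 degenerate out of 360 copies).  Ages default to a very
    recent burst (uniform on 0-0.1 My); ``mu`` is the plant nucleotide
    substitution rate 1.3e-8 per site per year.
    """

    n_chroms: int = 2
    chrom_length: int = 300_000
    gc_content: float = 0.37
    n_orf_full: int = 7
    n_orf_partial: int = 9
    n_nis: int = 19
    n_degenerate: int = 1
    #: per-class insertion age in years: scalar, (low, high) uniform range,
    #: or a mapping class -> scalar/range
    age_years: AgeSpec | Mapping[str, AgeSpec] = (0.0, 100_000.0)
    mu: float = 1.3e-8
    kappa: float = 2.0
    tsd_length: int = 5
    #: genes per megabase of background sequence
    gene_density: float = 100.0
    gene_length: int = 3000
    gene_flank_bp: int = 5000
    #: relative weight of genic (gene body or flank) positions when placing
    #: insertions; 1.0 = unbiased, larger values bias toward gene-dense space
    gene_bias_weight: float = 5.0
    seed: int = 0
    max_place_retries: int = 200

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.kappa <= 0:
            raise ValueError("mu and kappa must be positive")
        if not 4 <= self.tsd_length <= 6:
            raise ValueError("tsd_length must be in [4, 6]")
        for name in ("n_chroms", "chrom_length", "n_orf_full", "n_orf_partial",
                     "n_nis", "n_degenerate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if self.gene_bias_weight <= 0:
            raise ValueError("gene_bias_weight must be positive")

    def class_counts(self) -> dict[str, int]:
        return {
            "orf_full": self.n_orf_full,
            "orf_partial": self.n_orf_partial,
            "nis": self.n_nis,
            "degenerate": self.n_degenerate,
        }

    def age_spec_for(self, cls: str) -> AgeSpec:
        if isinstance(self.age_years, Mapping):
            return self.age_years[cls]
        return self.age_years


def _sample_age(spec: AgeSpec, rng: np.random.Generator) -> float:
    if isinstance(spec, (tuple, list)):
        lo, hi = spec
        return float(rng.uniform(lo, hi))
    return float(spec)


# ---------------------------------------------------------------------------
# substitution process
# ---------------------------------------------------------------------------

def substitute_sites(
    seq: str,
    n_subs: int,
    kappa: float,
    rng: np.random.Generator,
    forbid_stops_in: tuple[int, int] | None = None,
) -> str:
    """Apply ``n_subs`` substitutions at distinct sites.

    Given an event, a transition is chosen with probability kappa/(kappa+2)
    and each of the two transversions with probability 1/(kappa+2).  When
    ``forbid_stops_in`` delimits a reading frame (start, end in sequence
    coordinates, start at a codon boundary), substitutions that would create
    an in-frame stop codon there are re-drawn — a simple stand-in for the
    purifying selection that keeps autonomous copies coding.
    """
    if n_subs == 0:
        return seq
    chars = list(seq)
    sites = rng.choice(len(chars), size=min(n_subs, len(chars)), replace=False)
    p_ts = kappa / (kappa + 2.0)
    for site in sites:
        for _attempt in range(20):
            base = chars[site]
            if base not in _TRANSITION:  # N etc: leave untouched
                break
            if rng.random() < p_ts:
                new = _TRANSITION[base]
            else:
                new = _TRANSVERSIONS[base][rng.integers(2)]
            if forbid_stops_in is not None:
                lo, hi = forbid_stops_in
                if lo <= site < hi:
                    codon_start = lo + 3 * ((site - lo) // 3)
                    codon = chars[codon_start : codon_start + 3]
                    codon[site - codon_start] = new
                    if "".join(codon) in _STOP_CODONS:
                        site = int(rng.choice(np.arange(lo, hi)))
                        continue
            chars[site] = new
            break
    return "".join(chars)


def _n_substitutions(length: int, age_years: float, mu: float,
                     rng: np.random.Generator) -> int:
    """Binomial(L, 1 - exp(-mu*T)) draw of the substitution count."""
    p = 1.0 - math.exp(-mu * age_years)
    return int(rng.binomial(length, p))


def mutate_element(
    element_seq: str,
    age_years: float,
    config: SimConfig,
    rng: np.random.Generator,
    ltr_length: int,
    protect_orf: tuple[int, int] | None = None,
) -> str:
    """Age a canonical element: both LTR copies and the internal region are
    mutated independently at rate mu per site per year.

    ``protect_orf`` gives the ORF span within the *internal* region whose
    reading frame must stay stop-free (used for fully coding copies).
    """
    if age_years < 0:
        raise ValueError("age_years must be >= 0")
    if age_years == 0:
        return element_seq
    ltr5 = element_seq[:ltr_length]
    internal = element_seq[ltr_length : len(element_seq) - ltr_length]
    ltr3 = element_seq[len(element_seq) - ltr_length :]
    out = []
    for part, protected in ((ltr5, None), (internal, protect_orf), (ltr3, None)):
        n = _n_substitutions(len(part), age_years, config.mu, rng)
        out.append(substitute_sites(part, n, config.kappa, rng, forbid_stops_in=protected))
    return "".join(out)


# ---------------------------------------------------------------------------
# insertion mechanics
# ---------------------------------------------------------------------------

def plant_insertion(
    chrom_seq: str,
    element_seq: str,
    pos: int,
    tsd_length: int,
) -> tuple[str, TruthRecord]:
    """Insert an element at ``pos``, duplicating the ``tsd_length`` host
    bases starting at ``pos`` to flank the insertion.

    Returns the new sequence and a skeleton truth record whose coordinates
    (excluding the TSD copies) and tsd_seq are filled in; class, group, age
    and context are left for the caller to set via ``dataclasses.replace``.
    """
    if not 0 <= pos <= len(chrom_seq) - tsd_length:
        raise ValueError(f"insertion position {pos} out of range")
    tsd = chrom_seq[pos : pos + tsd_length]
    new_seq = chrom_seq[: pos + tsd_length] + element_seq + chrom_seq[pos:]
    start = pos + tsd_length
    record = TruthRecord(
        element_id="",
        chrom="",
        start=start,
        end=start + len(element_seq),
        strand="+",
        true_class="nis",
        true_group=None,
        true_age_years=0.0,
        tsd_seq=tsd,
        genic_context="intergenic",
    )
    return new_seq, record


# ---------------------------------------------------------------------------
# gene placement and biased insertion positions
# ---------------------------------------------------------------------------

def _place_genes(chrom_length: int, cfg: SimConfig,
                 rng: np.random.Generator) -> list[tuple[int, int, str]]:
    n_genes = int(round(cfg.gene_density * chrom_length / 1e6))
    genes: list[tuple[int, int, str]] = []
    occupied: list[tuple[int, int]] = []
    for _ in range(n_genes):
        for _try in range(cfg.max_place_retries):
            start = int(rng.integers(0, max(1, chrom_length - cfg.gene_length)))
            end = start + cfg.gene_length
            if all(end <= s or start >= e for s, e in occupied):
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append((start, end, strand))
                occupied.append((start, end))
                break
    genes.sort()
    return genes


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _sample_position(
    chrom_length: int,
    genic: list[tuple[int, int]],
    weight: float,
    tsd_length: int,
    rng: np.random.Generator,
) -> int:
    """Sample an insertion point; genic positions carry relative weight w."""
    limit = chrom_length - tsd_length
    clipped = [(min(s, limit), min(e, limit)) for s, e in genic if s < limit]
    g_len = sum(e - s for s, e in clipped)
    ng_len = limit - g_len
    p_genic = (weight * g_len) / (weight * g_len + ng_len) if g_len else 0.0
    if rng.random() < p_genic:
        offset = int(rng.integers(0, g_len))
        for s, e in clipped:
            if offset < e - s:
                return s + offset
            offset -= e - s
        return clipped[-1][1] - 1
    # uniform over non-genic positions
    for _try in range(1000):
        pos = int(rng.integers(0, max(1, ng_len)))
        covered = 0
        for s, e in clipped:
            if pos + covered >= s:
                covered += e - s
            else:
                break
        return pos + covered
    raise RuntimeError("position sampling failed")


def _genic_context(pos: int, genes: list[tuple[int, int, str]], flank: int) -> str:
    for s, e, _ in genes:
        if s <= pos < e:
            return "inside_gene"
    for s, e, _ in genes:
        if s - flank <= pos < e + flank:
            return "flank"
    return "intergenic"


# ---------------------------------------------------------------------------
# element construction per class
# ---------------------------------------------------------------------------

def _build_element(
    cls: str,
    group: int | None,
    family: FamilyReference,
    rng: np.random.Generator,
) -> tuple[str, tuple[int, int] | None]:
    """Canonical (age-0) element sequence for one class, plus the ORF span
    to keep stop-free during ageing (orf_full only)."""
    ltr_len = len(family.ltr_seq)
    if cls in ("orf_full", "orf_partial"):
        internal_class = f"orf_group{group}"
        internal = family.internal_seq(internal_class)
        # protect the realized reading frame (its start can sit upstream of
        # the annotated ORF, and the group-2 frame is shifted by the T
        # insertion), not the annotated span
        orf_span = plus_strand_longest_orf_span(internal)
        if cls == "orf_partial":
            # knock out the middle of the longest reading frame with a
            # premature stop so the longest surviving fragment carries only
            # a subset of domains (the group-2 frame is shifted relative to
            # the annotated span, so locate the real ORF first)
            lo, hi = plus_strand_longest_orf_span(internal)
            mid = lo + 3 * (((hi - lo) // 3) // 2)
            internal = internal[:mid] + "TAA" + internal[mid + 3 :]
            return family.ltr_seq + internal + family.ltr_seq, None
        return family.ltr_seq + internal + family.ltr_seq, orf_span
    if cls == "nis":
        return family.element_seq("nis"), None
    # degenerate: conserved flanks but a randomized core
    core = random_dna(rng, len(family.nis_seq))
    internal = family.pbs_atg_seq + core + family.at_rich_seq + family.cons3_seq
    return family.ltr_seq + internal + family.ltr_seq, None


# ---------------------------------------------------------------------------
# top-level generator
# ---------------------------------------------------------------------------

def generate_genome(
    config: SimConfig,
    family: FamilyReference,
) -> tuple[GenomeAssembly, list[TruthRecord], list[GeneModel]]:
    """Generate a genome, its planted-element truth table, and gene models.

    Deterministic for a fixed config (the seed lives in the config).  The
    output genome length equals the background length plus the sum of
    planted element lengths plus one TSD copy per element.
    """
    rng = np.random.default_rng(config.seed)
    ltr_len = len(family.ltr_seq)

    # plan all insertions first (class, group, age, element sequence)
    plan: list[dict] = []
    for cls, count in config.class_counts().items():
        for _ in range(count):
            group = int(rng.integers(1, 3)) if cls in ("orf_full", "orf_partial") else None
            age = _sample_age(config.age_spec_for(cls), rng)
            base_seq, orf_span = _build_element(cls, group, family, rng)
            if len(base_seq) + config.tsd_length >= config.chrom_length:
                raise ValueError("element longer than chromosome")
            seq = mutate_element(base_seq, age, config, rng, ltr_len,
                                 protect_orf=orf_span)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                from .alignment import reverse_complement
                seq = reverse_complement(seq)
            plan.append({"cls": cls, "group": group, "age": age,
                         "seq": seq, "strand": strand})

    chroms: list[tuple[str, str]] = []
    truth: list[TruthRecord] = []
    genes_out: list[GeneModel] = []
    # distribute elements over chromosomes
    chrom_of = rng.integers(0, config.n_chroms, size=len(plan)) if config.n_chroms else []

    element_counter = 0
    for ci in range(config.n_chroms):
        chrom_id = f"chr{ci + 1}"
        background = random_dna(rng, config.chrom_length, config.gc_content)
        genes = _place_genes(config.chrom_length, config, rng)
        genic = _merge_intervals(
            [(max(0, s - config.gene_flank_bp), min(config.chrom_length, e + config.gene_flank_bp))
             for s, e, _ in genes]
        )
        my_elements = [plan[i] for i in range(len(plan)) if chrom_of[i] == ci]

        # choose distinct, well-separated insertion points in background coords
        positions: list[int] = []
        for item in my_elements:
            placed = False
            for _try in range(config.max_place_retries):
                pos = _sample_position(config.chrom_length, genic,
                                       config.gene_bias_weight,
                                       config.tsd_length, rng)
                if all(abs(pos - q) > config.tsd_length for q in positions):
                    positions.append(pos)
                    placed = True
                    break
            if not placed:
                raise RuntimeError("could not place element without overlap")
            item["pos"] = pos
            item["context"] = _genic_context(pos, genes, config.gene_flank_bp)

        # apply insertions left to right, tracking the coordinate offset
        order = sorted(range(len(my_elements)), key=lambda i: my_elements[i]["pos"])
        seq = background
        offset = 0
        for idx in order:
            item = my_elements[idx]
            pos = item["pos"] + offset
            seq, rec = plant_insertion(seq, item["seq"], pos, config.tsd_length)
            element_counter += 1
            truth.append(replace(
                rec,
                element_id=f"E{element_counter:04d}",
                chrom=chrom_id,
                strand=item["strand"],
                true_class=item["cls"],
                true_group=item["group"],
                true_age_years=item["age"],
                genic_context=item["context"],
            ))
            offset += len(item["seq"]) + config.tsd_length

        # shift gene coordinates past the insertions; a gene hosting an
        # insertion is extended to contain it
        ins = sorted((my_elements[i]["pos"], len(my_elements[i]["seq"]) + config.tsd_length)
                     for i in range(len(my_elements)))
        for gi, (gs, ge, gstrand) in enumerate(genes):
            shift_start = sum(L for p, L in ins if p < gs)
            shift_end = sum(L for p, L in ins if p < ge)
            genes_out.append(GeneModel(
                gene_id=f"{chrom_id}g{gi + 1:04d}",
                chrom=chrom_id,
                start=gs + shift_start,
                end=ge + shift_end,
                strand=gstrand,
            ))
        chroms.append((chrom_id, seq))

    truth.sort(key=lambda r: (r.chrom, r.start))
    truth = [replace(r, element_id=f"E{i + 1:04d}") for i, r in enumerate(truth)]
    return GenomeAssembly(chroms), truth, genes_out


# ---------------------------------------------------------------------------
# synonymous-divergence pair simulation (for Ks calibration studies)
# ---------------------------------------------------------------------------

_FOURFOLD_PREFIXES = ("GC", "GG", "CC", "AC", "GT", "TC")
_BASES4 = "ACGT"


def simulate_synonymous_pairs(
    n_pairs: int,
    n_codons: int,
    ks_true: float,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Coding-sequence pairs with a known true synonymous divergence.

    Each sequence is built only from fourfold-degenerate codon boxes whose
    first two positions are strictly nonsynonymous under single changes
    (Ala/Gly/Pro/Thr/Val/Ser), so every codon contributes exactly one
    synonymous site — its third position.  One copy's third positions are
    then resampled under a Jukes-Cantor process with ``ks_true``
    substitutions per site, making the pair's true Ks equal ``ks_true``.
    """
    if ks_true < 0:
        raise ValueError("ks_true must be >= 0")
    p_change = 0.25 - 0.25 * math.exp(-4.0 * ks_true / 3.0)
    pairs = []
    for _ in range(n_pairs):
        prefixes = rng.choice(_FOURFOLD_PREFIXES, size=n_codons)
        thirds_a = rng.choice(list(_BASES4), size=n_codons)
        thirds_b = []
        for b in thirds_a:
            u = rng.random()
            if u < 3 * p_change:
                others = [x for x in _BASES4 if x != b]
                thirds_b.append(others[int(u / p_change)])
            else:
                thirds_b.append(b)
        seq_a = "".join(p + t for p, t in zip(prefixes, thirds_a))
        seq_b = "".join(p + t for p, t in zip(prefixes, thirds_b))
        pairs.append((seq_a, seq_b))
    return pairs


def simulate_ltr_cohort(
    n_elements: int,
    ages_years: Sequence[float] | AgeSpec,
    config: SimConfig,
    family: FamilyReference,
    rng: np.random.Generator,
) -> list[tuple[str, str, float]]:
    """Aged (ltr5, ltr3, true_age) triples without genome placement.

    A light-weight cohort generator for dating-calibration studies: each
    element's two LTR copies start identical and are mutated independently
    under the configured substitution process.
    """
    if isinstance(ages_years, (int, float, tuple)):
        ages = [_sample_age(ages_years, rng) for _ in range(n_elements)]
    else:
        ages = [float(a) for a in ages_years]
        if len(ages) != n_elements:
            raise ValueError("ages_years length mismatch")
    out = []
    for age in ages:
        ltrs = []
        for _copy in range(2):
            n = _n_substitutions(len(family.ltr_seq), age, config.mu, rng)
            ltrs.append(substitute_sites(family.ltr_seq, n, config.kappa, rng))
        out.append((ltrs[0], ltrs[1], age))
    return out
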