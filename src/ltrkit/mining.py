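"""Query-LTR-driven mining of candidate family elements.

The stage mirrors a BLASTN-style homology search without external tools:
exact k-mer seeds anchor candidate windows, each window is then aligned
locally against the query LTR, and hits passing the identity/coverage
filter (defaults: identity >= 90%, query coverage >= 70%) are paired into
elements when two same-strand hits lie 2-10 kb apart — the signature of
the two direct repeats of an intact LTR retrotransposon.  Extracted
elements carry their target-site duplication (if detectable) and the
global-alignment identity of their two LTR copies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .alignment import (
    AlignmentStats,
    alignment_stats,
    dna_aligner,
    pairwise_stats,
    reverse_complement,
)
from .simulate import GenomeAssembly

logger = logging.getLogger(__name__)

SEED_K = 12
#: chromosomes at most this long fall back to direct windowed alignment
#: when seeding finds nothing
_SMALL_CHROM_FALLBACK = 20_000


@dataclass
class MiningConfig:
    min_ltr_identity: float = 0.90
    min_ltr_coverage: float = 0.70
    min_gap_bp: int = 2000
    max_gap_bp: int = 10_000
    scan_both_strands: bool = True
    #: when True the 2-10 kb bounds constrain the inter-LTR gap (default);
    #: when False they constrain the full element span
    gap_is_internal: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.min_ltr_identity <= 1.0 and 0.0 < self.min_ltr_coverage <= 1.0):
            raise ValueError("identity and coverage thresholds must be in (0, 1]")
        if not 0 < self.min_gap_bp < self.max_gap_bp:
            raise ValueError("require 0 < min_gap_bp < max_gap_bp")


@dataclass(frozen=True)
class Interval:
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError("bad interval")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class IntervalHit:
    chrom: str
    start: int
    end: int
    strand: str
    identity: float
    query_coverage: float
    score: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("hit start must precede end")
        if not (0 <= self.identity <= 1 and 0 <= self.query_coverage <= 1):
            raise ValueError("identity and coverage must be fractions")


@dataclass
class LtrElement:
    """A mined two-LTR element; classification/dating fields start unset."""

    element_id: str
    chrom: str
    strand: str
    ltr5: Interval
    ltr3: Interval
    internal: Interval
    ltr_pair_identity: float
    tsd_seq: str | None = None
    ltr5_seq: str = ""
    ltr3_seq: str = ""
    internal_seq: str = ""
    class_label: str | None = None
    group: int | None = None
    family: str | None = None
    age_years: float | None = None

    def __post_init__(self) -> None:
        if not (self.ltr5.end <= self.internal.start
                and self.internal.start <= self.internal.end
                and self.internal.end <= self.ltr3.start):
            raise ValueError("element intervals out of order")

    @property
    def start(self) -> int:
        return self.ltr5.start

    @property
    def end(self) -> int:
        return self.ltr3.end

    @property
    def full_seq(self) -> str:
        return self.ltr5_seq + self.internal_seq + self.ltr3_seq

    @property
    def oriented_seq(self) -> str:
        """Full sequence in the element's own 5'->3' orientation."""
        if self.strand == "-":
            return reverse_complement(self.full_seq)
        return self.full_seq


# ---------------------------------------------------------------------------
# seeding and hit scanning
# ---------------------------------------------------------------------------

def _seed_windows(chrom_seq: str, query: str, k: int = SEED_K,
                  margin: int = 100) -> list[tuple[int, int]]:
    """Candidate (start, end) windows anchored by exact k-mer seeds."""
    qindex: dict[str, list[int]] = {}
    for i in range(len(query) - k + 1):
        qindex.setdefault(query[i : i + k], []).append(i)
    qlen = len(query)
    anchors: list[int] = []
    for p in range(len(chrom_seq) - k + 1):
        kmer = chrom_seq[p : p + k]
        hits = qindex.get(kmer)
        if hits:
            for qpos in hits:
                anchors.append(p - qpos)  # putative genome start of the query
    if not anchors:
        return []
    anchors.sort()
    windows: list[list[int]] = []
    for a in anchors:
        start = max(0, a - margin)
        end = min(len(chrom_seq), a + qlen + margin)
        if windows and start <= windows[-1][1]:
            windows[-1][1] = max(windows[-1][1], end)
        else:
            windows.append([start, end])
    return [(s, e) for s, e in windows]


def _window_hits(chrom: str, chrom_seq: str, window: tuple[int, int],
                 query: str, strand: str, cfg: MiningConfig) -> list[IntervalHit]:
    """Locally align the (oriented) query inside one window; a merged seed
    window may contain several tandem copies, so alignment is repeated on
    the remaining flanks after masking each accepted hit."""
    w_start, w_end = window
    region = chrom_seq[w_start:w_end]
    aligner = dna_aligner("local")
    hits: list[IntervalHit] = []
    segments = [(0, len(region))]
    qlen = len(query)
    while segments:
        s0, s1 = segments.pop()
        if s1 - s0 < qlen * cfg.min_ltr_coverage:
            continue
        sub = region[s0:s1]
        alns = aligner.align(sub, query)
        if len(alns) == 0 or alns[0].score <= 0:
            continue
        stats = alignment_stats(alns[0])
        coverage = (stats.query_end - stats.query_start) / qlen
        if stats.identity >= cfg.min_ltr_identity and coverage >= cfg.min_ltr_coverage:
            hits.append(IntervalHit(
                chrom=chrom,
                start=w_start + s0 + stats.target_start,
                end=w_start + s0 + stats.target_end,
                strand=strand,
                identity=stats.identity,
                query_coverage=coverage,
                score=stats.score,
            ))
        # recurse into the flanks either side of the aligned span
        if stats.target_end > stats.target_start:
            left = (s0, s0 + stats.target_start)
            right = (s0 + stats.target_end, s1)
            segments.extend([left, right])
    return hits


def _merge_overlaps(hits: list[IntervalHit]) -> list[IntervalHit]:
    """Among same-strand overlapping hits keep the higher-scoring one."""
    kept: list[IntervalHit] = []
    for hit in sorted(hits, key=lambda h: (h.chrom, h.strand, -h.score, h.start)):
        clash = any(
            k.chrom == hit.chrom and k.strand == hit.strand
            and hit.start < k.end and k.start < hit.end
            for k in kept
        )
        if not clash:
            kept.append(hit)
    kept.sort(key=lambda h: (h.chrom, h.start, h.end))
    return kept


def scan_ltr_hits(genome: GenomeAssembly, query_ltr: str,
                  cfg: MiningConfig | None = None) -> list[IntervalHit]:
    """Find query-LTR homologs passing the identity/coverage filter."""
    cfg = cfg or MiningConfig()
    if not genome.records:
        raise ValueError("empty genome")
    if len(query_ltr) < 50:
        raise ValueError("query LTR shorter than 50 bp")
    query_ltr = query_ltr.upper()
    strands = [("+", query_ltr)]
    if cfg.scan_both_strands:
        strands.append(("-", reverse_complement(query_ltr)))
    hits: list[IntervalHit] = []
    for chrom, seq in genome.records:
        for strand, oriented in strands:
            windows = _seed_windows(seq, oriented)
            if not windows and len(seq) <= _SMALL_CHROM_FALLBACK:
                windows = [(0, len(seq))]
            for window in windows:
                hits.extend(_window_hits(chrom, seq, window, oriented, strand, cfg))
    return _merge_overlaps(hits)


# ---------------------------------------------------------------------------
# tandem pairing
# ---------------------------------------------------------------------------

def pair_hits(hits: list[IntervalHit],
              cfg: MiningConfig | None = None) -> list[tuple[IntervalHit, IntervalHit]]:
    """Pair tandem same-strand hits whose gap lies within the configured
    bounds (inclusive).  Greedy left-to-right matching: each unpaired hit
    takes the nearest downstream unpaired partner, which maximizes the
    number of disjoint pairs with a leftmost tie-break."""
    cfg = cfg or MiningConfig()
    ordered = sorted(hits, key=lambda h: (h.chrom, h.start, h.end))
    used = [False] * len(ordered)
    pairs: list[tuple[IntervalHit, IntervalHit]] = []
    for i, h5 in enumerate(ordered):
        if used[i]:
            continue
        for j in range(i + 1, len(ordered)):
            if used[j]:
                continue
            h3 = ordered[j]
            if h3.chrom != h5.chrom:
                break
            if h3.strand != h5.strand:
                continue
            if cfg.gap_is_internal:
                gap = h3.start - h5.end
            else:
                gap = h3.end - h5.start
            if gap > cfg.max_gap_bp:
                break
            if gap >= cfg.min_gap_bp:
                used[i] = used[j] = True
                pairs.append((h5, h3))
                break
    return pairs


# ---------------------------------------------------------------------------
# element extraction
# ---------------------------------------------------------------------------

def _detect_tsd(chrom_seq: str, start: int, end: int,
                k_range: tuple[int, int] = (4, 6)) -> str | None:
    """Longest identical k-mer (k in 4..6) immediately flanking the span."""
    for k in range(k_range[1], k_range[0] - 1, -1):
        if start - k < 0 or end + k > len(chrom_seq):
            continue
        left = chrom_seq[start - k : start]
        right = chrom_seq[end : end + k]
        if left == right and "N" not in left:
            return left
    return None


def extract_elements(genome: GenomeAssembly,
                     pairs: list[tuple[IntervalHit, IntervalHit]],
                     cfg: MiningConfig | None = None) -> list[LtrElement]:
    """Realize paired hits as elements with sequences, TSD and LTR identity."""
    cfg = cfg or MiningConfig()
    elements: list[LtrElement] = []
    for idx, (h5, h3) in enumerate(pairs, start=1):
        seq = genome.get(h5.chrom)
        if h5.start < 0 or h3.end > len(seq):
            logger.warning("element span %s:%d-%d exceeds chromosome bounds; skipped",
                           h5.chrom, h5.start, h3.end)
            continue
        ltr5_seq = seq[h5.start : h5.end]
        ltr3_seq = seq[h3.start : h3.end]
        internal_seq = seq[h5.end : h3.start]
        stats = pairwise_stats(ltr5_seq, ltr3_seq, mode="global")
        elements.append(LtrElement(
            element_id=f"{h5.chrom}:{h5.start}-{h3.end}",
            chrom=h5.chrom,
            strand=h5.strand,
            ltr5=Interval(h5.start, h5.end),
            ltr3=Interval(h3.start, h3.end),
            internal=Interval(h5.end, h3.start),
            ltr_pair_identity=stats.identity,
            tsd_seq=_detect_tsd(seq, h5.start, h3.end),
            ltr5_seq=ltr5_seq,
            ltr3_seq=ltr3_seq,
            internal_seq=internal_seq,
        ))
    return elements


def mine_genome(genome: GenomeAssembly, query_ltr: str,
                cfg: MiningConfig | None = None) -> list[LtrElement]:
    """Full mining pipeline: scan -> pair -> extract."""
    cfg = cfg or MiningConfig()
    hits = scan_ltr_hits(genome, query_ltr, cfg)
    return extract_elements(genome, pair_hits(hits, cfg), cfg)
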