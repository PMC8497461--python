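"""Retrotransposon family reference bundle.

A :class:`FamilyReference` carries everything the mining/classification
stages need to know about one LTR retrotransposon family:

* the query LTR sequence (the direct repeat flanking every copy),
* the noncoding internal sequence ("nis") that replaces the ORF in
  nonautonomous copies,
* reference ORF sequences for the two autonomous sequence groups
  (group 2 differs from group 1 by a single-nucleotide T insertion near
  the 5' end that truncates the N-terminus of the encoded protein),
* four amino-acid consensus motifs for the canonical Copia-order protein
  domains (GAG, GAG-pre-integrase, integrase core, reverse transcriptase),
* offsets of the conserved noncoding regions (PBS_ATG, ORF/nis, 3_ATrich,
  3_cons) within the canonical element.

:func:`default_family` builds a fully synthetic but internally consistent
bundle from a fixed seed, dimensioned like a typical young Copia family
(775 bp LTRs, ~3.9 kb nis, ~4.2 kb ORF).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

DOMAIN_NAMES = ("GAG", "GAG_PRE_INT", "INT_CORE", "RT")
REGION_NAMES = ("PBS_ATG", "ORF_NIS", "3_ATrich", "3_cons")

_AA = "ACDEFGHIKLMNPQRSTVWY"
_BASES = np.array(list("ACGT"))

# codons per amino acid, stop codons excluded
_CODONS_BY_AA: dict[str, list[str]] = {}
for _b1 in "TCAG":
    for _b2 in "TCAG":
        for _b3 in "TCAG":
            _codon = _b1 + _b2 + _b3
            _aa = str(Seq(_codon).translate())
            if _aa != "*":
                _CODONS_BY_AA.setdefault(_aa, []).append(_codon)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.37) -> str:
    """Random DNA with the requested GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA), size=length))


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_CODONS_BY_AA[aa]) for aa in protein)


@dataclass
class FamilyReference:
    """Reference bundle for one LTR retrotransposon family."""

    ltr_seq: str
    nis_seq: str
    orf_group1_ref: str
    orf_group2_ref: str
    domain_motifs: dict[str, str]
    domain_clades: dict[str, str]
    #: region name -> (start, end), 0-based half-open, in canonical-element
    #: coordinates (canonical element = LTR + internal(nis) + LTR)
    region_annotation: dict[str, tuple[int, int]]
    #: flanking noncoding internal segments shared by all classes
    pbs_atg_seq: str = ""
    at_rich_seq: str = ""
    cons3_seq: str = ""

    def __post_init__(self) -> None:
        if tuple(self.domain_motifs) != DOMAIN_NAMES:
            raise ValueError(f"domain motifs must be named {DOMAIN_NAMES} in order")
        prev_end = 0
        for name in REGION_NAMES:
            if name not in self.region_annotation:
                raise ValueError(f"missing region annotation: {name}")
            start, end = self.region_annotation[name]
            if start < prev_end or end <= start:
                raise ValueError("region offsets must be ordered 5'->3' and non-overlapping")
            prev_end = end

    # -- canonical sequence assembly ------------------------------------

    def internal_seq(self, internal_class: str = "nis") -> str:
        """Internal region (between the LTRs) for one element class."""
        core = {
            "nis": self.nis_seq,
            "orf_group1": self.orf_group1_ref,
            "orf_group2": self.orf_group2_ref,
        }[internal_class]
        return self.pbs_atg_seq + core + self.at_rich_seq + self.cons3_seq

    def element_seq(self, internal_class: str = "nis") -> str:
        """Full canonical element: LTR + internal + LTR."""
        return self.ltr_seq + self.internal_seq(internal_class) + self.ltr_seq

    def orf_span_in_internal(self, group: int) -> tuple[int, int]:
        """ORF coordinates inside the internal region for one group."""
        ref = self.orf_group1_ref if group == 1 else self.orf_group2_ref
        start = len(self.pbs_atg_seq)
        return start, start + len(ref)

    def region_seq(self, region_name: str) -> str:
        """Canonical sequence of one annotated region (nis variant)."""
        start, end = self.region_annotation[region_name]
        return self.element_seq("nis")[start:end]

    # -- persistence -----------------------------------------------------

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "family.fa", "w") as fh:
            for name, seq in [
                ("ltr", self.ltr_seq),
                ("nis", self.nis_seq),
                ("orf_group1", self.orf_group1_ref),
                ("orf_group2", self.orf_group2_ref),
                ("pbs_atg", self.pbs_atg_seq),
                ("at_rich", self.at_rich_seq),
                ("cons3", self.cons3_seq),
            ]:
                fh.write(f">{name}\n{seq}\n")
        with open(out / "domains.fa", "w") as fh:
            for name, seq in self.domain_motifs.items():
                fh.write(f">{name} clade={self.domain_clades[name]}\n{seq}\n")
        with open(out / "regions.json", "w") as fh:
            json.dump({k: list(v) for k, v in self.region_annotation.items()}, fh, indent=1)

    @classmethod
    def load(cls, in_dir: str | Path) -> "FamilyReference":
        from Bio import SeqIO

        src = Path(in_dir)
        nucl = {rec.id: str(rec.seq) for rec in SeqIO.parse(src / "family.fa", "fasta")}
        motifs: dict[str, str] = {}
        clades: dict[str, str] = {}
        for rec in SeqIO.parse(src / "domains.fa", "fasta"):
            motifs[rec.id] = str(rec.seq)
            clades[rec.id] = rec.description.split("clade=")[-1].strip()
        with open(src / "regions.json") as fh:
            regions = {k: tuple(v) for k, v in json.load(fh).items()}
        return cls(
            ltr_seq=nucl["ltr"],
            nis_seq=nucl["nis"],
            orf_group1_ref=nucl["orf_group1"],
            orf_group2_ref=nucl["orf_group2"],
            domain_motifs={k: motifs[k] for k in DOMAIN_NAMES},
            domain_clades=clades,
            region_annotation=regions,
            pbs_atg_seq=nucl["pbs_atg"],
            at_rich_seq=nucl["at_rich"],
            cons3_seq=nucl["cons3"],
        )


def _build_group1_orf(rng: np.random.Generator, n_codons: int, motifs: dict[str, str]) -> str:
    """Group-1 reference ORF: ATG + filler + embedded domain motifs + stop.

    The protein carries an internal Met at codon 29 so that the group-2
    frameshift variant regains the reading frame at an in-frame ATG 84 nt
    downstream of the original start.
    """
    n_aa = n_codons - 1  # coding codons (stop excluded)
    protein = list(_random_protein(rng, n_aa))
    protein[0] = "M"
    protein[28] = "M"  # restart codon used by the group-2 variant
    # embed the four domain motifs, evenly spaced, in canonical order
    slots = np.linspace(60, n_aa - 80, num=len(motifs)).astype(int)
    for pos, motif in zip(slots, motifs.values()):
        protein[pos : pos + len(motif)] = list(motif)
    nt = _back_translate("".join(protein), rng)
    nt = nt[:84] + "ATG" + nt[87:]  # pin the restart codon to ATG exactly
    stop = "TGA"
    return nt + stop


def plus_strand_longest_orf_span(seq: str) -> tuple[int, int] | None:
    """(start, end) of the longest plus-strand ATG..stop run, stop included."""
    best: tuple[int, int, int] | None = None  # (-len, start, end)
    for frame in range(3):
        trimmed = seq[frame : frame + 3 * ((len(seq) - frame) // 3)]
        aa = str(Seq(trimmed).translate())
        start = None
        for i, ch in enumerate(aa):
            if ch == "M" and start is None:
                start = i
            elif ch == "*" and start is not None:
                cand = (-(i - start + 1), frame + 3 * start, frame + 3 * (i + 1))
                if best is None or cand < best:
                    best = cand
                start = None
    if best is None:
        return None
    return best[1], best[2]


def _longest_orf_len(seq: str) -> int:
    """Length in nt (ATG..stop inclusive) of the longest ORF, six frames."""
    best = 0
    for s in (seq, str(Seq(seq).reverse_complement())):
        for frame in range(3):
            aa = str(Seq(s[frame : frame + 3 * ((len(s) - frame) // 3)]).translate())
            start = None
            for i, ch in enumerate(aa):
                if ch == "M" and start is None:
                    start = i
                elif ch == "*" and start is not None:
                    best = max(best, 3 * (i - start + 1))
                    start = None
    return best


def default_family(seed: int = 7154) -> FamilyReference:
    """Deterministically built synthetic family reference bundle.

    All sequences are synthetic stand-ins dimensioned like a young plant
    Copia family: 775 bp LTRs, a 3,861 bp noncoding internal sequence,
    a 4,155 nt group-1 ORF, and a group-2 variant with a T inserted
    between nucleotides 66 and 67 whose longest ORF is 4,071 nt.
    """
    for attempt in range(100):
        rng = np.random.default_rng(seed + attempt)
        motifs = {
            "GAG": _random_protein(rng, 45),
            "GAG_PRE_INT": _random_protein(rng, 40),
            "INT_CORE": _random_protein(rng, 55),
            "RT": _random_protein(rng, 65),
        }
        orf1 = _build_group1_orf(rng, n_codons=1385, motifs=motifs)  # 4155 nt
        orf2 = orf1[:66] + "T" + orf1[66:]  # group-2 T insertion after nt 66
        # the insertion frameshifts the original start; the longest ORF of the
        # variant must be the restart ORF (84 nt shorter), as in real group-2
        # copies.  Rebuild on the rare draws where the shifted frame lacks an
        # early stop codon.
        if _longest_orf_len(orf1) != 4155 or _longest_orf_len(orf2) != 4071:
            continue
        ltr = "TG" + random_dna(rng, 771) + "CA"
        nis = random_dna(rng, 3861)
        pbs_atg = random_dna(rng, 300)
        at_rich = random_dna(rng, 250, gc=0.14)
        cons3 = random_dna(rng, 300)
        n_ltr = len(ltr)
        regions = {
            "PBS_ATG": (n_ltr, n_ltr + len(pbs_atg)),
            "ORF_NIS": (n_ltr + len(pbs_atg), n_ltr + len(pbs_atg) + len(nis)),
            "3_ATrich": (
                n_ltr + len(pbs_atg) + len(nis),
                n_ltr + len(pbs_atg) + len(nis) + len(at_rich),
            ),
            "3_cons": (
                n_ltr + len(pbs_atg) + len(nis) + len(at_rich),
                n_ltr + len(pbs_atg) + len(nis) + len(at_rich) + len(cons3),
            ),
        }
        return FamilyReference(
            ltr_seq=ltr,
            nis_seq=nis,
            orf_group1_ref=orf1,
            orf_group2_ref=orf2,
            domain_motifs=motifs,
            domain_clades={name: "Angela" for name in motifs},
            region_annotation=regions,
            pbs_atg_seq=pbs_atg,
            at_rich_seq=at_rich,
            cons3_seq=cons3,
        )
    raise RuntimeError("could not construct a consistent family reference")
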