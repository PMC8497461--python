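"""File-format plumbing: FASTA, GFF3, BED and the package's TSV tables.

Coordinates are 0-based half-open in memory and at BED boundaries, and
1-based inclusive in GFF3, per those standards.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mining import Interval, LtrElement
from .simulate import GeneModel, GenomeAssembly, TruthRecord

TRUTH_COLUMNS = [
    "element_id", "chrom", "start", "end", "strand", "true_class",
    "true_group", "true_age_years", "tsd_seq", "genic_context",
]

ELEMENT_COLUMNS = [
    "element_id", "chrom", "strand", "ltr5_start", "ltr5_end",
    "ltr3_start", "ltr3_end", "ltr_pair_identity", "tsd_seq",
    "class_label", "group", "family", "age_years",
    "ltr5_seq", "ltr3_seq", "internal_seq",
]


# -- FASTA -------------------------------------------------------------------

def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path), "fasta",
    )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def read_genome(path: str | Path) -> GenomeAssembly:
    return GenomeAssembly(read_fasta(path))


# -- GFF3 --------------------------------------------------------------------

def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Write simple single-CDS gene models as gene/mRNA/CDS triples."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start1, end1 = g.start + 1, g.end  # GFF3 is 1-based inclusive
            fh.write(f"{g.chrom}\tltrkit\tgene\t{start1}\t{end1}\t.\t{g.strand}\t."
                     f"\tID={g.gene_id}\n")
            fh.write(f"{g.chrom}\tltrkit\tmRNA\t{start1}\t{end1}\t.\t{g.strand}\t."
                     f"\tID={g.gene_id}.1;Parent={g.gene_id}\n")
            fh.write(f"{g.chrom}\tltrkit\tCDS\t{start1}\t{end1}\t.\t{g.strand}\t0"
                     f"\tID={g.gene_id}.1.cds;Parent={g.gene_id}.1\n")


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Read gene features from a GFF3 file back into 0-based half-open models."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        genes.append(GeneModel(
            gene_id=feat.id,
            chrom=feat.seqid,
            start=feat.start - 1,
            end=feat.end,
            strand=feat.strand,
        ))
    return genes


# -- truth table -------------------------------------------------------------

def write_truth(truth: list[TruthRecord], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(t) for t in truth], columns=TRUTH_COLUMNS)
    # %.17g keeps ages exact through a write/read cycle
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_truth(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"tsd_seq": str},
                     float_precision="round_trip")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        group = d["true_group"]
        d["true_group"] = None if pd.isna(group) else int(group)
        d["tsd_seq"] = "" if pd.isna(d["tsd_seq"]) else d["tsd_seq"]
        out.append(TruthRecord(**d))
    return out


# -- element catalog ---------------------------------------------------------

def write_elements(elements: list[LtrElement], path: str | Path) -> None:
    rows = []
    for e in elements:
        rows.append({
            "element_id": e.element_id, "chrom": e.chrom, "strand": e.strand,
            "ltr5_start": e.ltr5.start, "ltr5_end": e.ltr5.end,
            "ltr3_start": e.ltr3.start, "ltr3_end": e.ltr3.end,
            "ltr_pair_identity": e.ltr_pair_identity, "tsd_seq": e.tsd_seq or "",
            "class_label": e.class_label or "", "group": e.group or "",
            "family": e.family or "", "age_years": e.age_years or "",
            "ltr5_seq": e.ltr5_seq, "ltr3_seq": e.ltr3_seq,
            "internal_seq": e.internal_seq,
        })
    pd.DataFrame(rows, columns=ELEMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_elements(path: str | Path) -> list[LtrElement]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(LtrElement(
            element_id=str(d["element_id"]), chrom=str(d["chrom"]),
            strand=str(d["strand"]),
            ltr5=Interval(int(d["ltr5_start"]), int(d["ltr5_end"])),
            ltr3=Interval(int(d["ltr3_start"]), int(d["ltr3_end"])),
            internal=Interval(int(d["ltr5_end"]), int(d["ltr3_start"])),
            ltr_pair_identity=float(d["ltr_pair_identity"]),
            tsd_seq=str(d["tsd_seq"]) or None,
            ltr5_seq=str(d["ltr5_seq"]), ltr3_seq=str(d["ltr3_seq"]),
            internal_seq=str(d["internal_seq"]),
            class_label=str(d["class_label"]) or None,
            group=int(d["group"]) if str(d["group"]) else None,
            family=str(d["family"]) or None,
            age_years=float(d["age_years"]) if str(d["age_years"]) else None,
        ))
    return out


def write_elements_bed(elements: list[LtrElement], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in elements:
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.element_id}\t.\t{e.strand}\n")


def write_elements_fasta(elements: list[LtrElement], path: str | Path) -> None:
    write_fasta([(e.element_id.replace(":", "_"), e.full_seq) for e in elements], path)


# -- flat key=value config ---------------------------------------------------

def write_config(config, path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in dataclasses.fields(config):
            fh.write(f"{f.name}={getattr(config, f.name)}\n")


# -- density tracks ----------------------------------------------------------

def write_density_tsv(result, path: str | Path, value_name: str = "density") -> None:
    pd.DataFrame({"x": result.grid, value_name: result.density}).to_csv(
        path, sep="\t", index=False)
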