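"""Readers and writers for the standard formats the pipeline touches.

Conventions used throughout the package:

- genomic coordinates are GFF3-native, 1-based inclusive;
- protein residue positions are 1-based;
- output tables are tab-separated with a header row, preceded by
  ``#``-prefixed comment lines recording tool version and parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence, the unit of annotation."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"protein {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """An mRNA gene model as an ordered list of CDS segments.

    ``cds_segments`` are (start, end) genomic intervals, 1-based inclusive,
    listed in translation order (ascending coordinates on '+', descending
    on '-').  ``rank`` is the 1-based gene-order index on the chromosome.
    """

    gene_id: str
    chromosome: str
    strand: str
    rank: int
    cds_segments: list[tuple[int, int]] = field(default_factory=list)
    valid: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.rank < 1:
            raise FormatError(f"gene {self.gene_id}: rank must be >= 1")
        for start, end in self.cds_segments:
            if start > end:
                raise FormatError(
                    f"gene {self.gene_id}: CDS segment ({start},{end}) inverted"
                )

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_segments)

    @property
    def n_introns(self) -> int:
        return max(len(self.cds_segments) - 1, 0)


def _clean_sequence(protein_id: str, raw: str) -> str:
    seq = raw.upper().rstrip("*")
    if "*" in seq:
        raise FormatError(f"protein {protein_id!r}: internal stop codon in sequence")
    # letters outside the 20 standard residues map to X
    return "".join(c if c in STANDARD_AA else "X" for c in seq)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased, a trailing ``*`` stop is stripped, and any
    non-standard letter is mapped to ``X``.  Duplicate ids are an error.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, _clean_sequence(rec.id, str(rec.seq))))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description="") for rec in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models (one per mRNA) from a GFF3 file.

    Only CDS features are used; exon/UTR features are ignored.  CDS
    segments are sorted in translation order.  Gene rank is assigned by
    gene start position per chromosome.  A model whose total CDS length
    is not divisible by 3 is flagged invalid with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for gene in db.features_of_type("gene"):
        genes.append(gene)
    # rank by gene start per chromosome
    rank_of: dict[str, int] = {}
    by_chrom: dict[str, list] = {}
    for gene in genes:
        by_chrom.setdefault(gene.seqid, []).append(gene)
    for chrom, chrom_genes in by_chrom.items():
        for i, gene in enumerate(sorted(chrom_genes, key=lambda g: (g.start, g.id)), 1):
            rank_of[gene.id] = i

    models: list[GeneModel] = []
    for gene in genes:
        for mrna in db.children(gene, featuretype="mRNA"):
            segments = [
                (cds.start, cds.end) for cds in db.children(mrna, featuretype="CDS")
            ]
            if not segments:
                continue
            segments.sort()
            if mrna.strand == "-":
                segments.reverse()
            model = GeneModel(
                gene_id=mrna.id,
                chromosome=gene.seqid,
                strand=mrna.strand,
                rank=rank_of[gene.id],
                cds_segments=segments,
            )
            if model.cds_length % 3 != 0:
                warnings.warn(
                    f"gene model {mrna.id}: CDS length {model.cds_length} "
                    "not divisible by 3; flagged invalid"
                )
                model.valid = False
            models.append(model)
    return models


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models back out as gene/mRNA/CDS GFF3 features."""
    lines = ["##gff-version 3"]
    for model in sorted(models, key=lambda m: (m.chromosome, min(s for s, _ in m.cds_segments))):
        starts = [s for s, _ in model.cds_segments]
        ends = [e for _, e in model.cds_segments]
        gstart, gend = min(starts), max(ends)
        gene_id = f"{model.gene_id}.gene"
        lines.append(
            f"{model.chromosome}\tbzipscan\tgene\t{gstart}\t{gend}\t.\t{model.strand}\t.\t"
            f"ID={gene_id}"
        )
        lines.append(
            f"{model.chromosome}\tbzipscan\tmRNA\t{gstart}\t{gend}\t.\t{model.strand}\t.\t"
            f"ID={model.gene_id};Parent={gene_id}"
        )
        coding_before = 0
        rows = []
        for start, end in model.cds_segments:
            phase = (3 - coding_before % 3) % 3
            rows.append((start, end, phase))
            coding_before += end - start + 1
        for i, (start, end, phase) in enumerate(sorted(rows), 1):
            lines.append(
                f"{model.chromosome}\tbzipscan\tCDS\t{start}\t{end}\t.\t{model.strand}\t{phase}\t"
                f"ID={model.gene_id}.cds{i};Parent={model.gene_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_pairs_tsv(
    path: str | Path, known_ids: set[str] | None = None
) -> list[tuple[str, str]]:
    """Read a two-column TSV of homolog pairs.

    Pairs are unordered and deduplicated ((a,b) == (b,a)); self-pairs are
    dropped with a warning.  When ``known_ids`` is given, any gene id not
    in it is an error.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[frozenset[str]] = set()
    unknown: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated columns")
            a, b = fields[0].strip(), fields[1].strip()
            if a == b:
                warnings.warn(f"{path}:{lineno}: self-pair {a!r} dropped")
                continue
            if known_ids is not None:
                unknown.update(g for g in (a, b) if g not in known_ids)
            key = frozenset((a, b))
            if key in seen:
                continue
            seen.add(key)
            pairs.append(tuple(sorted((a, b))))
    if unknown:
        raise FormatError(f"unknown gene ids in {path}: {', '.join(sorted(unknown))}")
    return pairs


def write_table(
    df: pd.DataFrame, path: str | Path, params: dict | None = None
) -> None:
    """Write a TSV with '#' comment lines carrying tool version and parameters."""
    with open(path, "w") as fh:
        fh.write(f"# bzipscan {__version__}\n")
        for key, value in (params or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
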