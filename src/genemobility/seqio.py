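"""Sequence and annotation I/O: FASTA, GFF3, proteome extraction, assembly stats.

Data model conventions
----------------------
* Internal coordinates are 0-based half-open; GFF3 on disk is 1-based
  inclusive (the standard interchange convention).
* GC% is computed over unambiguous bases only (A/C/G/T); ``N`` is excluded
  from the denominator, which keeps the statistic stable on draft assemblies.
* CDS features whose translation contains an internal stop codon are kept and
  flagged as pseudo rather than dropped: truncated/frame-disrupted gene
  remnants are first-class objects for the marker screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_NT_ALPHABET = set("ACGTN")


class ParseError(ValueError):
    """Raised on malformed FASTA/GFF3 input; message names the offending line."""


@dataclass
class SeqRecord:
    """A named sequence (nucleotide over {A,C,G,T,N} or amino-acid).

    ``pseudo`` marks proteins translated from a CDS with an internal stop.
    """

    id: str
    sequence: str
    description: str = ""
    pseudo: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneAnnotation:
    """One CDS feature; ``start``/``end`` are 0-based half-open on ``contig_id``."""

    contig_id: str
    start: int
    end: int
    strand: str
    locus_tag: str
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.locus_tag}"
            )
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAssembly:
    """Named contigs plus gene annotations; the unit of all genome-level work."""

    id: str
    contigs: list[SeqRecord] = field(default_factory=list)
    annotations: list[GeneAnnotation] = field(default_factory=list)

    def contig(self, contig_id: str) -> SeqRecord:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(f"no contig {contig_id!r} in assembly {self.id}")

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    def validate(self) -> None:
        """Check annotation contig references and bounds; raise on violation."""
        lengths = {c.id: len(c) for c in self.contigs}
        if len(lengths) != len(self.contigs):
            raise ValueError(f"duplicate contig ids in assembly {self.id}")
        for a in self.annotations:
            if a.contig_id not in lengths:
                raise ValueError(
                    f"annotation {a.locus_tag} references unknown contig {a.contig_id}"
                )
            if a.end > lengths[a.contig_id]:
                raise ValueError(
                    f"annotation {a.locus_tag} [{a.start},{a.end}) exceeds "
                    f"contig {a.contig_id} length {lengths[a.contig_id]}"
                )


@dataclass
class AssemblyStats:
    n_contigs: int
    total_length: int
    gc_percent: float


def read_fasta(path) -> list[SeqRecord]:
    """Read a FASTA file into records, preserving order and uppercasing.

    Raises :class:`ParseError` naming the line number for malformed headers,
    empty sequences, or duplicate ids. A line-tracking reader is used (rather
    than a library parser) precisely so these errors can name their line.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    header_line = 0
    cur_id = cur_desc = None
    chunks: list[str] = []

    def _flush() -> None:
        if cur_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"{path}: empty sequence for record {cur_id!r} "
                             f"(header at line {header_line})")
        records.append(SeqRecord(id=cur_id, description=cur_desc, sequence=seq))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                _flush()
                parts = line[1:].split(maxsplit=1)
                if not parts:
                    raise ParseError(f"{path}: empty FASTA header at line {lineno}")
                cur_id = parts[0]
                cur_desc = parts[1] if len(parts) > 1 else ""
                if cur_id in seen:
                    raise ParseError(
                        f"{path}: duplicate record id {cur_id!r} at line {lineno}")
                seen.add(cur_id)
                header_line = lineno
                chunks = []
            else:
                if cur_id is None:
                    raise ParseError(
                        f"{path}: sequence before first header at line {lineno}")
                chunks.append(line.strip().upper())
    _flush()
    return records


def write_fasta(records, path, width: int = 70) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_gff3(path, assembly: GenomeAssembly) -> list[GeneAnnotation]:
    """Read CDS features from a GFF3 file into 0-based half-open annotations.

    On-disk coordinates are 1-based inclusive. Features referencing unknown
    contigs or exceeding contig bounds raise :class:`ParseError` naming the
    offending feature.
    """
    lengths = {c.id: len(c) for c in assembly.contigs}
    annotations: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}: expected 9 columns at line {lineno}, "
                                 f"got {len(fields)}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "CDS":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(
                    f"{path}: non-integer coordinates at line {lineno}") from None
            attr_map = _parse_attributes(attrs)
            locus_tag = attr_map.get("locus_tag") or attr_map.get("ID")
            if not locus_tag:
                raise ParseError(
                    f"{path}: CDS without ID/locus_tag at line {lineno}")
            if seqid not in lengths:
                raise ParseError(
                    f"{path}: feature {locus_tag} (line {lineno}) references "
                    f"unknown contig {seqid!r}")
            if not (1 <= start_i <= end_i <= lengths[seqid]):
                raise ParseError(
                    f"{path}: feature {locus_tag} (line {lineno}) coordinates "
                    f"{start_i}..{end_i} outside contig {seqid} "
                    f"(length {lengths[seqid]})")
            annotations.append(GeneAnnotation(
                contig_id=seqid,
                start=start_i - 1,
                end=end_i,
                strand=strand,
                locus_tag=locus_tag,
                product=attr_map.get("product", ""),
            ))
    tags = [a.locus_tag for a in annotations]
    if len(set(tags)) != len(tags):
        dup = sorted({t for t in tags if tags.count(t) > 1})
        raise ParseError(f"{path}: duplicate locus_tags {dup}")
    return annotations


def write_gff3(assembly: GenomeAssembly, path) -> None:
    """Write annotations as GFF3 (1-based inclusive coordinates on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in assembly.contigs:
            fh.write(f"##sequence-region {c.id} 1 {len(c)}\n")
        for a in assembly.annotations:
            attrs = f"ID={a.locus_tag};locus_tag={a.locus_tag}"
            if a.product:
                attrs += f";product={a.product}"
            fh.write("\t".join([
                a.contig_id, "genemobility", "CDS",
                str(a.start + 1), str(a.end), ".", a.strand, "0", attrs,
            ]) + "\n")


def _parse_attributes(attrs: str) -> dict[str, str]:
    out = {}
    for item in attrs.split(";"):
        item = item.strip()
        if item and "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def extract_proteome(assembly: GenomeAssembly,
                     translation_table: int = 11) -> list[SeqRecord]:
    """Translate every annotated CDS; one protein per CDS, id = locus_tag.

    Minus-strand CDS are reverse-complemented before translation; a trailing
    stop is removed. A CDS whose length is not a multiple of 3 is translated
    over the longest 3-divisible prefix and flagged pseudo, as is any protein
    retaining an internal stop (``*``).
    """
    proteins: list[SeqRecord] = []
    seqs = {c.id: c.sequence for c in assembly.contigs}
    for a in assembly.annotations:
        cds = seqs[a.contig_id][a.start:a.end]
        if a.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        pseudo = False
        if len(cds) % 3 != 0:
            logger.warning("CDS %s length %d not divisible by 3; flagged pseudo",
                           a.locus_tag, len(cds))
            cds = cds[: len(cds) - len(cds) % 3]
            pseudo = True
        aa = str(Seq(cds).translate(table=translation_table))
        if aa.endswith("*"):
            aa = aa[:-1]
        if "*" in aa:
            pseudo = True
        proteins.append(SeqRecord(id=a.locus_tag, sequence=aa,
                                  description=a.product, pseudo=pseudo))
    return proteins


def assembly_stats(assembly: GenomeAssembly) -> AssemblyStats:
    """Contig count, total length, and GC% over unambiguous bases.

    gc_percent = 100*(G+C)/(A+C+G+T); an all-N assembly yields gc_percent NaN
    with a logged warning.
    """
    if not assembly.contigs:
        raise ValueError("assembly has no contigs")
    gc = at = 0
    for c in assembly.contigs:
        s = c.sequence
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    if gc + at == 0:
        logger.warning("assembly %s has no unambiguous bases; GC undefined",
                       assembly.id)
        gc_percent = float("nan")
    else:
        gc_percent = 100.0 * gc / (gc + at)
    return AssemblyStats(n_contigs=len(assembly.contigs),
                         total_length=assembly.total_length,
                         gc_percent=gc_percent)
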