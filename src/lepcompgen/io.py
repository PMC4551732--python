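"""Readers and writers for the external formats the pipeline touches.

All genomic intervals inside the package are 0-based half-open; GFF3 and VCF
coordinates are converted at this boundary.  Sequences are uppercased DNA over
``{A, C, G, T, N}``; other ambiguity codes are rejected so that downstream
codon arithmetic stays total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import dendropy

__all__ = [
    "ParseError",
    "ScaffoldRecord",
    "GeneModel",
    "SnpRecord",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_vcf",
    "write_vcf",
    "read_newick",
    "write_newick",
    "read_bed",
    "write_bed",
]

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised when an input file violates its stated dialect."""


@dataclass
class ScaffoldRecord:
    """One assembly scaffold: an id and its uppercase DNA sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ParseError(
                f"scaffold {self.id!r}: unsupported sequence characters {sorted(bad)}; "
                "only A/C/G/T/N are accepted"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A protein-coding gene placement with its CDS intervals.

    Coordinates are 0-based half-open on the scaffold.  ``cds_intervals`` are
    sorted, non-overlapping and contained in ``[start, end)``.  ``coding`` is
    False when the total CDS length is not divisible by 3.
    """

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)
    coding: bool = True

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        prev_end = None
        for s, e in self.cds_intervals:
            if s >= e or s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: CDS ({s},{e}) outside gene body")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id}: CDS intervals overlap or are unsorted")
            prev_end = e
        if self.cds_total_length % 3 != 0:
            self.coding = False

    @property
    def cds_total_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)


@dataclass
class SnpRecord:
    """A biallelic SNP: 0-based position, ref/alt bases and zygosity."""

    scaffold: str
    pos: int
    ref: str
    alt: str
    zygosity: str = "het"

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"SNP at {self.scaffold}:{self.pos}: ref == alt")
        if self.zygosity not in ("het", "hom"):
            raise ValueError("zygosity must be 'het' or 'hom'")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ScaffoldRecord]:
    """Read a FASTA file into :class:`ScaffoldRecord` objects, in file order.

    Sequences are uppercased; CRLF line endings are tolerated.  A non-header
    line before the first ``>`` raises :class:`ParseError` naming the line.
    """
    records: list[ScaffoldRecord] = []
    seen: set[str] = set()
    current_id: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if current_id is None:
            return
        if current_id in seen:
            raise ParseError(f"duplicate scaffold id {current_id!r}")
        seen.add(current_id)
        records.append(ScaffoldRecord(current_id, "".join(chunks)))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                current_id = line[1:].split()[0] if line[1:].strip() else None
                if current_id is None:
                    raise ParseError(f"{path}: empty FASTA header at line {lineno}")
                chunks = []
            else:
                if current_id is None:
                    raise ParseError(
                        f"{path}: sequence before first '>' header at line {lineno}"
                    )
                chunks.append(line.upper())
        _flush()
    return records


def write_fasta(records: Iterable[ScaffoldRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (1-based inclusive -> 0-based half-open).

    Expects a gene/mRNA/CDS feature hierarchy linked by ``ID``/``Parent``
    attributes.  When a gene carries several mRNA isoforms the one with the
    longest total CDS is retained (ties broken by mRNA id).  A gene whose
    retained CDS length is not divisible by 3 is kept but marked non-coding,
    with a warning.
    """
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    mrna_cds: dict[str, list[tuple[int, int]]] = {}

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}: expected 9 tab-separated columns at line {lineno}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs_s = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}: bad coordinates at line {lineno}") from exc
            attrs = dict(
                kv.split("=", 1) for kv in attrs_s.split(";") if kv and "=" in kv
            )
            start, end = start1 - 1, end1  # GFF3 1-based inclusive -> half-open
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise ParseError(f"{path}: gene without ID at line {lineno}")
                genes[gid] = {"scaffold": seqid, "start": start, "end": end, "strand": strand}
            elif ftype == "mRNA":
                mid, parent = attrs.get("ID"), attrs.get("Parent")
                if mid is None or parent is None:
                    raise ParseError(f"{path}: mRNA missing ID/Parent at line {lineno}")
                mrna_parent[mid] = parent
                mrna_cds.setdefault(mid, [])
            elif ftype == "CDS":
                parent = attrs.get("Parent")
                if parent is None:
                    raise ParseError(f"{path}: CDS missing Parent at line {lineno}")
                mrna_cds.setdefault(parent, []).append((start, end))

    models: list[GeneModel] = []
    by_gene: dict[str, list[str]] = {}
    for mid, parent in mrna_parent.items():
        by_gene.setdefault(parent, []).append(mid)

    for gid, info in genes.items():
        isoforms = by_gene.get(gid, [])
        if not isoforms:
            continue
        # longest total CDS wins; deterministic tie-break on mRNA id
        best = max(
            sorted(isoforms),
            key=lambda m: sum(e - s for s, e in mrna_cds.get(m, [])),
        )
        cds = sorted(mrna_cds.get(best, []))
        for s, e in cds:
            if s < info["start"] or e > info["end"]:
                raise ParseError(
                    f"gene {gid}: CDS interval ({s},{e}) outside gene body "
                    f"({info['start']},{info['end']})"
                )
        model = GeneModel(
            gene_id=gid,
            scaffold=info["scaffold"],
            start=info["start"],
            end=info["end"],
            strand=info["strand"],
            cds_intervals=cds,
        )
        if cds and not model.coding:
            warnings.warn(
                f"gene {gid}: CDS length {model.cds_total_length} not divisible by 3; "
                "marked non-coding",
                stacklevel=2,
            )
        models.append(model)
    return models


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as a gene/mRNA/CDS hierarchy (0-based -> 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            base = f"{g.scaffold}\tlepcompgen\t"
            fh.write(
                base + f"gene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mid = f"{g.gene_id}.t1"
            fh.write(
                base
                + f"mRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={mid};Parent={g.gene_id}\n"
            )
            for s, e in g.cds_intervals:
                fh.write(base + f"CDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\tParent={mid}\n")


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path) -> tuple[list[SnpRecord], int]:
    """Read biallelic SNPs from a VCF 4.x file.

    Returns ``(records, n_skipped)`` where ``n_skipped`` counts indel and
    multiallelic rows.  POS is converted from 1-based to 0-based.  A file
    without a ``#CHROM`` header line raises :class:`ParseError`.
    """
    records: list[SnpRecord] = []
    skipped = 0
    saw_header = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                continue
            if not saw_header:
                raise ParseError(f"{path}: data before #CHROM header at line {lineno}")
            cols = line.split("\t")
            if len(cols) < 8:
                raise ParseError(f"{path}: short VCF row at line {lineno}")
            chrom, pos_s, _id, ref, alt = cols[0], cols[1], cols[2], cols[3], cols[4]
            if "," in alt or len(ref) != 1 or len(alt) != 1 or alt == ".":
                skipped += 1
                continue
            zygosity = "het"
            if len(cols) >= 10:
                gt = cols[9].split(":", 1)[0].replace("|", "/")
                if gt in ("1/1",):
                    zygosity = "hom"
            records.append(SnpRecord(chrom, int(pos_s) - 1, ref.upper(), alt.upper(), zygosity))
    if not saw_header:
        raise ParseError(f"{path}: missing #CHROM header")
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} non-SNP/multiallelic rows", stacklevel=2)
    return records, skipped


def write_vcf(snps: Iterable[SnpRecord], path: str | Path, sample: str = "sample") -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for s in snps:
            gt = "0/1" if s.zygosity == "het" else "1/1"
            fh.write(f"{s.scaffold}\t{s.pos + 1}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT\t{gt}\n")


# ---------------------------------------------------------------------------
# Newick trees (dendropy containers)


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read an unrooted Newick tree; unbalanced parentheses raise ParseError."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"{path}: invalid Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ParseError(f"{path}: duplicate leaf labels")
    return tree


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a Newick string (convenience wrapper around dendropy)."""
    try:
        return dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise ParseError(f"invalid Newick string: {exc}") from exc


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write Newick with branch lengths at 10 significant digits."""
    s = tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    )
    with open(path, "w") as fh:
        fh.write(s)


# ---------------------------------------------------------------------------
# BED (0-based half-open) and simple value tracks


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}: short BED row at line {lineno}")
            out.append((cols[0], int(cols[1]), int(cols[2])))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
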