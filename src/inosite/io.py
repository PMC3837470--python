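"""Readers and writers for every external format the pipeline touches.

Coordinates are 0-based half-open everywhere in memory; 1-based positions
appear only in human-readable report output.  Gene sequences are stored in
genomic plus-strand orientation regardless of gene strand.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pysam
from Bio import SeqIO


class FormatError(ValueError):
    """Raised when an input file violates its expected dialect."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded half-open genomic interval (0-based start, exclusive end)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass
class GeneRecord:
    """A gene sequence anchored to genomic coordinates.

    The sequence is always the genomic plus strand; ``interval.strand``
    records the transcribed strand and is consulted only when interpreting
    mismatch base identity.
    """

    gene_id: str
    interval: GenomicInterval
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.interval):
            raise ValueError(
                f"gene {self.gene_id}: sequence length {len(self.sequence)} "
                f"!= interval width {len(self.interval)}"
            )

    @property
    def strand(self) -> str:
        return self.interval.strand

    def genomic_pos(self, offset: int) -> int:
        return self.interval.start + offset


@dataclass(frozen=True)
class RepeatAnnotation:
    interval: GenomicInterval
    name: str
    repeat_class: str
    family: str
    is_alu: bool


@dataclass
class SnpSet:
    """Point-variant positions, 0-based, keyed by (chrom, position)."""

    positions: frozenset[tuple[str, int]] = frozenset()

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.positions

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class KnownSite:
    interval: GenomicInterval
    tissue: Optional[str] = None
    pubmed_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.interval) != 1:
            raise ValueError("known editing sites must be width-1 intervals")


@dataclass
class KnownSiteSet:
    sites: list[KnownSite] = field(default_factory=list)

    def positions(self) -> set[tuple[str, int]]:
        return {(s.interval.chrom, s.interval.start) for s in self.sites}

    def __len__(self) -> int:
        return len(self.sites)


# ---------------------------------------------------------------------------
# readers


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]``.

    Ids are the first whitespace-delimited header token; sequences are
    uppercased with U mapped to T.  A sequence line appearing before any
    header is reported with its line number.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FormatError(
                    f"{path}: line {lineno}: sequence data before first FASTA header"
                )
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq).upper().replace("U", "T")))
    return records


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTQ file; qualities are discarded."""
    return [
        (rec.id, str(rec.seq).upper().replace("U", "T"))
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def read_reads(path: str | Path) -> list[tuple[str, str]]:
    """Read short reads from FASTA or FASTQ, sniffing the format."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        return read_fastq(path)
    return read_fasta(path)


def _split_bed_line(line: str, path: Path, lineno: int, min_cols: int) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < min_cols:
        raise FormatError(
            f"{path}: line {lineno}: expected at least {min_cols} columns, "
            f"got {len(fields)}"
        )
    return fields


def _iter_bed_lines(path: Path) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_gene_bed(path: str | Path, fasta: list[tuple[str, str]]) -> list[GeneRecord]:
    """Join a BED6 sidecar with FASTA sequences into :class:`GeneRecord` s.

    The BED name column must match a FASTA id, and the interval width must
    equal the sequence length.
    """
    path = Path(path)
    seq_by_id = dict(fasta)
    genes = []
    missing = []
    for lineno, line in _iter_bed_lines(path):
        f = _split_bed_line(line, path, lineno, 6)
        chrom, start, end, name, _score, strand = f[:6]
        if name not in seq_by_id:
            missing.append(name)
            continue
        interval = GenomicInterval(chrom, int(start), int(end), strand)
        seq = seq_by_id[name]
        if len(seq) != len(interval):
            raise FormatError(
                f"{path}: gene {name}: sequence length {len(seq)} does not "
                f"match interval width {len(interval)}"
            )
        genes.append(GeneRecord(name, interval, seq))
    if missing:
        raise FormatError(
            f"{path}: BED names not found in FASTA: {', '.join(sorted(set(missing)))}"
        )
    return genes


def read_repeats(path: str | Path) -> list[RepeatAnnotation]:
    """Read repeat annotations from BED6+3 (name, class, family extensions).

    ``is_alu`` is true iff the family equals "Alu" or the name starts with
    "Alu" (case-insensitive).
    """
    path = Path(path)
    repeats = []
    for lineno, line in _iter_bed_lines(path):
        f = _split_bed_line(line, path, lineno, 9)
        chrom, start, end, _name, _score, strand = f[:6]
        name, rclass, family = f[6], f[7], f[8]
        is_alu = family.lower() == "alu" or name.lower().startswith("alu")
        repeats.append(
            RepeatAnnotation(
                GenomicInterval(chrom, int(start), int(end), strand),
                name,
                rclass,
                family,
                is_alu,
            )
        )
    return repeats


def read_snps(path: str | Path) -> SnpSet:
    """Read SNP positions from BED (width-1 intervals) or VCF.

    VCF POS is 1-based and converted; duplicate positions collapse.  BED
    intervals wider than one base are rejected: these are point variants.
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.readline()
    positions: set[tuple[str, int]] = set()
    if head.startswith("##fileformat"):
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                positions.add((rec.chrom, rec.pos - 1))
    else:
        for lineno, line in _iter_bed_lines(path):
            f = _split_bed_line(line, path, lineno, 3)
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if end - start != 1:
                raise FormatError(
                    f"{path}: line {lineno}: SNP interval wider than 1 base "
                    f"([{start}, {end})); point variants only"
                )
            positions.add((chrom, start))
    return SnpSet(frozenset(positions))


def read_known_sites(path: str | Path) -> KnownSiteSet:
    """Read known editing sites from BED.

    Columns beyond the first three are optional: column 4 is a tissue/organ
    label, column 5 a comma-separated PubMed id list.
    """
    path = Path(path)
    sites = []
    for lineno, line in _iter_bed_lines(path):
        f = _split_bed_line(line, path, lineno, 3)
        chrom, start, end = f[0], int(f[1]), int(f[2])
        if end - start != 1:
            raise FormatError(
                f"{path}: line {lineno}: known sites must be width-1 intervals"
            )
        tissue = f[3] if len(f) > 3 and f[3] not in (".", "") else None
        pubmed = tuple(p for p in f[4].split(",") if p) if len(f) > 4 else ()
        sites.append(KnownSite(GenomicInterval(chrom, start, end), tissue, pubmed))
    return KnownSiteSet(sites)


# ---------------------------------------------------------------------------
# report writers


def _fmt_p(p) -> str:
    return "NA" if p is None else format(p, ".6g")


def write_report(sites, path: str | Path, fmt: str = "txt") -> Path:
    """Write the per-site report in txt, xml or bed dialect.

    txt is tab-separated with a header; xml nests the same fields plus the
    supporting EST ids and (when present) repeat name/class/family; bed
    emits width-1 intervals scored by NAE.  Unknown significance prints as
    "NA".
    """
    path = Path(path)
    if fmt == "txt":
        _write_txt(sites, path)
    elif fmt == "xml":
        _write_xml(sites, path)
    elif fmt == "bed":
        _write_bed(sites, path)
    else:
        raise ValueError(f"unknown report format {fmt!r} (expected txt, xml or bed)")
    return path


TXT_COLUMNS = [
    "chrom",
    "position",
    "strand",
    "gene_id",
    "region_class",
    "nae",
    "color",
    "known",
    "pvalue",
    "adjusted_pvalue",
]


def _write_txt(sites, path: Path) -> None:
    from .stats import nae_color

    with open(path, "w") as out:
        out.write("\t".join(TXT_COLUMNS) + "\n")
        for s in sites:
            row = [
                s.chrom,
                str(s.genomic_pos + 1),  # 1-based in reports
                s.strand,
                s.gene_id,
                s.region_class,
                str(s.nae),
                nae_color(s.nae),
                "yes" if s.known else "no",
                _fmt_p(s.pvalue),
                _fmt_p(s.adjusted_pvalue),
            ]
            out.write("\t".join(row) + "\n")


def _write_xml(sites, path: Path) -> None:
    from .stats import nae_color

    root = ET.Element("editing_sites")
    for s in sites:
        el = ET.SubElement(root, "site")
        ET.SubElement(el, "chrom").text = s.chrom
        ET.SubElement(el, "position").text = str(s.genomic_pos + 1)
        ET.SubElement(el, "strand").text = s.strand
        ET.SubElement(el, "gene_id").text = s.gene_id
        ET.SubElement(el, "region_class").text = s.region_class
        ET.SubElement(el, "nae").text = str(s.nae)
        ET.SubElement(el, "color").text = nae_color(s.nae)
        ET.SubElement(el, "known").text = "yes" if s.known else "no"
        ET.SubElement(el, "pvalue").text = _fmt_p(s.pvalue)
        ET.SubElement(el, "adjusted_pvalue").text = _fmt_p(s.adjusted_pvalue)
        ests = ET.SubElement(el, "supporting_ests")
        for est_id in sorted(s.supporting_ests):
            ET.SubElement(ests, "est").text = est_id
        if s.repeat is not None:
            rep = ET.SubElement(el, "repeat")
            ET.SubElement(rep, "name").text = s.repeat.name
            ET.SubElement(rep, "class").text = s.repeat.repeat_class
            ET.SubElement(rep, "family").text = s.repeat.family
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)
    with open(path, "a") as out:
        out.write("\n")


def _write_bed(sites, path: Path) -> None:
    with open(path, "w") as out:
        for s in sites:
            out.write(
                "\t".join(
                    [
                        s.chrom,
                        str(s.genomic_pos),
                        str(s.genomic_pos + 1),
                        f"{s.gene_id}_{s.genomic_pos + 1}",
                        str(s.nae),
                        s.strand,
                    ]
                )
                + "\n"
            )
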