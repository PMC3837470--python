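"""Candidate-site detection: A-G mismatch extraction and the sequence filters.

A-to-I editing converts adenosine to inosine, which sequencing machinery
reads as guanosine.  Candidate sites are therefore alignment columns where
the gene shows A and the transcript evidence shows G, in the transcribed
orientation: for minus-strand genes this appears genomically as T→C.

Four sequence-level filters follow: editing happens in clusters (ADAR edits
many nearby adenosines, so isolated mismatches are discarded); sites are
classified by repeat context (Alu / other repeat / unique); a candidate must
sit in a plausibly double-stranded region, tested by searching for a
reverse-complement partner arm near the site; and positions catalogued as
SNPs are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from intervaltree import IntervalTree

from .align import PairAlignment, ScoringScheme, local_align, revcomp
from .io import GeneRecord, KnownSiteSet, RepeatAnnotation, SnpSet


@dataclass
class MismatchSite:
    """One candidate A-to-I editing site with its filter annotations."""

    gene_id: str
    genomic_pos: int  # 0-based genomic coordinate
    gene_offset: int  # 0-based offset into the gene sequence
    chrom: str
    strand: str
    gene_base: str = "A"  # transcribed orientation: always A
    est_base: str = "G"  # transcribed orientation: always G
    supporting_ests: set[str] = field(default_factory=set)
    region_class: str = "T2"
    repeat: Optional[RepeatAnnotation] = None
    in_cluster: bool = False
    ds_rna: bool = False
    is_snp: bool = False
    known: bool = False
    pvalue: Optional[float] = None
    adjusted_pvalue: Optional[float] = None
    significant: Optional[bool] = None

    @property
    def nae(self) -> int:
        """Number of Aligned ESTs supporting the site."""
        return len(self.supporting_ests)


@dataclass
class DsProbe:
    """Reverse-complement probe used for the double-strand region search."""

    site: MismatchSite
    sequence: str
    source_start: int  # gene offsets of the region the probe was built from
    source_end: int
    window_start: int
    window_end: int

    @property
    def probe_length(self) -> int:
        return len(self.sequence)


def _mismatch_bases(strand: str) -> tuple[str, str]:
    # transcribed A→G appears genomically as A→G on plus, T→C on minus
    return ("A", "G") if strand == "+" else ("T", "C")


def extract_ag_mismatches(aln: PairAlignment, gene: GeneRecord) -> list[MismatchSite]:
    """Candidate sites from one alignment: gene A vs EST G (transcribed).

    Bases in the alignment columns are genomically oriented; minus-strand
    genes contribute genomic T→C columns.  One site per qualifying column.
    """
    gb, eb = _mismatch_bases(gene.strand)
    sites = []
    for col in aln.columns:
        if col.gene_pos is None or col.est_pos is None:
            continue
        if col.gene_base == gb and col.est_base == eb:
            sites.append(
                MismatchSite(
                    gene_id=gene.gene_id,
                    genomic_pos=gene.genomic_pos(col.gene_pos),
                    gene_offset=col.gene_pos,
                    chrom=gene.interval.chrom,
                    strand=gene.strand,
                    supporting_ests={aln.est_id},
                )
            )
    return sites


def clustered_offsets(aln: PairAlignment, gene: GeneRecord, min_run: int = 4) -> set[int]:
    """Gene offsets belonging to a qualifying mismatch cluster in ``aln``.

    A qualifying cluster is a maximal run of at least ``min_run`` A-G
    mismatch columns in which every column between consecutive members is
    an exact match — no gaps and no other mismatch types.  All members of a
    qualifying run are putative editing events.
    """
    gb, eb = _mismatch_bases(gene.strand)
    retained: set[int] = set()
    run: list[int] = []
    for col in aln.columns:
        gapped = col.gene_pos is None or col.est_pos is None
        if not gapped and col.gene_base == gb and col.est_base == eb:
            run.append(col.gene_pos)
        elif not gapped and col.is_match:
            continue  # matches may separate run members
        else:
            if len(run) >= min_run:
                retained.update(run)
            run = []
    if len(run) >= min_run:
        retained.update(run)
    return retained


def clustering_filter(
    sites: list[MismatchSite], aln: PairAlignment, gene: GeneRecord, min_run: int = 4
) -> list[MismatchSite]:
    """Retain the sites of one alignment that lie in a qualifying cluster."""
    keep = clustered_offsets(aln, gene, min_run)
    return [s for s in sites if s.gene_offset in keep]


def merge_sites(per_alignment: list[list[MismatchSite]]) -> list[MismatchSite]:
    """Merge per-alignment sites at the same genomic position.

    Supporting EST sets accumulate (NAE counts every A-G-supporting EST);
    ``in_cluster`` is true if the site was clustered in at least one
    alignment.
    """
    merged: dict[tuple[str, int], MismatchSite] = {}
    for sites in per_alignment:
        for s in sites:
            key = (s.chrom, s.genomic_pos)
            if key in merged:
                merged[key].supporting_ests |= s.supporting_ests
                merged[key].in_cluster |= s.in_cluster
            else:
                merged[key] = s
    return sorted(merged.values(), key=lambda s: (s.chrom, s.genomic_pos))


def build_repeat_index(repeats: list[RepeatAnnotation]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for rep in repeats:
        trees.setdefault(rep.interval.chrom, IntervalTree()).addi(
            rep.interval.start, rep.interval.end, rep
        )
    return trees


def classify_region(
    site: MismatchSite, repeat_index: dict[str, IntervalTree]
) -> MismatchSite:
    """Assign T0 (Alu), T1 (other repeat) or T2 (unique) and attach the repeat."""
    tree = repeat_index.get(site.chrom)
    hits = [iv.data for iv in tree[site.genomic_pos]] if tree is not None else []
    alu = [r for r in hits if r.is_alu]
    if alu:
        site.region_class = "T0"
        site.repeat = alu[0]
    elif hits:
        site.region_class = "T1"
        site.repeat = hits[0]
    else:
        site.region_class = "T2"
        site.repeat = None
    return site


def build_ds_probe(
    site: MismatchSite,
    gene: GeneRecord,
    probe_len: int = 251,
    window_len: int = 4001,
) -> DsProbe:
    """Reverse-complement probe centered on the site, plus its search window.

    Alu-region (T0) sites use the full Alu interval as the probe source;
    otherwise the source spans ``probe_len`` nucleotides centered on the
    mismatch (``(probe_len-1)//2`` either side), truncated at gene
    boundaries.  The window spans up to ``(window_len-1)//2`` nucleotides
    either side of the site.
    """
    glen = len(gene.sequence)
    off = site.gene_offset
    if site.region_class == "T0" and site.repeat is not None:
        src_start = max(0, site.repeat.interval.start - gene.interval.start)
        src_end = min(glen, site.repeat.interval.end - gene.interval.start)
    else:
        flank = (probe_len - 1) // 2
        src_start = max(0, off - flank)
        src_end = min(glen, off + flank + 1)
    wflank = (window_len - 1) // 2
    win_start = max(0, off - wflank)
    win_end = min(glen, off + wflank + 1)
    return DsProbe(
        site=site,
        sequence=revcomp(gene.sequence[src_start:src_end]),
        source_start=src_start,
        source_end=src_end,
        window_start=win_start,
        window_end=win_end,
    )


def min_qualifying_length(probe_length: int, min_len_frac: float = 0.85) -> int:
    """Smallest aligned length that passes the minimum-length rule.

    For the default 251-nt probe at 85% this is 214 aligned nucleotides.
    """
    import math

    return math.ceil(min_len_frac * probe_length)


def _footprint_overlap(aln: PairAlignment, window_start: int, lo: int, hi: int) -> int:
    """Overlap (nt) between the alignment footprint on the gene and [lo, hi)."""
    gene_positions = [
        window_start + c.gene_pos for c in aln.columns if c.gene_pos is not None
    ]
    if not gene_positions:
        return 0
    fp_lo, fp_hi = min(gene_positions), max(gene_positions) + 1
    return max(0, min(fp_hi, hi) - max(fp_lo, lo))


def dsrna_filter(
    probe: DsProbe,
    gene: GeneRecord,
    min_len_frac: float = 0.85,
    min_identity: float = 0.85,
    scoring: ScoringScheme = ScoringScheme(),
) -> bool:
    """True when the probe finds a reverse-complement partner arm in the window.

    The probe is locally aligned against the window around the site; the
    site is annotated as double-stranded when the alignment spans at least
    ``min_len_frac`` of the probe length and reaches ``min_identity``
    identity over its aligned columns.  An alignment that mostly re-covers
    the probe's own source interval is rejected as a trivial self-hit: the
    source arm is masked and the search repeated.
    """
    window = gene.sequence[probe.window_start : probe.window_end]
    if not window or not probe.sequence:
        return False
    need_len = min_qualifying_length(probe.probe_length, min_len_frac)

    def passes(aln) -> bool:
        return (
            aln is not None
            and aln.aligned_length >= need_len
            and aln.identity >= min_identity
        )

    aln = local_align(probe.sequence, window, scoring)
    if aln is not None:
        overlap = _footprint_overlap(
            aln, probe.window_start, probe.source_start, probe.source_end
        )
        src_len = probe.source_end - probe.source_start
        if overlap * 2 > src_len:
            # self-hit: mask the source arm and search the rest of the window
            lo = max(0, probe.source_start - probe.window_start)
            hi = max(0, probe.source_end - probe.window_start)
            masked = window[:lo] + "N" * (hi - lo) + window[hi:]
            aln = local_align(probe.sequence, masked, scoring)
    return passes(aln)


def snp_filter(
    sites: list[MismatchSite], snps: SnpSet
) -> tuple[list[MismatchSite], list[MismatchSite]]:
    """Split sites into (retained, removed-as-SNP) by catalogued position."""
    kept, removed = [], []
    for s in sites:
        if (s.chrom, s.genomic_pos) in snps:
            s.is_snp = True
            removed.append(s)
        else:
            kept.append(s)
    return kept, removed


def annotate_known(sites: list[MismatchSite], known: KnownSiteSet) -> list[MismatchSite]:
    """Flag sites whose position matches a known editing site (annotation only)."""
    positions = known.positions()
    for s in sites:
        s.known = (s.chrom, s.genomic_pos) in positions
    return sites
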