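"""Alignment kernels: gapped local alignment and ungapped read placement.

Two kernels serve the whole pipeline.  A Smith-Waterman local aligner
(affine gaps, BLASTN-like scores) handles gene-vs-EST comparison and the
inverted-repeat probe search.  An exhaustive ungapped scanner places short
reads with at most two mismatches, reporting every valid placement in both
orientations — the report-all / ≤2-mismatch selection rule used for the
read-support step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pysam
from Bio import Align

from .io import GeneRecord

GAP = None  # sentinel for a gapped side of an alignment column

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def revcomp(seq: str) -> str:
    """Reverse complement; N self-complements."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap local alignment scores (BLASTN-like defaults).

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.  N is a
    wildcard scoring 0 against anything: it never counts as a match.
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


@dataclass
class AlignmentColumn:
    gene_pos: Optional[int]  # 0-based gene offset, or None for a gap
    est_pos: Optional[int]
    gene_base: str  # "-" on a gapped side
    est_base: str

    @property
    def is_match(self) -> bool:
        # N never counts as a match
        return (
            self.gene_pos is not None
            and self.est_pos is not None
            and self.gene_base == self.est_base
            and self.gene_base != "N"
        )


@dataclass
class PairAlignment:
    """A gapped local alignment between a gene and a transcript sequence."""

    gene_id: str
    est_id: str
    columns: list[AlignmentColumn]
    score: float
    est_reversed: bool = False

    @property
    def aligned_length(self) -> int:
        """Number of columns with a base on both sides."""
        return sum(
            1 for c in self.columns if c.gene_pos is not None and c.est_pos is not None
        )

    @property
    def matches(self) -> int:
        return sum(1 for c in self.columns if c.is_match)

    @property
    def identity(self) -> float:
        n = self.aligned_length
        return self.matches / n if n else 0.0


@dataclass
class ReadPlacement:
    """An ungapped placement of a short read on a gene, ≤2 mismatches."""

    read_id: str
    gene_id: str
    start: int  # 0-based gene offset of the leftmost placed base
    length: int
    mismatch_offsets: tuple[int, ...] = ()
    reverse: bool = False  # placed sequence is the reverse complement

    @property
    def mismatch_count(self) -> int:
        return len(self.mismatch_offsets)

    @property
    def end(self) -> int:
        return self.start + self.length


def _make_aligner(scoring: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    aligner.wildcard = "N"
    return aligner


def local_align(
    query: str,
    target: str,
    scoring: ScoringScheme = ScoringScheme(),
    query_id: str = "query",
    target_id: str = "target",
) -> Optional[PairAlignment]:
    """Best-scoring Smith-Waterman local alignment, or None when best ≤ 0.

    ``target`` maps to the gene side of the returned columns, ``query`` to
    the EST side.
    """
    if not query or not target:
        raise ValueError("local_align requires nonempty sequences")
    aligner = _make_aligner(scoring)
    alignments = aligner.align(target, query)
    if alignments.score <= 0 or len(alignments) == 0:
        return None
    best = alignments[0]
    columns = []
    indices = best.indices  # shape (2, n_cols); -1 marks a gap
    for k in range(indices.shape[1]):
        ti, qi = int(indices[0, k]), int(indices[1, k])
        columns.append(
            AlignmentColumn(
                gene_pos=ti if ti >= 0 else None,
                est_pos=qi if qi >= 0 else None,
                gene_base=target[ti] if ti >= 0 else "-",
                est_base=query[qi] if qi >= 0 else "-",
            )
        )
    return PairAlignment(
        gene_id=target_id,
        est_id=query_id,
        columns=columns,
        score=float(alignments.score),
    )


def align_gene_to_ests(
    gene: GeneRecord,
    ests: list[tuple[str, str]],
    scoring: ScoringScheme = ScoringScheme(),
    min_aligned_length: int = 50,
    min_identity: float = 0.90,
) -> list[PairAlignment]:
    """Best gene-vs-EST alignment per EST, passing the quality gate.

    ESTs are unoriented: both the given sequence and its reverse complement
    are tried and the better-scoring orientation kept.  EST bases in the
    returned columns are expressed in genomic (gene plus-strand)
    orientation.  Alignments shorter than ``min_aligned_length`` or below
    ``min_identity`` are dropped.
    """
    results = []
    for est_id, est_seq in ests:
        if not est_seq:
            continue
        fwd = local_align(est_seq, gene.sequence, scoring, est_id, gene.gene_id)
        rev = local_align(revcomp(est_seq), gene.sequence, scoring, est_id, gene.gene_id)
        best = None
        if fwd is not None and (rev is None or fwd.score >= rev.score):
            best = fwd
        elif rev is not None:
            best = rev
            best.est_reversed = True
        if best is None:
            continue
        if best.aligned_length >= min_aligned_length and best.identity >= min_identity:
            results.append(best)
    return results


def place_reads(
    gene: GeneRecord,
    reads: list[tuple[str, str]],
    max_mismatches: int = 2,
) -> list[ReadPlacement]:
    """Every ungapped placement of each read with ≤ ``max_mismatches``.

    Both orientations are scanned and all valid placements reported (a read
    may map to several loci).  N on either side counts as a mismatch.
    Placements must lie fully inside the gene.
    """
    gene_arr = np.frombuffer(gene.sequence.encode(), dtype=np.uint8)
    gene_code = _encode(gene_arr)
    placements: list[ReadPlacement] = []
    # group reads by (length, orientation) to vectorize the window scan
    by_length: dict[int, list[tuple[str, str]]] = {}
    for read_id, seq in reads:
        if not seq:
            continue
        if len(seq) > len(gene.sequence):
            continue
        by_length.setdefault(len(seq), []).append((read_id, seq))
    for length, group in by_length.items():
        windows = np.lib.stride_tricks.sliding_window_view(gene_code, length)
        win_is_n = windows == 4
        for is_rev in (False, True):
            seqs = [revcomp(s) if is_rev else s for _, s in group]
            mat = _encode(
                np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
            ).reshape(len(group), length)
            # chunk the read axis to bound the broadcast buffer
            chunk = max(1, 4_000_000 // max(1, windows.shape[0] * length))
            for lo in range(0, len(group), chunk):
                sub = mat[lo : lo + chunk]
                mism = (
                    (windows[None, :, :] != sub[:, None, :])
                    | win_is_n[None, :, :]
                    | (sub[:, None, :] == 4)
                )
                counts = mism.sum(axis=2)
                hit_read, hit_start = np.nonzero(counts <= max_mismatches)
                for r, s in zip(hit_read, hit_start):
                    offs = tuple(int(o) for o in np.nonzero(mism[r, s])[0])
                    placements.append(
                        ReadPlacement(
                            read_id=group[lo + r][0],
                            gene_id=gene.gene_id,
                            start=int(s),
                            length=length,
                            mismatch_offsets=offs,
                            reverse=is_rev,
                        )
                    )
    placements.sort(key=lambda p: (p.read_id, p.start, p.reverse))
    return placements


def _encode(ascii_arr: np.ndarray) -> np.ndarray:
    out = np.full(ascii_arr.shape, 4, dtype=np.uint8)
    for base, code in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
        out[ascii_arr == ord(base)] = code
    return out


def import_sam(
    path: str | Path,
    genes: list[GeneRecord],
    max_mismatches: int = 2,
) -> tuple[list[ReadPlacement], dict[str, str]]:
    """Convert SAM records to read placements, keeping ≤2-mismatch hits.

    Unmapped, secondary and supplementary records are dropped, as are
    records whose NM tag exceeds ``max_mismatches``.  Returns the
    placements plus the reference-oriented read sequences keyed by read id
    (SAM stores SEQ already in reference orientation, so placements carry
    ``reverse=False``).
    """
    gene_by_id = {g.gene_id: g for g in genes}
    placements: list[ReadPlacement] = []
    seqs: dict[str, str] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            ref = rec.reference_name
            if ref not in gene_by_id:
                raise ValueError(f"SAM reference {ref!r} is not a known gene id")
            seq = (rec.query_sequence or "").upper()
            if not seq:
                continue
            gene = gene_by_id[ref]
            start = rec.reference_start
            if start < 0 or start + len(seq) > len(gene.sequence):
                continue
            offsets = tuple(
                i
                for i, (a, b) in enumerate(
                    zip(seq, gene.sequence[start : start + len(seq)])
                )
                if a != b or a == "N" or b == "N"
            )
            nm = rec.get_tag("NM") if rec.has_tag("NM") else len(offsets)
            if nm > max_mismatches:
                continue
            seqs[rec.query_name] = seq
            placements.append(
                ReadPlacement(
                    read_id=rec.query_name,
                    gene_id=ref,
                    start=start,
                    length=len(seq),
                    mismatch_offsets=offsets,
                    reverse=False,
                )
            )
    return placements, seqs
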