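"""Read-support statistics: pileups, calibration, Fisher test, FDR, NAE bins.

The confidence model compares the observed A/G composition of the read
column over a candidate site against the composition expected at genuine
editing sites.  The expectation is calibrated empirically: at every known
editing site with enough read coverage, the A and G frequencies of the
pileup column are computed and averaged.  A candidate's observed A/G counts
are then tested against the calibrated expectation with a two-sided Fisher
exact test, and p-values are adjusted across sites by Benjamini-Hochberg.

Only A and G reads enter these computations: other bases in a column are
sequencing noise with respect to the A-vs-G question and are ignored.
Sites with fewer than ``min_reads`` A/G reads cannot be tested and are
annotated as unknown.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .align import ReadPlacement

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class PileupColumn:
    """Per-base read counts over one gene position."""

    gene_id: str
    gene_offset: int
    counts: dict[str, int] = field(default_factory=lambda: {b: 0 for b in "ACGT"})

    @property
    def ag_depth(self) -> int:
        return self.counts["A"] + self.counts["G"]

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class CalibrationModel:
    """Expected A/G column frequencies averaged over known editing sites."""

    expected_freq_A: float
    expected_freq_G: float
    n_sites: int

    def __post_init__(self) -> None:
        if not math.isclose(self.expected_freq_A + self.expected_freq_G, 1.0):
            raise ValueError("expected A and G frequencies must sum to 1")
        if self.n_sites < 1:
            raise ValueError("calibration requires at least one site")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "expected_freq_A": self.expected_freq_A,
                    "expected_freq_G": self.expected_freq_G,
                    "n_sites": self.n_sites,
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        d = json.loads(Path(path).read_text())
        return cls(d["expected_freq_A"], d["expected_freq_G"], d["n_sites"])


def pileup_at(
    gene_id: str,
    gene_offset: int,
    placements: Sequence[ReadPlacement],
    reads: dict[str, str],
    strand: str = "+",
) -> PileupColumn:
    """Tally read bases over one gene offset, in transcribed orientation.

    Reverse-orientation placements contribute the complement of the read
    base at the mirrored offset (the placed sequence is the reverse
    complement of the stored read).  For minus-strand genes the tallied
    bases are complemented once more so that counts are expressed in the
    transcribed orientation — the frame in which edited sites read A/G.
    N bases are not counted.
    """
    col = PileupColumn(gene_id, gene_offset)
    for p in placements:
        if p.gene_id != gene_id or not (p.start <= gene_offset < p.end):
            continue
        seq = reads[p.read_id]
        i = gene_offset - p.start
        base = _COMPLEMENT[seq[p.length - 1 - i]] if p.reverse else seq[i]
        if strand == "-":
            base = _COMPLEMENT[base]
        if base in col.counts:
            col.counts[base] += 1
    return col


def has_read_support(
    col: PileupColumn, min_reads: int = 5, require_g: bool = False
) -> bool:
    """True when the A/G column is deep enough to test.

    The default rule requires ``min_reads`` reads in the A/G column; the
    stricter ``require_g`` variant demands that many G-carrying reads.
    """
    if require_g:
        return col.counts["G"] >= min_reads
    return col.ag_depth >= min_reads


class CalibrationError(RuntimeError):
    pass


def calibrate(known_cols: Sequence[PileupColumn], min_reads: int = 5) -> CalibrationModel:
    """Average the A/G column frequencies over covered known sites.

    Columns with fewer than ``min_reads`` A/G reads are excluded.  Each
    qualifying column contributes fA = A/(A+G) and fG = G/(A+G); the model
    stores their unweighted means.
    """
    fa, fg, n = 0.0, 0.0, 0
    for col in known_cols:
        if col.ag_depth < min_reads:
            continue
        fa += col.counts["A"] / col.ag_depth
        fg += col.counts["G"] / col.ag_depth
        n += 1
    if n == 0:
        raise CalibrationError(
            "no known site has enough read coverage to calibrate expected "
            "A/G frequencies; supply calibration data or an explicit prior"
        )
    return CalibrationModel(fa / n, fg / n, n)


def expected_counts(model: CalibrationModel, ag_depth: int) -> tuple[int, int]:
    """Calibration frequencies scaled to the observed depth (round half-up)."""
    exp_a = int(math.floor(model.expected_freq_A * ag_depth + 0.5))
    return exp_a, ag_depth - exp_a


def fisher_pvalue(col: PileupColumn, model: CalibrationModel) -> float:
    """Two-sided Fisher exact p-value of observed vs expected A/G counts.

    The 2x2 table is [[obs_A, obs_G], [exp_A, exp_G]] with the expected row
    being the calibration frequencies scaled to the observed A/G depth.
    """
    if col.ag_depth == 0:
        raise ValueError("fisher_pvalue requires a column with A/G reads")
    exp_a, exp_g = expected_counts(model, col.ag_depth)
    table = [[col.counts["A"], col.counts["G"]], [exp_a, exp_g]]
    return float(fisher_exact(table, alternative="two-sided").pvalue)


def fdr_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    for p in pvalues:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
    if not pvalues:
        return []
    _, adj, _, _ = multipletests(list(pvalues), method="fdr_bh")
    return [float(x) for x in adj]


def assign_significance(
    sites,
    cols: dict[tuple[str, int], PileupColumn],
    model: Optional[CalibrationModel],
    alpha: float = 0.01,
    min_reads: int = 5,
    require_g: bool = False,
):
    """Attach p-values, BH-adjusted p-values and significance flags to sites.

    Sites without sufficient read support — or all sites, when no
    calibration model could be built — are annotated as unknown (None).
    Adjustment runs jointly over the testable sites only; ``significant``
    marks adjusted p ≤ alpha as a labeled threshold.
    """
    testable = []
    for s in sites:
        col = cols.get((s.gene_id, s.gene_offset))
        if (
            model is not None
            and col is not None
            and has_read_support(col, min_reads, require_g)
        ):
            s.pvalue = fisher_pvalue(col, model)
            testable.append(s)
        else:
            s.pvalue = None
            s.adjusted_pvalue = None
            s.significant = None
    adjusted = fdr_adjust([s.pvalue for s in testable])
    for s, adj in zip(testable, adjusted):
        s.adjusted_pvalue = adj
        s.significant = adj <= alpha
    return sites


def nae_color(nae: int) -> str:
    """Evidence-count color bin keyed by the Number of Aligned ESTs.

    yellow: 1-5, orange: 6-10, red: 11-19, fuxia: ≥20.
    """
    if nae < 1:
        raise ValueError("NAE must be at least 1")
    if nae >= 20:
        return "fuxia"
    if nae > 10:
        return "red"
    if nae > 5:
        return "orange"
    return "yellow"
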