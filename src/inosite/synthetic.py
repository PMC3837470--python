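"""Seeded synthetic fixtures: genes with planted edit clusters, ESTs, reads.

The generator emulates the data geometry the detection pipeline assumes:
clusters of nearby A→G edits supported by a fraction of the covering
transcripts, an inverted-repeat partner arm planted within hairpin range of
each cluster, SNP decoys, and a partially edited short-read pileup.  It
also always plants negative controls — an undersized cluster and a cluster
with no inverted-repeat partner — so recovery tests can check that the
filters reject them.

Background sequence is i.i.d. uniform over ACGT; repeat annotations are
labeled intervals (the repeat-class logic only consults the annotation, not
the sequence content).  All randomness flows through one numpy Generator
derived from the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import revcomp
from .io import GeneRecord, GenomicInterval

_BASES = np.array(list("ACGT"))


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic study condition."""

    seed: int = 0
    n_genes: int = 2
    gene_length: int = 5000
    n_planted_clusters: int = 2
    cluster_size: int = 4
    cluster_spacing: int = 60  # nt between cluster members
    editing_rate: float = 0.6  # fraction of ESTs/reads showing the edited base
    n_ests_per_gene: int = 8  # background (unedited) ESTs per gene
    est_length: int = 500
    read_length: int = 50
    read_depth: int = 20  # mean fold coverage
    snp_decoy_count: int = 2
    inverted_repeat: bool = True
    calibration_site_count: int = 4

    def __post_init__(self) -> None:
        if self.cluster_size < 1:
            raise ValueError("cluster_size must be >= 1")
        if not (0.0 <= self.editing_rate <= 1.0):
            raise ValueError("editing_rate must lie in [0, 1]")
        if self.read_depth < 0:
            raise ValueError("read_depth must be >= 0")


@dataclass
class PlantedSite:
    """Ground truth for one planted edited position."""

    chrom: str
    genomic_pos: int
    gene_id: str
    gene_offset: int
    kind: str  # cluster_good / cluster_small / cluster_noir / cluster_snp / calibration
    has_inverted_repeat: bool
    is_snp_decoy: bool
    expected_pass: bool


@dataclass
class Scenario:
    spec: ScenarioSpec
    genes: list[GeneRecord]
    ests: dict[str, list[tuple[str, str]]]  # gene_id -> [(est_id, seq)]
    reads: dict[str, list[tuple[str, str]]]
    repeats: list[tuple[GenomicInterval, str, str, str]]  # interval, name, class, family
    snp_positions: list[tuple[str, int]]
    known_positions: list[tuple[str, int]]
    truth: list[PlantedSite]
    files: dict[str, Path] = field(default_factory=dict)


_PROBE_FLANK = 125  # matches the default 251-nt probe
_PARTNER_GAP = 200  # nt between source arm end and planted partner arm


class _GeneLayout:
    """Sequential block allocator inside one gene."""

    def __init__(self, length: int, margin: int = 100):
        self.length = length
        self.cursor = margin
        self.margin = margin

    def take(self, size: int, what: str) -> int:
        base = self.cursor
        if base + size > self.length - self.margin:
            raise ValueError(
                f"infeasible geometry: cannot fit {what} (needs {size} nt at "
                f"offset {base}) in a gene of length {self.length}"
            )
        self.cursor = base + size
        return base


def _edited_base(strand: str) -> str:
    return "G" if strand == "+" else "C"


def _reference_base(strand: str) -> str:
    # transcribed adenosine: genomic A on plus, T on minus
    return "A" if strand == "+" else "T"


def generate_scenario(spec: ScenarioSpec, outdir: str | Path | None = None) -> Scenario:
    """Build the full synthetic study; optionally write pipeline input files.

    Planted elements per scenario: ``n_planted_clusters`` qualifying
    clusters (size ``cluster_size``, partner arm planted within hairpin
    range when ``inverted_repeat``), one undersized cluster of
    ``cluster_size - 1`` members, one cluster without a partner arm, one
    cluster carrying ``snp_decoy_count`` SNP-catalogued members, and
    ``calibration_site_count`` isolated known editing sites that receive
    edited reads but no edited ESTs.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.snp_decoy_count > spec.cluster_size:
        raise ValueError("snp_decoy_count cannot exceed cluster_size")

    chrom = "chr1"
    gene_gap = 1000
    seqs = [
        rng.choice(_BASES, size=spec.gene_length) for _ in range(spec.n_genes)
    ]
    strands = ["+" if i % 2 == 0 else "-" for i in range(spec.n_genes)]
    layouts = [_GeneLayout(spec.gene_length) for _ in range(spec.n_genes)]

    # job list: (kind, size, with_partner_arm)
    jobs: list[tuple[str, int, bool]] = [
        ("cluster_good", spec.cluster_size, spec.inverted_repeat)
        for _ in range(spec.n_planted_clusters)
    ]
    if spec.cluster_size > 1:
        jobs.append(("cluster_small", spec.cluster_size - 1, spec.inverted_repeat))
    jobs.append(("cluster_noir", spec.cluster_size, False))
    if spec.snp_decoy_count > 0:
        jobs.append(("cluster_snp", spec.cluster_size, spec.inverted_repeat))

    truth: list[PlantedSite] = []
    repeats: list[tuple[GenomicInterval, str, str, str]] = []
    snp_positions: list[tuple[str, int]] = []
    cluster_offsets: dict[int, list[tuple[str, list[int], bool]]] = {
        i: [] for i in range(spec.n_genes)
    }

    n_alu_assigned = 0
    for j, (kind, size, with_partner) in enumerate(jobs):
        g = j % spec.n_genes
        strand = strands[g]
        span = (size - 1) * spec.cluster_spacing + 1
        src_lo_pad = _PROBE_FLANK + 5
        partner_len = span + 2 * _PROBE_FLANK
        block = src_lo_pad + span + _PROBE_FLANK + _PARTNER_GAP + partner_len + 50
        base = layouts[g].take(block, f"{kind} #{j}")
        first = base + src_lo_pad
        members = [first + i * spec.cluster_spacing for i in range(size)]
        ref = _reference_base(strand)
        for off in members:
            seqs[g][off] = ref
        src_start, src_end = members[0] - _PROBE_FLANK, members[-1] + _PROBE_FLANK + 1
        if with_partner:
            # partner arm = reverse complement of the unedited source region
            partner_start = src_end + _PARTNER_GAP
            arm = revcomp("".join(seqs[g][src_start:src_end]))
            seqs[g][partner_start : partner_start + len(arm)] = list(arm)

        gene_start = g * (spec.gene_length + gene_gap)
        if kind == "cluster_good":
            # first good cluster sits in a labeled Alu, second in a LINE,
            # the rest in unique sequence — exercising all region classes
            if n_alu_assigned == 0:
                repeats.append(
                    (
                        GenomicInterval(
                            chrom, gene_start + src_start, gene_start + src_end, strand
                        ),
                        "AluSx",
                        "SINE",
                        "Alu",
                    )
                )
            elif n_alu_assigned == 1:
                repeats.append(
                    (
                        GenomicInterval(
                            chrom, gene_start + src_start, gene_start + src_end, strand
                        ),
                        "L1PA3",
                        "LINE",
                        "L1",
                    )
                )
            n_alu_assigned += 1
        snp_members = (
            set(members[: spec.snp_decoy_count]) if kind == "cluster_snp" else set()
        )
        for off in members:
            gpos = gene_start + off
            is_decoy = off in snp_members
            if is_decoy:
                snp_positions.append((chrom, gpos))
            truth.append(
                PlantedSite(
                    chrom=chrom,
                    genomic_pos=gpos,
                    gene_id=f"gene{g}",
                    gene_offset=off,
                    kind=kind,
                    has_inverted_repeat=with_partner,
                    is_snp_decoy=is_decoy,
                    expected_pass=(
                        kind in ("cluster_good", "cluster_snp")
                        and with_partner
                        and size >= spec.cluster_size
                        and not is_decoy
                    ),
                )
            )
        cluster_offsets[g].append((kind, members, with_partner))

    known_positions: list[tuple[str, int]] = []
    for c in range(spec.calibration_site_count):
        g = c % spec.n_genes
        off = layouts[g].take(120, f"calibration site #{c}") + 60
        seqs[g][off] = _reference_base(strands[g])
        gpos = g * (spec.gene_length + gene_gap) + off
        known_positions.append((chrom, gpos))
        truth.append(
            PlantedSite(
                chrom=chrom,
                genomic_pos=gpos,
                gene_id=f"gene{g}",
                gene_offset=off,
                kind="calibration",
                has_inverted_repeat=False,
                is_snp_decoy=False,
                expected_pass=False,
            )
        )

    genes = []
    for g in range(spec.n_genes):
        gene_start = g * (spec.gene_length + gene_gap)
        genes.append(
            GeneRecord(
                f"gene{g}",
                GenomicInterval(
                    chrom, gene_start, gene_start + spec.gene_length, strands[g]
                ),
                "".join(seqs[g]),
            )
        )

    ests = {g.gene_id: _make_ests(spec, genes[i], cluster_offsets[i], rng)
            for i, g in enumerate(genes)}

    edited_by_gene: dict[int, list[int]] = {i: [] for i in range(spec.n_genes)}
    for site in truth:
        gidx = int(site.gene_id.removeprefix("gene"))
        edited_by_gene[gidx].append(site.gene_offset)
    reads = {}
    for i, gene in enumerate(genes):
        reads[gene.gene_id] = generate_reads(
            gene,
            sorted(set(edited_by_gene[i])),
            spec.editing_rate,
            spec.read_depth,
            spec.read_length,
            rng,
        )

    scenario = Scenario(
        spec=spec,
        genes=genes,
        ests=ests,
        reads=reads,
        repeats=repeats,
        snp_positions=snp_positions,
        known_positions=known_positions,
        truth=truth,
    )
    if outdir is not None:
        _write_files(scenario, Path(outdir))
    return scenario


def _make_ests(
    spec: ScenarioSpec,
    gene: GeneRecord,
    clusters: list[tuple[str, list[int], bool]],
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Cluster-covering ESTs (edited fraction per ``editing_rate``) + background.

    Every cluster gets three dedicated covering ESTs; edited copies carry
    the edited base at all cluster members.  Background ESTs are exact gene
    substrings.  ESTs from minus-strand genes (and a random half of the
    background) are emitted reverse-complemented, since transcript evidence
    is unoriented.
    """
    L = len(gene.sequence)
    est_len = min(spec.est_length, L)
    out: list[tuple[str, str]] = []
    k = 0
    n_cov = 3
    for kind, members, _ in clusters:
        n_edited = max(1, int(round(spec.editing_rate * n_cov)))
        span_lo, span_hi = members[0], members[-1] + 1
        start = max(0, min(span_lo - (est_len - (span_hi - span_lo)) // 2, L - est_len))
        for c in range(n_cov):
            sub = list(gene.sequence[start : start + est_len])
            if c < n_edited:
                for off in members:
                    sub[off - start] = _edited_base(gene.strand)
            seq = "".join(sub)
            if gene.strand == "-" or rng.random() < 0.5:
                seq = revcomp(seq)
            out.append((f"{gene.gene_id}_est{k}", seq))
            k += 1
    for _ in range(spec.n_ests_per_gene):
        start = int(rng.integers(0, max(1, L - est_len + 1)))
        seq = gene.sequence[start : start + est_len]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        out.append((f"{gene.gene_id}_est{k}", seq))
        k += 1
    return out


def generate_reads(
    gene: GeneRecord,
    edited_positions: list[int],
    editing_fraction: float,
    depth: float,
    length: int,
    rng: np.random.Generator | int,
) -> list[tuple[str, str]]:
    """Uniform-start error-free reads with partially edited sites.

    At each edited position a covering read carries the edited base
    (transcribed G: genomic G on plus-strand genes, C on minus) with
    probability ``editing_fraction``, else the reference base.  A random
    half of the reads is emitted reverse-complemented.  Deterministic given
    the generator state.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    L = len(gene.sequence)
    if length > L:
        raise ValueError(f"read length {length} exceeds gene length {L}")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    n_reads = int(round(depth * L / length))
    edited = _edited_base(gene.strand)
    out = []
    pos_set = sorted(edited_positions)
    for i in range(n_reads):
        start = int(rng.integers(0, L - length + 1))
        sub = list(gene.sequence[start : start + length])
        for off in pos_set:
            if start <= off < start + length and rng.random() < editing_fraction:
                sub[off - start] = edited
        seq = "".join(sub)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        out.append((f"{gene.gene_id}_read{i}", seq))
    return out


# ---------------------------------------------------------------------------
# on-disk fixture writing


def _write_fasta(path: Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as out:
        for rid, seq in records:
            out.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                out.write(seq[i : i + 70] + "\n")


def _write_files(sc: Scenario, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    f = sc.files
    f["genes_fasta"] = outdir / "genes.fa"
    _write_fasta(f["genes_fasta"], [(g.gene_id, g.sequence) for g in sc.genes])
    f["genes_bed"] = outdir / "genes.bed"
    with open(f["genes_bed"], "w") as out:
        for g in sc.genes:
            iv = g.interval
            out.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{iv.strand}\n"
            )
    f["ests_fasta"] = outdir / "ests.fa"
    _write_fasta(f["ests_fasta"], [e for ests in sc.ests.values() for e in ests])
    f["reads_fasta"] = outdir / "reads.fa"
    _write_fasta(f["reads_fasta"], [r for reads in sc.reads.values() for r in reads])
    f["repeats_bed"] = outdir / "repeats.bed"
    with open(f["repeats_bed"], "w") as out:
        for iv, name, rclass, family in sc.repeats:
            out.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}"
                f"\t{name}\t{rclass}\t{family}\n"
            )
    f["snps_bed"] = outdir / "snps.bed"
    with open(f["snps_bed"], "w") as out:
        for chrom, pos in sorted(sc.snp_positions):
            out.write(f"{chrom}\t{pos}\t{pos + 1}\n")
    f["known_bed"] = outdir / "known.bed"
    with open(f["known_bed"], "w") as out:
        for chrom, pos in sorted(sc.known_positions):
            out.write(f"{chrom}\t{pos}\t{pos + 1}\tsynthetic\n")
    f["truth_tsv"] = outdir / "truth.tsv"
    with open(f["truth_tsv"], "w") as out:
        out.write(
            "chrom\tgenomic_pos\tgene_id\tgene_offset\tkind\t"
            "has_inverted_repeat\tis_snp_decoy\texpected_pass\n"
        )
        for t in sc.truth:
            out.write(
                f"{t.chrom}\t{t.genomic_pos}\t{t.gene_id}\t{t.gene_offset}\t"
                f"{t.kind}\t{int(t.has_inverted_repeat)}\t{int(t.is_snp_decoy)}\t"
                f"{int(t.expected_pass)}\n"
            )
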