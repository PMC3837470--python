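"""End-to-end orchestration of the six-step candidate detection workflow.

Step 1 aligns each gene against the transcript evidence and extracts A-G
mismatch candidates.  Steps 2-5 (clustering, repeat classification, dsRNA
probe search, SNP exclusion) are mandatory filters: a site failing any of
them is discarded, with per-step accounting.  Step 6 never discards — it
annotates surviving sites with read-support statistics, leaving sites
without sufficient coverage marked unknown.
"""

from __future__ import annotations

import configparser
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import align, detect, stats
from .io import (
    GeneRecord,
    GenomicInterval,
    KnownSiteSet,
    RepeatAnnotation,
    SnpSet,
    read_fasta,
    read_gene_bed,
    read_known_sites,
    read_reads,
    read_repeats,
    read_snps,
    write_report,
)

logger = logging.getLogger("inosite")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All input paths and thresholds of one pipeline run."""

    genes_fasta: str = ""
    genes_bed: str = ""
    ests_fasta: str = ""
    repeats_bed: str = ""
    snps: str = ""
    known_bed: str = ""
    reads: str = ""
    sam: str = ""
    output_dir: str = "inosite_out"

    cluster_min_run: int = 4
    probe_len: int = 251
    window_len: int = 4001
    min_len_frac: float = 0.85
    min_identity: float = 0.85
    est_min_aligned_length: int = 50
    est_min_identity: float = 0.90
    min_reads: int = 5
    alpha: float = 0.01
    require_g: bool = False
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    seed: int = 0

    @classmethod
    def from_ini(cls, path: str | Path) -> "PipelineConfig":
        """Load from a flat INI file; keys may live in any section."""
        parser = configparser.ConfigParser()
        read = parser.read(str(path))
        if not read:
            raise ConfigError(f"cannot read config file {path}")
        values: dict[str, str] = {}
        for section in parser.sections():
            values.update(dict(parser[section]))
        values.update(dict(parser.defaults()))
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in values:
                continue
            raw = values[f.name]
            if f.type in ("int",):
                kwargs[f.name] = int(raw)
            elif f.type in ("float",):
                kwargs[f.name] = float(raw)
            elif f.type in ("bool",):
                kwargs[f.name] = raw.strip().lower() in ("1", "true", "yes", "on")
            else:
                kwargs[f.name] = raw
        unknown = set(values) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**kwargs)

    def scoring(self) -> align.ScoringScheme:
        return align.ScoringScheme(self.match, self.mismatch, self.gap_open, self.gap_extend)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return warnings; raise :class:`ConfigError` on fatal inconsistencies."""
    if config.window_len < config.probe_len:
        raise ConfigError(
            f"window_len ({config.window_len}) must be >= probe_len ({config.probe_len})"
        )
    for key in ("cluster_min_run", "probe_len", "window_len", "min_reads"):
        if getattr(config, key) <= 0:
            raise ConfigError(f"{key} must be positive")
    for key in ("min_len_frac", "min_identity", "est_min_identity", "alpha"):
        v = getattr(config, key)
        if not (0.0 < v <= 1.0):
            raise ConfigError(f"{key} must lie in (0, 1], got {v}")
    warnings = []
    if not config.known_bed:
        warnings.append(
            "no known-sites file given: expected-frequency calibration is "
            "impossible and all significance fields will be unknown"
        )
    if not config.reads and not config.sam:
        warnings.append(
            "no reads or SAM input: read-support statistics will be unknown"
        )
    if config.reads and config.sam:
        warnings.append("both reads and SAM given; SAM placements take precedence")
    return warnings


@dataclass
class StepRecord:
    step: str
    entering: int
    surviving: int
    discarded: list[tuple[str, str]] = field(default_factory=list)  # (site, reason)

    def check(self) -> None:
        assert self.entering == self.surviving + len(self.discarded)


@dataclass
class StepAccounting:
    records: list[StepRecord] = field(default_factory=list)

    def add(self, step: str, entering: int, survivors: list, discarded: list[tuple[str, str]]):
        rec = StepRecord(step, entering, len(survivors), discarded)
        rec.check()
        self.records.append(rec)
        for site, reason in discarded:
            logger.info("discarded %s at step %s: %s", site, step, reason)

    def as_dict(self) -> dict:
        return {
            r.step: {
                "entering": r.entering,
                "surviving": r.surviving,
                "discarded": len(r.discarded),
            }
            for r in self.records
        }


@dataclass
class PipelineResult:
    sites: list[detect.MismatchSite]
    accounting: StepAccounting
    reports: dict[str, Path]
    calibration: Optional[stats.CalibrationModel]
    warnings: list[str]


def _site_key(s: detect.MismatchSite) -> str:
    return f"{s.chrom}:{s.genomic_pos + 1}"


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute Steps 1-6 and write TXT/XML/BED reports plus results JSON."""
    warnings = validate_config(config)
    for w in warnings:
        logger.warning(w)

    genes = read_gene_bed(config.genes_bed, read_fasta(config.genes_fasta))
    if not genes:
        raise ConfigError("empty gene set: at least one gene is required")
    ests = read_fasta(config.ests_fasta)
    repeats = read_repeats(config.repeats_bed) if config.repeats_bed else []
    snps = read_snps(config.snps) if config.snps else SnpSet()
    known = read_known_sites(config.known_bed) if config.known_bed else KnownSiteSet()
    scoring = config.scoring()

    # Step 1 + 2: per-alignment mismatch extraction and clustering
    per_alignment: list[list[detect.MismatchSite]] = []
    for gene in genes:
        alignments = align.align_gene_to_ests(
            gene,
            ests,
            scoring,
            min_aligned_length=config.est_min_aligned_length,
            min_identity=config.est_min_identity,
        )
        for aln in alignments:
            sites = detect.extract_ag_mismatches(aln, gene)
            clustered = detect.clustered_offsets(aln, gene, config.cluster_min_run)
            for s in sites:
                s.in_cluster = s.gene_offset in clustered
            per_alignment.append(sites)
    merged = detect.merge_sites(per_alignment)
    acct = StepAccounting()
    acct.add("1_mismatch_extraction", len(merged), merged, [])

    survivors = [s for s in merged if s.in_cluster]
    acct.add(
        "2_clustering",
        len(merged),
        survivors,
        [(_site_key(s), "not in a qualifying mismatch cluster") for s in merged if not s.in_cluster],
    )

    # Step 3: repeat-region classification (annotation, no discards)
    repeat_index = detect.build_repeat_index(repeats)
    for s in survivors:
        detect.classify_region(s, repeat_index)
    acct.add("3_region_classification", len(survivors), survivors, [])

    # Step 4: double-strand probe search
    gene_by_id = {g.gene_id: g for g in genes}
    ds_pass, ds_fail = [], []
    for s in survivors:
        gene = gene_by_id[s.gene_id]
        probe = detect.build_ds_probe(s, gene, config.probe_len, config.window_len)
        s.ds_rna = detect.dsrna_filter(
            probe, gene, config.min_len_frac, config.min_identity, scoring
        )
        (ds_pass if s.ds_rna else ds_fail).append(s)
    acct.add(
        "4_dsrna",
        len(survivors),
        ds_pass,
        [(_site_key(s), "no reverse-complement partner arm in window") for s in ds_fail],
    )
    survivors = ds_pass

    # Step 5: SNP exclusion
    kept, removed = detect.snp_filter(survivors, snps)
    acct.add(
        "5_snp_exclusion",
        len(survivors),
        kept,
        [(_site_key(s), "position catalogued as SNP") for s in removed],
    )
    survivors = kept
    detect.annotate_known(survivors, known)

    # Step 6: read support, calibration, Fisher + FDR (annotates, never discards)
    model = None
    if config.sam or config.reads:
        placements_by_gene, reads_by_id = _collect_placements(config, genes)
        cols: dict[tuple[str, int], stats.PileupColumn] = {}
        for s in survivors:
            gene = gene_by_id[s.gene_id]
            cols[(s.gene_id, s.gene_offset)] = stats.pileup_at(
                s.gene_id,
                s.gene_offset,
                placements_by_gene.get(s.gene_id, []),
                reads_by_id,
                strand=gene.strand,
            )
        known_cols = []
        for site in known.sites:
            for gene in genes:
                if gene.interval.contains(site.interval.chrom, site.interval.start):
                    off = site.interval.start - gene.interval.start
                    known_cols.append(
                        stats.pileup_at(
                            gene.gene_id,
                            off,
                            placements_by_gene.get(gene.gene_id, []),
                            reads_by_id,
                            strand=gene.strand,
                        )
                    )
        try:
            model = stats.calibrate(known_cols, config.min_reads)
        except stats.CalibrationError as exc:
            logger.warning("calibration unavailable: %s", exc)
            warnings.append(str(exc))
        stats.assign_significance(
            survivors, cols, model, config.alpha, config.min_reads, config.require_g
        )
    else:
        stats.assign_significance(survivors, {}, None, config.alpha, config.min_reads)
    acct.add("6_read_support", len(survivors), survivors, [])

    survivors.sort(key=lambda s: (s.chrom, s.genomic_pos))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    reports = {
        fmt: write_report(survivors, outdir / f"report.{fmt}", fmt)
        for fmt in ("txt", "xml", "bed")
    }
    reports["json"] = _write_results_json(survivors, outdir / "results.json")
    (outdir / "accounting.json").write_text(json.dumps(acct.as_dict(), indent=2) + "\n")
    reports["accounting"] = outdir / "accounting.json"
    if model is not None:
        model.to_json(outdir / "calibration.json")
        reports["calibration"] = outdir / "calibration.json"
    return PipelineResult(survivors, acct, reports, model, warnings)


def _collect_placements(config: PipelineConfig, genes: list[GeneRecord]):
    placements_by_gene: dict[str, list[align.ReadPlacement]] = {}
    if config.sam:
        placements, reads_by_id = align.import_sam(config.sam, genes)
        for p in placements:
            placements_by_gene.setdefault(p.gene_id, []).append(p)
    else:
        read_list = read_reads(config.reads)
        reads_by_id = dict(read_list)
        for gene in genes:
            placements_by_gene[gene.gene_id] = align.place_reads(gene, read_list)
    return placements_by_gene, reads_by_id


def _write_results_json(sites: list[detect.MismatchSite], path: Path) -> Path:
    payload = []
    for s in sites:
        d = {
            "gene_id": s.gene_id,
            "chrom": s.chrom,
            "genomic_pos": s.genomic_pos,
            "gene_offset": s.gene_offset,
            "strand": s.strand,
            "region_class": s.region_class,
            "supporting_ests": sorted(s.supporting_ests),
            "nae": s.nae,
            "in_cluster": s.in_cluster,
            "ds_rna": s.ds_rna,
            "known": s.known,
            "pvalue": s.pvalue,
            "adjusted_pvalue": s.adjusted_pvalue,
            "significant": s.significant,
        }
        if s.repeat is not None:
            d["repeat"] = {
                "chrom": s.repeat.interval.chrom,
                "start": s.repeat.interval.start,
                "end": s.repeat.interval.end,
                "strand": s.repeat.interval.strand,
                "name": s.repeat.name,
                "class": s.repeat.repeat_class,
                "family": s.repeat.family,
                "is_alu": s.repeat.is_alu,
            }
        payload.append(d)
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def load_results_json(path: str | Path) -> list[detect.MismatchSite]:
    """Rehydrate sites saved by :func:`run_pipeline` for re-export."""
    sites = []
    for d in json.loads(Path(path).read_text()):
        rep = None
        if "repeat" in d:
            r = d["repeat"]
            rep = RepeatAnnotation(
                GenomicInterval(r["chrom"], r["start"], r["end"], r["strand"]),
                r["name"],
                r["class"],
                r["family"],
                r["is_alu"],
            )
        sites.append(
            detect.MismatchSite(
                gene_id=d["gene_id"],
                genomic_pos=d["genomic_pos"],
                gene_offset=d["gene_offset"],
                chrom=d["chrom"],
                strand=d["strand"],
                supporting_ests=set(d["supporting_ests"]),
                region_class=d["region_class"],
                repeat=rep,
                in_cluster=d["in_cluster"],
                ds_rna=d["ds_rna"],
                known=d["known"],
                pvalue=d["pvalue"],
                adjusted_pvalue=d["adjusted_pvalue"],
                significant=d["significant"],
            )
        )
    return sites
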