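import numpy as np
import pytest
from hypothesis import given, strategies as st

from inosite import align, detect
from inosite.align import AlignmentColumn, PairAlignment, revcomp
from inosite.io import GeneRecord, GenomicInterval, RepeatAnnotation, SnpSet, KnownSite, KnownSiteSet
from conftest import random_seq
from oracles import cluster_retained, sw_local_score


def make_gene(seq, gene_id="g1", start=0, strand="+"):
    return GeneRecord(gene_id, GenomicInterval("chr1", start, start + len(seq), strand), seq)


def gapless_alignment(gene_seq, est_seq, est_id="e1", gene_id="g1", offset=0):
    cols = [
        AlignmentColumn(offset + i, i, g, e)
        for i, (g, e) in enumerate(zip(gene_seq, est_seq))
    ]
    return PairAlignment(gene_id, est_id, cols, score=len(cols))


class TestExtractAgMismatches:
    def test_plus_strand_a_to_g(self):
        gene = make_gene("TAAG", start=100)
        aln = gapless_alignment("TAAG", "TAGG")
        [site] = detect.extract_ag_mismatches(aln, gene)
        assert site.gene_offset == 2
        assert site.genomic_pos == 102
        assert (site.gene_base, site.est_base) == ("A", "G")

    def test_minus_strand_is_genomic_t_to_c(self):
        # genomic window CTTA on a minus gene; EST evidence CTCA genomically:
        # revcomp(CTTA)=TAAG transcribed, revcomp(CTCA)=TGAG -> A->G at
        # transcribed offset 1 == genomic offset 2
        gene = make_gene("CTTA", start=100, strand="-")
        aln = gapless_alignment("CTTA", "CTCA")
        [site] = detect.extract_ag_mismatches(aln, gene)
        assert site.genomic_pos == 102
        assert (site.gene_base, site.est_base) == ("A", "G")
        assert site.strand == "-"

    def test_identical_sequences_yield_nothing(self):
        gene = make_gene("ACGTACGT")
        assert detect.extract_ag_mismatches(gapless_alignment(gene.sequence, gene.sequence), gene) == []

    def test_sites_merge_across_ests_accumulating_nae(self):
        gene = make_gene("TAAG", start=100)
        per = [
            detect.extract_ag_mismatches(gapless_alignment("TAAG", "TAGG", est_id=e), gene)
            for e in ("e1", "e2")
        ]
        [site] = detect.merge_sites(per)
        assert site.nae == 2
        assert site.supporting_ests == {"e1", "e2"}

    def test_strand_symmetry(self):
        """Mirroring a gene to the minus strand mirrors the detected sites."""
        rng = np.random.default_rng(17)
        seq = list(random_seq(rng, 60))
        for off in (10, 20, 30, 40):
            seq[off] = "A"
        seq = "".join(seq)
        est = "".join("G" if i in (10, 20, 30, 40) else c for i, c in enumerate(seq))
        plus = make_gene(seq, start=0, strand="+")
        plus_sites = detect.extract_ag_mismatches(gapless_alignment(seq, est), plus)
        minus = make_gene(revcomp(seq), start=0, strand="-")
        minus_sites = detect.extract_ag_mismatches(
            gapless_alignment(revcomp(seq), revcomp(est)), minus
        )
        L = len(seq)
        assert {L - 1 - s.genomic_pos for s in minus_sites} == {
            s.genomic_pos for s in plus_sites
        }


def columns_from_code(code):
    """Build alignment columns from a string over {E, M, X, g, e}.

    E: A->G mismatch, M: match, X: other mismatch, g: gap in gene,
    e: gap in EST.
    """
    cols = []
    gi = ei = 0
    for c in code:
        if c == "E":
            cols.append(AlignmentColumn(gi, ei, "A", "G")); gi += 1; ei += 1
        elif c == "M":
            cols.append(AlignmentColumn(gi, ei, "C", "C")); gi += 1; ei += 1
        elif c == "X":
            cols.append(AlignmentColumn(gi, ei, "C", "T")); gi += 1; ei += 1
        elif c == "g":
            cols.append(AlignmentColumn(None, ei, "-", "A")); ei += 1
        elif c == "e":
            cols.append(AlignmentColumn(gi, None, "A", "-")); gi += 1
    return cols


def oracle_code(code):
    """Project the column code onto {E, M, X} with gaps as X."""
    return "".join("X" if c in "ge" else c for c in code)


def retained_gene_offsets(code):
    cols = columns_from_code(code)
    aln = PairAlignment("g1", "e1", cols, score=0)
    gene_len = sum(1 for c in cols if c.gene_pos is not None)
    gene = make_gene("A" * max(1, gene_len))
    return detect.clustered_offsets(aln, gene)


def oracle_gene_offsets(code):
    cols = columns_from_code(code)
    keep_col_idx = cluster_retained(oracle_code(code))
    return {cols[i].gene_pos for i in keep_col_idx}


class TestClusteringFilter:
    def test_run_of_four_all_retained(self):
        assert retained_gene_offsets("MEMEMEMEM") == {1, 3, 5, 7}

    def test_run_of_three_rejected(self):
        assert retained_gene_offsets("MEMEMEM") == set()

    def test_gap_splits_run(self):
        # 2 + 2 around a gap: neither half qualifies
        assert retained_gene_offsets("EMEgEME") == set()

    def test_other_mismatch_splits_run(self):
        assert retained_gene_offsets("EEXEEE") == set()
        assert retained_gene_offsets("EEEEXEEEE") == {0, 1, 2, 3, 5, 6, 7, 8}

    @given(st.text(alphabet="EMXge", min_size=0, max_size=60))
    def test_matches_run_enumeration_oracle(self, code):
        assert retained_gene_offsets(code) == oracle_gene_offsets(code)

    def test_filter_returns_matching_sites(self):
        gene = make_gene("A" * 10)
        code = "EMEMEMEM"
        aln = PairAlignment("g1", "e1", columns_from_code(code), score=0)
        sites = detect.extract_ag_mismatches(aln, gene)
        kept = detect.clustering_filter(sites, aln, gene)
        assert {s.gene_offset for s in kept} == {0, 2, 4, 6}


def repeat(start, end, name, rclass, family, is_alu):
    return RepeatAnnotation(GenomicInterval("chr1", start, end), name, rclass, family, is_alu)


class TestClassifyRegion:
    def setup_method(self):
        self.index = detect.build_repeat_index(
            [
                repeat(100, 400, "AluSx", "SINE", "Alu", True),
                repeat(600, 900, "L1PA3", "LINE", "L1", False),
            ]
        )

    def site_at(self, pos):
        return detect.MismatchSite("g1", pos, pos, "chr1", "+")

    def test_alu_is_t0(self):
        s = detect.classify_region(self.site_at(200), self.index)
        assert s.region_class == "T0"
        assert s.repeat.name == "AluSx"

    def test_other_repeat_is_t1(self):
        s = detect.classify_region(self.site_at(700), self.index)
        assert s.region_class == "T1"
        assert s.repeat.repeat_class == "LINE"

    def test_outside_repeats_is_t2(self):
        s = detect.classify_region(self.site_at(500), self.index)
        assert s.region_class == "T2"
        assert s.repeat is None


class TestBuildDsProbe:
    def test_t2_probe_251_window_4001(self):
        rng = np.random.default_rng(1)
        gene = make_gene(random_seq(rng, 12000))
        site = detect.MismatchSite("g1", 5000, 5000, "chr1", "+")
        probe = detect.build_ds_probe(site, gene)
        assert probe.probe_length == 251
        assert probe.window_end - probe.window_start == 4001
        assert probe.sequence == revcomp(gene.sequence[4875:5126])

    def test_t0_probe_spans_alu(self):
        rng = np.random.default_rng(2)
        gene = make_gene(random_seq(rng, 2000))
        site = detect.MismatchSite("g1", 500, 500, "chr1", "+", region_class="T0")
        site.repeat = repeat(400, 700, "AluSx", "SINE", "Alu", True)
        probe = detect.build_ds_probe(site, gene)
        assert probe.probe_length == 300
        assert probe.sequence == revcomp(gene.sequence[400:700])

    def test_boundary_truncation_near_gene_start(self):
        rng = np.random.default_rng(3)
        gene = make_gene(random_seq(rng, 2000))
        site = detect.MismatchSite("g1", 60, 60, "chr1", "+")
        probe = detect.build_ds_probe(site, gene)
        assert probe.probe_length == 186  # 60 left flank + site + 125 right
        assert probe.window_start == 0


class TestMinQualifyingLength:
    def test_worked_example_251_gives_214(self):
        assert detect.min_qualifying_length(251) == 214

    @pytest.mark.parametrize("n,expected", [(300, 255), (186, 159), (1, 1)])
    def test_ceiling_rule(self, n, expected):
        assert detect.min_qualifying_length(n) == expected


def t2_probe(gene, offset):
    site = detect.MismatchSite("g1", offset, offset, "chr1", "+")
    return detect.build_ds_probe(site, gene)


class TestDsrnaFilter:
    def test_exact_inverted_copy_downstream_passes(self):
        rng = np.random.default_rng(4)
        seq = list(random_seq(rng, 2000))
        src = "".join(seq[375:626])  # probe source for a site at offset 500
        seq[1100:1351] = list(revcomp(src))
        gene = make_gene("".join(seq))
        assert detect.dsrna_filter(t2_probe(gene, 500), gene) is True

    def test_random_window_fails(self):
        rng = np.random.default_rng(5)
        gene = make_gene(random_seq(rng, 2000))
        probe = t2_probe(gene, 500)
        assert detect.dsrna_filter(probe, gene) is False
        # oracle: a qualifying hit (>=214 columns at >=85% identity) would
        # score at least 214*(0.85 - 0.15*2) ~ 117; nothing comes close
        window = gene.sequence[probe.window_start : probe.window_end]
        assert sw_local_score(probe.sequence, window) < 100

    @pytest.mark.parametrize("arm_len,expected", [(214, True), (213, False)])
    def test_boundary_at_214_of_251(self, arm_len, expected):
        rng = np.random.default_rng(6)
        seq = list(random_seq(rng, 2600))
        site_off = 500
        src = "".join(seq[site_off - 125 : site_off + 126])
        probe_seq = revcomp(src)
        arm = probe_seq[-arm_len:]  # prefix of the source, revcomped
        arm_start = 1400
        seq[arm_start : arm_start + arm_len] = list(arm)
        # block left-extension of the planted arm with forced mismatches
        for k in range(1, 4):
            idx = len(probe_seq) - arm_len - k
            if idx >= 0:
                bad = {probe_seq[idx]}
                choice = next(b for b in "ACGT" if b not in bad)
                seq[arm_start - k] = choice
        gene = make_gene("".join(seq))
        probe = t2_probe(gene, site_off)
        assert probe.probe_length == 251
        assert detect.dsrna_filter(probe, gene) is expected

    def test_planted_arm_recovered_but_shuffled_window_fails(self):
        """Planting an exact inverted repeat flips the filter outcome."""
        rng = np.random.default_rng(8)
        for trial in range(5):
            seq = list(random_seq(rng, 2200))
            src = "".join(seq[275:526])
            gene_plain = make_gene("".join(seq))
            assert detect.dsrna_filter(t2_probe(gene_plain, 400), gene_plain) is False
            seq[900:1151] = list(revcomp(src))
            gene = make_gene("".join(seq))
            assert detect.dsrna_filter(t2_probe(gene, 400), gene) is True

    def test_self_overlap_is_not_a_partner(self):
        # a reverse-complement palindromic source arm matches itself; the
        # self-hit must not count as a partner arm
        rng = np.random.default_rng(9)
        seq = list(random_seq(rng, 2000))
        half = random_seq(rng, 125)
        pal = half + "A" + revcomp(half)  # 251-nt revcomp palindrome
        seq[375:626] = list(pal)
        gene = make_gene("".join(seq))
        assert detect.dsrna_filter(t2_probe(gene, 500), gene) is False


class TestSnpAndKnown:
    def sites(self, positions):
        return [detect.MismatchSite("g1", p, p, "chr1", "+") for p in positions]

    def test_snp_position_removed_neighbor_kept(self):
        kept, removed = detect.snp_filter(self.sites([100, 101]), SnpSet(frozenset({("chr1", 100)})))
        assert [s.genomic_pos for s in kept] == [101]
        assert [s.genomic_pos for s in removed] == [100]
        assert removed[0].is_snp is True

    def test_empty_snpset_is_identity(self):
        sites = self.sites([1, 2, 3])
        kept, removed = detect.snp_filter(sites, SnpSet())
        assert kept == sites and removed == []

    def test_known_annotation_only(self):
        known = KnownSiteSet([KnownSite(GenomicInterval("chr1", 100, 101))])
        sites = detect.annotate_known(self.sites([100, 200]), known)
        assert [s.known for s in sites] == [True, False]
        # annotation never filters
        assert len(sites) == 2

    def test_empty_known_set(self):
        sites = detect.annotate_known(self.sites([100]), KnownSiteSet())
        assert sites[0].known is False
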