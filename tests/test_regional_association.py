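"""Region classes, tiling, per-tile statistics and Spearman tables."""

import numpy as np
import pandas as pd
import pytest

from methmut import regional_association as ra
from methmut.genomic_io import GenomeSequence, Interval
from methmut.stages import STAGES
from methmut.variant_catalog import MutationType


class TestPromoterRule:
    def test_plus_strand(self):
        # TSS at 1-based 5001 -> 0-based 5000 -> promoter [4000, 5200)
        genes = [Interval("chr1", 5000, 9000, "+", "g")]
        prom = ra.promoter_intervals(genes, {"chr1": 20000})
        assert prom.iloc[0][["Start", "End"]].tolist() == [4000, 5200]

    def test_minus_strand_mirror(self):
        # TSS at 1-based 5000 (gene end) -> promoter [4800, 6000)
        genes = [Interval("chr1", 1000, 5000, "-", "g")]
        prom = ra.promoter_intervals(genes, {"chr1": 20000})
        assert prom.iloc[0][["Start", "End"]].tolist() == [4800, 6000]

    def test_clipped_to_chromosome(self):
        genes = [Interval("chr1", 500, 2000, "+", "g")]
        prom = ra.promoter_intervals(genes, {"chr1": 20000})
        assert prom.iloc[0]["Start"] == 0

    def test_strandless_gene_errors(self):
        with pytest.raises(ValueError, match="strand"):
            ra.promoter_intervals([Interval("chr1", 100, 200, ".", "g")], {"chr1": 1000})


def _mk(intervals):
    return [Interval("chr1", s, e, st, "x") for s, e, st in intervals]


class TestRegionAnnotation:
    LEN = {"chr1": 100_000}

    def build(self, genes=None, exons=None, cgis=None, enhancers=None, repeats=None):
        return ra.build_region_annotation(
            genes or [], exons or [], cgis or [], enhancers or [], repeats or [], self.LEN
        )

    def test_enhancer_loses_promoter_overlap(self):
        # promoter of + gene with TSS 1700 (0-based): [700, 1900)
        genes = _mk([(1700, 9000, "+")])
        classes = self.build(genes=genes, enhancers=_mk([(0, 1000, ".")]))
        enh = classes["enhancer"]
        assert enh.iloc[0][["Start", "End"]].tolist() == [0, 700]

    def test_repeat_excluded_from_exon(self):
        genes = _mk([(20000, 30000, "+")])
        exons = _mk([(20000, 21000, "+")])
        repeats = _mk([(20500, 20600, ".")])
        classes = self.build(genes=genes, exons=exons, repeats=repeats)
        exon = classes["exon"]
        # exon loses its promoter overlap [20000, 20200) by precedence, then the repeat
        assert [tuple(r) for r in exon[["Start", "End"]].to_numpy()] == [
            (20200, 20500), (20600, 21000)]

    def test_intergenic_is_complement(self):
        genes = _mk([(20000, 30000, "+")])
        classes = self.build(genes=genes)
        inter = classes["intergenic"]
        # complement of gene + its promoter [19000, 20200)
        assert [tuple(r) for r in inter[["Start", "End"]].to_numpy()] == [(0, 19000), (30000, 100000)]

    def test_pairwise_disjointness_and_coverage(self, sim_small):
        """On generated overlapping tracks, the eight classes are pairwise
        disjoint (except intragenic = exon + intron) and, with repeat and
        intergenic, cover every base."""
        tracks = sim_small["tracks"]
        lengths = sim_small["genome"].lengths
        classes = ra.build_region_annotation(
            tracks["genes"], tracks["exons"], tracks["cgis"],
            tracks["enhancers"], tracks["repeats"], lengths
        )
        names = [n for n in classes if n != "intragenic"]
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if {a, b} <= {"exon", "intron"}:
                    pass  # disjoint too, checked below
                assert ra.intersection_size(classes[a], classes[b]) == 0, (a, b)
        # intragenic decomposes into exon + intron
        assert ra.intersection_size(classes["exon"], classes["intron"]) == 0
        exon_intron = ra.union_intervals(classes["exon"], classes["intron"])
        intra = classes["intragenic"]
        assert (intra["End"] - intra["Start"]).sum() == (exon_intron["End"] - exon_intron["Start"]).sum()
        # coverage of the whole genome
        everything = ra.union_intervals(*classes.values())
        assert (everything["End"] - everything["Start"]).sum() == sum(lengths.values())

    def test_generated_tracks_really_overlap(self, sim_small):
        """The generator must exercise the eliminations: promoter-enhancer
        and CGI-enhancer overlaps exist in the raw tracks."""
        tracks = sim_small["tracks"]
        lengths = sim_small["genome"].lengths
        prom = ra.promoter_intervals(tracks["genes"], lengths)
        assert ra.intersection_size(prom, tracks["enhancers"]) > 0
        assert ra.intersection_size(tracks["cgis"], tracks["enhancers"]) > 0
        assert ra.intersection_size(tracks["genes"], tracks["repeats"]) > 0


class TestTiling:
    def test_consecutive_windows_with_partial_tail(self):
        tiles = ra.tile_regions(pd.DataFrame(
            {"Chromosome": ["chr1"], "Start": [0], "End": [2500]}), window=1000)
        assert [tuple(r) for r in tiles[["Start", "End"]].to_numpy()] == [(0, 1000), (1000, 2000), (2000, 2500)]

    def test_interval_shorter_than_window(self):
        tiles = ra.tile_regions(pd.DataFrame(
            {"Chromosome": ["chr1"], "Start": [100], "End": [400]}), window=1000)
        assert [tuple(r) for r in tiles[["Start", "End"]].to_numpy()] == [(100, 400)]

    def test_drop_partial(self):
        tiles = ra.tile_regions(pd.DataFrame(
            {"Chromosome": ["chr1"], "Start": [0], "End": [2500]}), window=1000, drop_partial=True)
        assert len(tiles) == 2

    def test_chromosomal_mode(self):
        tiles = ra.tile_chromosomes({"chr1": 2_500_000}, window=1_000_000)
        assert len(tiles) == 3

    def test_bad_window_errors(self):
        with pytest.raises(ValueError):
            ra.tile_regions(pd.DataFrame({"Chromosome": [], "Start": [], "End": []}), window=0)


class TestTileStats:
    def _study(self):
        # 60 bp genome, CpGs at 0-based 2, 10, 14, 20, 24, 30 (C positions)
        seq = list("A" * 60)
        cpg0 = [2, 10, 14, 20, 24, 30]
        for p in cpg0:
            seq[p], seq[p + 1] = "C", "G"
        seq[40] = "C"  # non-CpG C
        seq[45] = "G"  # non-CpG G
        genome = GenomeSequence({"chr1": "".join(seq)})
        frames = {}
        for j, s in enumerate(STAGES):
            frames[s] = pd.DataFrame({
                "chrom": "chr1", "pos": np.array(cpg0) + 1, "strand": "+", "context": "CpG",
                "methylated_reads": [j % 3, 1, 2, 3, 4, 5], "total_reads": 5,
            })
        catalog = pd.DataFrame({
            "chrom": "chr1",
            "pos": [3, 11, 41],
            "ref": ["C", "C", "C"],
            "alt": ["T", "T", "T"],
            "mutation_type": [MutationType.CPG_C_T.value, MutationType.CPG_C_T.value,
                              MutationType.NONCPG_C_T.value],
            "cpg_site_pos": [3, 11, -1],
        })
        return genome, frames, catalog

    def test_counts_and_densities_vs_naive(self):
        genome, frames, catalog = self._study()
        tiles = pd.DataFrame({"Chromosome": ["chr1"], "Start": [0], "End": [60]})
        out = ra.tile_stats(tiles, genome, frames, catalog, min_cpg=5)
        row = out.iloc[0]
        assert row["cpg_count"] == 6
        assert row["cpg_cg_bases"] == 12
        # naive: non-CpG C/G = all C or G bases minus CpG bases
        seq = genome.sequences["chr1"]
        naive_noncpg = sum(1 for i, b in enumerate(seq) if b in "CG") - 12
        assert row["noncpg_cg_bases"] == naive_noncpg == 2
        assert row["cpg_ct_snps"] == 2 and row["cpg_ct_density"] == pytest.approx(2 / 12)
        assert row["noncpg_ct_snps"] == 1 and row["noncpg_ct_density"] == pytest.approx(1 / 2)
        # weighted methylation equals the read-sum ratio
        assert row["meth_sperm"] == pytest.approx((0 + 1 + 2 + 3 + 4 + 5) / 30)

    def test_low_cpg_tiles_dropped(self):
        genome, frames, catalog = self._study()
        tiles = pd.DataFrame({"Chromosome": ["chr1", "chr1"], "Start": [0, 32], "End": [32, 60]})
        out = ra.tile_stats(tiles, genome, frames, catalog, min_cpg=5)
        assert len(out) == 1 and out.iloc[0]["Start"] == 0

    def test_straddling_cpg_contributes_in_tile_base_only(self):
        genome, frames, catalog = self._study()
        # boundary at 31 splits the CpG with C at 0-based 30
        tiles = pd.DataFrame({"Chromosome": ["chr1"], "Start": [0], "End": [31]})
        out = ra.tile_stats(tiles, genome, frames, catalog, min_cpg=1)
        assert out.iloc[0]["cpg_count"] == 6
        assert out.iloc[0]["cpg_cg_bases"] == 11  # G at 31 excluded

    def test_twenty_tile_fixture_matches_naive_recount(self):
        """Densities on a 20-tile random fixture equal an independent
        naive per-base recount."""
        rng = np.random.default_rng(21)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        genome = GenomeSequence({"chr1": seq})
        frames = {s: pd.DataFrame({
            "chrom": [], "pos": [], "strand": [], "context": [],
            "methylated_reads": [], "total_reads": []}) for s in STAGES}
        # random CpG C>T SNPs at actual CpG sites
        cpg0 = [i for i in range(1999) if seq[i] == "C" and seq[i + 1] == "G"]
        chosen = rng.choice(cpg0, size=min(10, len(cpg0)), replace=False)
        catalog = pd.DataFrame({
            "chrom": "chr1", "pos": np.array(chosen) + 1, "ref": "C", "alt": "T",
            "mutation_type": MutationType.CPG_C_T.value, "cpg_site_pos": np.array(chosen) + 1,
        })
        tiles = ra.tile_regions(pd.DataFrame(
            {"Chromosome": ["chr1"], "Start": [0], "End": [2000]}), window=100)
        assert len(tiles) == 20
        out = ra.tile_stats(tiles, genome, frames, catalog, min_cpg=0)
        for _, row in out.iterrows():
            s, e = int(row["Start"]), int(row["End"])
            n_cpg = sum(1 for i in range(s, min(e, 1999)) if seq[i] == "C" and seq[i + 1] == "G")
            cpg_bases = sum(
                1 for i in range(s, e)
                if (seq[i] == "C" and i < 1999 and seq[i + 1] == "G")
                or (seq[i] == "G" and i > 0 and seq[i - 1] == "C")
            )
            n_snp = sum(1 for p in chosen if s <= p < e)
            assert row["cpg_count"] == n_cpg
            assert row["cpg_cg_bases"] == cpg_bases
            assert row["cpg_ct_snps"] == n_snp


class TestRegionCorrelations:
    def _table(self, meth, dens, group="promoter"):
        df = pd.DataFrame({"region_class": group,
                           "cpg_ct_density": dens, "noncpg_ct_density": dens})
        for s in STAGES:
            df[f"meth_{s}"] = meth
        return df

    def test_perfect_concordance(self):
        out = ra.region_correlations(self._table([1, 2, 3, 4, 5] * 2, [1, 2, 3, 4, 5] * 2), min_tiles=5)
        sperm = out[(out["stage"] == "sperm") & (out["measure"] == "CpG")]
        assert sperm["spearman_rho"].iloc[0] == pytest.approx(1.0)

    def test_perfect_discordance(self):
        out = ra.region_correlations(
            self._table([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]), min_tiles=5)
        assert out["spearman_rho"].iloc[0] == pytest.approx(-1.0)

    def test_ties_match_rank_formula_oracle(self):
        """Rho on tied vectors equals the average-rank Pearson formula."""
        meth = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0])
        dens = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0])
        out = ra.region_correlations(self._table(meth, dens), min_tiles=5)
        rho = out["spearman_rho"].iloc[0]

        def avg_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v), dtype=float)
            sv = v[order]
            i = 0
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = np.mean(np.arange(i, j) + 1)
                i = j
            return ranks
        rm, rd = avg_ranks(meth), avg_ranks(dens)
        oracle = (((rm - rm.mean()) * (rd - rd.mean())).sum()
                  / np.sqrt(((rm - rm.mean()) ** 2).sum() * ((rd - rd.mean()) ** 2).sum()))
        assert rho == pytest.approx(oracle, rel=1e-12)

    def test_too_few_tiles_reported_missing(self):
        out = ra.region_correlations(self._table([1, 2, 3], [1, 2, 3]), min_tiles=10)
        assert out["spearman_rho"].isna().all()

    def test_constant_vector_warns_and_missing(self):
        with pytest.warns(UserWarning, match="constant"):
            out = ra.region_correlations(self._table([1] * 12, list(range(12))), min_tiles=10)
        assert out["spearman_rho"].isna().all()
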