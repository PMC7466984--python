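"""SNP-density mutability: categories, trends, tests, dynamic patterns."""

import numpy as np
import pandas as pd
import pytest

from methmut import methylome as my
from methmut import mutability as mb
from methmut.stages import STAGES
from methmut.variant_catalog import MutationType
from tests.conftest import make_stage_frames


def _catalog(rows):
    """rows: (pos, ref, mutation_type) on chr1; cpg_site_pos from ref."""
    return pd.DataFrame({
        "chrom": "chr1",
        "pos": [r[0] for r in rows],
        "ref": [r[1] for r in rows],
        "alt": "T",
        "mutation_type": [r[2].value for r in rows],
        "cpg_site_pos": [r[0] if r[1] == "C" else r[0] - 1 for r in rows],
    })


class TestSnpDensity:
    def test_two_snps_on_forty_sites(self):
        cat = _catalog([(10, "C", MutationType.CPG_C_T), (20, "C", MutationType.CPG_C_T)])
        sites = np.arange(1, 41)
        n_sites, n_snps, density = mb.snp_density(sites, mb.cpg_snp_sites(cat))
        assert (n_sites, n_snps, density) == (40, 2, 0.05)

    def test_noncpg_snp_not_counted(self):
        cat = _catalog([(10, "C", MutationType.NONCPG_C_T)])
        _, n_snps, density = mb.snp_density([10, 20], mb.cpg_snp_sites(cat))
        assert n_snps == 0 and density == 0.0

    def test_deduplication_both_cytosines_count_once(self):
        # C at 10 and G at 11 of the same CpG: one mutated site
        cat = _catalog([(10, "C", MutationType.CPG_C_T), (11, "G", MutationType.CPG_C_A)])
        _, n_snps, density = mb.snp_density([10, 20, 30, 40], mb.cpg_snp_sites(cat))
        assert n_snps == 1 and density == 0.25

    def test_brute_force_oracle(self):
        """Density on a 12-site fixture equals exhaustive per-site
        enumeration."""
        rng = np.random.default_rng(5)
        sites = np.sort(rng.choice(200, size=12, replace=False)) + 1
        snp_at = rng.choice(sites, size=3, replace=False)
        cat = _catalog([(int(p), "C", MutationType.CPG_C_T) for p in snp_at])
        n_sites, n_snps, density = mb.snp_density(sites, mb.cpg_snp_sites(cat))
        # oracle: naive loop
        naive = sum(1 for s in sites if s in set(snp_at))
        assert n_snps == naive == 3
        assert density == naive / len(sites) == 0.25

    def test_empty_category_errors(self):
        with pytest.raises(ZeroDivisionError):
            mb.snp_density([], np.array([], dtype=np.int64))


def _annotated(levels, positions, calls=None):
    n = len(positions)
    df = pd.DataFrame({
        "chrom": "chr1", "pos": positions, "strand": "+", "context": "CpG",
        "methylated_reads": np.rint(np.asarray(levels) * 10).astype(int),
        "total_reads": 10, "level": levels,
    })
    df["call"] = calls if calls is not None else np.where(np.asarray(levels) > 0.05, "methylated", "unmethylated")
    df["bin"] = my.assign_bin(levels)
    df.loc[df["call"] != "methylated", "bin"] = ""
    df["three_state"] = my.three_state(levels)
    return df


class TestStageBinProfile:
    def test_additivity_and_oracle(self):
        rng = np.random.default_rng(7)
        n = 1000
        positions = np.arange(1, n + 1) * 7
        levels = rng.beta(0.8, 0.8, size=n).round(2)
        ann = _annotated(levels, positions)
        mutated = rng.random(n) < 0.02 + 0.1 * levels
        cat = _catalog([(int(p), "C", MutationType.CPG_C_T) for p in positions[mutated]])
        profile = mb.stage_bin_profile(ann, cat, "sperm")
        tab = profile.table.set_index("category")
        # additivity over calls and bins
        assert tab.loc["methylated", "n_sites"] + tab.loc["unmethylated", "n_sites"] == tab.loc["all", "n_sites"]
        bins = [b for b in my.BIN_LABELS if b in tab.index]
        assert tab.loc[bins, "n_sites"].sum() == tab.loc["methylated", "n_sites"]
        assert tab.loc[bins, "n_snps"].sum() == tab.loc["methylated", "n_snps"]
        # independent naive loop over every category
        snp_set = set(positions[mutated])
        for cat_name, mask in [
            ("all", np.ones(n, bool)),
            ("methylated", (ann["call"] == "methylated").to_numpy()),
            ("unmethylated", (ann["call"] == "unmethylated").to_numpy()),
        ]:
            naive = sum(1 for p in positions[mask] if p in snp_set) / mask.sum()
            assert tab.loc[cat_name, "density"] == pytest.approx(naive, abs=0)

    def test_degenerate_all_unmethylated_drops_categories(self):
        ann = _annotated([0.0, 0.0, 0.01], [10, 20, 30],
                         calls=["unmethylated"] * 3)
        cat = _catalog([(10, "C", MutationType.CPG_C_T)])
        with pytest.warns(UserWarning):
            profile = mb.stage_bin_profile(ann, cat, "sperm")
        assert "methylated" not in set(profile.table["category"])


class TestBinTrend:
    def _profile(self, densities):
        rows = [("all", 100, 10, 0.1), ("methylated", 80, 9, 0.1125), ("unmethylated", 20, 1, 0.05)]
        rows += [(lbl, 16, int(d * 16), d) for lbl, d in zip(my.BIN_LABELS, densities)]
        return mb.StageBinProfile("sperm", pd.DataFrame(rows, columns=["category", "n_sites", "n_snps", "density"]))

    def test_perfect_linearity(self):
        r, p = mb.bin_trend_correlation(self._profile([0.01, 0.02, 0.03, 0.04, 0.05]))
        assert r == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        dens = np.array([0.05, 0.07, 0.10, 0.14, 0.18])
        x = np.array(my.BIN_MIDPOINTS)
        expected = (((x - x.mean()) * (dens - dens.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum() * ((dens - dens.mean()) ** 2).sum()))
        r, _ = mb.bin_trend_correlation(self._profile(dens))
        assert r == pytest.approx(expected, rel=1e-12)

    def test_constant_densities_error(self):
        with pytest.raises(ValueError, match="constant"):
            mb.bin_trend_correlation(self._profile([0.1] * 5))

    def test_missing_bin_listed(self):
        profile = self._profile([0.1, 0.2, 0.3, 0.4, 0.5])
        profile.table = profile.table[profile.table["category"] != "40-60%"]
        with pytest.raises(ValueError, match="40-60%"):
            mb.bin_trend_correlation(profile)


class TestMethVsUnmethTest:
    def _profile(self, m_snps, m_sites, u_snps, u_sites):
        rows = [("methylated", m_sites, m_snps, m_snps / m_sites),
                ("unmethylated", u_sites, u_snps, u_snps / u_sites)]
        return mb.StageBinProfile("sperm", pd.DataFrame(rows, columns=["category", "n_sites", "n_snps", "density"]))

    def test_hand_computed_yates_chi2(self):
        """[[50,950],[5,995]] against the Yates-corrected formula."""
        chi2, p = mb.meth_vs_unmeth_test(self._profile(50, 1000, 5, 1000))
        table = np.array([[50.0, 950.0], [5.0, 995.0]])
        n = table.sum()
        row, col = table.sum(1), table.sum(0)
        expected = np.outer(row, col) / n
        hand = (((np.abs(table - expected) - 0.5) ** 2) / expected).sum()
        assert chi2 == pytest.approx(hand, rel=1e-12)
        assert p < 1e-8

    def test_identical_rates_p_near_one(self):
        _, p = mb.meth_vs_unmeth_test(self._profile(10, 1000, 10, 1000))
        assert p == pytest.approx(1.0)

    def test_empty_group_errors(self):
        profile = self._profile(10, 1000, 1, 1000)
        profile.table = profile.table[profile.table["category"] != "unmethylated"]
        with pytest.raises(ValueError):
            mb.meth_vs_unmeth_test(profile)


class TestPatterns:
    def test_codes_from_levels(self):
        levels = np.vstack([
            np.full(13, 0.9),                       # all H
            np.r_[0.9, np.full(12, 0.1)],           # sperm H, rest U
            np.full(13, 0.5),                       # all M
        ])
        common = pd.DataFrame({"chrom": "chr1", "pos": [10, 20, 30]})
        for j, s in enumerate(STAGES):
            common[f"level_{s}"] = levels[:, j]
        patterned, n_unique = mb.enumerate_patterns(common)
        assert patterned["pattern"].tolist() == ["H" * 13, "H" + "U" * 12, "M" * 13]
        assert n_unique == 3

    def test_unique_count_with_duplicates(self):
        common = pd.DataFrame({"chrom": "chr1", "pos": [10, 20, 30]})
        for s in STAGES:
            common[f"level_{s}"] = [0.9, 0.9, 0.1]
        _, n_unique = mb.enumerate_patterns(common)
        assert n_unique == 2

    def test_missing_level_errors(self):
        common = pd.DataFrame({"chrom": "chr1", "pos": [10]})
        for s in STAGES:
            common[f"level_{s}"] = [0.5]
        common.loc[0, "level_ICM"] = np.nan
        with pytest.raises(ValueError):
            mb.enumerate_patterns(common)

    def _patterned(self, codes, start=1):
        pos = np.arange(start, start + len(codes)) * 10
        return pd.DataFrame({"chrom": "chr1", "pos": pos, "pattern": codes})

    def test_min_snp_filter_and_ranking(self):
        codes = ["H" * 13] * 100 + ["U" * 13] * 100 + ["M" * 13] * 30
        patterned = self._patterned(codes)
        # 12 SNPs on H-sites, 10 on U-sites, 9 on M-sites
        snp_pos = (list(patterned["pos"][:12]) + list(patterned["pos"][100:110])
                   + list(patterned["pos"][200:209]))
        cat = _catalog([(int(p), "C", MutationType.CPG_C_T) for p in snp_pos])
        full, top = mb.pattern_mutability(patterned, cat, min_snps=10)
        assert len(full) == 3  # full table keeps everything
        assert top["pattern"].tolist() == ["H" * 13, "U" * 13]  # M excluded: 9 < 10
        assert top["density"].tolist() == [0.12, 0.10]

    def test_tie_break_by_sites_then_code(self):
        codes = ["H" * 13] * 20 + ["M" * 13] * 10 + ["U" * 13] * 10
        patterned = self._patterned(codes)
        snp_pos = list(patterned["pos"][:2]) + list(patterned["pos"][20:21]) + list(patterned["pos"][30:31])
        cat = _catalog([(int(p), "C", MutationType.CPG_C_T) for p in snp_pos])
        full, _ = mb.pattern_mutability(patterned, cat, min_snps=0)
        # densities: H 0.1, M 0.1, U 0.1 -> order by n_sites desc, then code
        assert full["pattern"].tolist() == ["H" * 13, "M" * 13, "U" * 13]

    def test_site_conservation(self):
        codes = ["H" * 13] * 7 + ["U" * 13] * 5
        patterned = self._patterned(codes)
        cat = _catalog([(10, "C", MutationType.CPG_C_T)])
        full, _ = mb.pattern_mutability(patterned, cat, min_snps=0)
        assert full["n_sites"].sum() == len(patterned)

    def test_empty_ranking_warns(self):
        patterned = self._patterned(["H" * 13] * 5)
        cat = _catalog([(10, "C", MutationType.CPG_C_T)])
        with pytest.warns(UserWarning, match="ranking is empty"):
            _, top = mb.pattern_mutability(patterned, cat, min_snps=10)
        assert top.empty
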