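"""Method-agreement statistics: overlap, similarity, resolution, correlation."""

import math

import numpy as np
import pandas as pd
import pytest

from apiflora.compare import (
    TaxonomyIndex,
    _match_rank,
    abundance_correlations,
    bonferroni,
    frequency_table,
    harmonize,
    mean_sd,
    overlap_breakdown,
    percent,
    pooled_ttest,
    repeat_similarity,
    resolution_profile,
    spearman,
    spearman_pvalue,
)
from apiflora.model import PollenCounts, SampleComposition, Taxon
from oracles import (
    best_matching_oracle,
    perm_pvalue_oracle,
    pooled_t_oracle,
    spearman_oracle,
)

TAX = TaxonomyIndex(
    genus_to_family={
        "rubus": "Rosaceae", "crataegus": "Rosaceae", "quercus": "Fagaceae",
        "trifolium": "Fabaceae",
    }
)


def sp(name):
    return Taxon(name=name, rank="species")


def gn(name):
    return Taxon(name=name, rank="genus")


def fm(name):
    return Taxon(name=name, rank="family")


class TestHarmonize:
    def test_species_species_match(self):
        pairs, d, m = harmonize([sp("Rubus fruticosus")], [sp("Rubus fruticosus")])
        assert len(pairs) == 1 and not d and not m

    def test_species_genus_containment(self):
        pairs, d, m = harmonize([sp("Quercus robur")], [gn("Quercus")])
        assert pairs == [(sp("Quercus robur"), gn("Quercus"))]

    def test_genus_family_needs_taxonomy(self):
        pairs, _, _ = harmonize([gn("Rubus")], [fm("Rosaceae")], TAX)
        assert len(pairs) == 1
        # a missing taxonomy cannot attempt the cross-rank match at all
        pairs, d, m = harmonize([gn("Rubus")], [fm("Rosaceae")])
        assert not pairs
        # a taxonomy that lacks the genus raises, naming the taxon
        with pytest.raises(KeyError, match="Salix"):
            harmonize([gn("Salix")], [fm("Salicaceae")], TAX)

    def test_finest_rank_preferred(self):
        # the DNA species should pair with the identical microscopy species,
        # leaving the genus record to the DNA genus
        dna = [sp("Rubus fruticosus"), gn("Rubus")]
        micro = [gn("Rubus"), sp("Rubus fruticosus")]
        pairs, d, m = harmonize(dna, micro)
        assert (sp("Rubus fruticosus"), sp("Rubus fruticosus")) in pairs
        assert (gn("Rubus"), gn("Rubus")) in pairs

    def test_matching_is_maximal_vs_exhaustive_oracle(self):
        rng = np.random.default_rng(73)
        genera = ["Rubus", "Crataegus", "Quercus", "Trifolium"]
        for _ in range(60):
            def rand_taxa(n):
                out = []
                for _ in range(n):
                    g = genera[int(rng.integers(0, 4))]
                    r = rng.random()
                    if r < 0.4:
                        out.append(sp(f"{g} sp{int(rng.integers(0, 2))}"))
                    elif r < 0.8:
                        out.append(gn(g))
                    else:
                        out.append(fm(TAX.genus_to_family[g.lower()]))
                return list(dict.fromkeys(out))

            dna = rand_taxa(int(rng.integers(1, 6)))
            micro = rand_taxa(int(rng.integers(1, 6)))
            pairs, _, _ = harmonize(dna, micro, TAX)
            expected = best_matching_oracle(
                dna, micro, lambda a, b: _match_rank(a, b, TAX)
            )
            assert len(pairs) == expected


class TestOverlapBreakdown:
    def _micro(self, sample, rows):
        return PollenCounts(table={sample: rows})

    def test_identical_single_taxon(self):
        comp = SampleComposition("H", {sp("Rubus fruticosus"): 100})
        ov = overlap_breakdown(comp, self._micro("H", {sp("Rubus fruticosus"): 50}))
        assert ov.similarity_pct == 100

    def test_disjoint_lists(self):
        comp = SampleComposition("H", {sp("Rubus fruticosus"): 100})
        ov = overlap_breakdown(comp, self._micro("H", {sp("Trifolium repens"): 50}))
        assert ov.similarity_pct == 0

    def test_22_shared_of_24_gives_92(self):
        shared = [sp(f"Genus{i} alpha") for i in range(22)]
        comp = SampleComposition("H", {t: 100 for t in shared + [sp("OnlyDna alpha")]})
        micro_rows = {t: 10 for t in shared}
        micro_rows[sp("OnlyMicro alpha")] = 5
        ov = overlap_breakdown(comp, self._micro("H", micro_rows))
        assert len(ov.both) == 22 and ov.n_taxa == 24
        assert ov.similarity_pct == 92

    def test_single_grain_subdivision_partitions_universe(self):
        comp = SampleComposition("H", {sp("A a"): 100, sp("B b"): 50})
        ov = overlap_breakdown(
            comp, self._micro("H", {sp("A a"): 30, sp("C c"): 1, sp("D d"): 4})
        )
        assert len(ov.both) == 1
        assert ov.micro_only_single == {sp("C c")}
        assert ov.micro_only_multi == {sp("D d")}
        assert ov.dna_only == {sp("B b")}
        assert ov.n_taxa == 4


class TestRepeatSimilarity:
    def test_dna_replicates_give_64(self):
        shared = [sp(f"S{i} x") for i in range(18)]
        a = shared + [sp(f"A{i} x") for i in range(6)]    # 24 taxa
        b = shared + [sp(f"B{i} x") for i in range(4)]    # 22 taxa
        assert repeat_similarity(a, b) == 64

    def test_micro_replicates_give_28(self):
        shared = [sp(f"S{i} x") for i in range(13)]
        a = shared + [sp(f"A{i} x") for i in range(18)]   # 31 taxa
        b = shared + [sp(f"B{i} x") for i in range(15)]   # 28 taxa
        assert repeat_similarity(a, b) == 28

    def test_identical_lists_100_and_symmetry(self):
        a = [sp("A a"), gn("B"), fm("Rosaceae")]
        assert repeat_similarity(a, list(a)) == 100
        b = [sp("A a"), sp("C c")]
        assert repeat_similarity(a, b) == repeat_similarity(b, a)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            repeat_similarity([], [])


class TestResolutionProfile:
    def test_table_style_percentages(self):
        taxa = [fm(f"F{i}") for i in range(5)] + [gn(f"G{i}") for i in range(13)] \
            + [sp(f"S{i} x") for i in range(6)]
        prof = resolution_profile(taxa)
        assert (prof.n_taxa, prof.pct_family, prof.pct_genus, prof.pct_species) == (
            24, 21, 54, 25
        )

    def test_all_species(self):
        prof = resolution_profile([sp("A a"), sp("B b")])
        assert (prof.pct_family, prof.pct_genus, prof.pct_species) == (0, 0, 100)

    def test_random_lists_match_counting_oracle(self):
        rng = np.random.default_rng(79)
        ranks = ["family", "genus", "species"]
        for _ in range(50):
            taxa = [
                Taxon(f"T{i}", ranks[int(rng.integers(0, 3))])
                for i in range(int(rng.integers(1, 30)))
            ]
            prof = resolution_profile(taxa)
            n = len(taxa)
            for rank, got in (
                ("family", prof.pct_family),
                ("genus", prof.pct_genus),
                ("species", prof.pct_species),
            ):
                k = sum(t.rank == rank for t in taxa)
                assert got == int(math.floor(100 * k / n + 0.5))


class TestPooledTTest:
    # per-honey DNA and microscopy species-resolution percentages
    DNA_SPECIES_PCT = [25, 28, 40, 42, 22, 30, 38, 16, 36]
    MICRO_SPECIES_PCT = [26, 13, 29, 33, 31, 23, 30, 30, 22]

    def test_identical_groups(self):
        t, df, p = pooled_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_nine_vs_nine_has_df_16(self):
        t, df, p = pooled_ttest(self.DNA_SPECIES_PCT, self.MICRO_SPECIES_PCT)
        assert df == 16
        assert t > 0  # DNA resolves more taxa to species on these columns
        assert p > 0.05  # not significant

    def test_random_groups_match_textbook_formula(self):
        rng = np.random.default_rng(83)
        for _ in range(50):
            a = list(rng.normal(10, 3, size=int(rng.integers(2, 12))))
            b = list(rng.normal(11, 3, size=int(rng.integers(2, 12))))
            t, df, _ = pooled_ttest(a, b)
            t_exp, df_exp = pooled_t_oracle(a, b)
            assert t == pytest.approx(t_exp, abs=1e-9)
            assert df == df_exp

    def test_group_too_small(self):
        with pytest.raises(ValueError):
            pooled_ttest([1.0], [1.0, 2.0])


class TestSpearman:
    def test_perfect_monotone(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0]
        assert spearman(x, x) == pytest.approx(1.0)
        assert spearman(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(89)
        x = list(rng.uniform(0, 10, size=12))
        assert spearman(x, [math.exp(v) for v in x]) == pytest.approx(1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(97)
        for _ in range(50):
            n = int(rng.integers(4, 15))
            x = list(rng.integers(0, 5, size=n).astype(float))
            y = list(rng.integers(0, 5, size=n).astype(float))
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            assert spearman(x, y) == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_zero_variance_signalled(self):
        with pytest.raises(ValueError, match="zero variance"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSpearmanPvalue:
    def test_exact_permutation_n5_matches_exhaustive(self):
        for rho in (-1.0, -0.6, 0.0, 0.3, 0.9, 1.0):
            assert spearman_pvalue(rho, 5) == pytest.approx(perm_pvalue_oracle(rho, 5))

    def test_t_approximation_for_larger_n(self):
        p = spearman_pvalue(0.5, 20)
        assert 0.0 < p < 0.05  # rho 0.5 at n=20 is borderline-significant
        assert spearman_pvalue(0.99, 50) < spearman_pvalue(0.2, 50)

    def test_bonferroni(self):
        assert bonferroni([0.001], m=9) == [pytest.approx(0.009)]
        assert bonferroni([0.5, 0.9], m=9) == [1.0, 1.0]


class TestPercent:
    @pytest.mark.parametrize(
        "num,den,expected",
        [
            (3976, 4612, 86),
            (47512, 51131, 93),
            (11, 15, 73),
            (0, 100, 0),
            (1, 200, 1),   # half-up at .5
        ],
    )
    def test_printed_values(self, num, den, expected):
        assert percent(num, den) == expected

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            percent(1, 0)


class TestMeanSd:
    def test_per_honey_dna_taxon_counts(self):
        counts = [24, 18, 5, 12, 18, 10, 21, 19, 11]
        assert mean_sd(counts) == (15, 6)


class TestFrequencyTable:
    def _fixture(self):
        rubus = sp("Rubus fruticosus")
        comps = []
        for i in range(9):
            rows = {}
            if i < 8:
                rows[rubus] = 100
            if i < 3:
                rows[gn("Salix")] = 50
            if i == 0:
                rows[sp("Lonely taxon")] = 20
            rows[gn(f"Filler{i}")] = 30
            comps.append(SampleComposition(f"H{i+1}", rows))
        pollen_rows = {}
        for i in range(9):
            rows = {}
            if i < 7:
                rows[rubus] = 10
            if i < 2:
                rows[gn("Salix")] = 4
            pollen_rows[f"H{i+1}"] = rows
        return comps, PollenCounts(table=pollen_rows)

    def test_presence_counts(self):
        comps, pollen = self._fixture()
        df = frequency_table(comps, pollen)
        row = df[df.taxon == "Rubus fruticosus"].iloc[0]
        assert (row.n_dna, row.n_micro) == (8, 7)
        assert bool(row.in_multiple)
        assert df.iloc[0].taxon == "Rubus fruticosus"  # sorted by DNA count

    def test_single_sample_taxa_flagged_out(self):
        comps, pollen = self._fixture()
        df = frequency_table(comps, pollen)
        row = df[df.taxon == "Lonely taxon"].iloc[0]
        assert not bool(row.in_multiple)
        multi = df[df.in_multiple]
        assert "Lonely taxon" not in set(multi.taxon)

    def test_random_presence_matrices_match_column_sums(self):
        rng = np.random.default_rng(101)
        taxa = [gn(f"G{i}") for i in range(12)]
        comps = []
        presence = np.zeros(12, dtype=int)
        for s in range(6):
            mask = rng.random(12) < 0.4
            rows = {t: 10 for t, m in zip(taxa, mask) if m}
            if not rows:
                rows = {taxa[0]: 10}
                mask = np.zeros(12, bool)
                mask[0] = True
            presence += mask.astype(int)
            comps.append(SampleComposition(f"S{s}", rows))
        df = frequency_table(comps, PollenCounts(table={})).set_index("taxon")
        for t, count in zip(taxa, presence):
            if count:
                assert df.loc[t.name, "n_dna"] == count


class TestAbundanceCorrelations:
    def test_correlated_mixture_detected(self):
        rng = np.random.default_rng(103)
        comps, pollen_tables = [], {}
        for s in range(4):
            taxa = [sp(f"G{i} x") for i in range(8)]
            true = rng.dirichlet(np.ones(8) * 2)
            reads = (true * 5000).astype(int) + 10
            grains = (true * 300).astype(int) + 2
            comps.append(SampleComposition(f"S{s}", dict(zip(taxa, map(int, reads)))))
            pollen_tables[f"S{s}"] = dict(zip(taxa, map(int, grains)))
        res = abundance_correlations(comps, PollenCounts(table=pollen_tables))
        assert len(res) == 4
        assert all(r.rho > 0.8 for r in res)
        assert all(r.p_bonferroni == min(1.0, 4 * r.p_raw) for r in res)

    def test_single_grain_exclusion_changes_vector_length(self):
        taxa = [sp(f"G{i} x") for i in range(5)]
        comp = SampleComposition("S", {t: 100 for t in taxa[:3]})
        rows = {t: 20 for t in taxa[:3]}
        rows[taxa[3]] = 1   # single grain, micro-only
        rows[taxa[4]] = 7
        pollen = PollenCounts(table={"S": rows})
        with_excl = abundance_correlations([comp], pollen, exclude_single_grain=True)
        without = abundance_correlations([comp], pollen, exclude_single_grain=False)
        assert with_excl[0].n == 4
        assert without[0].n == 5
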