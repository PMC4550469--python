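"""Agreement statistics between DNA compositions and pollen counts.

Covers taxon-list overlap with single-grain subdivision, replicate
similarity, rank-resolution profiles, a pooled-variance t test on
resolution percentages, Spearman rank correlations of per-taxon
abundances with Bonferroni correction, and cross-sample frequency
tabulation.

Two mixed-rank taxon lists are harmonised before any overlap statistic:
a DNA taxon and a microscopy taxon match when they are identical at the
finest rank both report (species-species by name; a species matches a
genus record when its genus token agrees; genus/species match a family
record when the taxonomy places them in that family).  Each taxon
participates in at most one match and finer-rank matches are preferred.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import PollenCounts, SampleComposition, Taxon, genus_of, normalize_name

RANK_ORDER = {"species": 0, "genus": 1, "family": 2}


@dataclass
class TaxonomyIndex:
    """Name-based lineage lookups for cross-rank matching."""

    genus_to_family: dict[str, str]
    species_to_family: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_table(cls, df) -> "TaxonomyIndex":
        """Build from a taxonomy DataFrame (accession, family, genus, species)."""
        g2f: dict[str, str] = {}
        s2f: dict[str, str] = {}
        for r in df.itertuples():
            if r.genus:
                g2f[normalize_name(r.genus)] = r.family
            if r.species:
                s2f[normalize_name(r.species)] = r.family
        return cls(genus_to_family=g2f, species_to_family=s2f)

    def family_of(self, taxon: Taxon) -> str:
        if taxon.rank == "family":
            return taxon.name
        if taxon.rank == "genus":
            key = normalize_name(taxon.name)
        else:
            key = normalize_name(genus_of(taxon.name))
        fam = self.genus_to_family.get(key)
        if fam is None and taxon.rank == "species":
            fam = self.species_to_family.get(normalize_name(taxon.name))
        if fam is None:
            raise KeyError(f"taxon {taxon.name!r} absent from taxonomy")
        return fam


@dataclass
class OverlapBreakdown:
    both: set[tuple[Taxon, Taxon]]
    dna_only: set[Taxon]
    micro_only_multi: set[Taxon]
    micro_only_single: set[Taxon]

    @property
    def n_taxa(self) -> int:
        return (
            len(self.both) + len(self.dna_only)
            + len(self.micro_only_multi) + len(self.micro_only_single)
        )

    @property
    def similarity_pct(self) -> int:
        return percent(len(self.both), self.n_taxa)


@dataclass
class ResolutionProfile:
    n_taxa: int
    pct_family: int
    pct_genus: int
    pct_species: int


@dataclass
class CorrelationResult:
    sample: str
    rho: float
    p_raw: float
    p_bonferroni: float
    n: int


def percent(numerator: float, denominator: float) -> int:
    """Integer percent, rounded half-up (matching table presentation)."""
    if denominator == 0:
        raise ZeroDivisionError("percent with zero denominator")
    if not (0 <= numerator <= denominator):
        raise ValueError("numerator must lie in [0, denominator]")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def _match_rank(a: Taxon, b: Taxon, taxonomy: TaxonomyIndex | None):
    """Rank at which two taxa agree, or None; coarser of the two ranks."""
    ra, rb = RANK_ORDER[a.rank], RANK_ORDER[b.rank]
    fine, coarse = (a, b) if ra <= rb else (b, a)
    if fine.rank == coarse.rank:
        return coarse.rank if normalize_name(fine.name) == normalize_name(coarse.name) else None
    if coarse.rank == "genus":  # fine is species
        return "genus" if normalize_name(genus_of(fine.name)) == normalize_name(coarse.name) else None
    # coarse is family; fine is species or genus — needs taxonomy. Without
    # one no such match can be attempted; a taxonomy lacking the queried
    # name raises KeyError from family_of.
    if taxonomy is None:
        return None
    return "family" if normalize_name(taxonomy.family_of(fine)) == normalize_name(coarse.name) else None


def harmonize(
    dna_taxa: set[Taxon] | list[Taxon],
    micro_taxa: set[Taxon] | list[Taxon],
    taxonomy: TaxonomyIndex | None = None,
) -> tuple[list[tuple[Taxon, Taxon]], list[Taxon], list[Taxon]]:
    """Match the two taxon lists; returns (pairs, dna unmatched, micro unmatched).

    Greedy over candidate pairs ordered by the fineness of the rank at
    which they agree (species before genus before family), which yields
    a maximal matching preferring the finest-rank pairings.
    """
    dna = list(dict.fromkeys(dna_taxa))
    micro = list(dict.fromkeys(micro_taxa))
    candidates = []
    for d in dna:
        for m in micro:
            rank = _match_rank(d, m, taxonomy)
            if rank is not None:
                candidates.append((RANK_ORDER[rank], d, m))
    candidates.sort(key=lambda c: (c[0], normalize_name(c[1].name), normalize_name(c[2].name)))
    used_d: set[Taxon] = set()
    used_m: set[Taxon] = set()
    pairs: list[tuple[Taxon, Taxon]] = []
    for _, d, m in candidates:
        if d in used_d or m in used_m:
            continue
        pairs.append((d, m))
        used_d.add(d)
        used_m.add(m)
    return (
        pairs,
        [d for d in dna if d not in used_d],
        [m for m in micro if m not in used_m],
    )


def overlap_breakdown(
    dna_comp: SampleComposition,
    micro_counts: PollenCounts,
    taxonomy: TaxonomyIndex | None = None,
) -> OverlapBreakdown:
    """Partition the combined taxon list into both / DNA-only / microscopy-only,
    subdividing microscopy-only taxa by whether more than one grain was seen."""
    sample = dna_comp.sample
    micro_rows = micro_counts.table.get(sample, {})
    micro_taxa = {t for t, n in micro_rows.items() if n > 0}
    if not dna_comp.rows and not micro_taxa:
        raise ValueError(f"sample {sample!r}: both methods empty")
    pairs, dna_only, micro_only = harmonize(dna_comp.taxa, micro_taxa, taxonomy)
    return OverlapBreakdown(
        both=set(pairs),
        dna_only=set(dna_only),
        micro_only_multi={t for t in micro_only if micro_rows[t] >= 2},
        micro_only_single={t for t in micro_only if micro_rows[t] == 1},
    )


def repeat_similarity(taxa_a, taxa_b, taxonomy: TaxonomyIndex | None = None) -> int:
    """Replicate similarity: 100 x shared taxa / total distinct taxa, integer."""
    a = list(dict.fromkeys(taxa_a))
    b = list(dict.fromkeys(taxa_b))
    if not a and not b:
        raise ValueError("both replicate lists empty")
    pairs, only_a, only_b = harmonize(a, b, taxonomy)
    total = len(pairs) + len(only_a) + len(only_b)
    return percent(len(pairs), total)


def resolution_profile(taxa) -> ResolutionProfile:
    """Percent of taxa resolved at family / genus / species rank."""
    taxa = list(taxa)
    if not taxa:
        raise ValueError("empty taxon list")
    bad = [t for t in taxa if t.rank not in RANK_ORDER]
    if bad:
        raise ValueError(f"taxa with unknown rank: {bad!r}")
    n = len(taxa)
    return ResolutionProfile(
        n_taxa=n,
        pct_family=percent(sum(t.rank == "family" for t in taxa), n),
        pct_genus=percent(sum(t.rank == "genus" for t in taxa), n),
        pct_species=percent(sum(t.rank == "species" for t in taxa), n),
    )


def pooled_ttest(group_a, group_b) -> tuple[float, int, float]:
    """Two-sample Student's t with pooled variance; returns (t, df, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=True)
    df = len(a) + len(b) - 2
    t = float(res.statistic)
    p = float(res.pvalue)
    if not math.isfinite(t):  # identical constant groups
        t, p = 0.0, 1.0
    return t, df, p


def spearman(x, y) -> float:
    """Spearman's rho: Pearson correlation of average (tie-shared) ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise ValueError("zero variance in ranks; rho undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_pvalue(rho: float, n: int, exact_max_n: int = 8) -> float:
    """Two-sided p for Spearman's rho.

    Exact permutation null (all n! rank orders, no ties assumed) for
    n <= ``exact_max_n``; t approximation with n-2 df otherwise.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if n <= exact_max_n:
        ref = np.arange(1, n + 1, dtype=float)
        denom = n * (n * n - 1)
        count = 0
        total = 0
        for perm in itertools.permutations(range(1, n + 1)):
            d2 = sum((ref[i] - perm[i]) ** 2 for i in range(n))
            r = 1.0 - 6.0 * d2 / denom
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        return count / total
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def bonferroni(p_list, m: int | None = None) -> list[float]:
    """Multiply each p by m (default: list length) and clip at 1."""
    p_list = list(p_list)
    m = m if m is not None else len(p_list)
    return [min(1.0, m * p) for p in p_list]


def abundance_correlations(
    dna_comps: list[SampleComposition],
    pollen: PollenCounts,
    taxonomy: TaxonomyIndex | None = None,
    exclude_single_grain: bool = True,
    union_zero_fill: bool = True,
    m: int | None = None,
) -> list[CorrelationResult]:
    """Per-sample Spearman correlation of DNA vs microscopy relative abundance.

    Vectors are built over the union of taxa detected by either method
    (absent method filled with 0), after harmonising ranks; microscopy
    taxa seen as a single grain and not found by DNA are excluded by
    default.  Bonferroni m defaults to the number of samples tested.
    """
    results = []
    for comp in dna_comps:
        sample = comp.sample
        micro_rows = {t: c for t, c in pollen.table.get(sample, {}).items() if c > 0}
        total_grains = sum(micro_rows.values())
        if not micro_rows or not comp.rows:
            continue
        pairs, dna_only, micro_only = harmonize(comp.taxa, set(micro_rows), taxonomy)
        rel_dna = comp.rel_abundance
        xs, ys = [], []
        for d, mi in pairs:
            xs.append(rel_dna[d] * 100.0)
            ys.append(100.0 * micro_rows[mi] / total_grains)
        if union_zero_fill:
            for d in dna_only:
                xs.append(rel_dna[d] * 100.0)
                ys.append(0.0)
            for mi in micro_only:
                if exclude_single_grain and micro_rows[mi] == 1:
                    continue
                xs.append(0.0)
                ys.append(100.0 * micro_rows[mi] / total_grains)
        if len(xs) < 3:
            continue
        try:
            rho = spearman(xs, ys)
        except ValueError:
            continue
        p = spearman_pvalue(rho, len(xs))
        results.append(CorrelationResult(sample=sample, rho=rho, p_raw=p, p_bonferroni=p, n=len(xs)))
    mm = m if m is not None else len(results)
    adj = bonferroni([r.p_raw for r in results], mm)
    for r, pa in zip(results, adj):
        r.p_bonferroni = pa
    return results


def frequency_table(
    compositions: list[SampleComposition],
    pollen: PollenCounts,
    min_samples: int = 2,
):
    """Per-taxon presence counts across samples for each method.

    Returns a DataFrame (taxon, rank, n_dna, n_micro, in_multiple)
    sorted descending by DNA count then microscopy count; taxa present
    in at least ``min_samples`` samples by either method are flagged.
    """
    import pandas as pd

    if len(compositions) < 2:
        raise ValueError("frequency table needs at least 2 samples")
    dna_presence: dict[Taxon, int] = {}
    for comp in compositions:
        for t in comp.taxa:
            dna_presence[t] = dna_presence.get(t, 0) + 1
    micro_presence: dict[Taxon, int] = {}
    for sample in pollen.table:
        for t in pollen.taxa(sample):
            micro_presence[t] = micro_presence.get(t, 0) + 1
    taxa = sorted(
        set(dna_presence) | set(micro_presence),
        key=lambda t: (
            -dna_presence.get(t, 0),
            -micro_presence.get(t, 0),
            t.name,
        ),
    )
    rows = [
        {
            "taxon": t.name,
            "rank": t.rank,
            "n_dna": dna_presence.get(t, 0),
            "n_micro": micro_presence.get(t, 0),
            "in_multiple": max(dna_presence.get(t, 0), micro_presence.get(t, 0)) >= min_samples,
        }
        for t in taxa
    ]
    return pd.DataFrame(rows, columns=["taxon", "rank", "n_dna", "n_micro", "in_multiple"])


def mean_sd(values, ddof: int = 1) -> tuple[int, int]:
    """Integer-rounded (half-up) mean and sample SD, as printed in summary rows."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=ddof))
    return int(math.floor(mean + 0.5)), int(math.floor(sd + 0.5))
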