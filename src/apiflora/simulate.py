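"""Seeded synthetic data: reference libraries, honey mixtures, tagged reads
and paired pollen counts.

The generator emulates the study design the pipeline targets: a
hierarchical plant reference taxonomy whose sequences diverge down the
family/genus/species tree, honey samples that are mixtures of a few
dominant taxa (>=20% each) plus a long low-abundance tail, thousands of
tagged pyrosequencing-style reads per sample (substitutions plus
homopolymer indels, occasional 3' truncation, a tagless contaminant
fraction, reads emitted on either strand), and ~300-grain multinomial
pollen counts drawn from the same underlying mixture but distorted by
per-species counting bias and limited morphological resolution (some
species only recognisable to genus).

Everything is driven by ``numpy.random.default_rng`` seeded explicitly;
identical seeds give identical outputs on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demux import SampleManifest, reverse_complement
from .model import (
    AmpliconRead,
    Checklist,
    PollenCounts,
    ReferenceEntry,
    SampleComposition,
    Taxon,
    genus_of,
)

BASES = np.array(list("ACGT"))

# rbcL barcode primer pair used for the synthetic amplicons
FORWARD_PRIMER = "ATGTCACCACAAACAGAGACTAAAGC"
REVERSE_PRIMER = "GTAAAATCAAGTCCACCRCG"

_EPITHETS = [
    "alba", "rubra", "montana", "vulgaris", "officinalis", "sylvestris",
    "palustris", "arvensis", "maritima", "nemorosa", "pratensis", "minor",
]
_GENUS_STEMS = [
    "Altheria", "Borania", "Cardui", "Dactyla", "Eremia", "Fagopsis",
    "Galium", "Hestia", "Iridos", "Juncea", "Kalmara", "Lotopsis",
]


@dataclass
class SimConfig:
    """Error-model and contamination knobs for read generation."""

    seed: int = 0
    substitution_rate: float = 0.01
    homopolymer_indel_rate: float = 0.01   # per run of length >= 3
    truncation_rate: float = 0.2           # fraction of reads cut short at 3'
    truncation_min: int = 240              # shortest truncated insert
    tagless_contaminant_fraction: float = 0.05
    mean_qv: float = 28.0
    sd_qv: float = 2.0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "homopolymer_indel_rate",
                     "truncation_rate", "tagless_contaminant_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class MixtureSpec:
    """True per-taxon proportions of one honey, plus sampling depths."""

    proportions: dict[str, float]          # species name -> proportion
    n_reads: int = 5000
    n_grains: int = 300

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, not 1")

    def dominants(self, threshold: float = 0.20) -> list[str]:
        return [t for t, p in self.proportions.items() if p >= threshold]


@dataclass
class SyntheticTaxonomy:
    """A family/genus/species tree with one barcode sequence per species."""

    records: pd.DataFrame  # columns: family, genus, species, sequence, in_checklist

    @property
    def species(self) -> list[str]:
        return list(self.records["species"])

    def sequence_of(self, species: str) -> str:
        return self.records.set_index("species").loc[species, "sequence"]

    def lineage(self, species: str) -> tuple[str, str, str]:
        row = self.records.set_index("species").loc[species]
        return (row["family"], row["genus"], species)

    def checklist(self, rng: np.random.Generator | None = None) -> Checklist:
        rng = rng or np.random.default_rng(0)
        statuses = ["native", "alien", "horticulture", "agriculture"]
        entries = {}
        for r in self.records.itertuples():
            if r.in_checklist:
                entries[r.species] = statuses[int(rng.integers(0, 4))]
        return Checklist(entries=entries)

    def references(self, genus_level_refs: int = 2,
                   dual_library_species: int = 1) -> list[ReferenceEntry]:
        """One reference per species (regional when checklist-listed, global
        otherwise), plus a few genus-level global references and a species
        duplicated in both libraries with an identical sequence."""
        refs: list[ReferenceEntry] = []
        for i, r in enumerate(self.records.itertuples()):
            lib = "regional" if r.in_checklist else "global"
            refs.append(ReferenceEntry(
                accession=f"REF{i:04d}", family=r.family, genus=r.genus,
                species=r.species, library=lib, bases=r.sequence,
            ))
        # genus-level references use the genus ancestor proxy: first species seq
        genera = self.records.drop_duplicates("genus").head(genus_level_refs)
        for j, r in enumerate(genera.itertuples()):
            refs.append(ReferenceEntry(
                accession=f"GREF{j:04d}", family=r.family, genus=r.genus,
                species=None, library="global", bases=r.sequence,
            ))
        for k in range(dual_library_species):
            r = self.records.iloc[k]
            other = "global" if refs[k].library == "regional" else "regional"
            refs.append(ReferenceEntry(
                accession=f"DREF{k:04d}", family=r["family"], genus=r["genus"],
                species=r["species"], library=other, bases=r["sequence"],
            ))
        return refs

    def taxonomy_table(self, refs: list[ReferenceEntry] | None = None) -> pd.DataFrame:
        refs = refs if refs is not None else self.references()
        return pd.DataFrame(
            {
                "accession": [r.accession for r in refs],
                "family": [r.family for r in refs],
                "genus": [r.genus or "" for r in refs],
                "species": [r.species or "" for r in refs],
                "library": [r.library for r in refs],
            }
        )


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        out[i] = (out[i] + rng.integers(1, 4)) % 4
    return out


def simulate_reference(
    n_fam: int = 5,
    n_gen_per_fam: int = 2,
    n_sp_per_gen: int = 2,
    seq_len: int = 300,
    branch_divergence: float = 0.10,
    seed: int = 0,
    checklist_absent_frac: float = 0.2,
) -> SyntheticTaxonomy:
    """Grow a reference library down a family/genus/species tree.

    A random root sequence is mutated independently along each branch;
    per-level substitution rates scale the single ``branch_divergence``
    (family 1.0x, genus 0.4x, species 0.15x) so that sequences within a
    genus stay mutually closer than sequences from different families.
    A ``checklist_absent_frac`` fraction of species is marked absent
    from the geographic checklist.
    """
    if min(n_fam, n_gen_per_fam, n_sp_per_gen) < 1:
        raise ValueError("taxon counts must be >= 1")
    if not (0.0 < branch_divergence <= 0.2):
        raise ValueError("branch_divergence must be in (0, 0.2]")
    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, seq_len)
    rows = []
    sp_index = 0
    for f in range(n_fam):
        fam_name = f"{_GENUS_STEMS[f % len(_GENUS_STEMS)]}ceae"
        fam_seq = _mutate(root, branch_divergence, rng)
        for g in range(n_gen_per_fam):
            genus_name = f"{_GENUS_STEMS[f % len(_GENUS_STEMS)]}{chr(ord('a') + g)}".capitalize()
            gen_seq = _mutate(fam_seq, branch_divergence * 0.4, rng)
            for s in range(n_sp_per_gen):
                species_name = f"{genus_name} {_EPITHETS[(sp_index + s) % len(_EPITHETS)]}"
                sp_seq = _mutate(gen_seq, branch_divergence * 0.15, rng)
                rows.append(
                    {
                        "family": fam_name,
                        "genus": genus_name,
                        "species": species_name,
                        "sequence": "".join(BASES[sp_seq]),
                        "in_checklist": True,
                    }
                )
            sp_index += n_sp_per_gen
    df = pd.DataFrame(rows)
    n_absent = int(round(checklist_absent_frac * len(df)))
    if n_absent:
        absent = rng.choice(len(df), size=n_absent, replace=False)
        df.loc[absent, "in_checklist"] = False
    return SyntheticTaxonomy(records=df)


def default_mixture(taxonomy: SyntheticTaxonomy, seed: int = 0,
                    n_reads: int = 5000, n_grains: int = 300) -> MixtureSpec:
    """The default honey: 3 dominant taxa (>=20% each) over a 12-taxon tail.

    The tail spans ~3.5% down to <0.1%; the two rarest taxa draw so few
    reads at the default depth that the 10-read abundance filter removes
    them, mirroring low-abundance dropout.
    """
    rng = np.random.default_rng(seed)
    species = list(taxonomy.species)
    if len(species) < 15:
        raise ValueError("taxonomy too small: need >= 15 species")
    chosen = list(rng.choice(species, size=15, replace=False))
    weights = [0.30, 0.25, 0.21,
               0.035, 0.032, 0.028, 0.025, 0.022, 0.019,
               0.016, 0.013, 0.010, 0.008, 0.0007, 0.0003]
    total = sum(weights)
    props = {sp: w / total for sp, w in zip(chosen, weights)}
    return MixtureSpec(proportions=props, n_reads=n_reads, n_grains=n_grains)


def default_manifest(sample_ids: list[str]) -> SampleManifest:
    """Distinct 5-bp tags (pairwise Hamming distance >= 2) per sample."""
    pool = [
        "ACGTA", "CAGTC", "GTCAG", "TGACT", "ATCGG", "CGATA",
        "GATCC", "TCAGA", "AGGCT", "CTTGC", "GCCAT", "TAACG",
    ]
    if len(sample_ids) > len(pool):
        raise ValueError(f"at most {len(pool)} samples supported by the tag pool")
    return SampleManifest(
        samples={s: pool[i] for i, s in enumerate(sample_ids)},
        forward_primer=FORWARD_PRIMER,
        reverse_primer=REVERSE_PRIMER,
    )


def _apply_errors(seq: str, config: SimConfig, rng: np.random.Generator) -> str:
    codes = np.array([("ACGT").index(c) if c in "ACGT" else 0 for c in seq])
    codes = _mutate(codes, config.substitution_rate, rng)
    out = "".join(BASES[codes])
    if config.homopolymer_indel_rate > 0:
        chars = list(out)
        # scan homopolymer runs of length >= 3 right-to-left so edits
        # do not disturb the coordinates of unprocessed runs
        runs = []
        i = 0
        while i < len(chars):
            j = i
            while j < len(chars) and chars[j] == chars[i]:
                j += 1
            if j - i >= 3:
                runs.append((i, j))
            i = j
        for start, end in reversed(runs):
            if rng.random() < config.homopolymer_indel_rate:
                if rng.random() < 0.5:
                    chars.insert(start, chars[start])      # one base longer
                else:
                    del chars[start]                       # one base shorter
        out = "".join(chars)
    return out


def _quality(n: int, config: SimConfig, rng: np.random.Generator) -> list[int]:
    read_mean = rng.normal(config.mean_qv, config.sd_qv)
    qv = rng.normal(read_mean, 3.0, size=n)
    return [int(q) for q in np.clip(np.rint(qv), 2, 40)]


def simulate_reads(
    mixture: MixtureSpec,
    taxonomy: SyntheticTaxonomy,
    sample: str,
    tag: str,
    config: SimConfig | None = None,
    seed: int | None = None,
    forward_primer: str = FORWARD_PRIMER,
    reverse_primer: str = REVERSE_PRIMER,
) -> tuple[list[AmpliconRead], pd.DataFrame]:
    """Generate one sample's tagged reads plus a per-read truth table.

    Each non-contaminant read is tag + forward primer + insert +
    reverse-complemented reverse primer, where the insert is the source
    species' reference copy bearing substitutions and homopolymer
    indels, optionally truncated at the 3' end; half the reads are
    emitted reverse-complemented.  ``n_reads`` are allocated to taxa by
    a single multinomial draw; a ``tagless_contaminant_fraction`` of
    additional positions is replaced by random untagged sequence.

    The truth table records (read_id, sample, species, n_insert_bases,
    truncated, contaminant).
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    taxa = list(mixture.proportions)
    probs = np.array([mixture.proportions[t] for t in taxa])
    n_contam = int(rng.binomial(mixture.n_reads, config.tagless_contaminant_fraction))
    n_real = mixture.n_reads - n_contam
    alloc = rng.multinomial(n_real, probs)
    reads: list[AmpliconRead] = []
    truth_rows = []
    idx = 0
    for taxon, n in zip(taxa, alloc):
        ref = taxonomy.sequence_of(taxon)
        for _ in range(n):
            insert = _apply_errors(ref, config, rng)
            truncated = False
            if rng.random() < config.truncation_rate:
                cut = int(rng.integers(config.truncation_min, len(insert) + 1))
                if cut < len(insert):
                    truncated = True
                    insert = insert[:cut]
                full = tag + forward_primer + insert
            else:
                full = tag + forward_primer + insert + reverse_complement(reverse_primer)
            rid = f"{sample}_r{idx:05d}"
            idx += 1
            if rng.random() < 0.5:
                full = reverse_complement(full)
            reads.append(AmpliconRead(id=rid, bases=full, quality=_quality(len(full), config, rng)))
            truth_rows.append(
                {
                    "read_id": rid, "sample": sample, "species": taxon,
                    "n_insert_bases": len(insert), "truncated": truncated,
                    "contaminant": False,
                }
            )
    for c in range(n_contam):
        n_bases = int(rng.integers(280, 380))
        seq = "".join(BASES[rng.integers(0, 4, n_bases)])
        rid = f"{sample}_c{c:05d}"
        reads.append(AmpliconRead(id=rid, bases=seq, quality=_quality(n_bases, config, rng)))
        truth_rows.append(
            {
                "read_id": rid, "sample": sample, "species": "",
                "n_insert_bases": n_bases, "truncated": False, "contaminant": True,
            }
        )
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = pd.DataFrame([truth_rows[i] for i in order])
    return reads, truth


def simulate_pollen_counts(
    mixture: MixtureSpec,
    taxonomy: SyntheticTaxonomy,
    sample: str,
    n_grains: int | None = None,
    bias_sigma: float = 0.9,
    rank_blur_frac: float = 0.35,
    unidentified_frac: float = 0.015,
    seed: int = 0,
) -> PollenCounts:
    """Multinomial grain counts from the mixture, as microscopy would see it.

    Per-species log-normal bias multipliers (sigma ``bias_sigma``)
    reweight the true proportions, emulating differential pollen
    production and counting bias; a ``rank_blur_frac`` fraction of
    species is only recognisable to genus, so their grains are recorded
    at genus rank; a small fraction of grains stays unidentified.
    """
    rng = np.random.default_rng(seed)
    n_grains = n_grains if n_grains is not None else mixture.n_grains
    taxa = list(mixture.proportions)
    bias = np.exp(rng.normal(0.0, bias_sigma, size=len(taxa)))
    if (bias <= 0).any():
        raise ValueError("bias multipliers must be > 0")
    w = np.array([mixture.proportions[t] for t in taxa]) * bias
    w = w / w.sum()
    blurred = rng.random(len(taxa)) < rank_blur_frac
    n_unid = int(rng.binomial(n_grains, unidentified_frac))
    counts = rng.multinomial(n_grains - n_unid, w)
    rows: dict[Taxon, int] = {}
    for taxon_name, blur, n in zip(taxa, blurred, counts):
        if n == 0:
            continue
        if blur:
            key = Taxon(name=genus_of(taxon_name), rank="genus")
        else:
            key = Taxon(name=taxon_name, rank="species")
        rows[key] = rows.get(key, 0) + int(n)
    return PollenCounts(table={sample: rows}, unidentified={sample: n_unid})


@dataclass
class RecoveryReport:
    """Truth-vs-inferred comparison for one simulated sample."""

    precision: float
    recall_all: float
    recall_dominant: float
    recall_rare: float
    mean_abs_abundance_error: float
    missed: list[str] = field(default_factory=list)
    spurious: list[str] = field(default_factory=list)


def recovery_report(
    truth: MixtureSpec,
    inferred: SampleComposition,
    dominant_threshold: float = 0.20,
    rare_threshold: float = 0.02,
) -> RecoveryReport:
    """Precision/recall of the inferred composition against the true mixture.

    A true species counts as recovered when the composition contains it
    at species rank or contains its genus at genus rank.  Recall is
    reported over all taxa and separately for dominant (>= 20%) and
    rare (< 2%) taxa; the abundance error is the mean absolute
    difference between true proportion and inferred relative abundance
    (0 for undetected taxa's inferred value).
    """
    inferred_species = {t.name for t in inferred.taxa if t.rank == "species"}
    inferred_genera = {t.name for t in inferred.taxa if t.rank == "genus"}
    rel = {t.name: v for t, v in inferred.rel_abundance.items()}

    def detected(sp: str) -> bool:
        return sp in inferred_species or genus_of(sp) in inferred_genera

    hits = {sp for sp in truth.proportions if detected(sp)}
    recall_all = len(hits) / len(truth.proportions)
    dom = [sp for sp, p in truth.proportions.items() if p >= dominant_threshold]
    rare = [sp for sp, p in truth.proportions.items() if p < rare_threshold]
    recall_dom = sum(sp in hits for sp in dom) / len(dom) if dom else 1.0
    recall_rare = sum(sp in hits for sp in rare) / len(rare) if rare else 1.0

    truth_names = set(truth.proportions) | {genus_of(sp) for sp in truth.proportions}
    spurious = [t.name for t in inferred.taxa if t.name not in truth_names]
    precision = 1.0 - len(spurious) / len(inferred.rows) if inferred.rows else 0.0

    errs = []
    for sp, p in truth.proportions.items():
        got = rel.get(sp, rel.get(genus_of(sp), 0.0) if detected(sp) else 0.0)
        errs.append(abs(p - got))
    return RecoveryReport(
        precision=precision,
        recall_all=recall_all,
        recall_dominant=recall_dom,
        recall_rare=recall_rare,
        mean_abs_abundance_error=float(np.mean(errs)),
        missed=sorted(set(truth.proportions) - hits),
        spurious=sorted(spurious),
    )


@dataclass
class Scenario:
    """A complete simulated study: references, samples, reads, pollen, truth."""

    taxonomy: SyntheticTaxonomy
    references: list[ReferenceEntry]
    checklist: Checklist
    manifest: SampleManifest
    mixtures: dict[str, MixtureSpec]
    reads: dict[str, list[AmpliconRead]]
    pollen: PollenCounts
    truth: pd.DataFrame


def simulate_scenario(
    seed: int = 0,
    n_samples: int = 9,
    n_reads: int = 5000,
    n_grains: int = 300,
    replicate_first: bool = True,
    config: SimConfig | None = None,
) -> Scenario:
    """The default study: ``n_samples`` honeys plus a replicate of the first.

    Each honey gets its own mixture (3 dominants + 12-taxon tail drawn
    from a shared 20-species reference taxonomy); the replicate sample
    (suffix ``_2``) re-draws reads and grains from the *same* mixture as
    the first honey, providing the repeatability comparison.
    """
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(4 + 2 * (n_samples + 1))
    tax_seed = child[0].generate_state(1)[0] % (2**31)
    taxonomy = simulate_reference(seed=int(tax_seed))
    references = taxonomy.references()
    checklist = taxonomy.checklist(np.random.default_rng(int(child[1].generate_state(1)[0] % (2**31))))

    sample_ids = [f"H{i+1}" for i in range(n_samples)]
    if replicate_first:
        sample_ids.append("H1_2")
    manifest = default_manifest(sample_ids)

    config = config or SimConfig()
    mixtures: dict[str, MixtureSpec] = {}
    reads: dict[str, list[AmpliconRead]] = {}
    pollen_tables: dict[str, dict] = {}
    unid: dict[str, int] = {}
    truths = []
    for i, sample in enumerate(sample_ids):
        mseed = int(child[2 + 2 * i].generate_state(1)[0] % (2**31))
        pseed = int(child[3 + 2 * i].generate_state(1)[0] % (2**31))
        if sample == "H1_2":
            mixture = mixtures["H1"]
        else:
            mixture = default_mixture(taxonomy, seed=mseed, n_reads=n_reads, n_grains=n_grains)
        mixtures[sample] = mixture
        sample_reads, truth = simulate_reads(
            mixture, taxonomy, sample, manifest.samples[sample], config=config, seed=mseed + 1
        )
        reads[sample] = sample_reads
        truths.append(truth)
        pc = simulate_pollen_counts(mixture, taxonomy, sample, seed=pseed)
        pollen_tables[sample] = pc.table[sample]
        unid[sample] = pc.unidentified[sample]
    return Scenario(
        taxonomy=taxonomy,
        references=references,
        checklist=checklist,
        manifest=manifest,
        mixtures=mixtures,
        reads=reads,
        pollen=PollenCounts(table=pollen_tables, unidentified=unid),
        truth=pd.concat(truths, ignore_index=True),
    )
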