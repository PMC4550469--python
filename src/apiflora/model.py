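"""Core domain types shared across the pipeline.

The pipeline moves tagged amplicon reads through demultiplexing, a
similarity search against a merged dual reference library (a regional
curated barcode set plus a global sequence-repository dump), consensus
taxonomic assignment, checklist groundtruthing and abundance filtering,
ending in per-sample floral compositions that can be compared with
microscopy pollen counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_STATUSES = frozenset({"native", "alien", "horticulture", "agriculture"})
LIBRARIES = ("regional", "global")
RANKS = ("species", "genus", "family", "unknown")

_IUPAC = frozenset("ACGTRYSWKMBDHVN")


def normalize_name(name: str) -> str:
    """Whitespace-normalise and case-fold a taxon name for matching."""
    return " ".join(name.split()).lower()


def genus_of(species: str) -> str:
    """Genus as the first token of a binomial."""
    return species.split()[0]


def binomial(name: str) -> str:
    """Drop hybrid/subspecies tokens beyond the first two words."""
    parts = name.split()
    return " ".join(parts[:2])


@dataclass
class AmpliconRead:
    """A tagged sequencing read, optionally with per-base phred quality."""

    id: str
    bases: str
    quality: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"read {self.id!r}: empty sequence")
        bad = set(self.bases.upper()) - _IUPAC
        if bad:
            raise ValueError(
                f"read {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )
        self.bases = self.bases.upper()
        if self.quality is not None:
            if len(self.quality) != len(self.bases):
                raise ValueError(
                    f"read {self.id!r}: quality length {len(self.quality)} "
                    f"!= sequence length {len(self.bases)}"
                )
            if any(q < 0 or q > 60 for q in self.quality):
                raise ValueError(f"read {self.id!r}: phred values outside [0, 60]")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class ReferenceEntry:
    """A barcode reference sequence with its taxonomy and source library.

    ``species`` (and possibly ``genus``) may be absent for references
    identified only to a coarser rank; whichever ranks are present must
    form a contiguous lineage from family downward.
    """

    accession: str
    family: str
    bases: str
    library: str
    genus: str | None = None
    species: str | None = None

    def __post_init__(self) -> None:
        if self.library not in LIBRARIES:
            raise ValueError(
                f"reference {self.accession!r}: library must be one of "
                f"{LIBRARIES}, got {self.library!r}"
            )
        if self.species and not self.genus:
            raise ValueError(
                f"reference {self.accession!r}: species given without genus"
            )
        if self.genus and not self.family:
            raise ValueError(
                f"reference {self.accession!r}: genus given without family"
            )
        if not self.bases:
            raise ValueError(f"reference {self.accession!r}: empty sequence")
        self.bases = self.bases.upper()
        if self.species:
            self.species = binomial(self.species)

    @property
    def taxon(self) -> tuple[str, str | None, str | None]:
        return (self.family, self.genus, self.species)


@dataclass
class Checklist:
    """A geographic species checklist used for groundtruthing assignments.

    ``genera`` is derived: the set of first-word genus tokens of the
    listed species.  Membership tests are case-insensitive after
    whitespace normalisation.
    """

    entries: dict[str, str] = field(default_factory=dict)  # species -> status

    def __post_init__(self) -> None:
        bad = {s for s in self.entries.values() if s not in VALID_STATUSES}
        if bad:
            raise ValueError(f"unknown checklist statuses: {sorted(bad)!r}")
        self._species_norm = {normalize_name(s) for s in self.entries}

    @property
    def genera(self) -> set[str]:
        return {genus_of(s) for s in self.entries}

    def has_species(self, name: str) -> bool:
        return normalize_name(binomial(name)) in self._species_norm

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class HitRecord:
    """One similarity hit of a read against a reference."""

    read_id: str
    accession: str
    bit_score: float
    raw_score: float
    identity_pct: float | None = None
    align_len: int | None = None
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.bit_score):
            raise ValueError(f"hit {self.read_id}->{self.accession}: non-finite bit score")
        if self.raw_score < 0:
            raise ValueError(f"hit {self.read_id}->{self.accession}: negative raw score")


@dataclass
class TaxonAssignment:
    """A read's resolved taxon: species, genus, family or unknown."""

    read_id: str
    rank: str
    name: str | None = None

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"invalid rank {self.rank!r}")
        if self.rank == "unknown" and self.name is not None:
            raise ValueError("unknown-rank assignment cannot carry a name")
        if self.rank != "unknown" and not self.name:
            raise ValueError(f"{self.rank}-rank assignment requires a name")


@dataclass(frozen=True)
class Taxon:
    """A named taxon at a declared rank, as it appears in a composition."""

    name: str
    rank: str

    def __post_init__(self) -> None:
        if self.rank not in ("species", "genus", "family"):
            raise ValueError(f"invalid composition rank {self.rank!r}")


@dataclass
class SampleComposition:
    """Per-sample taxon read counts with derived relative abundances."""

    sample: str
    rows: dict[Taxon, int]
    unknown_reads: int = 0
    filtered_reads: int = 0

    @property
    def total_identified(self) -> int:
        return sum(self.rows.values())

    @property
    def rel_abundance(self) -> dict[Taxon, float]:
        total = self.total_identified
        if total == 0:
            return {}
        return {t: c / total for t, c in self.rows.items()}

    @property
    def taxa(self) -> set[Taxon]:
        return set(self.rows)


@dataclass
class PollenCounts:
    """Per-sample grain counts per taxon from light microscopy."""

    table: dict[str, dict[Taxon, int]]
    unidentified: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sample, rows in self.table.items():
            for taxon, n in rows.items():
                if n < 0 or n != int(n):
                    raise ValueError(
                        f"sample {sample!r} taxon {taxon.name!r}: "
                        f"grain count must be a non-negative integer"
                    )
        for sample, n in self.unidentified.items():
            if n < 0:
                raise ValueError(f"sample {sample!r}: negative unidentified count")

    def total_grains(self, sample: str) -> int:
        return sum(self.table.get(sample, {}).values()) + self.unidentified.get(sample, 0)

    def taxa(self, sample: str) -> set[Taxon]:
        return {t for t, n in self.table.get(sample, {}).items() if n > 0}
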