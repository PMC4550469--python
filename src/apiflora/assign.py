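"""Consensus taxonomic assignment and per-sample composition building.

The assignment rule is LCA-style over the top-bit-score tie set: a
single species wins the read; several species of one genus resolve to
the genus; several genera of one family resolve to the family; several
families make the read unknown.  Agreement is computed at the finest
rank shared by *all* tie-set taxa, so a species tied with its own
genus-level reference still resolves to genus.

Species-level calls are then groundtruthed against a geographic
checklist: a species not recorded in the region is demoted to its
genus.  Finally taxa supported by fewer than ``min_reads`` reads in a
sample are removed as likely amplification or sequencing artefacts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .model import (
    Checklist,
    SampleComposition,
    TaxonAssignment,
    Taxon,
    genus_of,
)
from .match import TopHitSet

MIN_READS_PER_TAXON = 10


@dataclass
class AssignLog:
    """Tallies of every reclassification and removal, for auditability."""

    reclassified_to_genus: Counter = field(default_factory=Counter)
    removed_low_abundance: dict[str, dict[Taxon, int]] = field(default_factory=dict)


def consensus_assign(top: TopHitSet, taxonomy: dict[str, tuple]) -> TaxonAssignment:
    """Resolve a read's taxon from its top-bit-score tie set.

    ``taxonomy`` maps accession to a (family, genus, species) triple
    where genus/species may be ``None`` for coarser references.
    """
    taxa = []
    for hit in top.hits:
        if hit.accession not in taxonomy:
            raise KeyError(f"accession {hit.accession!r} unresolvable in taxonomy")
        t = taxonomy[hit.accession]
        if t not in taxa:
            taxa.append(t)
    if not taxa:
        raise ValueError(f"read {top.read_id!r}: empty tie set")

    families = {t[0] for t in taxa}
    genera = {t[1] for t in taxa}
    species = {t[2] for t in taxa}

    if None not in species and len(species) == 1:
        return TaxonAssignment(read_id=top.read_id, rank="species", name=next(iter(species)))
    if None not in genera and len(genera) == 1:
        return TaxonAssignment(read_id=top.read_id, rank="genus", name=next(iter(genera)))
    if len(families) == 1:
        return TaxonAssignment(read_id=top.read_id, rank="family", name=next(iter(families)))
    return TaxonAssignment(read_id=top.read_id, rank="unknown")


def apply_checklist(
    assignment: TaxonAssignment, checklist: Checklist, log: AssignLog | None = None
) -> TaxonAssignment:
    """Demote a species not recorded in the checklist to its genus.

    Genus- and family-rank assignments pass through unchanged — only
    species claims are screened.  Idempotent.
    """
    if assignment.rank != "species":
        return assignment
    if checklist.has_species(assignment.name):
        return assignment
    genus = genus_of(assignment.name)
    if log is not None:
        log.reclassified_to_genus[assignment.name] += 1
    return TaxonAssignment(read_id=assignment.read_id, rank="genus", name=genus)


def tally(assignments: list[TaxonAssignment]) -> tuple[dict[Taxon, int], int]:
    """Aggregate one sample's assignments into (taxon -> count, n unknown)."""
    counts: dict[Taxon, int] = {}
    unknown = 0
    for a in assignments:
        if a.rank == "unknown":
            unknown += 1
            continue
        taxon = Taxon(name=a.name, rank=a.rank)
        counts[taxon] = counts.get(taxon, 0) + 1
    return counts, unknown


def abundance_filter(
    counts: dict[Taxon, int], min_reads: int = MIN_READS_PER_TAXON
) -> tuple[dict[Taxon, int], dict[Taxon, int]]:
    """Drop taxa with fewer than ``min_reads`` reads; return (kept, removed)."""
    kept = {t: c for t, c in counts.items() if c >= min_reads}
    removed = {t: c for t, c in counts.items() if c < min_reads}
    return kept, removed


def relative_abundance(sample: str, counts: dict[Taxon, int], unknown: int = 0,
                       filtered: int = 0) -> SampleComposition:
    """Build a composition whose proportions sum to 1 over surviving taxa."""
    if not counts:
        raise ValueError(f"sample {sample!r}: no taxa survive filtering")
    return SampleComposition(
        sample=sample, rows=dict(counts), unknown_reads=unknown, filtered_reads=filtered
    )


def compose_sample(
    sample: str,
    assignments: list[TaxonAssignment],
    checklist: Checklist | None = None,
    min_reads: int = MIN_READS_PER_TAXON,
    filter_order: str = "checklist_first",
    log: AssignLog | None = None,
) -> SampleComposition:
    """Full per-sample path: checklist screening, tally, threshold, proportions.

    ``filter_order`` selects whether the read-count threshold applies
    after checklist reclassification (``checklist_first``, the default:
    demoted reads pool into their genus before thresholding) or before
    it (``threshold_first``).
    """
    if filter_order not in ("checklist_first", "threshold_first"):
        raise ValueError(f"invalid filter_order {filter_order!r}")
    log = log if log is not None else AssignLog()

    if checklist is not None and filter_order == "checklist_first":
        assignments = [apply_checklist(a, checklist, log) for a in assignments]
        counts, unknown = tally(assignments)
        kept, removed = abundance_filter(counts, min_reads)
    else:
        counts, unknown = tally(assignments)
        if checklist is not None:
            kept0, removed = abundance_filter(counts, min_reads)
            kept = {}
            for taxon, c in kept0.items():
                if taxon.rank == "species" and not checklist.has_species(taxon.name):
                    log.reclassified_to_genus[taxon.name] += c
                    g = Taxon(name=genus_of(taxon.name), rank="genus")
                    kept[g] = kept.get(g, 0) + c
                else:
                    kept[taxon] = kept.get(taxon, 0) + c
        else:
            kept, removed = abundance_filter(counts, min_reads)

    log.removed_low_abundance[sample] = removed
    return relative_abundance(
        sample, kept, unknown=unknown, filtered=sum(removed.values())
    )
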