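"""Readers and writers for the external formats the pipeline touches.

All parsers validate strictly and raise :class:`ParseError` naming the
offending line.  FASTA/FASTQ round-trip byte-identically for canonical
fixtures (uppercase sequence, single-line records).
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .model import (
    AmpliconRead,
    Checklist,
    HitRecord,
    PollenCounts,
    ReferenceEntry,
    SampleComposition,
    Taxon,
    VALID_STATUSES,
)

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class ParseError(ValueError):
    """A malformed input file; message carries file and line number."""

    def __init__(self, path, line_no: int | None, message: str) -> None:
        loc = f"{path}" if line_no is None else f"{path}:{line_no}"
        super().__init__(f"{loc}: {message}")
        self.path = str(path)
        self.line_no = line_no


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path) -> list[AmpliconRead]:
    """Parse a FASTA file into reads; duplicate ids and empty records are errors."""
    reads: list[AmpliconRead] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush(line_no: int) -> None:
        nonlocal header
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(path, header_line, f"record {header!r} has empty sequence")
        try:
            reads.append(AmpliconRead(id=header, bases=seq))
        except ValueError as exc:
            raise ParseError(path, header_line, str(exc)) from exc
        header = None
        chunks.clear()

    with open(path) as fh:
        n = 0
        for n, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush(n)
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise ParseError(path, n, "empty FASTA header")
                if name in seen:
                    raise ParseError(path, n, f"duplicate record id {name!r}")
                seen.add(name)
                header = name
                header_line = n
            else:
                if header is None:
                    raise ParseError(path, n, "sequence data before first header")
                chunks.append(line.strip())
        flush(n + 1)
    return reads


def write_fasta(reads, path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f">{read.id}\n{read.bases}\n")


def read_fastq(path) -> list[AmpliconRead]:
    """Parse 4-line phred+33 FASTQ; quality/sequence length mismatch is an error."""
    reads: list[AmpliconRead] = []
    seen: set[str] = set()
    with open(path) as fh:
        lines = fh.read().splitlines()
    # trailing blank lines are tolerated
    while lines and not lines[-1].strip():
        lines.pop()
    if len(lines) % 4 != 0:
        raise ParseError(path, len(lines), "truncated FASTQ record (not a multiple of 4 lines)")
    for i in range(0, len(lines), 4):
        ln = i + 1
        head, seq, plus, qual = lines[i], lines[i + 1], lines[i + 2], lines[i + 3]
        if not head.startswith("@"):
            raise ParseError(path, ln, "expected '@' header")
        name = head[1:].split()[0] if head[1:].split() else ""
        if not name:
            raise ParseError(path, ln, "empty FASTQ header")
        if name in seen:
            raise ParseError(path, ln, f"duplicate record id {name!r}")
        seen.add(name)
        if not plus.startswith("+"):
            raise ParseError(path, ln + 2, "expected '+' separator")
        if len(qual) != len(seq):
            raise ParseError(
                path, ln + 3,
                f"quality length {len(qual)} != sequence length {len(seq)}",
            )
        phred = [ord(c) - 33 for c in qual]
        if any(q < 0 or q > 60 for q in phred):
            raise ParseError(path, ln + 3, "phred+33 quality outside [0, 60]")
        try:
            reads.append(AmpliconRead(id=name, bases=seq, quality=phred))
        except ValueError as exc:
            raise ParseError(path, ln, str(exc)) from exc
    return reads


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            if read.quality is None:
                raise ValueError(f"read {read.id!r} has no quality; cannot write FASTQ")
            qual = "".join(chr(q + 33) for q in read.quality)
            fh.write(f"@{read.id}\n{read.bases}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# BLAST-tabular hit tables

def read_hits_table(path, params=None) -> list[HitRecord]:
    """Parse a 12-column blast-tabular (outfmt 6) TSV into hit records.

    The raw alignment score is not part of the dialect; it is
    back-computed from the bit score with the Karlin-Altschul inverse
    using ``params`` (defaults used when omitted).
    """
    from .match import AlignmentParams

    params = params or AlignmentParams()
    records: list[HitRecord] = []
    with open(path) as fh:
        for n, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ParseError(path, n, f"expected 12 columns, got {len(cols)}")
            try:
                pident = float(cols[2])
                length = int(cols[3])
                bits = float(cols[11])
            except ValueError as exc:
                raise ParseError(path, n, f"non-numeric field: {exc}") from exc
            if not math.isfinite(bits):
                raise ParseError(path, n, "non-finite bitscore")
            raw_score = max(0.0, (bits * math.log(2) + math.log(params.k_const)) / params.lambda_)
            records.append(
                HitRecord(
                    read_id=cols[0],
                    accession=cols[1],
                    bit_score=bits,
                    raw_score=raw_score,
                    identity_pct=pident,
                    align_len=length,
                    annotations=dict(zip(BLAST_COLUMNS[4:11], cols[4:11])),
                )
            )
    return records


def write_hits_table(rows: list[dict], path) -> None:
    """Write 12-column blast-tabular rows (dicts keyed by BLAST_COLUMNS)."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in BLAST_COLUMNS) + "\n")


# ---------------------------------------------------------------------------
# Checklist / taxonomy / manifest tables

def read_checklist(path) -> Checklist:
    """Read a TSV of (species, status); statuses outside the vocabulary fail."""
    df = _read_tsv(path, ["species", "status"])
    dup = df["species"].str.strip().duplicated()
    if dup.any():
        first = df.loc[dup, "species"].iloc[0]
        raise ParseError(path, None, f"duplicate species row {first!r}")
    bad = set(df["status"]) - VALID_STATUSES
    if bad:
        raise ParseError(
            path, None,
            f"unknown status values {sorted(bad)!r}; expected {sorted(VALID_STATUSES)}",
        )
    return Checklist(entries=dict(zip(df["species"].str.strip(), df["status"])))


def write_checklist(checklist: Checklist, path) -> None:
    pd.DataFrame(
        {"species": list(checklist.entries), "status": list(checklist.entries.values())}
    ).to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> pd.DataFrame:
    """Taxonomy TSV (accession, family, genus, species, library) as a DataFrame."""
    df = _read_tsv(path, ["accession", "family", "genus", "species", "library"])
    if df["accession"].duplicated().any():
        raise ParseError(path, None, "duplicate accession in taxonomy")
    df = df.fillna("")
    return df


def write_taxonomy(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_references(fasta_paths, taxonomy_path) -> list[ReferenceEntry]:
    """Join one or more reference FASTA files with the taxonomy table."""
    tax = read_taxonomy(taxonomy_path).set_index("accession")
    refs: list[ReferenceEntry] = []
    for fp in fasta_paths:
        for rec in read_fasta(fp):
            if rec.id not in tax.index:
                raise ParseError(fp, None, f"accession {rec.id!r} missing from taxonomy")
            row = tax.loc[rec.id]
            refs.append(
                ReferenceEntry(
                    accession=rec.id,
                    family=row["family"],
                    genus=row["genus"] or None,
                    species=row["species"] or None,
                    library=row["library"],
                    bases=rec.bases,
                )
            )
    return refs


def read_manifest(path):
    """Sample manifest TSV (sample, tag) plus primer columns on the first row."""
    from .demux import SampleManifest

    df = _read_tsv(path, ["sample", "tag", "forward_primer", "reverse_primer"])
    return SampleManifest(
        samples=dict(zip(df["sample"], df["tag"].str.upper())),
        forward_primer=str(df["forward_primer"].iloc[0]).upper(),
        reverse_primer=str(df["reverse_primer"].iloc[0]).upper(),
    )


def write_manifest(manifest, path) -> None:
    rows = [
        {
            "sample": s,
            "tag": t,
            "forward_primer": manifest.forward_primer,
            "reverse_primer": manifest.reverse_primer,
        }
        for s, t in manifest.samples.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Compositions and pollen counts

def write_composition(compositions: list[SampleComposition], path) -> None:
    rows = []
    for comp in compositions:
        rel = comp.rel_abundance
        for taxon, count in sorted(comp.rows.items(), key=lambda kv: (-kv[1], kv[0].name)):
            rows.append(
                {
                    "sample": comp.sample,
                    "taxon": taxon.name,
                    "rank": taxon.rank,
                    "read_count": count,
                    "rel_abundance": f"{rel[taxon]:.6f}",
                }
            )
    pd.DataFrame(rows, columns=["sample", "taxon", "rank", "read_count", "rel_abundance"]).to_csv(
        path, index=False
    )


def read_composition(path) -> list[SampleComposition]:
    df = pd.read_csv(path)
    missing = {"sample", "taxon", "rank", "read_count"} - set(df.columns)
    if missing:
        raise ParseError(path, None, f"missing columns {sorted(missing)}")
    comps = []
    for sample, grp in df.groupby("sample", sort=False):
        rows = {
            Taxon(name=r.taxon, rank=r.rank): int(r.read_count)
            for r in grp.itertuples()
        }
        comps.append(SampleComposition(sample=str(sample), rows=rows))
    return comps


def read_pollen_counts(path) -> PollenCounts:
    """Pollen TSV in long format (sample, taxon, rank, grains).

    Rows whose taxon is the literal ``Unidentified`` accumulate into the
    per-sample unidentified total.
    """
    df = _read_tsv(path, ["sample", "taxon", "rank", "grains"])
    table: dict[str, dict[Taxon, int]] = {}
    unidentified: dict[str, int] = {}
    for r in df.itertuples():
        n = int(r.grains)
        if n < 0:
            raise ParseError(path, None, f"negative grain count for {r.taxon!r}")
        if str(r.taxon).lower() == "unidentified":
            unidentified[r.sample] = unidentified.get(r.sample, 0) + n
            continue
        taxon = Taxon(name=str(r.taxon), rank=str(r.rank))
        sample = table.setdefault(str(r.sample), {})
        if taxon in sample:
            raise ParseError(path, None, f"duplicate taxon {r.taxon!r} in sample {r.sample!r}")
        sample[taxon] = n
    return PollenCounts(table=table, unidentified=unidentified)


def write_pollen_counts(pollen: PollenCounts, path) -> None:
    rows = []
    for sample, taxa in pollen.table.items():
        for taxon, n in sorted(taxa.items(), key=lambda kv: (-kv[1], kv[0].name)):
            rows.append({"sample": sample, "taxon": taxon.name, "rank": taxon.rank, "grains": n})
        uid = pollen.unidentified.get(sample, 0)
        if uid:
            rows.append({"sample": sample, "taxon": "Unidentified", "rank": "family", "grains": uid})
    pd.DataFrame(rows, columns=["sample", "taxon", "rank", "grains"]).to_csv(
        path, sep="\t", index=False
    )


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    if not Path(path).exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=required)
    missing = set(required) - set(df.columns)
    if missing:
        raise ParseError(path, 1, f"missing columns {sorted(missing)}")
    return df
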