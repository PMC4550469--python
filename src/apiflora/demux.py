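"""Demultiplexing of tagged amplicon reads.

Reads carry a 5-bp sample tag followed immediately by the full forward
primer; a read is kept only when both are found (tag anchored within a
small 5' slop), and the insert after primer removal must exceed the
length floor.  Reads failing forward detection are rescanned
reverse-complemented by default, since pyrosequencing emits amplicons in
either orientation.  Quality is summarised for reporting but never used
to filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .model import AmpliconRead

MIN_INSERT_LEN = 250  # inserts of this length or shorter are discarded
TAG_ANCHOR_SLOP = 2   # tag may start at read positions 0..2

_RC = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class SampleManifest:
    """Sample-to-tag map plus the primer pair shared by all samples."""

    samples: dict[str, str]
    forward_primer: str
    reverse_primer: str

    def __post_init__(self) -> None:
        bad = [s for s, t in self.samples.items() if len(t) != 5]
        if bad:
            raise ValueError(f"tags must be 5 bp; offending samples: {bad}")
        tags = list(self.samples.values())
        if len(set(tags)) != len(tags):
            raise ValueError("sample tags must be pairwise distinct")
        if not self.forward_primer or not self.reverse_primer:
            raise ValueError("primers must be non-empty")


@dataclass
class DemuxReport:
    """Outcome of demultiplexing: kept reads per sample plus rejection tallies."""

    kept: dict[str, list[AmpliconRead]]
    rejected_no_tag_or_primer: int = 0
    rejected_short: int = 0

    @property
    def n_kept(self) -> int:
        return sum(len(v) for v in self.kept.values())

    @property
    def n_total(self) -> int:
        return self.n_kept + self.rejected_no_tag_or_primer + self.rejected_short


@dataclass
class QualitySummary:
    n_reads: int
    mean_len: float
    sd_len: float
    mean_qv: float
    sd_qv: float
    pct_reads_qv_gt20: int


def locate_tag_primer(
    read: AmpliconRead, tag: str, primer: str, max_mismatch: int = 0
) -> int | None:
    """Start index of the insert after tag+primer, or ``None`` if absent.

    The tag must start within the first ``TAG_ANCHOR_SLOP + 1`` positions
    and be followed directly by the complete primer; up to
    ``max_mismatch`` substitutions are tolerated over the combined
    tag+primer region.  Scanning is 5'-to-3'; the first acceptable
    placement wins.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    probe = (tag + primer).upper()
    seq = read.bases
    for start in range(0, TAG_ANCHOR_SLOP + 1):
        end = start + len(probe)
        if end > len(seq):
            break
        mism = sum(1 for a, b in zip(seq[start:end], probe) if a != b)
        if mism <= max_mismatch:
            return end
    return None


def trim_trailing_reverse_primer(insert: str, reverse_primer: str, max_mismatch: int = 0) -> str:
    """Remove a trailing reverse-complemented reverse primer, if present.

    Amplicons read through to the far primer unless truncated; when the
    reverse complement of the reverse primer occurs at the very end of
    the insert it is trimmed.
    """
    probe = reverse_complement(reverse_primer.upper())
    k = len(probe)
    if len(insert) >= k:
        tail = insert[-k:]
        mism = sum(1 for a, b in zip(tail, probe) if a != b)
        if mism <= max_mismatch:
            return insert[:-k]
    return insert


def demultiplex(
    reads: list[AmpliconRead],
    manifest: SampleManifest,
    max_mismatch: int = 0,
    scan_reverse: bool = True,
    min_len: int = MIN_INSERT_LEN,
) -> DemuxReport:
    """Sort reads into samples by tag, trim tag+primer, apply the length floor.

    A read matching the tags of two samples (possible when
    ``max_mismatch`` > 0) is ambiguous and rejected.  Read counts are
    conserved: every input read is either kept in exactly one sample or
    tallied under one rejection reason.
    """
    report = DemuxReport(kept={s: [] for s in manifest.samples})
    fwd = manifest.forward_primer
    for read in reads:
        oriented = read
        matches = _match_samples(read, manifest, max_mismatch)
        if not matches and scan_reverse:
            oriented = AmpliconRead(
                id=read.id,
                bases=reverse_complement(read.bases),
                quality=None if read.quality is None else read.quality[::-1],
            )
            matches = _match_samples(oriented, manifest, max_mismatch)
        if len(matches) != 1:  # absent, or ambiguous across samples
            report.rejected_no_tag_or_primer += 1
            continue
        sample, insert_start = matches[0]
        insert = oriented.bases[insert_start:]
        insert = trim_trailing_reverse_primer(insert, manifest.reverse_primer, max_mismatch)
        qual = None
        if oriented.quality is not None:
            qual = oriented.quality[insert_start:insert_start + len(insert)]
        if len(insert) <= min_len:
            report.rejected_short += 1
            continue
        report.kept[sample].append(AmpliconRead(id=read.id, bases=insert, quality=qual))
    return report


def _match_samples(read, manifest, max_mismatch):
    out = []
    for sample, tag in manifest.samples.items():
        pos = locate_tag_primer(read, tag, manifest.forward_primer, max_mismatch)
        if pos is not None:
            out.append((sample, pos))
    return out


def length_filter(
    reads: list[AmpliconRead], min_exclusive: int = MIN_INSERT_LEN
) -> tuple[list[AmpliconRead], int]:
    """Keep reads strictly longer than ``min_exclusive``; return (kept, n rejected)."""
    kept = [r for r in reads if len(r) > min_exclusive]
    return kept, len(reads) - len(kept)


def quality_summary(reads: list[AmpliconRead]) -> QualitySummary:
    """Length and quality statistics in the style of a sequencing run report.

    Per-read QV is the mean of its per-base phred scores; sample-level
    mean/SD are over reads, and ``pct_reads_qv_gt20`` is the integer
    percentage of reads whose mean QV exceeds 20.
    """
    if not reads:
        raise ValueError("cannot summarise zero reads")
    for r in reads:
        if r.quality is None:
            raise ValueError(f"read {r.id!r} has no quality scores")
    lens = [len(r) for r in reads]
    qvs = [sum(r.quality) / len(r.quality) for r in reads]
    n = len(reads)
    return QualitySummary(
        n_reads=n,
        mean_len=_mean(lens),
        sd_len=_sd(lens),
        mean_qv=_mean(qvs),
        sd_qv=_sd(qvs),
        pct_reads_qv_gt20=round(100.0 * sum(1 for q in qvs if q > 20) / n),
    )


def _mean(xs) -> float:
    return sum(xs) / len(xs)


def _sd(xs) -> float:
    if len(xs) < 2:
        return 0.0
    m = _mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))
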