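"""Local alignment scoring against the merged dual reference library.

The engine is a Smith-Waterman local aligner with affine gaps, scored in
blastn-like units and converted to bit scores with the Karlin-Altschul
transform.  Everything downstream consumes bit-score *ranks* only, so
the scoring constants are reporting conveniences; an external search
engine's tabular output can be imported instead via
:func:`apiflora.formats.read_hits_table`.

Gap convention: a gap of length k scores ``gap_open + k * gap_extend``
(the first gap base pays both penalties).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model import AmpliconRead, HitRecord, ReferenceEntry
from .demux import reverse_complement

_ENCODE = np.full(256, 4, dtype=np.uint8)  # anything non-ACGT scores as mismatch
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DNA_STRICT = frozenset("ACGTRYSWKMBDHVN")


@dataclass
class AlignmentParams:
    """Scoring scheme and Karlin-Altschul constants for bit conversion.

    Defaults mirror blastn's +1/-2 rewards with gap existence 5 and
    extension 2, lambda 0.625 and K 0.41.
    """

    match_reward: int = 1
    mismatch_penalty: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    lambda_: float = 0.625
    k_const: float = 0.41

    def __post_init__(self) -> None:
        if self.match_reward <= 0:
            raise ValueError("match_reward must be > 0")
        if self.mismatch_penalty > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be > 0")
        if not (0 < self.k_const < 1):
            raise ValueError("k_const must be in (0, 1)")


@dataclass
class TopHitSet:
    """All hits of one read attaining the top bit score (within tie tolerance)."""

    read_id: str
    max_bit_score: float
    hits: list[HitRecord]
    taxa: list[tuple[str, str | None, str | None]] = field(default_factory=list)


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes for the alignment kernels."""
    bad = set(seq.upper()) - _DNA_STRICT
    if bad:
        raise ValueError(f"non-DNA characters {sorted(bad)!r}")
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=False)
def _sw_kernel(q, r, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    m = r.shape[0]
    H = np.zeros(m + 1, np.int64)
    E = np.full(m + 1, -(1 << 40), np.int64)
    best = 0
    for i in range(q.shape[0]):
        qi = q[i]
        diag = 0
        F = -(1 << 40)
        for j in range(1, m + 1):
            up = H[j]
            e = E[j] + gap_extend
            t = up + gap_open + gap_extend
            if t > e:
                e = t
            E[j] = e
            f = F + gap_extend
            t = H[j - 1] + gap_open + gap_extend
            if t > f:
                f = t
            F = f
            if qi == r[j - 1] and qi < 4:
                s = diag + match
            else:
                s = diag + mismatch
            h = 0
            if s > h:
                h = s
            if e > h:
                h = e
            if f > h:
                h = f
            diag = up
            H[j] = h
            if h > best:
                best = h
    return best


@njit(cache=False)
def _sw_traceback(q, r, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Full-matrix affine SW with traceback.

    Returns (score, qstart, qend, sstart, send, matches, mismatches,
    gap_opens, align_len); coordinates are 1-based inclusive.
    """
    n = q.shape[0]
    m = r.shape[0]
    NEG = -(1 << 40)
    H = np.zeros((n + 1, m + 1), np.int64)
    E = np.full((n + 1, m + 1), NEG, np.int64)
    F = np.full((n + 1, m + 1), NEG, np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = E[i, j - 1] + gap_extend
            t = H[i, j - 1] + gap_open + gap_extend
            if t > e:
                e = t
            E[i, j] = e
            f = F[i - 1, j] + gap_extend
            t = H[i - 1, j] + gap_open + gap_extend
            if t > f:
                f = t
            F[i, j] = f
            if qi == r[j - 1] and qi < 4:
                s = H[i - 1, j - 1] + match
            else:
                s = H[i - 1, j - 1] + mismatch
            h = 0
            if s > h:
                h = s
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback from (bi, bj) until H == 0
    i, j = bi, bj
    matches = 0
    mismatches = 0
    gap_opens = 0
    align_len = 0
    state = 0  # 0=H, 1=E (gap in query), 2=F (gap in reference)
    while i > 0 and j > 0:
        if state == 0:
            if H[i, j] == 0:
                break
            sub = match if (q[i - 1] == r[j - 1] and q[i - 1] < 4) else mismatch
            if H[i, j] == H[i - 1, j - 1] + sub:
                align_len += 1
                if q[i - 1] == r[j - 1] and q[i - 1] < 4:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            align_len += 1
            if E[i, j] == H[i, j - 1] + gap_open + gap_extend:
                gap_opens += 1
                state = 0
            j -= 1
        else:
            align_len += 1
            if F[i, j] == H[i - 1, j] + gap_open + gap_extend:
                gap_opens += 1
                state = 0
            i -= 1
    return best, i + 1, bi, j + 1, bj, matches, mismatches, gap_opens, align_len


def local_align(query: str, reference: str, params: AlignmentParams | None = None) -> int:
    """Smith-Waterman local alignment raw score (affine gaps, >= 0)."""
    params = params or AlignmentParams()
    if not query or not reference:
        raise ValueError("sequences must be non-empty")
    return int(
        _sw_kernel(
            encode(query), encode(reference),
            params.match_reward, params.mismatch_penalty,
            params.gap_open, params.gap_extend,
        )
    )


def align_details(query: str, reference: str, params: AlignmentParams | None = None) -> dict:
    """Best local alignment with identity and coordinate details.

    Used when emitting blast-tabular rows for top hits; coordinates are
    1-based inclusive on the forward orientations given.
    """
    params = params or AlignmentParams()
    score, qs, qe, ss, se, matches, mism, gaps, alen = _sw_traceback(
        encode(query), encode(reference),
        params.match_reward, params.mismatch_penalty,
        params.gap_open, params.gap_extend,
    )
    return {
        "raw_score": int(score),
        "qstart": int(qs), "qend": int(qe),
        "sstart": int(ss), "send": int(se),
        "matches": int(matches), "mismatch": int(mism),
        "gapopen": int(gaps), "length": int(alen),
        "pident": (100.0 * matches / alen) if alen else 0.0,
    }


def bit_score(raw_score: float, params: AlignmentParams | None = None) -> float:
    """Karlin-Altschul normalised score: (lambda*S - ln K) / ln 2 bits."""
    params = params or AlignmentParams()
    if raw_score < 0:
        raise ValueError("raw_score must be >= 0")
    return (params.lambda_ * raw_score - math.log(params.k_const)) / math.log(2)


def search(
    read: AmpliconRead,
    references: list[ReferenceEntry],
    params: AlignmentParams | None = None,
    strand: str = "both",
    min_identity: float | None = None,
) -> list[HitRecord]:
    """Score one read against every reference; keep hits with raw score > 0.

    Both strands are scored by default and the better kept; the library
    a reference came from never affects its score.  ``min_identity``
    optionally floors hits on percent identity (computed only when
    requested, via traceback).
    """
    if not references:
        raise ValueError("empty reference pool")
    if strand not in ("both", "forward"):
        raise ValueError("strand must be 'both' or 'forward'")
    params = params or AlignmentParams()
    q_fwd = encode(read.bases)
    q_rev = encode(reverse_complement(read.bases)) if strand == "both" else None
    hits: list[HitRecord] = []
    for ref in references:
        r = encode(ref.bases)
        score = _sw_kernel(
            q_fwd, r, params.match_reward, params.mismatch_penalty,
            params.gap_open, params.gap_extend,
        )
        if q_rev is not None:
            rev = _sw_kernel(
                q_rev, r, params.match_reward, params.mismatch_penalty,
                params.gap_open, params.gap_extend,
            )
            if rev > score:
                score = rev
        if score <= 0:
            continue
        identity = None
        if min_identity is not None:
            identity = align_details(read.bases, ref.bases, params)["pident"]
            if identity < min_identity:
                continue
        hits.append(
            HitRecord(
                read_id=read.id,
                accession=ref.accession,
                bit_score=bit_score(float(score), params),
                raw_score=float(score),
                identity_pct=identity,
            )
        )
    return hits


def top_hits(hits: list[HitRecord], tie_tol: float = 0.0) -> TopHitSet:
    """Retain every hit whose bit score is within ``tie_tol`` of the maximum."""
    if not hits:
        raise ValueError("top_hits requires at least one hit")
    if tie_tol < 0:
        raise ValueError("tie_tol must be >= 0")
    best = max(h.bit_score for h in hits)
    kept = [h for h in hits if h.bit_score >= best - tie_tol]
    return TopHitSet(read_id=hits[0].read_id, max_bit_score=best, hits=kept)


def resolve_taxa(top: TopHitSet, taxonomy: dict[str, tuple]) -> TopHitSet:
    """Attach the distinct (family, genus, species) triples of the tie set."""
    taxa = []
    for h in top.hits:
        if h.accession not in taxonomy:
            raise KeyError(f"accession {h.accession!r} not in taxonomy")
        t = taxonomy[h.accession]
        if t not in taxa:
            taxa.append(t)
    top.taxa = taxa
    return top
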