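"""End-to-end orchestration: demux -> search -> assign -> compare.

Each stage writes its outputs atomically (temp file + rename) and
appends machine-parseable ``key=value`` tally lines to the run log, so
that read-count conservation can be audited at every step.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assign as assign_mod
from . import compare as compare_mod
from . import formats
from .demux import DemuxReport, SampleManifest, demultiplex, quality_summary
from .match import (
    AlignmentParams,
    TopHitSet,
    align_details,
    bit_score,
    encode,
    top_hits,
    _sw_kernel,
)
from .model import AmpliconRead, Checklist, HitRecord, ReferenceEntry, SampleComposition


@dataclass
class PipelineConfig:
    """All pipeline thresholds and paths, with the standard defaults.

    Unknown keys in a config file are rejected; every threshold
    surfaces here under a named field.
    """

    reads: str = ""
    manifest: str = ""
    references: list[str] = field(default_factory=list)
    taxonomy: str = ""
    checklist: str = ""
    pollen: str = ""
    out_dir: str = "apiflora_out"
    min_len: int = 250
    min_reads: int = 10
    max_mismatch: int = 0
    tie_tol: float = 0.0
    seed: int = 0
    filter_order: str = "checklist_first"
    strand: str = "forward"        # demux orientation-normalises kept reads
    scan_reverse: bool = True
    exclude_single_grain: bool = True
    union_zero_fill: bool = True

    def __post_init__(self) -> None:
        if self.min_len < 0 or self.min_reads < 0 or self.max_mismatch < 0:
            raise ValueError("thresholds must be >= 0")
        if self.tie_tol < 0:
            raise ValueError("tie_tol must be >= 0")
        if self.filter_order not in ("checklist_first", "threshold_first"):
            raise ValueError(f"invalid filter_order {self.filter_order!r}")
        if self.strand not in ("forward", "both"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        valid = set(cls.__dataclass_fields__)
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


class RunLog:
    """Append-only key=value log, one event per line."""

    def __init__(self) -> None:
        self.lines: list[str] = []

    def event(self, stage: str, **kv) -> None:
        parts = [f"stage={stage}"] + [f"{k}={v}" for k, v in kv.items()]
        self.lines.append(" ".join(parts))

    def write(self, path) -> None:
        _atomic_write(path, "\n".join(self.lines) + "\n")

    def tallies(self, stage: str) -> list[dict[str, str]]:
        out = []
        for line in self.lines:
            kv = dict(p.split("=", 1) for p in line.split(" "))
            if kv.get("stage") == stage:
                out.append(kv)
        return out


def _atomic_write(path, text: str) -> None:
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def search_sample(
    reads: list[AmpliconRead],
    references: list[ReferenceEntry],
    params: AlignmentParams | None = None,
    strand: str = "forward",
    tie_tol: float = 0.0,
) -> list[TopHitSet]:
    """Batch search returning only each read's top-bit-score tie set.

    Identical decisions to ``top_hits(search(read, ...))`` but avoids
    materialising a hit record per reference; used by the pipeline on
    large read sets.
    """
    from .demux import reverse_complement

    if not references:
        raise ValueError("empty reference pool")
    params = params or AlignmentParams()
    encoded = [encode(r.bases) for r in references]
    out: list[TopHitSet] = []
    for read in reads:
        q = encode(read.bases)
        qr = encode(reverse_complement(read.bases)) if strand == "both" else None
        scores = np.empty(len(references), dtype=np.int64)
        for i, r in enumerate(encoded):
            s = _sw_kernel(q, r, params.match_reward, params.mismatch_penalty,
                           params.gap_open, params.gap_extend)
            if qr is not None:
                s2 = _sw_kernel(qr, r, params.match_reward, params.mismatch_penalty,
                                params.gap_open, params.gap_extend)
                if s2 > s:
                    s = s2
            scores[i] = s
        best_raw = int(scores.max())
        if best_raw <= 0:
            continue
        best_bits = bit_score(float(best_raw), params)
        hits = [
            HitRecord(
                read_id=read.id,
                accession=references[i].accession,
                bit_score=bit_score(float(scores[i]), params),
                raw_score=float(scores[i]),
            )
            for i in np.flatnonzero(scores > 0)
            if bit_score(float(scores[i]), params) >= best_bits - tie_tol
        ]
        out.append(TopHitSet(read_id=read.id, max_bit_score=best_bits, hits=hits))
    return out


def hits_table_rows(
    top_sets: list[TopHitSet],
    reads_by_id: dict[str, AmpliconRead],
    refs_by_acc: dict[str, ReferenceEntry],
    params: AlignmentParams | None = None,
) -> list[dict]:
    """Blast-tabular rows (outfmt 6) for top hits, with traceback details."""
    params = params or AlignmentParams()
    rows = []
    for top in top_sets:
        read = reads_by_id[top.read_id]
        for hit in top.hits:
            det = align_details(read.bases, refs_by_acc[hit.accession].bases, params)
            rows.append(
                {
                    "qseqid": top.read_id,
                    "sseqid": hit.accession,
                    "pident": f"{det['pident']:.2f}",
                    "length": det["length"],
                    "mismatch": det["mismatch"],
                    "gapopen": det["gapopen"],
                    "qstart": det["qstart"],
                    "qend": det["qend"],
                    "sstart": det["sstart"],
                    "send": det["send"],
                    "evalue": 0,
                    "bitscore": f"{hit.bit_score:.1f}",
                }
            )
    return rows


@dataclass
class PipelineResult:
    compositions: list[SampleComposition]
    demux_report: DemuxReport
    log: RunLog
    out_dir: Path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run demux -> search -> assign -> compare from file inputs.

    Stage outputs land in ``config.out_dir``: per-sample FASTA, a top-hit
    table, ``composition.csv``, a comparison report, a Table-2-style
    per-sample summary and ``run.log``.
    """
    for required in ("reads", "manifest", "references", "taxonomy"):
        if not getattr(config, required):
            raise FileNotFoundError(f"config.{required} is required")
    log = RunLog()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    reads = (
        formats.read_fastq(config.reads)
        if str(config.reads).endswith((".fastq", ".fq"))
        else formats.read_fasta(config.reads)
    )
    manifest = formats.read_manifest(config.manifest)
    references = formats.load_references(config.references, config.taxonomy)
    checklist = formats.read_checklist(config.checklist) if config.checklist else None
    log.event("input", n_reads=len(reads), n_references=len(references))

    # --- demux ------------------------------------------------------------
    report = demultiplex(
        reads, manifest,
        max_mismatch=config.max_mismatch,
        scan_reverse=config.scan_reverse,
        min_len=config.min_len,
    )
    assert report.n_total == len(reads), "demux lost reads"
    log.event(
        "demux",
        kept=report.n_kept,
        rejected_no_tag_or_primer=report.rejected_no_tag_or_primer,
        rejected_short=report.rejected_short,
    )
    for sample, kept in report.kept.items():
        formats.write_fasta(kept, out / f"{sample}.fasta")
        log.event("demux_sample", sample=sample, kept=len(kept))

    # --- search + assign --------------------------------------------------
    params = AlignmentParams()
    taxonomy_df = formats.read_taxonomy(config.taxonomy)
    tax_map = {
        r.accession: (r.family, r.genus or None, r.species or None)
        for r in taxonomy_df.itertuples()
    }
    refs_by_acc = {r.accession: r for r in references}

    compositions: list[SampleComposition] = []
    all_rows: list[dict] = []
    summary_rows = []
    for sample, kept in report.kept.items():
        if not kept:
            continue
        tops = search_sample(kept, references, params,
                             strand=config.strand, tie_tol=config.tie_tol)
        reads_by_id = {r.id: r for r in kept}
        all_rows.extend(hits_table_rows(tops, reads_by_id, refs_by_acc, params))
        alog = assign_mod.AssignLog()
        assignments = [assign_mod.consensus_assign(t, tax_map) for t in tops]
        comp = assign_mod.compose_sample(
            sample, assignments,
            checklist=checklist,
            min_reads=config.min_reads,
            filter_order=config.filter_order,
            log=alog,
        )
        identified = comp.total_identified
        conserved = identified + comp.unknown_reads + comp.filtered_reads
        assert conserved == len(kept), f"sample {sample}: reads not conserved"
        log.event(
            "assign", sample=sample, reads=len(kept), identified=identified,
            unknown=comp.unknown_reads, filtered_low_abundance=comp.filtered_reads,
            reclassified_to_genus=sum(alog.reclassified_to_genus.values()),
        )
        compositions.append(comp)
        qs = quality_summary(kept) if all(r.quality is not None for r in kept) else None
        summary_rows.append(
            {
                "sample": sample,
                "reads_kept": len(kept),
                "identified": identified,
                "pct_identified": compare_mod.percent(identified, len(kept)),
                "mean_len": None if qs is None else round(qs.mean_len, 1),
                "sd_len": None if qs is None else round(qs.sd_len, 1),
                "mean_qv": None if qs is None else round(qs.mean_qv, 1),
                "sd_qv": None if qs is None else round(qs.sd_qv, 1),
                "pct_reads_qv_gt20": None if qs is None else qs.pct_reads_qv_gt20,
            }
        )

    formats.write_hits_table(all_rows, out / "hits.tsv")
    formats.write_composition(compositions, out / "composition.csv")
    _atomic_write(
        out / "sample_summary.csv",
        pd.DataFrame(summary_rows).to_csv(index=False),
    )

    # --- compare ----------------------------------------------------------
    if config.pollen:
        pollen = formats.read_pollen_counts(config.pollen)
        tax_index = compare_mod.TaxonomyIndex.from_table(taxonomy_df)
        report_rows = []
        for comp in compositions:
            if comp.sample not in pollen.table:
                continue
            ov = compare_mod.overlap_breakdown(comp, pollen, tax_index)
            prof = compare_mod.resolution_profile(list(comp.taxa))
            report_rows.append(
                {
                    "sample": comp.sample,
                    "n_dna_taxa": len(comp.rows),
                    "n_micro_taxa": len(pollen.taxa(comp.sample)),
                    "both": len(ov.both),
                    "dna_only": len(ov.dna_only),
                    "micro_only_multi": len(ov.micro_only_multi),
                    "micro_only_single": len(ov.micro_only_single),
                    "similarity_pct": ov.similarity_pct,
                    "dna_pct_family": prof.pct_family,
                    "dna_pct_genus": prof.pct_genus,
                    "dna_pct_species": prof.pct_species,
                }
            )
            log.event("compare", sample=comp.sample, similarity_pct=ov.similarity_pct)
        corr = compare_mod.abundance_correlations(
            compositions, pollen, tax_index,
            exclude_single_grain=config.exclude_single_grain,
            union_zero_fill=config.union_zero_fill,
        )
        corr_df = pd.DataFrame(
            [
                {
                    "sample": c.sample, "rho": round(c.rho, 3), "n": c.n,
                    "p_raw": round(c.p_raw, 4), "p_bonferroni": round(c.p_bonferroni, 4),
                    "significant": c.p_bonferroni < 0.05,
                }
                for c in corr
            ]
        )
        _atomic_write(out / "comparison.csv", pd.DataFrame(report_rows).to_csv(index=False))
        _atomic_write(out / "correlations.csv", corr_df.to_csv(index=False))

    log.write(out / "run.log")
    return PipelineResult(
        compositions=compositions, demux_report=report, log=log, out_dir=out
    )


def write_scenario(scenario, out_dir) -> dict[str, Path]:
    """Materialise a simulated scenario as pipeline input files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref_fasta = out / "references.fasta"
    formats.write_fasta(
        [AmpliconRead(id=r.accession, bases=r.bases) for r in scenario.references],
        ref_fasta,
    )
    tax_path = out / "taxonomy.tsv"
    formats.write_taxonomy(scenario.taxonomy.taxonomy_table(scenario.references), tax_path)
    chk_path = out / "checklist.tsv"
    formats.write_checklist(scenario.checklist, chk_path)
    man_path = out / "manifest.tsv"
    formats.write_manifest(scenario.manifest, man_path)
    reads_path = out / "reads.fastq"
    pooled = [r for sample in scenario.reads.values() for r in sample]
    formats.write_fastq(pooled, reads_path)
    pollen_path = out / "pollen.tsv"
    formats.write_pollen_counts(scenario.pollen, pollen_path)
    truth_path = out / "truth.csv"
    scenario.truth.to_csv(truth_path, index=False)
    return {
        "references": ref_fasta, "taxonomy": tax_path, "checklist": chk_path,
        "manifest": man_path, "reads": reads_path, "pollen": pollen_path,
        "truth": truth_path,
    }
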