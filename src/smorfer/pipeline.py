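"""Orchestration of the three detection modules and the candidate funnel.

Stage order: putative -> non_annotated -> ft_genomic (genomic GC
periodicity) -> translated (footprint count) -> 3nt_translated (calibrated
footprint periodicity), with the TIS call as an independent flag intersected
at the end.  Modules are skippable: a genome-only run stops after the
genomic stages; Ribo-Seq and TIS-Ribo-Seq stages engage only when their
alignments are configured.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Sequence

from . import io as fio
from .orfs import OrfConfig, filter_unannotated, find_orfs
from .periodicity import FtThresholds, score_orfs_genomic
from .tis import TisConfig, build_mid_track, score_tis
from .translation import (
    OffsetTable,
    TranslationThresholds,
    a_site_vector,
    calibrate_offsets,
    count_rpfs,
    classify_3nt_translated,
)

logger = logging.getLogger("smorfer")

_STAGE_ORDER = {"putative": 0, "ft_genomic": 1, "translated": 2,
                "3nt_translated": 3}


def in_stage(orf: fio.OrfCandidate, stage: str) -> bool:
    """Whether a candidate reached (at least) the given funnel stage."""
    if stage == "tis":
        return orf.tis_positive
    return _STAGE_ORDER[orf.category] >= _STAGE_ORDER[stage]


@dataclass
class RunConfig:
    """Paths, thresholds and switches for one pipeline run."""

    genome: str
    annotation: str | None = None
    ribo_alignments: list[str] = field(default_factory=list)
    tis_alignments: list[str] = field(default_factory=list)
    out_dir: str | None = None
    orf: OrfConfig = field(default_factory=OrfConfig)
    ft: FtThresholds = field(default_factory=FtThresholds)
    translation: TranslationThresholds = field(default_factory=TranslationThresholds)
    tis: TisConfig = field(default_factory=TisConfig)
    offsets: OffsetTable | str = "auto"
    read_lengths: tuple[int, ...] = (27, 28, 29, 30)
    ft_band: str = "closed"
    annotation_feature_types: frozenset = frozenset({"gene", "CDS"})

    def validate(self) -> None:
        for path in ([self.genome]
                     + ([self.annotation] if self.annotation else [])
                     + list(self.ribo_alignments) + list(self.tis_alignments)):
            if not os.path.exists(path):
                raise FileNotFoundError(f"configured input missing: {path}")
        if self.offsets == "auto" and self.ribo_alignments and not self.annotation:
            raise ValueError(
                "offset calibration (offsets='auto') needs an annotation with "
                "CDS features; provide one or pass an explicit OffsetTable")


@dataclass
class FunnelReport:
    """Per-stage candidate counts and start-codon usage, Table-style."""

    counts: dict[str, int] = field(default_factory=dict)
    start_codons: dict[str, dict[str, int]] = field(default_factory=dict)
    offsets_used: dict[int, int] | None = None

    def to_json(self, path=None) -> str:
        obj = {"counts": self.counts, "start_codons": self.start_codons,
               "offsets_used": self.offsets_used}
        text = json.dumps(obj, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def start_codon_breakdown(
    orfs: Sequence[fio.OrfCandidate],
    stage: str,
    codons: Sequence[str] = ("ATG", "GTG", "TTG", "CTG"),
) -> dict[str, int]:
    """Start-codon usage within one funnel stage; sums to the stage total."""
    out = {c: 0 for c in codons}
    for o in orfs:
        if in_stage(o, stage) and o.start_codon in out:
            out[o.start_codon] += 1
    return out


def cross_compare(
    orfs: Sequence[fio.OrfCandidate],
    ribo_run: bool = True,
    tis_run: bool = True,
) -> dict[str, int]:
    """Intersections of translation evidence with the TIS flag.

    Callers orchestrating modules themselves must confirm both the Ribo-Seq
    and the TIS module actually ran; intersecting unset evidence is an error,
    not an empty result.
    """
    if not (ribo_run and tis_run):
        raise ValueError("cross-comparison needs both the Ribo-Seq and the "
                         "TIS module to have run")
    translated = {o.key for o in orfs if in_stage(o, "translated")}
    three_nt = {o.key for o in orfs if in_stage(o, "3nt_translated")}
    tis = {o.key for o in orfs if o.tis_positive}
    return {
        "translated_and_tis": len(translated & tis),
        "3nt_translated_and_tis": len(three_nt & tis),
    }


def _load_reads(paths: Sequence[str], lengths: Sequence[int]):
    lo, hi = min(lengths), max(lengths)
    reads = []
    for p in paths:
        reads.extend(r for r in fio.read_alignments(p, lo, hi)
                     if r.length in set(lengths))
    return reads


def run_pipeline(config: RunConfig) -> tuple[FunnelReport, list[fio.OrfCandidate]]:
    """Run the configured modules and return the funnel plus all candidates.

    Deterministic for fixed inputs and config.  When ``out_dir`` is set,
    per-stage BED files, the master TSV and the funnel JSON are written.
    """
    config.validate()
    report = FunnelReport()
    t0 = time.time()

    genomes = fio.read_fasta(config.genome)
    orfs: list[fio.OrfCandidate] = []
    for g in genomes:
        orfs.extend(find_orfs(g, config.orf))
    report.counts["putative"] = len(orfs)
    logger.info("putative ORFs: %d (len %d-%d nt)", len(orfs),
                config.orf.min_len_nt, config.orf.max_len_nt)

    features = []
    if config.annotation:
        features = fio.read_annotation(
            config.annotation, set(config.annotation_feature_types))
        orfs = filter_unannotated(orfs, features,
                                  stranded=config.orf.annotation_filter_stranded)
        report.counts["non_annotated"] = len(orfs)
        logger.info("non-annotated: %d (stranded=%s)", len(orfs),
                    config.orf.annotation_filter_stranded)

    genome_by_id = {g.seq_id: g for g in genomes}
    for g_id, g in genome_by_id.items():
        score_orfs_genomic(g, [o for o in orfs if o.seq_id == g_id],
                           config.ft, band=config.ft_band)
    ft_passing = [o for o in orfs if in_stage(o, "ft_genomic")]
    report.counts["ft_genomic"] = len(ft_passing)
    report.start_codons["ft_genomic"] = start_codon_breakdown(
        orfs, "ft_genomic", config.orf.start_codons)
    logger.info("genomic periodicity FT > %g: %d", config.ft.genomic_cutoff,
                len(ft_passing))

    if config.ribo_alignments:
        reads = _load_reads(config.ribo_alignments, config.read_lengths)
        logger.info("Ribo-Seq reads in length bins %s: %d",
                    sorted(config.read_lengths), len(reads))
        count_rpfs(ft_passing, reads, config.translation)
        if isinstance(config.offsets, OffsetTable):
            offsets = config.offsets
        else:
            cds = [f for f in features if f.feature_type == "CDS"] or features
            offsets = calibrate_offsets(reads, cds, config.read_lengths)
        report.offsets_used = dict(offsets.entries)
        logger.info("A-site offsets (read length -> nt): %s", offsets.entries)
        eligible = [o for o in ft_passing
                    if o.rpf_count >= config.translation.min_rpf
                    and o.rpk >= config.translation.min_rpk]
        profiles = {o.key: a_site_vector(o, reads, offsets) for o in eligible}
        classify_3nt_translated(ft_passing, profiles, config.translation,
                                band=config.ft_band)
        report.counts["translated"] = sum(
            1 for o in orfs if in_stage(o, "translated"))
        report.counts["3nt_translated"] = sum(
            1 for o in orfs if in_stage(o, "3nt_translated"))
        report.start_codons["translated"] = start_codon_breakdown(
            orfs, "translated", config.orf.start_codons)
        logger.info("translated (>= %d RPF): %d; 3nt-translated (FT > %g at "
                    ">= %g RPK): %d", config.translation.min_rpf,
                    report.counts["translated"], config.translation.rpf_ft_cutoff,
                    config.translation.min_rpk, report.counts["3nt_translated"])

    if config.tis_alignments:
        tis_reads = _load_reads(config.tis_alignments, config.read_lengths)
        track = build_mid_track(tis_reads)
        score_tis(ft_passing, track, config.tis)
        report.counts["tis_positive"] = sum(1 for o in orfs if o.tis_positive)
        report.start_codons["tis_positive"] = start_codon_breakdown(
            orfs, "tis", config.orf.start_codons)
        logger.info("TIS-positive (>= %d mid-nt in window): %d",
                    config.tis.min_tis_count, report.counts["tis_positive"])

    if config.ribo_alignments and config.tis_alignments:
        report.counts.update(cross_compare(orfs))
        logger.info("cross-comparison: %d translated+TIS, %d 3nt-translated+TIS",
                    report.counts["translated_and_tis"],
                    report.counts["3nt_translated_and_tis"])

    logger.info("pipeline finished in %.1f s", time.time() - t0)

    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        fio.write_candidates(orfs, os.path.join(config.out_dir, "candidates.tsv"))
        for stage in ("putative", "ft_genomic", "translated", "3nt_translated"):
            if stage in ("translated", "3nt_translated") and \
                    not config.ribo_alignments:
                continue
            stage_orfs = [o for o in orfs if in_stage(o, stage)]
            fio.write_candidates(
                stage_orfs, os.path.join(config.out_dir, f"{stage}.bed"), "bed")
        report.to_json(os.path.join(config.out_dir, "funnel.json"))
    return report, orfs
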