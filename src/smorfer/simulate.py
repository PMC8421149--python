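"""Deterministic synthetic genomes and footprint alignments with known truth.

The generator emulates the three signals the pipeline detects:

* planted smORFs whose codons carry a position-3 GC bias (codon positions
  1 and 2 get GC probability ``1 - strength``, position 3 gets ``strength``),
  against an i.i.d. background with no engineered period — at strength 1.0
  every planted codon is W-W-S, at strength 0.5 on a 50% GC background the
  planted ORFs are statistically indistinguishable from it;
* ribosome footprints whose true A site sits on a codon start with
  probability ``1 - frame_noise``, with the 3' end placed at the A site plus
  a known per-length offset; annotated calibration genes additionally carry
  an elevated stop-codon occupancy (terminating-ribosome dwell) so the
  3'-end stop metagene has a modal peak;
* TIS reads whose middle nucleotides pile over planted start codons within
  the start +/- 1 codon window.

Shuffled-control ORFs (valid start/stop, internal sequence drawn from the
background composition, no reads) are planted alongside as negatives.  One
global seed governs everything; each component draws from its own derived
stream, so adding a stage never perturbs earlier draws.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .io import AlignedRead, GeneFeature, GenomeRecord, reverse_complement
from .orfs import START_CODONS, STOP_CODONS
from .tis import middle_nt_index

_PLACE_MARGIN = 60  # nt kept free around every planted element


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic data set."""

    seed: int = 0
    genome_length: int = 40_000
    n_planted_orfs: int = 20
    planted_lengths: tuple[int, ...] = (75, 90, 105, 120, 135, 150)
    gc_periodicity_strength: float = 0.9
    background_gc: float = 0.5
    rpf_per_orf: int = 50
    true_offset_by_length: dict[int, int] = field(
        default_factory=lambda: {27: 11, 28: 11, 29: 12, 30: 12})
    tis_reads_per_start: int = 10
    frame_noise: float = 0.1
    n_control_orfs: int = 20
    n_annotated_genes: int = 6
    gene_length_nt: int = 300
    gene_rpf_per_gene: int = 250
    stop_pause_weight: float = 6.0

    def __post_init__(self) -> None:
        for L in self.planted_lengths:
            if L % 3 or not 9 <= L <= 150:
                raise ValueError(f"planted length {L} must be a multiple of 3 in 9-150")
        if not 0.0 <= self.gc_periodicity_strength <= 1.0:
            raise ValueError("gc_periodicity_strength must be in [0, 1]")
        if not 0.0 <= self.frame_noise <= 1.0:
            raise ValueError("frame_noise must be in [0, 1]")


@dataclass
class PlantedOrf:
    seq_id: str
    strand: str
    start: int
    end: int
    start_codon: str
    role: str  # "smorf" | "control" | "gene"

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple:
        return (self.seq_id, self.strand, self.start, self.end)


@dataclass
class FixtureTruth:
    """Ground truth consistent with the emitted files."""

    planted: list[PlantedOrf] = field(default_factory=list)
    controls: list[PlantedOrf] = field(default_factory=list)
    genes: list[PlantedOrf] = field(default_factory=list)
    read_a_site_codons: list[dict] = field(default_factory=list)
    tis_counts: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        obj = {
            "planted": [asdict(p) for p in self.planted],
            "controls": [asdict(p) for p in self.controls],
            "genes": [asdict(p) for p in self.genes],
            "read_a_site_codons": self.read_a_site_codons,
            "tis_counts": {"|".join(map(str, k)): v
                           for k, v in self.tis_counts.items()},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def _draw_base(rng, p_gc: float) -> str:
    if rng.random() < p_gc:
        return "G" if rng.random() < 0.5 else "C"
    return "A" if rng.random() < 0.5 else "T"


def _periodic_codon(rng, strength: float) -> str:
    while True:
        codon = (_draw_base(rng, 1.0 - strength) + _draw_base(rng, 1.0 - strength)
                 + _draw_base(rng, strength))
        if codon not in STOP_CODONS:
            return codon


def _background_codon(rng, gc: float) -> str:
    while True:
        codon = "".join(_draw_base(rng, gc) for _ in range(3))
        if codon not in STOP_CODONS:
            return codon


def _orf_sequence(rng, length_nt: int, strength: float | None,
                  background_gc: float) -> str:
    """Start codon + internal codons + stop codon; periodic when strength is
    given, background-composition (shuffled-control) otherwise."""
    n_internal = length_nt // 3 - 2
    start = START_CODONS[rng.integers(len(START_CODONS))]
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    if strength is None:
        internal = "".join(_background_codon(rng, background_gc)
                           for _ in range(n_internal))
    else:
        internal = "".join(_periodic_codon(rng, strength)
                           for _ in range(n_internal))
    return start + internal + stop


def make_genome(spec: FixtureSpec, seq_id: str = "synth_chr"
                ) -> tuple[GenomeRecord, list[GeneFeature], FixtureTruth]:
    """Build the toy genome, its annotation (calibration genes) and truth."""
    rng = _rng(spec, 0)
    n = spec.genome_length
    letters = np.array(list("GCAT"))
    p = [spec.background_gc / 2, spec.background_gc / 2,
         (1 - spec.background_gc) / 2, (1 - spec.background_gc) / 2]
    genome = list(rng.choice(letters, size=n, p=p))

    truth = FixtureTruth()
    occupied: list[tuple[int, int]] = []

    def place(length: int) -> int:
        for _ in range(500):
            s = int(rng.integers(_PLACE_MARGIN, n - length - _PLACE_MARGIN))
            if all(s - _PLACE_MARGIN >= e or s + length + _PLACE_MARGIN <= b
                   for b, e in occupied):
                occupied.append((s, s + length))
                return s
        raise RuntimeError(
            "could not place non-overlapping planted ORFs; "
            "increase genome_length or reduce the number of planted elements")

    def insert(seq: str, start: int, strand: str) -> None:
        ins = seq if strand == "+" else reverse_complement(seq)
        genome[start : start + len(seq)] = list(ins)

    plan = (
        [("smorf", spec.planted_lengths[i % len(spec.planted_lengths)],
          spec.gc_periodicity_strength) for i in range(spec.n_planted_orfs)]
        + [("control", spec.planted_lengths[i % len(spec.planted_lengths)],
            None) for i in range(spec.n_control_orfs)]
        + [("gene", spec.gene_length_nt, spec.gc_periodicity_strength)
           for _ in range(spec.n_annotated_genes)]
    )
    features: list[GeneFeature] = []
    for idx, (role, length, strength) in enumerate(plan):
        seq = _orf_sequence(rng, length, strength, spec.background_gc)
        start = place(length)
        strand = "+" if rng.random() < 0.5 else "-"
        insert(seq, start, strand)
        planted = PlantedOrf(seq_id, strand, start, start + length, seq[:3], role)
        if role == "smorf":
            truth.planted.append(planted)
        elif role == "control":
            truth.controls.append(planted)
        else:
            truth.genes.append(planted)
            features.append(GeneFeature(seq_id, strand, start, start + length,
                                        "CDS", f"gene_{idx}"))
    record = GenomeRecord(seq_id, "".join(genome))
    return record, features, truth


def _emit_read(rng, spec, orf: PlantedOrf, genome_len: int,
               codon_weights: np.ndarray) -> tuple[AlignedRead, int] | None:
    """One footprint for one ORF; returns (read, true A-site codon)."""
    lengths = sorted(spec.true_offset_by_length)
    ncod = orf.length_nt // 3
    codon = int(rng.choice(ncod, p=codon_weights))
    pos_in_orf = 3 * codon
    # out-of-frame reads land uniformly over the codon's three nts
    if spec.frame_noise > 0 and rng.random() < spec.frame_noise:
        pos_in_orf += int(rng.integers(0, 3))
        pos_in_orf = min(pos_in_orf, orf.length_nt - 1)
    length = int(lengths[rng.integers(len(lengths))])
    off = spec.true_offset_by_length[length]
    if orf.strand == "+":
        a_nt = orf.start + pos_in_orf
        g3 = a_nt + off
        start, end = g3 - length + 1, g3 + 1
    else:
        a_nt = orf.end - 1 - pos_in_orf
        g3 = a_nt - off
        start, end = g3, g3 + length
    if start < 0 or end > genome_len:
        return None
    return AlignedRead(orf.seq_id, orf.strand, start, end), codon


def make_ribo_reads(truth: FixtureTruth, spec: FixtureSpec,
                    genome_len: int | None = None) -> list[AlignedRead]:
    """Footprints for planted smORFs (uniform codon occupancy) and for the
    annotated calibration genes (stop-codon dwell of ``stop_pause_weight``).
    Control ORFs receive none.  Per-read true A-site codons are appended to
    ``truth.read_a_site_codons``."""
    rng = _rng(spec, 1)
    genome_len = genome_len or spec.genome_length
    reads: list[AlignedRead] = []
    for orf in truth.planted + truth.genes:
        ncod = orf.length_nt // 3
        w = np.ones(ncod)
        n_reads = spec.rpf_per_orf
        if orf.role == "gene":
            w[-1] = spec.stop_pause_weight
            n_reads = spec.gene_rpf_per_gene
        w /= w.sum()
        for _ in range(n_reads):
            emitted = _emit_read(rng, spec, orf, genome_len, w)
            if emitted is None:
                continue
            read, codon = emitted
            reads.append(read)
            truth.read_a_site_codons.append(
                {"orf": list(orf.key), "codon": codon,
                 "read": [read.seq_id, read.strand, read.start, read.end]})
    return reads


def make_tis_reads(truth: FixtureTruth, spec: FixtureSpec,
                   genome_len: int | None = None) -> list[AlignedRead]:
    """Initiation footprints: middle nucleotides land in the start +/- 1
    codon window, peaked over the start codon itself."""
    rng = _rng(spec, 2)
    genome_len = genome_len or spec.genome_length
    deltas = np.arange(-3, 6)
    weights = np.array([1, 1, 1, 4, 5, 4, 1, 1, 1], dtype=float)
    weights /= weights.sum()
    lengths = sorted(spec.true_offset_by_length)
    reads: list[AlignedRead] = []
    for orf in truth.planted + truth.genes:
        n_placed = 0
        for _ in range(spec.tis_reads_per_start):
            delta = int(rng.choice(deltas, p=weights))
            length = int(lengths[rng.integers(len(lengths))])
            i = middle_nt_index(length)
            if orf.strand == "+":
                mid = orf.start + delta
                start, end = mid - (i - 1), mid - (i - 1) + length
            else:
                mid = orf.end - 1 - delta
                end = mid + i
                start = end - length
            if start < 0 or end > genome_len:
                continue
            reads.append(AlignedRead(orf.seq_id, orf.strand, start, end))
            n_placed += 1
        truth.tis_counts[orf.key] = n_placed
    return reads


def write_fasta(record: GenomeRecord, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{record.seq_id}\n")
        for i in range(0, record.length, 70):
            fh.write(record.sequence[i : i + 70] + "\n")


def write_gff3(features: Sequence[GeneFeature], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(f"{f.seq_id}\tsmorfer_fixture\t{f.feature_type}\t"
                     f"{f.start + 1}\t{f.end}\t.\t{f.strand}\t0\t"
                     f"ID={f.feature_id}\n")


def write_reads_bed(reads: Sequence[AlignedRead], path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"{r.seq_id}\t{r.start}\t{r.end}\tread_{i}\t0\t{r.strand}\n")


def write_reads_sam(reads: Sequence[AlignedRead], genome: GenomeRecord, path) -> None:
    """Plain-text SAM with sequences taken from the genome (reverse reads
    stored reverse-complemented, per SAM convention)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{genome.seq_id}\tLN:{genome.length}\n")
        for i, r in enumerate(reads):
            seq = genome.sequence[r.start : r.end]
            flag = 0
            if r.strand == "-":
                seq = reverse_complement(seq)
                flag = 16
            fh.write(f"read_{i}\t{flag}\t{genome.seq_id}\t{r.start + 1}\t42\t"
                     f"{r.length}M\t*\t0\t0\t{seq}\t*\n")


def write_fixture(spec: FixtureSpec, out_dir,
                  reads_format: str = "bed") -> dict[str, str]:
    """Emit the full fixture (FASTA, GFF3, Ribo/TIS alignments, truth JSON);
    returns the file paths."""
    os.makedirs(out_dir, exist_ok=True)
    record, features, truth = make_genome(spec)
    ribo = make_ribo_reads(truth, spec, record.length)
    tis = make_tis_reads(truth, spec, record.length)
    paths = {
        "genome": os.path.join(out_dir, "genome.fasta"),
        "annotation": os.path.join(out_dir, "annotation.gff3"),
        "ribo": os.path.join(out_dir, f"ribo_reads.{reads_format}"),
        "tis": os.path.join(out_dir, f"tis_reads.{reads_format}"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    write_fasta(record, paths["genome"])
    write_gff3(features, paths["annotation"])
    if reads_format == "bed":
        write_reads_bed(ribo, paths["ribo"])
        write_reads_bed(tis, paths["tis"])
    elif reads_format == "sam":
        write_reads_sam(ribo, record, paths["ribo"])
        write_reads_sam(tis, record, paths["tis"])
    else:
        raise ValueError(f"unknown reads format {reads_format!r}")
    truth.to_json(paths["truth"])
    return paths
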