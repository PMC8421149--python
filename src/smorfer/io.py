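"""Readers and writers for the standard formats the pipeline touches.

All coordinates are internally 0-based, half-open ``[start, end)``, on genomic
(not transcript) coordinates for both strands.  GFF3/GTF input (1-based,
inclusive) is converted on read; BED is taken as-is.  For an aligned read the
biological 3' end is ``end - 1`` on the forward strand and ``start`` on the
reverse strand.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, fields
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

_VALID_BASES = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: columns of the candidate TSV report, in order
TSV_COLUMNS = [
    "seq_id", "strand", "start", "end", "start_codon", "stop_codon",
    "length_nt", "gc_ft_score", "rpf_count", "rpk", "rpf_ft_score",
    "tis_count", "category", "tis_positive",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """One contig/replicon: uppercase DNA over {A,C,G,T,N}."""

    seq_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        norm = self.sequence.upper().replace("U", "T")
        bad = set(norm) - _VALID_BASES
        if bad:
            raise ValueError(
                f"record {self.seq_id!r}: unsupported characters {sorted(bad)}; "
                "only A,C,G,T,N (and lowercase / U) are accepted"
            )
        object.__setattr__(self, "sequence", norm)


@dataclass(frozen=True)
class GeneFeature:
    """An annotated interval (gene, CDS, rRNA, ...) on a contig."""

    seq_id: str
    strand: str
    start: int
    end: int
    feature_type: str = "gene"
    feature_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.feature_id!r}: invalid interval "
                f"[{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class AlignedRead:
    """One uniquely mapped ribosome-protected fragment."""

    seq_id: str
    strand: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def three_prime(self) -> int:
        """Genomic position of the biological 3' end."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class OrfCandidate:
    """A putative ORF with its accumulated evidence.

    ``category`` tracks the furthest pipeline stage reached
    (putative -> ft_genomic -> translated -> 3nt_translated); the TIS call is
    an independent flag because module C can run without module B.
    """

    seq_id: str
    strand: str
    start: int
    end: int
    start_codon: str
    stop_codon: str
    in_annotated_region: bool | None = None
    gc_ft_score: float | None = None
    rpf_count: int = 0
    rpk: float = 0.0
    rpf_ft_score: float | None = None
    tis_count: int = 0
    tis_positive: bool = False
    category: str = "putative"

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def stop_key(self) -> tuple[str, str, int]:
        """(seq_id, strand, genomic coordinate of the stop codon's last nt)."""
        pos = self.end - 1 if self.strand == "+" else self.start
        return (self.seq_id, self.strand, pos)

    @property
    def start_pos(self) -> int:
        """Genomic coordinate of the start codon's first nt (translation dir)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def key(self) -> tuple[str, str, int, int]:
        """Stable identity used for stage intersections."""
        return (self.seq_id, self.strand, self.start, self.end)


def read_fasta(path: str | os.PathLike) -> list[GenomeRecord]:
    """Read a (multi-)FASTA into :class:`GenomeRecord` objects.

    Sequences are folded to uppercase and U is mapped to T; any residue
    outside {A,C,G,T,N} raises.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: line {lineno}: expected FASTA header '>', "
                        f"got {line.strip()[:30]!r}"
                    )
                break
        else:
            raise ValueError(f"{path}: empty FASTA file")
    records = [
        GenomeRecord(seq_id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def _read_bed_features(path: str | os.PathLike) -> list[GeneFeature]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            start, end = int(cols[1]), int(cols[2])
            if end < start:
                raise ValueError(f"{path}: line {lineno}: end < start")
            name = cols[3] if len(cols) > 3 else f"bed_{lineno}"
            strand = cols[5] if len(cols) > 5 else "+"
            out.append(GeneFeature(cols[0], strand, start, end, "region", name))
    return out


def read_annotation(
    path: str | os.PathLike,
    feature_types: set[str] | None = None,
) -> list[GeneFeature]:
    """Read gene annotation from GFF3/GTF (1-based) or BED (0-based).

    ``feature_types`` selects which rows are returned (default: ``{"gene"}``
    for GFF/GTF; all rows for BED, which has no type column).
    """
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".bed":
        feats = _read_bed_features(path)
        if feature_types:
            feats = [f for f in feats if f.feature_type in feature_types]
        return feats
    if ext not in {".gff", ".gff3", ".gtf"}:
        raise ValueError(f"{path}: unknown annotation extension {ext!r} "
                         "(expected .gff/.gff3/.gtf/.bed)")

    # cheap pre-scan so coordinate errors carry a line number
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) >= 5:
                try:
                    s, e = int(cols[3]), int(cols[4])
                except ValueError:
                    raise ValueError(f"{path}: line {lineno}: non-integer coordinates")
                if e < s:
                    raise ValueError(f"{path}: line {lineno}: end < start")

    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    if feature_types is None:
        feature_types = {"gene"}
    out = []
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype not in feature_types:
            continue
        strand = feat.strand if feat.strand in "+-" else "+"
        out.append(GeneFeature(
            seq_id=feat.seqid, strand=strand,
            start=feat.start - 1, end=feat.end,
            feature_type=feat.featuretype, feature_id=feat.id,
        ))
    return out


def _read_bed_reads(path, min_len, max_len) -> Iterator[AlignedRead]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ValueError(f"{path}: line {lineno}: BED6 required for reads")
            start, end = int(cols[1]), int(cols[2])
            if not min_len <= end - start <= max_len:
                continue
            yield AlignedRead(cols[0], cols[5], start, end)


def read_alignments(
    path: str | os.PathLike,
    min_len: int = 1,
    max_len: int = 10**9,
    min_mapq: int = 0,
) -> Iterator[AlignedRead]:
    """Stream mapped primary alignments from SAM/BAM or a 6-column BED.

    Unmapped, secondary and supplementary records are skipped.  Read length is
    the aligned reference span, so soft clips do not shift the 3' end.  Reads
    outside ``[min_len, max_len]`` are dropped.  Unique mapping is normally
    enforced upstream at mapping time; ``min_mapq`` allows re-filtering
    third-party SAM/BAM (no effect on BED, which carries no quality).
    """
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".bed":
        yield from _read_bed_reads(path, min_len, max_len)
        return

    import pysam

    save = pysam.set_verbosity(0)  # silence missing-index warning
    try:
        af = pysam.AlignmentFile(str(path), check_sq=False)
    finally:
        pysam.set_verbosity(save)
    with af:
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if min_mapq and rec.mapping_quality < min_mapq:
                continue
            start, end = rec.reference_start, rec.reference_end
            if end is None or not min_len <= end - start <= max_len:
                continue
            strand = "-" if rec.is_reverse else "+"
            yield AlignedRead(rec.reference_name, strand, start, end)


def candidates_to_frame(orfs: Sequence[OrfCandidate]) -> pd.DataFrame:
    rows = []
    for o in orfs:
        rows.append({
            "seq_id": o.seq_id, "strand": o.strand, "start": o.start,
            "end": o.end, "start_codon": o.start_codon,
            "stop_codon": o.stop_codon, "length_nt": o.length_nt,
            "gc_ft_score": o.gc_ft_score, "rpf_count": o.rpf_count,
            "rpk": o.rpk, "rpf_ft_score": o.rpf_ft_score,
            "tis_count": o.tis_count, "category": o.category,
            "tis_positive": o.tis_positive,
        })
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def write_candidates(
    orfs: Sequence[OrfCandidate],
    path: str | os.PathLike,
    format: str = "tsv",
) -> None:
    """Write candidates as a TSV report (all fields) or BED6.

    BED: 0-based half-open, ``<id>|<category>`` in the name column, the
    genomic FT score in the score column, strand in column 6.
    """
    fmt = format.lower()
    if fmt == "tsv":
        candidates_to_frame(orfs).to_csv(path, sep="\t", index=False)
    elif fmt == "bed":
        with open(path, "w") as fh:
            for i, o in enumerate(orfs):
                name = f"{o.seq_id}:{o.start}-{o.end}({o.strand})|{o.category}"
                score = 0.0 if o.gc_ft_score is None else o.gc_ft_score
                fh.write(f"{o.seq_id}\t{o.start}\t{o.end}\t{name}\t"
                         f"{score:.4g}\t{o.strand}\n")
    else:
        raise ValueError(f"unknown candidate format {format!r}")


def read_candidates(path: str | os.PathLike) -> list[OrfCandidate]:
    """Read back a TSV report written by :func:`write_candidates`."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(OrfCandidate(
            seq_id=str(row.seq_id), strand=row.strand,
            start=int(row.start), end=int(row.end),
            start_codon=row.start_codon, stop_codon=row.stop_codon,
            gc_ft_score=None if pd.isna(row.gc_ft_score) else float(row.gc_ft_score),
            rpf_count=int(row.rpf_count),
            rpk=float(row.rpk),
            rpf_ft_score=None if pd.isna(row.rpf_ft_score) else float(row.rpf_ft_score),
            tis_count=int(row.tis_count),
            tis_positive=bool(row.tis_positive),
            category=str(row.category),
        ))
    return out
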