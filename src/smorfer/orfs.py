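"""Genome-wide enumeration of putative ORFs (module A, first stage).

Every maximal in-frame span (start codon ... first in-frame stop codon) on
both strands and in all three frames per strand is reported.  Several start
codons sharing one stop yield several candidates with the same ``stop_key``
("maximal-to-stop" semantics), which is what makes unique-stop grouping a
meaningful reduction.  Codons containing N are neither starts nor stops and
reset the scan across them.  The scan is linear: ORFs spanning the origin of
a circular replicon are not called.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .io import GeneFeature, GenomeRecord, OrfCandidate, reverse_complement

START_CODONS = ("ATG", "GTG", "TTG", "CTG")
STOP_CODONS = ("TGA", "TAG", "TAA")


@dataclass(frozen=True)
class OrfConfig:
    """Length window and codon sets for the putative-ORF scan.

    Defaults target smORFs: 3 to 50 codons including start and stop
    (9-150 nt), the four most common prokaryotic start codons with equal
    weight, and the three universal stop codons.
    """

    min_len_nt: int = 9
    max_len_nt: int = 150
    start_codons: tuple[str, ...] = START_CODONS
    stop_codons: tuple[str, ...] = STOP_CODONS
    annotation_filter_stranded: bool = False

    def __post_init__(self) -> None:
        if self.min_len_nt < 9 or self.min_len_nt % 3:
            raise ValueError("min_len_nt must be >= 9 and divisible by 3")
        if self.max_len_nt < self.min_len_nt or self.max_len_nt % 3:
            raise ValueError("max_len_nt must be >= min_len_nt and divisible by 3")


def _scan_strand(seq, starts, stops, min_len, max_len):
    """Yield (start, end, start_codon, stop_codon) in local coordinates."""
    n = len(seq)
    bounded = max_len < 10**9
    for frame in range(3):
        pending: deque[int] = deque()
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if "N" in codon:
                pending.clear()
                continue
            if codon in stops:
                end = i + 3
                for s in pending:
                    if min_len <= end - s <= max_len:
                        yield (s, end, seq[s : s + 3], codon)
                pending.clear()
            elif codon in starts:
                pending.append(i)
            if bounded:
                while pending and i + 3 - pending[0] > max_len:
                    pending.popleft()


def find_orfs(genome: GenomeRecord, config: OrfConfig | None = None) -> list[OrfCandidate]:
    """Enumerate putative ORFs on both strands of one contig.

    Returns candidates sorted by (start, end, strand), each guaranteed to
    begin with a configured start codon, end at the first in-frame stop and
    contain no internal in-frame stop.
    """
    config = config or OrfConfig()
    starts = frozenset(config.start_codons)
    stops = frozenset(config.stop_codons)
    seq = genome.sequence
    n = len(seq)
    out: list[OrfCandidate] = []
    for s, e, sc, tc in _scan_strand(seq, starts, stops,
                                     config.min_len_nt, config.max_len_nt):
        out.append(OrfCandidate(genome.seq_id, "+", s, e, sc, tc))
    rc = reverse_complement(seq)
    for s, e, sc, tc in _scan_strand(rc, starts, stops,
                                     config.min_len_nt, config.max_len_nt):
        out.append(OrfCandidate(genome.seq_id, "-", n - e, n - s, sc, tc))
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out


def find_long_orfs(genome: GenomeRecord, min_len_nt: int = 1000) -> list[OrfCandidate]:
    """Enumerate ORFs strictly longer than ``min_len_nt`` (no upper bound)."""
    starts = frozenset(START_CODONS)
    stops = frozenset(STOP_CODONS)
    seq = genome.sequence
    n = len(seq)
    out = []
    for s, e, sc, tc in _scan_strand(seq, starts, stops, min_len_nt + 1, 10**9):
        out.append(OrfCandidate(genome.seq_id, "+", s, e, sc, tc))
    rc = reverse_complement(seq)
    for s, e, sc, tc in _scan_strand(rc, starts, stops, min_len_nt + 1, 10**9):
        out.append(OrfCandidate(genome.seq_id, "-", n - e, n - s, sc, tc))
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out


def filter_unannotated(
    orfs: list[OrfCandidate],
    features: list[GeneFeature],
    stranded: bool = False,
) -> list[OrfCandidate]:
    """Keep ORFs with zero overlap (>= 1 shared nt disqualifies) with any feature.

    With ``stranded=True`` only same-strand overlaps disqualify.  Sets
    ``in_annotated_region`` on every input candidate.
    """
    if orfs and features:
        orf_ids = {o.seq_id for o in orfs}
        feat_ids = {f.seq_id for f in features}
        if not orf_ids & feat_ids:
            raise ValueError(
                "no shared seq_ids between candidates and annotation: "
                f"candidates on {sorted(orf_ids)}, features on {sorted(feat_ids)}"
            )

    def key(seq_id, strand):
        return (seq_id, strand) if stranded else (seq_id,)

    merged: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
    by_key: dict[tuple, list[tuple[int, int]]] = {}
    for f in features:
        by_key.setdefault(key(f.seq_id, f.strand), []).append((f.start, f.end))
    for k, ivals in by_key.items():
        ivals.sort()
        ms, me = [], []
        for s, e in ivals:
            if ms and s <= me[-1]:
                me[-1] = max(me[-1], e)
            else:
                ms.append(s)
                me.append(e)
        merged[k] = (np.asarray(ms), np.asarray(me))

    kept = []
    for o in orfs:
        k = key(o.seq_id, o.strand)
        overlap = False
        if k in merged:
            ms, me = merged[k]
            idx = int(np.searchsorted(ms, o.end, side="left"))
            overlap = idx > 0 and int(me[idx - 1]) > o.start
        o.in_annotated_region = overlap
        if not overlap:
            kept.append(o)
    return kept


def group_by_stop(orfs: list[OrfCandidate]) -> dict[tuple, list[OrfCandidate]]:
    """Partition candidates by shared stop codon, longest-first within groups."""
    groups: dict[tuple, list[OrfCandidate]] = {}
    for o in orfs:
        groups.setdefault(o.stop_key, []).append(o)
    for g in groups.values():
        g.sort(key=lambda o: -o.length_nt)
    return groups
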