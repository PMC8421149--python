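"""Translation evidence from Ribo-Seq (module B).

Two gates: candidates covered by at least ``min_rpf`` footprints become
*translated*; among those with at least ``min_rpk`` coverage, candidates
whose 3'-end-calibrated A-site profile carries period-3 power above the
footprint FT cutoff become *3nt_translated*.

Calibration anchors on 3' ends: prokaryotic nucleases trim footprint 3' ends
more reproducibly than 5' ends, so per read-length bin a fixed distance from
the 3' end back to the A-site codon is inferred from a metagene around
annotated stop codons (the terminating ribosome's A site is the stop codon).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import AlignedRead, GeneFeature, OrfCandidate
from .periodicity import ft_score

#: A-site offsets used for E. coli / B. subtilis 27-30 nt footprint bins
#: (11 nt for lengths up to 28, 12 nt for 29-30); S. aureus uses 24-28 at 11.
DEFAULT_OFFSETS = {24: 11, 25: 11, 26: 11, 27: 11, 28: 11, 29: 12, 30: 12}


@dataclass(frozen=True)
class TranslationThresholds:
    min_rpf: int = 5
    min_rpk: float = 100.0
    rpf_ft_cutoff: float = 2.0

    def __post_init__(self) -> None:
        if self.min_rpf <= 0 or self.min_rpk <= 0 or self.rpf_ft_cutoff <= 0:
            raise ValueError("all translation thresholds must be > 0")


@dataclass
class OffsetTable:
    """Per read-length distance from the footprint 3' end back to the A site."""

    entries: dict[int, int]

    def __post_init__(self) -> None:
        for length, off in self.entries.items():
            if not 0 <= off < length:
                raise ValueError(f"offset {off} invalid for read length {length}")
        if not self.entries:
            raise ValueError("offset table has no calibrated length bins")

    @property
    def accepted_lengths(self) -> list[int]:
        return sorted(self.entries)

    @classmethod
    def default(cls) -> "OffsetTable":
        return cls(dict(DEFAULT_OFFSETS))


@dataclass
class CodonProfile:
    """Calibrated A-site counts per codon of one ORF."""

    orf_key: tuple
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _reads_by_key(reads: Iterable[AlignedRead]):
    by_key: dict[tuple[str, str], list[AlignedRead]] = {}
    for r in reads:
        by_key.setdefault((r.seq_id, r.strand), []).append(r)
    return by_key


def count_rpfs(
    orfs: Sequence[OrfCandidate],
    reads: Iterable[AlignedRead],
    thresholds: TranslationThresholds | None = None,
) -> list[OrfCandidate]:
    """Count same-strand footprints overlapping each ORF by >= 1 nt.

    Sets ``rpf_count`` and ``rpk`` (reads per kilobase of ORF length) and
    promotes candidates with ``rpf_count >= min_rpf`` to *translated*.
    Any-overlap counting is used for this gate; A-site placement only enters
    the calibrated profile.
    """
    thresholds = thresholds or TranslationThresholds()
    by_key = _reads_by_key(reads)
    sorted_arrays = {}
    for k, rs in by_key.items():
        starts = np.sort(np.array([r.start for r in rs]))
        ends = np.sort(np.array([r.end for r in rs]))
        sorted_arrays[k] = (starts, ends, len(rs))
    for o in orfs:
        k = (o.seq_id, o.strand)
        if k not in sorted_arrays:
            o.rpf_count, o.rpk = 0, 0.0
            continue
        starts, ends, n = sorted_arrays[k]
        # non-overlapping reads either end at/before the ORF or start at/after it
        n_left = int(np.searchsorted(ends, o.start, side="right"))
        n_right = n - int(np.searchsorted(starts, o.end, side="left"))
        o.rpf_count = n - n_left - n_right
        o.rpk = o.rpf_count * 1000.0 / o.length_nt
        if o.rpf_count >= thresholds.min_rpf and o.category != "3nt_translated":
            o.category = "translated"
    return list(orfs)


def _stop_anchor(f: GeneFeature) -> int:
    """Genomic coordinate of the first nt of the stop codon (translation
    direction); the feature interval is assumed to include the stop codon."""
    return f.end - 3 if f.strand == "+" else f.start + 2


def calibrate_offsets(
    reads: Iterable[AlignedRead],
    annotated_stops: Sequence[GeneFeature],
    length_bins: Sequence[int] = (27, 28, 29, 30),
) -> OffsetTable:
    """Infer the 3'-end -> A-site offset per read-length bin.

    For every read, the distance from its 3' end back to the nearest upstream
    stop-codon anchor is histogrammed per length bin; a terminating-ribosome
    peak makes the modal distance the offset.  A bin whose mode is less than
    twice the runner-up (including exact ties) is considered uncalibrated and
    dropped; so are empty bins.
    """
    if not annotated_stops:
        raise ValueError("offset calibration requires annotated stop codons")
    bins = set(length_bins)
    anchors: dict[tuple[str, str], np.ndarray] = {}
    grouped: dict[tuple[str, str], list[int]] = {}
    for f in annotated_stops:
        grouped.setdefault((f.seq_id, f.strand), []).append(_stop_anchor(f))
    for k, pos in grouped.items():
        anchors[k] = np.sort(np.array(pos))

    hists: dict[int, Counter] = {l: Counter() for l in bins}
    max_len = max(bins)
    for r in reads:
        if r.length not in bins:
            continue
        k = (r.seq_id, r.strand)
        if k not in anchors:
            continue
        g3 = r.three_prime
        pos = anchors[k]
        # candidate anchors with distance d = (3' end - anchor) in [0, read len)
        if r.strand == "+":
            lo = np.searchsorted(pos, g3 - max_len, side="left")
            hi = np.searchsorted(pos, g3, side="right")
            ds = g3 - pos[lo:hi]
        else:
            lo = np.searchsorted(pos, g3, side="left")
            hi = np.searchsorted(pos, g3 + max_len, side="right")
            ds = pos[lo:hi] - g3
        for d in ds:
            if 0 <= d < r.length:
                hists[r.length][int(d)] += 1

    entries: dict[int, int] = {}
    for length in sorted(bins):
        hist = hists[length]
        if not hist:
            warnings.warn(f"read length {length}: no reads near stop codons; "
                          "bin dropped", stacklevel=2)
            continue
        ranked = hist.most_common()
        mode_d, mode_n = ranked[0]
        runner_n = ranked[1][1] if len(ranked) > 1 else 0
        if mode_n < 2 * runner_n or (runner_n and mode_n == runner_n):
            warnings.warn(f"read length {length}: ambiguous stop metagene "
                          f"(mode {mode_n} vs runner-up {runner_n}); bin "
                          "marked uncalibrated", stacklevel=2)
            continue
        entries[length] = mode_d
    if not entries:
        raise ValueError("no read-length bin could be calibrated")
    return OffsetTable(entries)


def a_site_position(read: AlignedRead, offsets: OffsetTable) -> int | None:
    """Genomic position of the read's A-site nt, or None if the length bin
    is uncalibrated.  The offset is walked from the 3' end toward the 5' end
    along the read's own orientation."""
    off = offsets.entries.get(read.length)
    if off is None:
        return None
    return read.three_prime - off if read.strand == "+" else read.three_prime + off


def a_site_vector(
    orf: OrfCandidate,
    reads: Iterable[AlignedRead],
    offsets: OffsetTable,
) -> np.ndarray:
    """Per-nt A-site counts along the ORF in translation direction (length L).

    Reads of uncalibrated lengths and reads whose A site falls outside the
    ORF are skipped.
    """
    vec = np.zeros(orf.length_nt)
    for r in reads:
        if r.seq_id != orf.seq_id or r.strand != orf.strand:
            continue
        pos = a_site_position(r, offsets)
        if pos is None:
            continue
        in_orf = pos - orf.start if orf.strand == "+" else orf.end - 1 - pos
        if 0 <= in_orf < orf.length_nt:
            vec[in_orf] += 1
    return vec


def calibrated_profile(
    orf: OrfCandidate,
    reads: Iterable[AlignedRead],
    offsets: OffsetTable,
) -> CodonProfile:
    """Per-codon calibrated A-site counts (nt vector summed per codon)."""
    vec = a_site_vector(orf, reads, offsets)
    return CodonProfile(orf.key, vec.reshape(-1, 3).sum(axis=1).astype(int))


def classify_3nt_translated(
    orfs: Sequence[OrfCandidate],
    nt_profiles: Mapping[tuple, np.ndarray],
    thresholds: TranslationThresholds | None = None,
    band: str = "closed",
) -> list[OrfCandidate]:
    """FT-score calibrated A-site profiles and call *3nt_translated*.

    Only candidates passing both coverage gates (``rpf_count >= min_rpf`` and
    ``rpk >= min_rpk``) are scored; those above the cutoff are promoted, the
    rest remain *translated*.
    """
    thresholds = thresholds or TranslationThresholds()
    for o in orfs:
        if o.rpf_count < thresholds.min_rpf or o.rpk < thresholds.min_rpk:
            continue
        vec = nt_profiles.get(o.key)
        if vec is None:
            continue
        res = ft_score(vec, band=band)
        o.rpf_ft_score = res.score
        if not res.degenerate and res.score > thresholds.rpf_ft_cutoff:
            o.category = "3nt_translated"
    return list(orfs)
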