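"""Translation-initiation-site evidence from TIS-Ribo-Seq (module C).

Footprints from initiation-arrested ribosomes (retapamulin) pile over start
codons but cannot be offset-calibrated — coverage is absent at termination
and the drug blurs the P-site over at least two codons.  Instead, each
read's middle nucleotide is taken as its positional signature, and for each
candidate the middle-nucleotide counts over the start codon plus one codon
upstream and downstream (a 9-nt window by default) are summed.  Candidates
reaching ``min_tis_count`` are flagged TIS-positive, which also disambiguates
overlapping same-stop candidates whose start codons are >= 3 nt apart.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import AlignedRead, OrfCandidate


@dataclass(frozen=True)
class TisConfig:
    """Gate (>= min_tis_count middle nucleotides in window) and window size
    in codons on each side of the start codon (restrictive default: 1)."""

    min_tis_count: int = 5
    window_codons_up: int = 1
    window_codons_down: int = 1

    def __post_init__(self) -> None:
        if self.min_tis_count < 1:
            raise ValueError("min_tis_count must be >= 1")
        if self.window_codons_up < 0 or self.window_codons_down < 0:
            raise ValueError("window sizes must be >= 0")


def middle_nt_index(read_length: int) -> int:
    """1-based index (from the 5' end) of a read's middle nucleotide.

    Odd lengths have an exact middle; for even lengths the 3' nucleotide of
    the first half is taken (L=28 -> 14, same as L=27).
    """
    if read_length < 1:
        raise ValueError("read length must be >= 1")
    return (read_length + 1) // 2


@dataclass
class MidNtTrack:
    """Stranded per-position counts of TIS-read middle nucleotides."""

    counts: dict[tuple[str, str], Counter]
    total: int = 0

    def get(self, seq_id: str, strand: str, pos: int) -> int:
        return self.counts.get((seq_id, strand), Counter()).get(pos, 0)

    def window_sum(self, seq_id: str, strand: str, lo: int, hi: int) -> int:
        """Sum of counts over genomic [lo, hi); negative positions ignored."""
        track = self.counts.get((seq_id, strand))
        if not track:
            return 0
        return sum(track.get(p, 0) for p in range(max(lo, 0), hi))

    def to_bedgraph(self, path, strand: str) -> None:
        with open(path, "w") as fh:
            for (seq_id, s), track in sorted(self.counts.items()):
                if s != strand:
                    continue
                for pos in sorted(track):
                    fh.write(f"{seq_id}\t{pos}\t{pos + 1}\t{track[pos]}\n")


def build_mid_track(reads: Iterable[AlignedRead]) -> MidNtTrack:
    """Project each read onto its middle nucleotide's genomic position.

    The middle index is counted along the read's own 5'->3' axis, so on the
    reverse strand it is measured from the read's genomic end.
    """
    counts: dict[tuple[str, str], Counter] = {}
    total = 0
    for r in reads:
        i = middle_nt_index(r.length)
        pos = r.start + i - 1 if r.strand == "+" else r.end - 1 - (i - 1)
        counts.setdefault((r.seq_id, r.strand), Counter())[pos] += 1
        total += 1
    return MidNtTrack(counts, total)


def tis_window(orf: OrfCandidate, config: TisConfig | None = None) -> tuple[int, int]:
    """Genomic [lo, hi) spanning the start codon +/- the configured codons."""
    config = config or TisConfig()
    up = 3 * config.window_codons_up
    down = 3 * config.window_codons_down
    if orf.strand == "+":
        return orf.start - up, orf.start + 3 + down
    return orf.end - 3 - down, orf.end + up


def score_tis(
    orfs: Sequence[OrfCandidate],
    track: MidNtTrack,
    config: TisConfig | None = None,
) -> list[OrfCandidate]:
    """Set ``tis_count`` and ``tis_positive`` on every candidate."""
    config = config or TisConfig()
    for o in orfs:
        lo, hi = tis_window(o, config)
        o.tis_count = track.window_sum(o.seq_id, o.strand, lo, hi)
        o.tis_positive = o.tis_count >= config.min_tis_count
    return list(orfs)


def resolve_overlapping_starts(
    group: Sequence[OrfCandidate],
    track: MidNtTrack,
    config: TisConfig | None = None,
) -> dict[tuple, str]:
    """Assign start codons within one same-stop group from TIS signal.

    Returns per-candidate status: ``resolved`` for TIS-positive members whose
    start codon is more than one codon away from every other TIS-positive
    start, ``ambiguous`` for TIS-positive members with another passing start
    at most 3 nt away — adjacent or overlapping start codons whose
    middle-nucleotide windows blend (both are retained), ``unsupported``
    otherwise.
    """
    config = config or TisConfig()
    if len({o.stop_key for o in group}) > 1:
        raise ValueError("resolve_overlapping_starts expects one same-stop group")
    score_tis(group, track, config)
    passing = [o for o in group if o.tis_positive]
    status: dict[tuple, str] = {o.key: "unsupported" for o in group}
    for o in passing:
        close = [p for p in passing
                 if p.key != o.key and abs(p.start_pos - o.start_pos) <= 3]
        status[o.key] = "ambiguous" if close else "resolved"
    return status
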