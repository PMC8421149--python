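# Methods

## Model and procedure

The detector treats smORF annotation as three nearly independent filters
over an exhaustively enumerated candidate set.

**Candidate enumeration.** For each contig, both strands are scanned in all
three frames. Every in-frame start codon opens a candidate that closes at
the first in-frame stop codon ("maximal-to-stop" semantics): several starts
upstream of one stop therefore yield several overlapping candidates sharing
a `stop_key`, and unique-stop grouping is the natural deduplication.
Candidates are 9–150 nt by default (3–50 codons including start and stop;
the shortest encodes a dipeptide). Codons containing N are never starts or
stops and reset the scan, so no ORF bridges an assembly gap. The scan is
linear; ORFs spanning the origin of a circular replicon are not called —
a declared convention, not an oversight, since candidate counts are only
reproducible under a fixed origin policy.

**Genomic periodicity score.** Coding DNA biases G/C toward the third codon
position. For a candidate of length L, the per-nt GC indicator g(t) ∈ {0,1}
(N counts as 0) is transformed with the full-length DFT; magnitudes are
divided by L. The period-3 component sits at integer index k₃ = round(L/3)
and the period-1.5 component at round(2L/3) — on a real signal the latter
is the conjugate mirror of the former, which is why the two peaks always
co-occur. The score is the normalized magnitude at k₃ divided by the
arithmetic mean of normalized magnitudes over the closed band
[k₃, round(2L/3)]. The DC term never enters numerator or baseline, so mean
GC content (which varies several-fold across bacteria) cannot leak into the
score. Random sequence scores ≈ 1; the default genomic cutoff is 3.

**Footprint calibration and the translated gates.** RPF counting for the
*translated* gate (default ≥ 5 reads, the level above sporadic counting
noise when replicates are unavailable) is strand-specific any-overlap,
before calibration, so lowly covered candidates are kept even when their
footprints cannot be placed precisely. Calibration is per read-length bin
and anchored at 3′ ends: bacterial nucleases trim 3′ ends more reproducibly
than 5′ ends. For every read, the distance from its 3′ end to each
annotated stop-codon anchor within one read length is histogrammed; the
modal distance is the offset because terminating ribosomes dwell with the
stop codon in the A site. A bin whose mode is below twice the runner-up
(ties included) is marked uncalibrated and dropped — ambiguity means
insufficient signal, not a tie-break. A-site position = 3′ end − offset
walked toward the 5′ end along the read's orientation; the per-nt A-site
count vector over the ORF (length L, translation direction) is scored with
the same FT statistic, so "3-nt periodicity" means the same thing for
sequence and for footprints. Only candidates with ≥ 100 reads per kilobase
are FT-scored (about one read per 10 nt, the coverage at which the spectrum
is informative); score > 2 promotes to *3nt-translated*, and failures
remain *translated* rather than being discarded.

**TIS evidence.** Initiation-arrested footprints pile over start codons but
have no termination coverage, so offset calibration is impossible and the
drug blurs the P site across ≥ 2 codons; each read is instead reduced to
its middle nucleotide — index (L+1)//2 from the 5′ end, i.e. the 3′
nucleotide of the first half for even L — mapped to genomic coordinates
along the read's own orientation. A candidate's TIS count sums the track
over its start codon ± 1 codon (9 nt), the restrictive window within which
initiation signal is crisp; ≥ 5 counts (the same cutoff as the translated
gate) sets the independent `tis_positive` flag. Within a same-stop group,
TIS-positive members whose starts are > 3 nt apart are *resolved*; members
at ≤ 3 nt (adjacent or overlapping start codons, whose windows blend) are
both retained as *ambiguous*.

## Parameters

| parameter | default | meaning |
|---|---|---|
| min/max candidate length | 9 / 150 nt | 3–50 codons incl. start and stop |
| start codons | ATG, GTG, TTG, CTG | equal weight, no usage prior |
| genomic FT cutoff | 3.0 | retains ~70% of known coding ORFs |
| footprint FT cutoff | 2.0 | on calibrated A-site profiles |
| min RPFs (translated) | 5 | above counting error without replicates |
| min coverage for FT | 100 RPK | ≈ 1 read / 10 nt |
| read-length bins | 27–30 nt | organism-dependent; 24–28 also common |
| min TIS count | 5 | middle nucleotides in the 9-nt window |
| annotation filter | strand-agnostic | `stranded` switch available |
| FT band | closed | `open` excludes the band endpoints |

The baseline band convention (endpoints included, numerator index included
in the mean) is a frozen declared choice; since the band is dominated by
its interior for the lengths involved, the variants differ only marginally,
and the `open` flag exposes the alternative.

## Synthetic data

The generator plants three element classes in an i.i.d. background (50% GC
by default): periodic smORFs whose codons draw G/C with probability
`strength` at position 3 and `1 − strength` at positions 1–2 (strength 1.0
gives strict weak-weak-strong codons; strength equal to the background GC
is indistinguishable from background), shuffled-control ORFs with valid
start/stop but background-composition interiors and no reads, and longer
(300 nt) annotated "calibration genes". Planted smORF lengths default to
75–150 nt — the upper half of the smORF range, where per-candidate spectra
are informative at realistic coverage. Simulated footprints place the true
A site on a codon start with probability `1 − frame_noise` (noise is
uniform over the codon), then set the 3′ end at A-site + the per-length
true offset; calibration genes carry a 6× occupancy at the stop codon,
emulating the terminating-ribosome dwell that real 3′-end metagenes rely
on, and receive deeper coverage (250 reads/gene) because calibration
presumes well-expressed genes. TIS reads put middle nucleotides in the
start ± 1 codon window with a center-peaked distribution. One global seed
drives per-component derived streams, so outputs are byte-reproducible and
adding a stage never shifts earlier draws.

What the fixture does **not** emulate: nuclease sequence bias, rRNA
contamination, non-uniform elongation pauses within ORF bodies, operon
structure, or annotation drift. Passing tests therefore demonstrate the
correctness of the operations and the self-consistency of the pipeline
under clean periodic signals — not detection power on real libraries,
where coverage, bias and overlapping transcription reduce sensitivity.

## Numerical choices and degenerate inputs

* FT requires L ≥ 3; a flat (all-constant) signal or an empty baseline band
  yields score 0 with a `degenerate` flag rather than NaN, keeping
  downstream filters total.
* Candidate identity across stages is `(seq_id, strand, start, end)`, so
  stage intersections are exact set operations.
* Read length is the aligned reference span, not the query length; soft
  clips do not move the 3′ end.
* Interval overlap uses 0-based half-open coordinates everywhere; one
  shared nt is an overlap.
* Offset-calibration ties → bin dropped (see above); A-site positions
  outside the ORF are skipped in profiles but such reads still count toward
  the any-overlap translated gate.
* Problem sizes: the test suite and the acceptance script run on 40 kb toy
  genomes with ~2,500 footprints — large enough that a 40 kb genome yields
  ~4,400 putative candidates and every gate is exercised with comfortable
  margins, while a full run completes in well under a second.

## Known limitations

* The annotation-overlap filter defaults to strand-agnostic removal;
  genuine antisense smORFs under annotated genes require the `stranded`
  switch.
* Very short candidates (9–21 nt) have few spectral bins; their genomic FT
  scores are noisy and the cutoff of 3 is conservative for them.
* TIS resolution cannot separate starts ≤ 3 nt apart (adjacent codons) —
  both are reported as ambiguous.
* Pooling multiple Ribo-Seq alignment files treats them as one library; no
  replicate-aware counting model is included.
* Genome-scale scanning is pure-Python and processes roughly a megabase
  per handful of seconds; it is linear in genome size.
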