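# smorfer

Detection of small open reading frames (smORFs, ≤ 50 codons) in prokaryotic
genomes by integrating three independent lines of evidence:

* **Module A — genome-based detection.** Every in-frame span from a start
  codon (ATG, GTG, TTG, CTG, equal weight) to the first in-frame stop (TGA,
  TAG, TAA) on both strands, 9–150 nt, is a putative smORF. Candidates in
  annotated regions are removed, and each remaining candidate is scored for
  the 3-nt *sequence* periodicity characteristic of coding DNA: the discrete
  Fourier transform of the per-nt GC indicator is evaluated at the period-3
  index k₃ = L/3, and the score is |X(k₃)|/L divided by the mean normalized
  magnitude over the band between the 3-nt and 1.5-nt periods,
  [L/3, 2L/3]. Scores > 3 pass.
* **Module B — translated ORF detection.** Ribosome-protected fragments
  (RPFs) from Ribo-Seq are counted per candidate (strand-specific,
  any-overlap); ≥ 5 RPFs → *translated*. RPFs are then calibrated at their
  3′ ends: per read-length bin, the modal distance from the 3′ end to
  annotated stop codons gives the A-site offset (e.g. 11 nt for 24–28 nt
  reads, 12 nt for 29–30 nt). Candidates with ≥ 100 reads per kilobase get
  their calibrated A-site profile scored with the same FT statistic;
  score > 2 → *3nt-translated*.
* **Module C — TIS detection.** Footprints from initiation-arrested
  ribosomes (TIS-Ribo-Seq, retapamulin) cannot be calibrated; each read is
  reduced to its middle nucleotide (for even lengths, the 3′ nucleotide of
  the first half), and counts over the start codon ± 1 codon are summed.
  ≥ 5 counts → TIS-positive. TIS signal also resolves overlapping same-stop
  candidates whose start codons are more than one codon apart.

Modules run independently or in combination (A, A+B, A+C, A+B+C), producing
a candidate funnel, per-stage BED/TSV output and start-codon usage tables.
A deterministic synthetic-data generator (`smorfer.simulate`) builds toy
genomes with planted periodic smORFs, shuffled controls, simulated RPFs
with known A-site offsets, and TIS reads — so the entire method is testable
without downloads.

## Worked example

```sh
python examples/05_full_pipeline.py
```

builds a synthetic data set (20 planted smORFs, periodicity strength 0.9,
50 RPFs per ORF, 10% frame noise, 10 TIS reads per start) and runs all
three modules:

```
candidate funnel:
  putative                   4426
  non_annotated              4196
  ft_genomic                  215
  translated                  148
  3nt_translated              148
  tis_positive                 23
  translated_and_tis           23
  3nt_translated_and_tis       23
...
planted smORFs recovered in the final category: 20/20
```

Reading the funnel: 4,426 putative smORFs are enumerated in a 40 kb toy
genome; 4,196 fall outside annotated genes; 215 show genomic 3-nt
periodicity above the FT cutoff of 3; 148 carry ≥ 5 footprints; all of
those also show periodic calibrated A-site profiles (FT > 2); 23 have TIS
support — the 20 planted smORFs plus same-stop sub-ORFs. Shuffled-control
ORFs (no periodicity, no reads) never reach the final category.

The other scripts in `examples/` demonstrate each capability in isolation:
ORF enumeration and unique-stop grouping, FT periodicity scoring, offset
calibration and A-site profiles, TIS scoring and overlap resolution.

## Command line

```sh
smorfer run --genome g.fasta --annotation g.gff3 \
    --ribo ribo.bam --tis tis.bam --out-dir out/
```

writes `out/candidates.tsv` (all fields per candidate), per-stage BED files
and `out/funnel.json`. Subcommands `scan`, `ft`, `translate`, `tis` run the
modules individually on TSV candidate files; `fixtures` emits a synthetic
data set. Run `smorfer --help` for options.

For real data, alignments must be uniquely mapped (the reference mapping
used Bowtie with `-l 16 -n 1 -e 50 -m 1 --strata --best`); read trimming
and mapping happen upstream of this package, which consumes SAM/BAM or
6-column BED alignments.

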