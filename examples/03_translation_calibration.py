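"""Calibrate footprint 3' ends, build A-site profiles, call translation.

Ribosome-protected fragments are binned by length; per bin, the distance
from the 3' end back to the A site is the modal distance to annotated stop
codons (the terminating ribosome's A site is the stop).  Calibrated A-site
profiles of genuinely translated ORFs step codon-wise, which the same FT
statistic turns into a score (> 2 at >= 100 reads per kilobase).
"""

from smorfer import (FixtureSpec, OrfCandidate, a_site_vector,
                     calibrate_offsets, classify_3nt_translated, count_rpfs,
                     ft_score, make_genome, make_ribo_reads)

spec = FixtureSpec(seed=11)
record, annotation, truth = make_genome(spec)
reads = make_ribo_reads(truth, spec, record.length)
print(f"simulated {len(reads)} footprints "
      f"(true offsets {spec.true_offset_by_length})")

offsets = calibrate_offsets(reads, annotation, (27, 28, 29, 30))
print(f"recovered offsets: {offsets.entries}")

p = truth.planted[0]
orf = OrfCandidate(p.seq_id, p.strand, p.start, p.end, p.start_codon, "TAA")
count_rpfs([orf], reads)
vec = a_site_vector(orf, reads, offsets)
classify_3nt_translated([orf], {orf.key: vec})
print(f"\nplanted smORF [{orf.start},{orf.end}){orf.strand}: "
      f"{orf.rpf_count} RPFs, {orf.rpk:.0f} RPK")
print(f"calibrated per-codon counts: {vec.reshape(-1, 3).sum(axis=1).astype(int)}")
print(f"footprint FT score {orf.rpf_ft_score:.2f} -> category {orf.category}")
print("\nIn-frame A-site placement concentrates counts on codon starts, so "
      "the FT score clears the cutoff of 2.")
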