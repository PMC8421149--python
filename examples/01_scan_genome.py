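"""Enumerate putative smORFs in a toy genome and group them by stop codon.

Prokaryotic smORF search begins by listing every in-frame span from a start
codon (ATG/GTG/TTG/CTG, all with equal weight) to the first in-frame stop
(TGA/TAG/TAA), on both strands, 3-50 codons long.  Because several starts
often share one stop, candidates are also grouped by unique stop codon.
"""

from smorfer import GenomeRecord, OrfConfig, find_orfs, group_by_stop

# two nested ORFs on + (ATG... and GTG... share the TAA) and one on -
seq = "ATGGTGAAACCCTAA" + "TTACATGGGAGCCAT"
genome = GenomeRecord("toy", seq)

orfs = find_orfs(genome, OrfConfig())
print(f"{len(orfs)} putative smORFs in {genome.length} nt:")
for o in orfs:
    print(f"  [{o.start:3d},{o.end:3d}) {o.strand}  {o.start_codon}..."
          f"{o.stop_codon}  {o.length_nt} nt")

groups = group_by_stop(orfs)
print(f"{len(groups)} unique stop codons "
      f"(overlapping starts collapse onto shared stops):")
for stop_key, members in groups.items():
    starts = ", ".join(f"{m.start_codon}@{m.start}" for m in members)
    print(f"  stop at {stop_key[2]} ({stop_key[1]}): {starts}")
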