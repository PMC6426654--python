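"""Build a truncation-aware tRNA reference from a simulated gene set.

Every mature tRNA ends in CCA; reads that stop short of that terminus
come from 3'-truncated ("defective") molecules.  The reference therefore
holds, per gene, the mature transcript plus every variant missing up to
13 3' nucleotides, so a read's truncation depth can be assigned exactly.
"""

import retrotrace as rt

genes = rt.simulate_genes(323, seed=1)
ref = rt.build_truncation_set(genes, max_missing=13)

print(f"genes:                {len(ref.genes)}")
print(f"reference entries:    {len(ref.entries)}  (= genes x 14 variants)")
gid, k, seq = ref.entries[3]
print(f"example entry:        {ref.entry_name(gid, k)} length={len(seq)}")
print(f"mature 3' end:        ...{ref.genes[gid].mature_seq[-6:]}")
print(f"entry missing {k} nt:  ...{seq[-6:]}")
# The 323 x 14 = 4522 entries mirror a pseudogene-free human tRNA gene set
# expanded to single-nucleotide 3' resolution.
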