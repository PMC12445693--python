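"""Diagnose a long 5'UTR as noncoding.

Two signals: stop codons in all six translation frames (a real gene
keeps its own frame clear), and a trinucleotide composition farther from
every coding region than coding regions are from each other.
"""

import itertools

from fldseg.records import NucSequence
from fldseg.synthgen import SimConfig, simulate_genomes
from fldseg.utr import composition_distance, stop_codon_map, trinuc_profile

(g,) = simulate_genomes(SimConfig(n_genomes=1, long_utr_frac=1.0, seed=11))
seg1 = g.segments[0]
utr = NucSequence("5utr", seg1.seq[30 : 30 + g.utr5_len])

smap = stop_codon_map(utr)
print("stop codons per frame:", [len(f) for f in smap.frames])
# All six entries are nonzero: no frame is open, the region cannot code.

p_utr = trinuc_profile(utr, "utr")
cds = []
for sid, s, e, _, _ in g.orf_truth:
    seg = next(x for x in g.segments if x.id == sid)
    cds.append(trinuc_profile(NucSequence(f"{sid}:{s}", seg.seq[s:e])))
d_utr = [composition_distance(p_utr, p) for p in cds]
d_cds = [composition_distance(a, b) for a, b in itertools.combinations(cds, 2)]
print(f"min UTR-vs-CDS distance: {min(d_utr):.4f}")
print(f"max CDS-vs-CDS distance: {max(d_cds):.4f}")
# The UTR sits farther from every gene than genes sit from each other:
# its composition is not codon-driven.
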