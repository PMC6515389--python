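"""The junction-overlap search on a hand-built template switch.

Builds a tiny reference, plants a 7 bp microhomology at a junction the
way MDA template switching leaves one, and runs the two-sided search.
"""

import numpy as np

from mdachimera import OverlapParams, ReferenceGenome, search_overlap_head, search_overlap_tail
from mdachimera.realigner import SubsectionHit

rng = np.random.default_rng(0)
seq = list(rng.choice(list("ACGT"), size=800))

# the former subsection ends with GATTACA; the same 7-mer sits immediately
# upstream of where the following subsection realigned (position 400)
omer = "GATTACA"
former_seq = "".join(rng.choice(list("ACGT"), size=53)) + omer
seq[400 - len(omer) : 400] = list(omer)
ref = ReferenceGenome({"chr_demo": "".join(seq)})

following_hit = SubsectionHit("following", "chr_demo", 400, 441, "+")
former_hit = SubsectionHit("former", "chr_demo", 100, 160, "+")
params = OverlapParams()

tail = search_overlap_tail(former_seq, following_hit, ref, params)
print(f"tail side: overlap {tail.sequence!r}, length {tail.length}")

head = search_overlap_head("".join(rng.choice(list("ACGT"), size=41)), former_hit, ref, params)
print(f"head side: {'overlap ' + repr(head.sequence) if head else 'none'}")
# The tail search recovers the planted 7 bp microhomology (it may extend
# if the random context happens to agree further); the head side, with no
# planted agreement, usually finds nothing >= 3 bp under the mismatch rules.
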