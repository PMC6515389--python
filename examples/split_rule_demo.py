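"""The minimum soft-clip subsection length across chromosome sizes.

A clipped piece shorter than floor(log4 L) + 1 is expected to occur more
than once by chance in a chromosome of L bp, so it cannot be placed
uniquely and is discarded before realignment (with an 8 bp hard floor).
"""

from mdachimera import min_softclip_length

for label, length in [
    ("mitochondrial genome", 16_569),
    ("yeast chr IV", 1_531_933),
    ("human chr 21", 48_129_895),
    ("human chr 1", 249_250_621),
]:
    print(f"{label:22s} L={length:>12,d} bp -> min subsection {min_softclip_length(length)} bp")

# Output: 8, 11, 13 and 14 bp respectively — the rule grows by one base
# every fourfold increase in chromosome length, and for human chr 1 a
# clipped piece must be at least 14 bp before realignment is attempted.
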