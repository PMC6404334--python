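"""Hypergeometric over-representation of a gene set in a DE list.

In a 10-gene universe where the 5 DE genes are exactly the 5 members of a
set, only one of the C(10,5) = 252 possible draws achieves that overlap, so
p = 1/252.
"""

from gsepd.enrichment import overrepresentation_test

universe = [f"g{i}" for i in range(10)]
gene_set = universe[:5]
de_list = universe[:5]

p = overrepresentation_test(gene_set, de_list, universe)
print(f"overlap 5/5 in a 10-gene universe: p = {p:.6f}  (1/252 = {1/252:.6f})")

p_partial = overrepresentation_test(gene_set, universe[3:8], universe)
print(f"overlap 2/5: p = {p_partial:.4f}")
# the pipeline runs this test for every (gene set, direction) pair and
# BH-adjusts within each of the up/down/all DE lists.
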