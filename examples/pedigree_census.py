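"""Grow a single-replicore pedigree under parity and disparity mutagenesis
and compare what survives.

Disparity (all new mutations on the lagging-strand copy) keeps one pristine
zero-mutation genome in every generation and never loses a genotype; parity
(mutations split evenly) marches every lineage away from the ancestor.
"""

from replicore import pedigree

for mode in ("disparity", "parity"):
    tree = pedigree.grow(mode, d=2, g=5)
    print(f"\n{mode}: census at generation 5 (mutation_count -> n_genomes)")
    print(" ", pedigree.census(tree, 5))
    print("  every past genotype still present in every later generation:",
          pedigree.genotype_persistence(tree))

# The disparity counts are binomial: C(5, k) genomes carry 2k mutations.
# The single genome at 0 mutations is the guaranteed ancestral genotype.
print("\nNewick for a 2-generation disparity pedigree "
      "(branch length = new mutations on that edge):")
print(pedigree.export_newick(pedigree.grow("disparity", d=2, g=2)))
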