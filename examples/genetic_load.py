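"""Genetic-load arithmetic for the human mutation budget.

L = 1 - exp(-U) is the fraction of the population truncation selection must
remove per generation to purge U new deleterious mutations per diploid.
U = 2.2 (the human estimate) gives L = 0.89 - a load that should have driven
humans extinct, which is the paradox the disparity model addresses.
"""

from replicore import load

for U in (0.0, 0.35, 2.2, 3.2):
    print(f"U = {U:4.2f}  ->  genetic load L = {load.genetic_load(U):.2f}")

per_gen_low = load.mutations_per_generation(1e-9, 3e9, 20)
per_gen_high = load.mutations_per_generation(1e-9, 3e9, 25)
print(f"\nhuman mutations per generation (1e-9/site/yr x 3e9 bp x 20-25 yr): "
      f"{per_gen_low:.0f}-{per_gen_high:.0f}")
print(f"cell-level mutations (10,000 replicores x 0.01 each): "
      f"{load.cell_level_mutations(10_000, 0.01):.0f}")
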