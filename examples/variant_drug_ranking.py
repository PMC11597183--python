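"""Rank drugs per receptor variant and normalize the affinity heatmap.

Loads the packaged variant x ligand binding free-energy matrix, reports
the globally most and least favorable combinations, ranks the drugs for
each binding-site variant (most favorable binding first, endogenous S1P
excluded), and shows the per-ligand 0-10 heatmap normalization where 10
marks each drug's most favorable variant.
"""

import pandas as pd

from snplie import datasets, extreme_combinations, normalize_heatmap, rank_ligands

matrix = datasets.load_variant_affinity_matrix()
most, least = extreme_combinations(matrix)
print(f"most favorable : {most.ligand} with {most.variant} ({most.dg:.2f} kcal/mol)")
print(f"least favorable: {least.ligand} with {least.variant} ({least.dg:.2f} kcal/mol)\n")

print("drug ranking per variant (best binder first):")
for variant in matrix.variants:
    print(f"  {variant:<12} {' > '.join(rank_ligands(matrix, variant))}")

grid = pd.DataFrame(normalize_heatmap(matrix).round(2),
                    index=list(matrix.variants), columns=list(matrix.ligands))
print("\nnormalized heatmap grid (0 = least, 10 = most favorable per drug):")
print(grid.to_string())
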