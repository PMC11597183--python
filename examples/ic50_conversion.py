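"""Convert experimental IC50 values to binding free energies.

Loads the packaged IC50 measurements for the S1PR1 ligands, converts each
to dG = R*T*ln(IC50) at body temperature, and aggregates replicate assays
per ligand (mean and population standard deviation).  More negative dG
means tighter binding; these aggregates are the experimental targets the
LIE weights are calibrated against.
"""

from snplie import aggregate_replicas, datasets

affinities = datasets.load_experimental_affinities()
print(f"{'ligand':<12} {'IC50 [M]':>10} {'dG_exp [kcal/mol]':>18}")
for aff in affinities:
    print(f"{aff.ligand:<12} {aff.ic50:>10.2e} {aff.dg_exp:>18.2f}")

print("\nper-ligand aggregates of the reported values:")
for ligand, values in datasets.load_reported_dg_columns().items():
    mean, sd = aggregate_replicas(values)
    print(f"  {ligand:<12} mean {mean:6.2f}  spread {sd:4.2f}  (n={len(values)})")
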