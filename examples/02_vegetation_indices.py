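"""Compute the ten broadband vegetation indices for one reflectance
vector and for a whole table.

The worked vector is a typical green canopy: low visible reflectance,
high NIR.  NDVI near 0.75 says dense green vegetation; SRPI (B/R)
below 1 reflects stronger red than blue absorption features.
"""

import canespec as cs

refl = {"B": 0.05, "G": 0.10, "R": 0.08, "RE": 0.30, "NIR": 0.55}
print("reflectance:", refl, "\n")
for name in cs.VI_NAMES:
    print(f"{name:>6} = {cs.compute_vi(name, refl):8.4f}")

table = cs.build_feature_table(cs.generate_dataset(config=cs.GeneratorConfig(seed=0)))
print(f"\nfeature table: {table.shape[0]} rows x {table.shape[1]} columns "
      f"(ids, treatments, 5 bands, 10 indices, cnc)")
print(table[["NDVI", "SRPI", "NPCI", "NGBDI"]].describe().round(3))
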