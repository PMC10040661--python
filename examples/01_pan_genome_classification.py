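"""Classify a pan-genome PAV matrix into core / dispensable / specific genes.

Builds the 11-cultivar pomegranate composition matrix (31,016 genes), runs
the classifier, and reports category percentages, how much of the
pan-genome the two donor cultivars carry, and a permutation accumulation
curve. The percentages printed are the published-style one-decimal values;
the accumulation curve shows how quickly the pan-gene count saturates as
cultivars are added.
"""

from pomepan import accumulation_curve, classify_pav, subset_representation
from pomepan.simulate import pomegranate_pan_composition

pav = pomegranate_pan_composition()
cls = classify_pav(pav)

print(f"pan-genome: {pav.n_genes} genes x {pav.n_cultivars} cultivars")
for cat, count in cls.counts.items():
    print(f"  {cat:17s} {count:6d}  ({cls.percentages[cat]}%)")
print(f"  core (all + missing-one): {cls.percentages['core']}%")

n, pct = subset_representation(pav, ["Taishanhong", "Tunisia"])
print(f"\nTaishanhong + Tunisia carry {n} genes = {pct}% of the pan-genome")

curve = accumulation_curve(pav, n_perm=50, seed=0)
print("\naccumulation curve (mean pan-genes over 50 random orders):")
for _, row in curve.iterrows():
    print(f"  k={int(row['k']):2d}  {row['pan_genes_mean']:9.1f}")
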