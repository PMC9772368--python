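"""Inter- vs intra-observer Dice and the variance decomposition.

Generates a small multi-reader cohort (3 readers; A and B contour in three
rounds, C once), pairs the reads, tests whether readers agree with themselves
more than with each other, and decomposes the volume measurements into
lesion / inter-observer / intra-observer variance with reliability ICCs.
"""

import numpy as np

from segdosim import (
    CohortConfig,
    compare_dice,
    dice_pairs,
    fit_variance_components,
    generate_cohort,
    reliability_coefficients,
)

cfg = CohortConfig(n_lesions=6, volume_range_ml=(3.0, 60.0),
                   grid_spacing_mm=(2.0, 2.0, 2.5), seed=7)
cohort = generate_cohort(cfg)

inter = [p.dice for p in dice_pairs(cohort.reads, "inter")]
intra = [p.dice for p in dice_pairs(cohort.reads, "intra")]
t, p = compare_dice(inter, intra)
print(f"{len(cohort.reads)} reads -> {len(inter)} inter pairs, {len(intra)} intra pairs")
print(f"mean inter-observer Dice: {np.mean(inter):.3f}")
print(f"mean intra-observer Dice: {np.mean(intra):.3f}")
print(f"Welch t = {t:.2f}, p = {p:.2g}  (negative t: readers agree more with themselves)")

obs = cohort.reads_table().rename(columns={"volume_ml": "value"})[
    ["lesion_id", "reader_id", "round", "value"]
]
vc = fit_variance_components(obs)
rel = reliability_coefficients(vc)
print()
print(f"volume variance components (mL^2): lesion {vc.sigma2_lesion:.1f}, "
      f"inter {vc.sigma2_inter:.2f}, intra {vc.sigma2_intra:.2f}")
print(f"reliability: rho_inter = {rel.rho_inter:.3f}, rho_intra = {rel.rho_intra:.3f}")
print(f"observer variance split: {rel.inter_share_pct:.1f}% between-reader, "
      f"{rel.intra_share_pct:.1f}% within-reader")
print()
print("rho near 1 = measurements dominated by true lesion differences;")
print("the split shows which observer effect to attack to improve precision.")
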