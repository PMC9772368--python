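"""Dose metrics inside a contour and partial-volume correction.

Generates a lesion with a blurred dose map (emulating Y-90 PET resolution),
samples the dose inside the contour, and shows the recovery-coefficient
partial-volume correction: measured mean dose divided by RC(v) < 1, a
correction that grows rapidly as lesions get smaller.
"""

from segdosim import (
    apply_pvc,
    compute_dose_metrics,
    generate_dose_map,
    generate_true_lesion,
    recovery_coefficient,
)

lesion = generate_true_lesion(15.0, 0.25, (1.5, 1.5, 2.5), seed=3)
dose_map = generate_dose_map(lesion, dose_peak_gy=150.0, psf_sigma_mm=5.0, seed=4)

m = compute_dose_metrics(dose_map, lesion.mask, pvc=True)
print(f"contour volume:    {m.volume_ml:7.2f} mL")
print(f"mean dose:         {m.mean_gy:7.1f} Gy")
print(f"RC(v):             {m.rc:7.4f}")
print(f"mean dose w/ PVC:  {m.mean_pvc_gy:7.1f} Gy")
print(f"D10 / D90:         {m.d10_gy:7.1f} / {m.d90_gy:7.1f} Gy")
print()
print("D10 >= mean >= D90 orders the dose-volume histogram; PVC inflates the")
print("mean because the blurred map underestimates dose in small volumes.")
print()
for v in (2.0, 8.0, 50.0, 200.0):
    print(f"RC({v:5.1f} mL) = {recovery_coefficient(v):.3f}  ->  "
          f"100 Gy measured becomes {apply_pvc(100.0, v):6.1f} Gy corrected")
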