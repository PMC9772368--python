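# segdosim

Multi-reader lesion segmentation variability and its propagation into
radionuclide-therapy dosimetry and outcome prediction.

When radiologists contour the same tumor on MRI, the contours differ — between
readers and even between sessions of the same reader. In dosimetry-guided
therapies such as Y-90 radioembolization, those contours are transferred onto
absorbed-dose maps, so contouring variability propagates into the dose metrics
that drive treatment decisions. `segdosim` provides the full analysis chain for
quantifying that propagation in a multi-reader, multi-round contouring study,
plus a synthetic cohort generator so the pipeline can be exercised and
validated without patient data.

## What it computes

**Contour agreement.** For binary masks A, B on a common grid, the Dice
coefficient 2|A∩B|/(|A|+|B|); volumes (mL) and RECIST longest axial diameters
(mm). Inter-observer pairs are reads by different readers in the same round;
intra-observer pairs are reads by the same reader across rounds; the two
groups are compared with a Welch two-sample t-test.

**Dose metrics.** Inside each contour: mean absorbed dose (Gy), the DVH
percentiles D10 and D90 (minimum dose to 10% / 90% of the contoured volume),
and a partial-volume-corrected mean dose using the sphere-phantom recovery
coefficient curve

    RC(v) = -0.934 · v^(-0.573) + 0.883      (v in mL),   corrected = mean / RC(v)

applied per read with that read's own volume.

**Variance decomposition.** Repeated measurements y<sub>lrk</sub> follow a
two-factor random-effects model y = μ + a<sub>l</sub> + b<sub>lr</sub> +
e<sub>lrk</sub> with variances σ²<sub>lesion</sub>, σ²<sub>inter</sub>,
σ²<sub>intra</sub> (REML; expected-mean-squares fallback for balanced
designs), from which the reliability ICCs

    ρ_inter = σ²_lesion / σ²_total,    ρ_intra = (σ²_lesion + σ²_inter) / σ²_total

and the observer-variance split 100·σ²_inter/(σ²_inter+σ²_intra) follow.

**Uncertainty model and TCP.** Per-lesion uncertainty is the coefficient of
variation across reads, CV% = 100·SD/mean; across lesions it is modelled as a
power law CV = α·v^β (log-log OLS, t-test of β = 0). The fitted curve predicts
the dose SD of an unseen lesion from its volume, and that SD is pushed through
a logistic tumor-control-probability model TCP(d) = 1/(1+e^-(b0+b1·d)) to get

    Δ_TCP = TCP(d + 2·SD) − TCP(d − 2·SD),

the spread of predicted tumor control attributable to contouring alone.

## Worked example

```bash
python examples/03_observer_variability.py
```

```
42 reads -> 30 inter pairs, 36 intra pairs
mean inter-observer Dice: 0.732
mean intra-observer Dice: 0.849
Welch t = -8.08, p = 9.7e-10  (negative t: readers agree more with themselves)

volume variance components (mL^2): lesion 27.0, inter 0.45, intra 0.24
reliability: rho_inter = 0.975, rho_intra = 0.991
observer variance split: 64.7% between-reader, 35.3% within-reader
```

A 6-lesion synthetic cohort with 3 readers (A and B contour in three rounds,
C in one) yields 42 reads. Intra-observer overlap (0.849) exceeds
inter-observer overlap (0.732), as expected when each reader carries a
persistent bias, and the Welch test confirms the difference. The variance
decomposition attributes most volume variance to genuine lesion differences
(ρ near 1); of the observer variance, about two thirds is between-reader.

The other examples cover the geometric metrics (`01_mask_metrics.py`), dose
sampling and partial-volume correction (`02_dosimetry_pvc.py`), and the full
pipeline through the power-law fit and Δ_TCP (`04_uncertainty_to_tcp.py`).

A thin CLI wraps the same pipeline:

```bash
segdosim generate --seed 1 --out data/          # synthetic cohort as NIfTI + manifest
segdosim analyze --manifest data/manifest.csv --out run/
segdosim report run/
```

Real studies are consumed the same way: per-read NIfTI masks, per-lesion
NIfTI dose maps, and a manifest CSV (lesion_id, reader_id, round, mask_path,
dosemap_path), all co-registered on (or resampled to) the dose-map grid.

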