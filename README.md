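# breastcomp

Breast composition, substructure dosimetry and toxicity association from
radiotherapy planning CT.

After breast-conserving surgery and radiotherapy (RT), late toxicities —
pain, oedema, atrophy, induration — may depend not only on the dose to the
whole breast but on how that dose lands in its constituent tissues.  The
breast is mostly adipose (fat, ≈ −110 HU on CT) and fibroglandular tissue
(≈ −50 to +20 HU), in proportions that vary strongly between patients.
`breastcomp` implements an automated pipeline for studying this link on
planning CT, dose grids and ordinal toxicity grades:

1. **Skin crop** — each breast contour is reduced by 5 mm from the skin
   surface (Euclidean distance transform at native voxel spacing), so
   unreliable superficial dose and skin artefacts are excluded.
2. **Global density classification** — per breast, three first-order
   intensity features are extracted from the HU histogram: median, IQR and
   uniformity *U* = Σᵢ p(i)², with p(i) the probability of histogram bin
   *i*.  k-means (k = 4) on the z-scored features partitions the cohort
   into four BI-RADS-like classes, named by ascending centroid median HU:
   *fatty*, *scattered*, *heterogeneously dense*, *extremely dense*.
3. **Tissue segmentation** — a two-component Gaussian mixture is fitted to
   each patient's in-breast HU histogram (EM on a weighted 1-HU histogram,
   inside a restricted HU window that excludes air and surgical clips).
   Tissue intervals are μ ± 2σ per component; overlap is resolved in
   favour of fat (the narrower peak), and out-of-interval voxels stay
   unclassified.  Composition is reported as % of the complete breast.
4. **Substructure dosimetry** — physical dose D in n fractions is
   converted voxelwise to the equivalent dose in 2 Gy fractions,
   EQD2 = D·(d + α/β)/(2 + α/β) with d = D/n and α/β = 1.7 Gy, and mean /
   maximum / uniformity of both dose forms are reported for the breast and
   each tissue substructure.
5. **Toxicity association** — clinician and patient grades (0–3) are
   merged by maximum severity; candidate variables are screened for
   collinearity (|r| ≥ 0.9); proportional-odds (ordinal logistic) models
   are fitted per endpoint × timepoint, and composition/dose variables are
   added to a fixed clinical baseline by forward AIC-stepwise selection
   (with a backward pass as a consistency check).

Because the clinical imaging and outcome data such pipelines are built for
are not redistributable, the package ships a first-class phantom module:
synthetic breasts with known tissue ground truth (HU statistics calibrated
to published per-cluster values for the four density archetypes),
parametric dose fields with optional boost, and proportional-odds outcome
generation with machine-readable truth.  Every stage is validated against
these phantoms.

## Worked example

`examples/` contains one short script per capability.  For instance,
patient-specific tissue segmentation
(`python examples/03_tissue_segmentation.py`):

```
mixture fit (6 EM iterations, window (-114.9..., 8.96...)):
  fat:            N(-100.6, 6.6) HU, weight 0.55
  fibroglandular: N(-13.5, 10.3) HU, weight 0.45
tissue intervals (mean +/- 2 SD): fat [-114, -87] HU, fibroglandular [-34, 7] HU
composition: 51.8 % fat, 42.1 % fibroglandular, 6.1 % unclassified
Dice vs ground truth (fat): 0.970
Dice vs ground truth (fibroglandular): 0.967
```

The mixture recovered the generating HU distributions of a
heterogeneously-dense phantom, the ±2σ intervals translate them into
patient-specific thresholds, and the resulting masks overlap the ground
truth at Dice ≈ 0.97.  The association workflow
(`python examples/05_toxicity_association.py`) on a cohort generated with
"fat dose → pain, fibroglandular dose → induration" truth prints:

```
  endpoint   n  baseline_aic  best_aic    selected  forward_backward_agree
      pain 200         430.7     419.8 fat_mean_gy                    True
induration 200         450.0     435.8  fg_mean_gy                    True
```

i.e. the stepwise selection adds exactly the generating dose variable for
each endpoint, lowering the AIC against the clinical baseline.

A thin CLI mirrors the library (`breastcomp simulate | features | cluster |
segment | dose-metrics | associate | run-all`); `run-all` executes the full
staged workflow into an append-only run directory with a config hash on
every artifact.

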