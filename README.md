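# vesselmorph

Quantitative retinal vessel morphometry for posterior-pole fundus
segmentations, built for the clinical question of separating retinopathy
of prematurity (ROP) from familial exudative vitreoretinopathy (FEVR) —
two infant retinal vascular diseases with confusingly similar peripheries
but different posterior-pole vessel geometry.

Given a pair of binary masks per eye (vessel segmentation + optic-disc
segmentation), the pipeline:

1. fits the **minimum enclosing circle** of the optic disc and gates out
   frames whose disc center is farther than W/4 from the image center;
2. builds a **concentric analysis ring** spanning 2–4 disc radii;
3. reduces the ring-clipped vessel mask to a **centerline graph**
   (skeleton → endpoints / bifurcations / crossings → pruned edges);
4. measures four per-eye statistics:
   - **vessel angle** — mean daughter–daughter angle at bifurcations,
     with the parent identified as the branch pointing back toward the
     disc;
   - **vessel density** — vessel area as % of the ring;
   - **fractal dimension** — box-counting slope, FD = −d log N(ε)/d log ε;
   - **tortuosity** — Hart's arc-length-normalized total squared
     curvature τ = (1/L)∫κ² ds, reported ×10⁻³ px⁻²;
5. compares groups with mean ± SD, one-way ANOVA, χ² for categorical
   tables, and Holm-adjusted pairwise Welch t-tests.

Because no patient images ship with the package, a **synthetic vascular
tree generator** (`vesselmorph.synthetic`) produces OD + vessel mask pairs
with exact ground truth — every bifurcation angle, every centerline, the
analytic tortuosity of every segment — so the whole chain is validated by
parameter recovery. See `docs/methods.md` for the model and the numerical
choices.

## Worked example

Run the analysis scripts in order (masks and other binary artifacts go to
`scratch/`, tables to `results/`):

```sh
python analysis/01_generate_cohort.py --n-eyes 50 --seed 1
python analysis/02_qc_gate.py
python analysis/03_measure_morphometry.py
python analysis/04_compare_groups.py
```

The last step prints the group comparison (this exact output, seed 1):

```
| Metric | FEVR (n = 50) | ROP (n = 50) | healthy (n = 50) | P |
|---|---|---|---|---|
| Vessel angle (deg) | 38.039 ± 1.581 | 40.460 ± 2.162 | 39.802 ± 1.782 | <0.001 |
| Vessel density (%) | 3.211 ± 0.064 | 3.255 ± 0.065 | 3.249 ± 0.077 | 0.003 |
| Fractal dimension | 0.905 ± 0.022 | 0.909 ± 0.023 | 0.911 ± 0.024 | 0.337 |
| Vascular tortuosity (x10^-3) | 0.014 ± 0.004 | 0.026 ± 0.003 | 0.019 ± 0.004 | <0.001 |

tortuosity ordering ROP > healthy > FEVR: True
vessel angle lowest in FEVR: True
```

Reading it: the synthetic ROP group was generated with the waviest vessels
and comes out most tortuous; FEVR was generated with the narrowest
branching (37.4° truth) and is measured lowest at 38.0°, significantly
below both other groups (Holm-adjusted P < 0.001 vs ROP), while ROP vs
healthy is not significant (P = 0.100) — the qualitative pattern reported
clinically for these diseases. Tortuosity magnitudes are in pixel units of
this pipeline and are not comparable across imaging systems; orderings
are.

The same steps are available as a CLI for external mask sets:

```sh
vesselmorph analyze --manifest cohort/manifest.csv --out outdir
vesselmorph summarize --metrics outdir/metrics.csv --out outdir
```

where `manifest.csv` has columns `eye_id, group, vessel_path, od_path`.

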