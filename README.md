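# hippofuse

Automated hippocampal segmentation and volumetry by multi-atlas label
fusion, with a synthetic-phantom testbed.

Hippocampal volumetry matters clinically because hippocampal sclerosis —
the common pathology of drug-resistant temporal lobe epilepsy — shows up on
T1-weighted MRI as volume loss, and reliable left/right volumes inform both
diagnosis and surgical planning. Manual delineation is slow and
rater-dependent, while single-template automated methods fail precisely on
the atrophic, atypically shaped hippocampi that matter most. `hippofuse`
implements the multi-atlas answer: register a *database* of labelled
template scans to the new image and fuse their propagated labels, ranking
templates **per voxel** by local image similarity so only the locally
best-matching subset votes at each location.

The package is for method developers and students of multi-atlas
segmentation: every stage is exposed as a library function, and a
synthetic-phantom generator makes the whole pipeline testable end to end
with no scan data.

## Method

Given a template database {(Iⱼ, Lⱼ)} and a subject image I:

1. **Groupwise template** — iterative register-and-average builds a mean
   anatomy and probabilistic label prior from the database.
2. **ROI** — the prior is propagated to the subject (affine + nonrigid
   registration); each hippocampus gets a region of interest around the
   prior's 0.5-level set.
3. **Selection** — each template is coarsely registered to the ROI and the
   top `k_coarse` (default 75) ranked by normalized cross-correlation are
   kept, then finely registered; labels follow as probability maps dⱼ.
4. **Locally ranked fusion (the core)** — at each voxel i the `k_local`
   (default 15) templates with the highest locally normalized
   cross-correlation (Gaussian window, σ = 2 voxels) are selected, and a
   STAPLE-type EM estimates the consensus W and per-template performance
   (pⱼ sensitivity, qⱼ specificity):

       E-step:  aᵢ = πᵢ ∏ⱼ pⱼ^dᵢⱼ (1-pⱼ)^(1-dᵢⱼ),
                bᵢ = (1-πᵢ) ∏ⱼ (1-qⱼ)^dᵢⱼ qⱼ^(1-dᵢⱼ),   Wᵢ = aᵢ/(aᵢ+bᵢ)
       M-step:  pⱼ = Σ Wᵢ dᵢⱼ / Σ Wᵢ,   qⱼ = Σ (1-Wᵢ)(1-dᵢⱼ) / Σ (1-Wᵢ)

   (products and sums over the locally selected, disputed voxels), with a
   mean-field Markov-random-field prior update (β = 0.5) between
   iterations. The consensus is thresholded at 0.5 and cleaned to the
   largest connected component.
5. **Volumetry** — volumes are corrected for head size,
   `corrected = raw − Grad·(ICV − mean ICV)`, with `Grad` the control
   regression slope of volume on intracranial volume (itself estimated by
   the same pipeline run with whole-head labels); the normative range is
   the control mean ± 1.96 SD, and subjects are classified
   (normal / left / right / bilateral atrophy) on the corrected
   sum-versus-difference plane.

See `docs/methods.md` for assumptions, parameter defaults and the design
choices behind the registration engine and the EM support.

## Worked example

Build a small synthetic cohort and segment one phantom (a few minutes):

```bash
hippofuse simulate --n 6 --seed 7 --out db
hippofuse build-db --db db --out tpl --max-iter 2
hippofuse segment --db db --template tpl --subject db/t004_image.nii.gz \
    --out seg --k-local 5 --k-coarse 6
cat seg/volumes.csv
```

```
subject,side,raw_cm3,method,slice_mode
t004_image.nii.gz,left,3.528,automated,all
t004_image.nii.gz,right,3.64,automated,all
```

Phantom `t004` was generated with true volumes 3.552 / 3.624 cm³
(`db/manifest.csv`), so the automated volumes land within 1% even on this
six-template toy database. `seg/` also contains the fused mask
(`hippocampus_mask.nii.gz`, labels 1 = left, 2 = right) and per-template
fusion diagnostics (similarity ranks and estimated sensitivities).

Classification from a volumes table (columns
`subject,left_cm3,right_cm3,icv_cm3,group`; `control` rows fit the
normative model):

```bash
hippofuse report --volumes volumes.csv --out rep
# reference range: 2.97-3.15 cm^3 (Grad=0.0114, n=4)
cat rep/classification.csv
```

```
subject,group,left_corrected_cm3,right_corrected_cm3,sum_cm3,diff_cm3,classification
t000,patient,0.131,0.171,0.303,-0.04,bilateral
t001,patient,0.878,3.086,3.964,-2.208,left
t003,patient,3.016,0.824,3.84,2.192,right
...
```

Each side is flagged atrophic when its corrected volume falls below the
control mean − 1.96 SD; the sum/difference columns are the coordinates of
the usual group scatter plot.

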