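# mdesmap

Mapping patterns of ongoing thought onto brain activity during movie-watching.

## The problem

When people watch a film, their experience moves through different states —
absorbed multi-sensory engagement, episodic reflection, verbal evaluation,
intrusive distraction. Probing viewers often enough to track these states
would destroy the very experience (and the brain dynamics) being measured.
`mdesmap` implements a two-cohort solution: one cohort watches the clips in
the laboratory and answers sparse, **jittered, counterbalanced**
multi-dimensional experience-sampling (mDES) probes — 5 probes per 11-minute
clip, arranged in 16 probe orders so that the cohort as a whole tiles every
15-second slot of the clip twice — while a second, independent cohort's
movie-watching fMRI (TR = 1 s) is analysed with the first cohort's
reconstructed experience time series.

The package is aimed at researchers running naturalistic-cognition studies
who want to reuse (or simulate) this design end to end.

## The method

1. **Probe design** (`mdesmap.design`): construct the 16 counterbalanced
   jittered orders — one probe per 120-s window on a 15-s grid starting at
   75 s; orders 1–8 mutually disjoint and tiling all 40 slots, orders 9–16
   re-covering every slot while overlapping any single earlier order in at
   most one time — and assign orders to participants balanced within ±1 per
   (movie, order) cell.
2. **Thought space** (`mdesmap.thought`): PCA of the 16-item correlation
   matrix. For probe *i* with standardised item vector **z**ᵢ and loading
   matrix **W** (item × component, unit columns), component scores are
   **s**ᵢ = **W**ᵀ**z**ᵢ; explained variance of component *k* is λₖ/16·100.
   Reliability is bootstrapped split-half homologue similarity: the mean
   absolute correlation of optimally matched loading columns across
   independent decompositions of random halves.
3. **Experience time series** (`mdesmap.timeseries`): group-mean score per
   15-s slot, linearly interpolated to one value per TR over the sampled
   10-minute section.
4. **Voxel-space mapping** (`mdesmap.voxelmap`): per-subject OLS of each
   unit's BOLD series on the four experience regressors; group-level
   one-sample *t* on subject betas converted to *z*, cluster-forming
   threshold |z| ≥ 3.1, and family-wise cluster-mass inference by
   sign-flipping whole subject maps (a distribution-free random-effects
   replacement for FSL FLAME).
5. **State space** (`mdesmap.statespace`): z-score each subject per unit,
   average across the cohort, and Spearman-correlate the group map at every
   TR with each of the first five macroscale gradients (G1
   association–primary, G2 visual–motor, G3 frontoparietal–DMN, G4
   DAN/visual–DMN, G5 lateral-DMN–primary) inside a binary mask. The five
   correlations are the film's per-TR coordinates in "brain space".
6. **Models** (`mdesmap.models`): random-intercept linear mixed models of
   thought by movie (Tukey-adjusted lsmeans contrasts), single-df ANOVAs of
   score on sampling bin, the comprehension model (movie × thought-pattern
   interactions with simple slopes), gradient→thought mixed models, and
   Benjamini–Hochberg FDR.
7. **Spin test** (`mdesmap.spin`): does a cluster sit unusually high or low
   on a gradient? Unit coordinates are rotated on the sphere (mirrored
   across hemispheres), re-assigned one-to-one, and the cluster's mean
   gradient value is recomputed per rotation; two-tailed p uses the
   (count+1)/(n+1) estimator over 2500 rotations.

A fully parameterised synthetic-study generator (`mdesmap.simulate`)
produces probe responses, gradient-structured parcel BOLD, comprehension
scores and ground truth, so every stage is testable without any download.

## Worked example

```bash
mdesmap simulate --out study --seed 11 --n-parcels 100
mdesmap run --study study --out results --seed 3 --n-perm 500 --spin-n-perm 500
```

prints (elapsed time varies):

```
synthetic study written to study
pipeline finished in 8.74 s; stages: thoughtspace, regressors, statespace, voxelmap, models, spin
```

and `results/spin.json` then contains, for the default planted couplings
(Sensory Engagement × G1 negative, Episodic Knowledge × G4 positive):

```json
{
 "Sensory Engagement": {
  "gradient": 1,
  "observed": -0.9180328308006437,
  "p_two_tailed": 0.003992015968063872,
  "n_perm": 500,
  "null_mean": -3.095734957352825e-05,
  "cluster_significant": true
 },
 "Episodic Knowledge": {
  "gradient": 4,
  "observed": 0.8605028144165888,
  "p_two_tailed": 0.003992015968063872,
  "n_perm": 500,
  "null_mean": -0.020580162332235776,
  "cluster_significant": true
 }
}
```

meaning the cluster of parcels tracking the Sensory-Engagement regressor
sits at the sensory (negative) end of gradient 1 far outside its rotation
null — the synthetic analogue of the study's headline convergence between
the voxel-space and state-space analyses. `results/models.json` holds the
mixed-model summaries (e.g. the gradient-1 term predicting Sensory
Engagement is significantly negative after FDR), `results/clusters.tsv` the
cluster table with bootstrap CIs, and `results/manifest.json` the seeds,
parameters and SHA-256 of every output.

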