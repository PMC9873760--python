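# artvalue

Feature-based construction of aesthetic value: a computational pipeline for
testing how subjective liking of visual images can be assembled from
interpretable stimulus features, and how such a computation could be laid
out across visual and prefrontal cortex.

## The scientific problem

How does a brain (or any system) assign a value to a complex, possibly
never-before-seen visual stimulus such as a painting?  One influential
answer is *value construction*: decompose the stimulus into a shared
feature space and compute value as a weighted sum over the features.  For
stimulus *i* with feature values *f*<sub>*i,j*</sub>, the linear feature
summation (LFS) model states

> *v*<sub>*i*</sub> = Σ<sub>*j*=0..*n*<sub>f</sub></sub> *w*<sub>*j*</sub> *f*<sub>*i,j*</sub>

with *f*<sub>*i*,0</sub> = 1 and participant-specific taste weights
*w*<sub>*j*</sub> shared across all stimuli.  Features split into
*low-level* statistics computable from pixels (segment sizes, hue means,
spatial moments, entropy, mirror symmetry, blur, intensity-bin fractions)
and *high-level* annotated attributes (concreteness, dynamics, temperature,
valence, presence of a person).

The pipeline implements and tests, on fully synthetic data with planted
ground truth:

1. **Image feature bank** — an 83-entry candidate catalog computed through
   three segmentation backends (statistical region merging, k-means on LAB
   chroma, and a graph-based segmenter), plus whole-image statistics.
2. **Value model fitting** — 20-fold cross-validated ridge regression of
   0–3 liking ratings on features; accuracy = Pearson correlation of pooled
   out-of-fold predictions; significance by a stimulus-label permutation
   null.
3. **Shared-feature selection** — sparse PCA orthogonalisation, a group
   lasso across participants solved by FISTA with backtracking, sharing and
   r²-dedup rules, yielding the 18-feature shared set.
4. **Interaction features** — pairwise products within/across levels,
   reduced to 5 principal components per group.
5. **Encoding analyses** — HRF-convolved parametric GLMs with group
   F-tests, per-trial beta estimation, voxelwise lasso encoding with
   shuffled-label nulls, and ROI proportion profiles quantifying the
   low→high hierarchy across ordered visual regions.
6. **Feature–value integration (PPI)** — psychophysiological-interaction
   maps from a value-region seed, with a stimulus-epoch versus ITI-epoch
   contrast and per-ROI overlap fractions with feature-encoding voxels.
7. **Layer probe** — a small convolutional rating network (numpy,
   softmax-head with probability-weighted 0–3 readout, Huber loss);
   features are decoded from every ReLU layer and classified as low/high
   by the permutation-tested sign of their decoding-accuracy slope.

A synthetic-data module generates procedural stimulus images with known
segment structure, annotations as noisy mixtures of low-level features,
ratings from the LFS rule, the task's 20-run × 50-trial design (3 s
stimuli, 2–9 s jittered ITIs, TR 1.12 s), and multi-region BOLD with a
planted low→high ROI gradient and stimulus-gated value-region coupling.

## Worked example

The numbered scripts under `analysis/` run the study end to end on
synthetic data and write their tables under `results/`:

```bash
python analysis/01_extract_features.py
python analysis/02_fit_value_model.py
python analysis/05_encoding_hierarchy.py
python analysis/06_ppi_overlap.py
```

prints, among other things:

```
catalog: 83 features (78 low, 5 high)
extracted 120 stimuli x 83 features -> results/stimulus_features.tsv
pooled CV accuracy (mean over 6 participants): 0.570
planted-weight recovery r: 0.828
permutation p (participant 1): 0.001996 (chance level -0.029)
example ROI proportion profile (fraction of significant voxels):
      low  high
V1   1.00  0.15
V2   1.00  0.85
V4   1.00  1.00
LO   0.85  1.00
PHC  0.15  1.00
hierarchy index mean 1.00; recovered (>= 0.8) in 100% of sessions
overlap fraction (feature-encoding voxels also PPI-positive):
  coupled ROIs, stimulus epochs: 1.00
  visual ROIs,  stimulus epochs: 0.03
  coupled ROIs, ITI control:     0.00
```

Reading these: ratings generated at signal-to-noise 1 and discretised to
the 0–3 scale are predicted out-of-sample at r ≈ 0.57, far above the
permutation chance level; the encoding analysis recovers the planted ROI
gradient (low-level features dominate early regions, high-level features
late regions; hierarchy index 1.0); and feature-encoding voxels are
noise-coupled to the value region almost exclusively in the
parietal/prefrontal analogues, during stimulus epochs but not ITIs —
exactly the planted integration structure.

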