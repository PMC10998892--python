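# tumorconn

Brain tumors disturb both the resting-state functional signal and the white
matter architecture around them, and surgery reorganizes structural
connectivity in ways that are hard to anticipate per patient.  `tumorconn`
implements an analysis chain for this setting, end to end, over a synthetic
cohort with known ground truth:

* **Spectral desynchronization scoring.**  Regional BOLD series are compared
  in the frequency domain, where arbitrary dephasing between subjects is
  irrelevant.  The Dynamics Alteration Score between signals *i* and *j* is
  the area between their cumulative spectral power curves,
  `DAS(i,j) = ∫ dω (CP_ω^i − CP_ω^j) = −DAS(j,i)`;
  a positive score means signal *i* oscillates more slowly.  Mixed
  repetition times (2.1 s / 2.4 s) are harmonized by zero-padding/truncation
  to a common duration.
* **Functional-network scores.**  Pearson-correlation networks over the 41
  default-mode regions; the Θ richness
  `Θ = 1 − m/(2(m−1)) Σ_μ |P_μ(r_ij) − 1/m|`
  compares the correlation histogram with a uniform one (1 = maximally rich,
  0 = collapsed); node similarity, tumor/DMN voxel overlap
  `|T ∩ D|/|D|`, and centroid distances.
* **Connectome assembly.**  The arithmetic of a hybrid tractography
  pipeline: the lesion streamline budget (mean lesion-crossing count over
  controls), the greedy merge `ω_ij = max(ω_ij^healthy, ω_ij^lesion)`,
  `log(1+w)` weight normalization, and maximum-likelihood power-law tail
  fits (α, KS distance D, σ) of weighted degree distributions.
* **Post-surgery prediction.**  FCNET — a one-hidden-layer network mapping
  the 13695-edge pre-surgery vector to the post-surgery vector, its output
  gated elementwise by an anatomical prior (the thresholded average edge
  presence across healthy controls) inside the loss — trained with SGD
  (learning rate 0.01, 100 epochs, 80/20 train/validation split).
  Benchmarked under leave-one-out cross-validation against a pooled Huber
  regressor and an untrained null generator, both gated by the same prior,
  on six metrics: MSE, MAE, Pearson correlation, cosine similarity, and
  base-2 KL / Jensen–Shannon divergences of the weight distributions.

The synthetic cohort generator (`tumorconn.synthetic`) is first-class,
tested code: it fixes the study conditions (sample sizes, spectral tilts,
lognormal edge weights, a lesion-dependent surgery operator) and exposes the
ground truth every downstream stage is validated against.  See
`docs/methods.md` for the models, parameter choices, and what the generator
does and does not emulate.

## Worked example

The numbered scripts under `analysis/` run the study replica step by step
(cohort → DAS → functional scores → assembly → prediction → diagnostics),
writing tables under `results/analysis/`.  Running

```bash
python analysis/01_simulate_cohort.py
python analysis/02_spectral_das.py
python analysis/05_predict_surgery.py
```

prints (abridged):

```
cohort: 10 controls + 20 patients
TR dialects: Counter({2.1: 15, 2.4: 15})
ground-truth tilts span [-1.88, +1.84]

DAS vs ground-truth tilt: r = 0.967 (p = 3.4e-12), sign agreement 95%
tumor DAS vs DMN DAS: r = 0.992 (p = 1.5e-17) - intra-lesion dynamics track
the network-level alteration

LOO summary (mean +/- SEM per model):
  fcnet  mse: 0.396+/-0.004  mae: 0.179+/-0.001  pcc: 0.914+/-0.001  cs: 0.938+/-0.001  kl: 0.025+/-0.001  js: 0.006+/-0.000
  huber  mse: 0.400+/-0.004  mae: 0.183+/-0.001  pcc: 0.913+/-0.001  cs: 0.938+/-0.001  kl: 0.025+/-0.002  js: 0.005+/-0.000
  null   mse: 4.312+/-0.025  mae: 1.048+/-0.003  pcc: -0.003+/-0.003  cs: -0.003+/-0.003  kl: 5.976+/-0.331  js: 0.354+/-0.006
```

Reading the numbers: the per-region DAS recovers each patient's ground-truth
spectral tilt almost perfectly (r = 0.967), and the score computed from the
intra-tumor signal tracks the network-level score (r = 0.992) — the
synthetic analogue of desynchronization being shared between lesioned and
distant regions.  In the prediction benchmark, FCNET attains the lowest
reconstruction errors; the prior-gated Huber regressor is close behind on
numerical metrics, while the untrained null generator shows what the
anatomical prior alone cannot do (PCC ≈ 0, an order of magnitude larger
errors).

The same pipeline is available as a CLI:

```bash
tumorconn all --out runs/demo --seed 1
tumorconn predict --out runs/demo --seed 1 --model fcnet --model huber \
    --prior-tau 0.5 --hidden 256 --lr 0.01 --epochs 100
```

Exit codes: 0 success, 2 configuration error, 3 data error, 4 numeric
failure.

## File formats

Everything is plain text: BOLD as time-by-region TSV with a JSON sidecar
carrying the repetition time; masks as 3-column integer CSV; connectomes as
dense TSV with a node-label header and a JSON sidecar (active labels, scale
flag); tractogram streamlines as one `x y z` vertex per line with blank
lines separating polylines; cohort manifests as JSON.

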