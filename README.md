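# ctanomaly

Generative anomaly detection and worklist triage for volumetric head CT,
at configurable scale.

A style-based generator/encoder pair is trained only on normal scans
(two phases: adversarial generator training, then encoder training with
perceptual, domain-guided, and adversarial losses plus random erasing).
A query slice is mapped to its *closest normal-style* reconstruction by
latent optimization followed by masked noise optimization; the residual
mask doubles as a lesion attention map.  Masked per-slice density errors
are z-normalised per slice order against normal-scan statistics and
summed into a scan-level anomaly score.  Downstream tooling covers
threshold tuning (Youden / fixed-sensitivity), ROC/AUC with bootstrap
CIs, and a randomized-crossover worklist-triage simulation with
wait-time / turnaround-time / reading-time summaries.

Because no public CT cohort ships with the method, a seeded phantom
module (`ctanomaly.phantom`) generates synthetic head CT in Hounsfield
units — skull ring, parenchyma, slice-order-dependent ventricles,
near left-right symmetry — with injectable hyperdense/hypodense/mass
lesions and exact ground-truth masks.

The neural backbone runs on a small NumPy reverse-mode autodiff engine
(`ctanomaly.backbone.autograd`) with exact double backprop for the R1
gradient penalty, so the package has no deep-learning framework
dependency and trains a desk-scale (64×64) model on CPU in minutes.

## Command line

```sh
ctanomaly phantom --n 60 --seed 1 --prevalence 0.11 --out data/cohort
ctanomaly train --data data/normals --out ckpt.npz --seed 1
ctanomaly calibrate --checkpoint ckpt.npz --data data/normals \
    --out-latent latent.npz --out-errors errors.json
ctanomaly score --checkpoint ckpt.npz --latent-stats latent.npz \
    --error-stats errors.json --data data/cohort --out scored/
ctanomaly tune --scores scored/scores.csv --manifest data/cohort/manifest.csv \
    --out tuned.json
ctanomaly triage-sim --scores scored/scores.csv \
    --manifest data/cohort/manifest.csv --threshold 3.2 --seed 7 --out sim/
ctanomaly report --times sim/times.csv --manifest data/cohort/manifest.csv \
    --out summary.csv
```

Scans are NIfTI (HU as int16, slope 1 / intercept 0) or `.npz` archives
with a JSON sidecar; manifests are CSV (`case_id,category,is_emergency`).
Every stochastic entry point takes an explicit `--seed`, and outputs are
stamped with the config hash.  A YAML config (`--config`) mirrors the
`PipelineConfig` sections (backbone, train, inversion, scoring, triage,
simulation); unknown keys are rejected.

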