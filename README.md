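# fmrileak

**How slice-level train/test splits leak subject identity in fMRI
classification — a reusable, fully synthetic demonstration harness.**

## The problem

Deep-learning papers on resting-state fMRI sometimes report near-perfect
accuracy for Alzheimer's disease (AD) and mild-cognitive-impairment (MCI)
diagnosis from individual 2D slices of the 4D BOLD signal. A 4D scan of
shape (H, W, D, T) yields D·T axial slices — e.g. 18,715 slices for a
(99, 117, 95, 197) volume — and the evaluation hinges on how those slices
are divided into training and test sets:

* **subject-level (brain) hold-out** — every subject's slices go wholly to
  train *or* test. The model is evaluated on brains it has never seen,
  which is what a diagnostic claim requires.
* **slice-level hold-out** — slices are pooled and split 70/30 regardless
  of subject, so the two sides share brains. The model can score highly by
  *recognizing the patient*, not the pathology: data leakage.

A replication of one such ResNet-18 pipeline on ADNI-3 found median
accuracy/sensitivity/specificity of **46.22 / 25.14 / 33.00 %** across
seven binary diagnostic problems under subject-level splitting — versus
**84.12 / 82.36 / 88.47 %** for the *same* pipeline under slice-level
splitting. `fmrileak` packages that contrast as a controlled experiment:
a synthetic cohort generator whose only "signal" is a per-subject spatial
fingerprint, the exact slicing/filtering/sampling pipeline, both
splitters, a leakage audit, a deterministic CNN, and a two-panel report.

## The model

Each synthetic subject-scan is

```
X[i,j,k,t] = baseline + σ_f · F_s[i,j,k] + σ_c · G_c[i,j,k] + ε[i,j,k,t]
```

where `F_s` is a smooth unit-variance 3D random field fixed per subject
(the identity fingerprint), `G_c` is a smooth field fixed per diagnosis
(the genuine class effect), and `ε ~ N(0, σ_n²)` is i.i.d. acquisition
noise. Setting `σ_c = 0` with `σ_f ≫ σ_n` creates a cohort with *no
diagnostic information at all*: any above-chance test accuracy can only
come from subject identity crossing the split.

The pipeline then mirrors the replicated procedure: deduplicate to each
subject's earliest scan; slice along depth and time; keep slices whose
mean BOLD signal reaches the per-subject 90th percentile (~10% retained —
1,872 of 18,715 at study scale); sample a fixed number per subject;
min-max normalize, resize and triplicate to 3 channels; train a binary
CNN (ResNet-18 with a linear→ReLU→dropout(0.2)→linear head at study
scale, a 3-block `tinycnn` at desk scale); report accuracy, sensitivity
and specificity per problem and their medians per hold-out mode.

## Worked example

```python
import dataclasses
from fmrileak import ExperimentConfig, run_experiment

cfg = ExperimentConfig(seed=1)  # desk scale: 10 subjects/class, 24x28x22x10
cfg = dataclasses.replace(cfg, cohort=dataclasses.replace(cfg.cohort, seed=1))
result = run_experiment(cfg, outdir="demo")
```

writes `demo/results.md`:

```
| Binary classes | Subject hold-out acc/sens/spec (%) | Slice hold-out acc/sens/spec (%) |
| --- | --- | --- |
| CN vs. AD | 30.25 / 14.50 / 46.00 | 97.50 / 97.50 / 97.50 |
| **median** | 30.25 / 14.50 / 46.00 | 97.50 / 97.50 / 97.50 |
```

The cohort has `class_effect_sd = 0` — there is nothing diagnostic to
learn — yet the slice-level split scores 97.5% because 70% of every
subject's slices are in the training set. The subject-level split, facing
five unseen brains per class, is at chance: single-seed subject-mode
accuracy is noisy (here 30%) because all ~40 slices of a test subject
share one fingerprint and succeed or fail together, so the effective
sample is 10 subjects, not 400 slices. Averaged over seeds 1–5 it is
49.1%, squarely at chance, while the slice-mode mean is 97.5% — a
leakage gap of ~48 accuracy points. The same experiment is available from
the shell:

```bash
fmrileak run-all --seed 1 --outdir demo
```

and stage by stage via `fmrileak simulate | slice | split | train |
evaluate | report`.

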