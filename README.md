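# somnastage

Single- versus multi-channel automatic sleep staging, as a tested,
reusable pipeline.

Clinical sleep scoring assigns one of five stages — Wake, N1, N2, N3,
REM — to every 30 s page of an overnight polysomnogram (PSG).  Automatic
staging models commonly use either a single EEG derivation or several
channels, and a practical question for portable-device design is how much
each additional channel (in particular the electrooculogram pair,
EOG(L)/EOG(R)) contributes.  `somnastage` implements the full analysis
needed to answer that question reproducibly:

* **Preprocessing** of EDF recordings: resampling to 100 Hz (polyphase,
  anti-aliased), a zero-phase notch at the 50/60 Hz line frequency, a
  zero-phase 4th-order Butterworth band-pass at 1–40 Hz, optional
  re-referencing (C3-M2-style derivations), and 30 s epoching with the
  R&K N4→N3 merge and per-stage epoch bookkeeping.
* **A hybrid attention network**: one tower per channel, each a
  multi-branch 1-D CNN (kernel sizes 50 and 400), squeeze-and-excitation
  residual blocks, and causal-convolution multi-head attention
  (d = 5 heads; attention written `softmax(QKᵀ/d)V`) with a
  position-wise 80→120→80 feed-forward; towers fuse into a softmax
  classifier.  An ablated "simplified" variant omits the attention stage.
* **A capped class-weighted loss**: inverse-frequency weights
  `w_k = max_j n_j / n_k`, N1 boosted ×1.5, all weights capped at 3.5×
  the minimum, to counter the heavy Wake/N2 imbalance of real nights.
* **Baselines**: six handcrafted features per epoch per channel (mean,
  SD, spectral energy, dominant frequency, Higuchi fractal dimension,
  Lempel–Ziv complexity) fed to an RBF SVM (C=1) and a 100-tree random
  forest.
* **Evaluation**: record-level k-fold and leave-one-subject-out
  cross-validation (no night ever contributes to both training and
  testing), overall accuracy, Cohen's κ = (Acc − Pe)/(1 − Pe), and
  one-vs-rest per-class F1, over 2/3/4/5-class staging tasks.
* **A synthetic PSG generator** — a Markov-chain hypnogram plus
  stage-conditioned spectral recipes with conjugate REM eye movements on
  the EOG pair — so the entire pipeline, including the channel
  comparison, runs end to end with no dataset download.

The network, its training loop (Adam + AMSGrad, weight decay 1e-3, step
LR decay) and the reverse-mode autodiff engine underneath are implemented
in numpy within this package.

## Worked example

Simulate a small cohort, preprocess it, and compare channel
configurations on the five-class task:

```python
from somnastage.experiments import (build_synthetic_dataset,
                                    channel_comparison)

data = build_synthetic_dataset(n_records=60, epochs_per_record=15,
                               seed=11)
accs = channel_comparison(data, seed=0)
print(accs)
```

which prints per-configuration overall accuracies (percent); with these
arguments it prints

```
{'EEG+2xEOG': 95.9, 'EEG+EOG': 92.6, 'EEG': 83.7, 'EOG': 47.0}
```

(values shift by a few points with the seed; the ordering is the stable
part).  Reading: EOG
alone carries too little of the stage structure; EEG alone resolves
Wake/N2/N3 well but confuses N1 with REM, whose evidence in this cohort —
as in real PSG — lives in the eye channels; one EOG channel recovers
part of that evidence, and the conjugate EOG pair recovers most of it.
The same experiment is available from the shell:

```bash
somnastage simulate --n-records 60 --n-epochs 15 --out scratch/cohort --seed 11
somnastage preprocess --edf scratch/cohort --labels scratch/cohort \
    --channels "EEG,EOG(L),EOG(R)" --line-freq 50 --out scratch/prep
somnastage compare --data scratch/prep --classes 5 --protocol holdout \
    --n-epochs 10 --out scratch/cmp
```

## Layout

```
src/somnastage/
  stages.py       stage alphabets, task mappings, class weights
  preprocess.py   EDF/CSV I/O, filters, resampling, epoching
  synthetic.py    Markov hypnograms and stage-conditioned signal recipes
  nn.py           numpy autodiff engine, layers, Adam/AMSGrad, StepLR
  model.py        the hybrid attention network and its config
  features.py     handcrafted features and classical baselines
  train_eval.py   training loop, CV protocols, metrics, comparisons
  experiments.py  desk-scale synthetic experiments
  cli.py          `somnastage` command-line interface
docs/methods.md   model, assumptions, parameter choices, limitations
```
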