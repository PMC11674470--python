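"""Desk-scale experiments on synthetic cohorts.

The headline analysis compares channel configurations — single-channel EEG,
single-channel EOG, EEG plus one EOG, and EEG plus both EOG channels — under
identical record-level splits.  On real archives this runs at full scale
(hundreds of records, five folds, tens of training epochs); here the same
code runs on a synthetic cohort small enough for a single CPU, with the
problem sizes below chosen as the package's desk-scale defaults.

The synthetic cohort concentrates the N1-vs-REM evidence in the EOG pair
(conjugate REM deflections vs in-phase N1 slow activity, with intermittent
per-channel artifacts), so the qualitative channel ordering — EEG+2xEOG >=
EEG+EOG >= max(EEG, EOG) — is the expected outcome when the classifier
exploits channel complementarity.  Real-data accuracy magnitudes are not
reproduced at this scale.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np

from .model import ModelConfig, build_model
from .preprocess import (EpochSet, concat_epoch_sets, epoch_and_align,
                         preprocess_record)
from .stages import StagingTask
from .synthetic import default_spec, generate_record
from .train_eval import TrainConfig, run_comparison, run_protocol, \
    make_holdout_split

logger = logging.getLogger("somnastage")

#: Desk-scale problem sizes (single CPU, minutes not hours).
DESK_N_RECORDS = 60
DESK_EPOCHS_PER_RECORD = 15
DESK_TRAIN_CONFIG = dict(n_epochs=6, batch_size=16)
DESK_TEST_FRACTION = 0.3

CHANNEL_CONFIGS: Mapping[str, tuple[str, ...]] = {
    "EEG": ("EEG",),
    "EOG": ("EOG(L)",),
    "EEG+EOG": ("EEG", "EOG(L)"),
    "EEG+2xEOG": ("EEG", "EOG(L)", "EOG(R)"),
}


def build_synthetic_dataset(n_records: int = DESK_N_RECORDS,
                            epochs_per_record: int = DESK_EPOCHS_PER_RECORD,
                            seed: int = 11) -> EpochSet:
    """Generate and fully preprocess a synthetic cohort."""
    spec = default_spec(n_epochs=epochs_per_record, seed=seed)
    sets = []
    for i in range(n_records):
        rec = generate_record(spec, f"synthetic-{i:03d}")
        eset, _ = epoch_and_align(preprocess_record(rec))
        sets.append(eset)
    return concat_epoch_sets(sets)


def channel_comparison(data: EpochSet, seed: int,
                       train_config: TrainConfig | None = None,
                       n_classes: int = 5) -> dict[str, float]:
    """One paired channel-configuration comparison; returns accuracies (%).
    """
    task = StagingTask.from_n_classes(n_classes)
    tc = train_config or TrainConfig(seed=seed, **DESK_TRAIN_CONFIG)
    table, _ = run_comparison(
        {k: list(v) for k, v in CHANNEL_CONFIGS.items()}, task, data,
        protocol="holdout", train_config=tc, seed=seed,
        test_fraction=DESK_TEST_FRACTION)
    return dict(zip(table["config"], table["accuracy"]))


def ordering_holds(accs: Mapping[str, float]) -> bool:
    """The qualitative multi-channel ordering of the comparison."""
    return (accs["EEG+2xEOG"] >= accs["EEG+EOG"]
            >= max(accs["EEG"], accs["EOG"]))


def channel_complementarity_experiment(
        seeds: Sequence[int] = (0, 1, 2),
        data_seed: int = 11,
        n_records: int = DESK_N_RECORDS,
        epochs_per_record: int = DESK_EPOCHS_PER_RECORD) -> dict:
    """The end-to-end desk experiment over several training/split seeds.

    Returns per-seed accuracies, the number of seeds in which the channel
    ordering holds, and the best full-model (EEG+2xEOG) accuracy.
    """
    data = build_synthetic_dataset(n_records, epochs_per_record, data_seed)
    per_seed = {}
    for s in seeds:
        per_seed[int(s)] = channel_comparison(data, int(s))
        logger.info("seed %d: %s", s,
                    {k: round(v, 2) for k, v in per_seed[int(s)].items()})
    n_hold = sum(ordering_holds(a) for a in per_seed.values())
    return {
        "per_seed": per_seed,
        "ordering_holds_in": n_hold,
        "n_seeds": len(list(seeds)),
        "full_model_best_accuracy": max(a["EEG+2xEOG"]
                                        for a in per_seed.values()),
        "n_epochs_total": len(data),
    }


def ablation_check(data: EpochSet, seed: int = 0,
                   train_config: TrainConfig | None = None) -> dict:
    """Train and evaluate the simplified model (no feature optimization).

    Returns its pooled accuracy; used to confirm the ablated variant runs
    end to end, not to match any accuracy level.
    """
    task = StagingTask.from_n_classes(5)
    tc = train_config or TrainConfig(seed=seed, n_epochs=3, batch_size=32)
    sub = data.select_channels(["EEG"])
    split = make_holdout_split(sub.record_ids, DESK_TEST_FRACTION, seed)
    mc = ModelConfig(n_channels=1, n_classes=5, feature_optimization=False,
                     seed=seed)
    report, _ = run_protocol(sub, task, split, mc, tc)
    return {"accuracy": report.accuracy, "kappa": report.kappa,
            "n_parameters": build_model(mc).n_parameters()}
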