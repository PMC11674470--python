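"""Sleep-stage alphabets, multi-class task schemes and class weighting.

Scored polysomnography uses the AASM five-stage alphabet ``W, N1, N2, N3,
REM``; older R&K scoring splits slow-wave sleep into N3 and N4, so a sixth
code ``N4`` appears in raw annotations and is merged into N3 during
preprocessing.  Applications differ in how many classes they need, so the
five AASM stages are mapped onto 2/3/4/5-class target schemes:

* 2-class: Wake vs Sleep
* 3-class: Wake, NREM, REM
* 4-class: Wake, Light (N1+N2), Deep (N3), REM
* 5-class: identity

Stage frequencies in overnight recordings are heavily imbalanced (Wake and
N2 dominate; N1 and N3 are rare), so training uses a weighted cross-entropy
whose per-class weights are inverse frequencies, with an extra 1.5x boost
for N1 (the hardest stage) and a cap keeping every weight within 3.5x of
every other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

# Five-class AASM alphabet (order is the canonical class order everywhere).
STAGES_5 = ("W", "N1", "N2", "N3", "REM")
# Six-code annotation alphabet (R&K N4 still present before the merge).
STAGES_6 = ("W", "N1", "N2", "N3", "N4", "REM")

STAGE_TO_INDEX_5 = {s: i for i, s in enumerate(STAGES_5)}
STAGE_TO_INDEX_6 = {s: i for i, s in enumerate(STAGES_6)}

_TASK_TABLES: dict[int, tuple[tuple[str, ...], dict[str, str]]] = {
    2: (("Wake", "Sleep"),
        {"W": "Wake", "N1": "Sleep", "N2": "Sleep", "N3": "Sleep",
         "REM": "Sleep"}),
    3: (("Wake", "NREM", "REM"),
        {"W": "Wake", "N1": "NREM", "N2": "NREM", "N3": "NREM",
         "REM": "REM"}),
    4: (("Wake", "Light", "Deep", "REM"),
        {"W": "Wake", "N1": "Light", "N2": "Light", "N3": "Deep",
         "REM": "REM"}),
    5: (STAGES_5, {s: s for s in STAGES_5}),
}


@dataclass(frozen=True)
class StagingTask:
    """A surjective map from the 5-class alphabet onto a target scheme."""

    n_classes: int
    class_names: tuple[str, ...]
    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.n_classes != len(self.class_names):
            raise ValueError("n_classes must equal len(class_names)")
        missing = set(STAGES_5) - set(self.mapping)
        if missing:
            raise ValueError(f"mapping not total; missing {sorted(missing)}")
        if set(self.mapping.values()) != set(self.class_names):
            raise ValueError("mapping must be surjective onto class_names")

    @classmethod
    def from_n_classes(cls, n_classes: int) -> "StagingTask":
        if n_classes not in _TASK_TABLES:
            raise ValueError(f"n_classes must be in {{2,3,4,5}}, got {n_classes}")
        names, mapping = _TASK_TABLES[n_classes]
        return cls(n_classes=n_classes, class_names=tuple(names),
                   mapping=dict(mapping))

    def class_index(self, name: str) -> int:
        return self.class_names.index(name)

    def map_label(self, stage: str) -> str:
        try:
            return self.mapping[stage]
        except KeyError:
            raise ValueError(f"unknown 5-class stage label {stage!r}") from None


def map_stages(labels: Sequence[str], task: StagingTask) -> np.ndarray:
    """Map a sequence of 5-class labels onto the task's classes.

    Count-conserving: output has exactly one label per input label.
    """
    return np.array([task.map_label(s) for s in labels], dtype=object)


def map_stage_indices(labels: Sequence[str], task: StagingTask) -> np.ndarray:
    """Map 5-class string labels directly to integer task-class indices."""
    lut = {s: task.class_index(task.mapping[s]) for s in STAGES_5}
    try:
        return np.array([lut[s] for s in labels], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"unknown 5-class stage label {exc.args[0]!r}") from None


@dataclass(frozen=True)
class ClassWeights:
    """Per-class loss weights (inverse-frequency, N1-boosted, ratio-capped)."""

    class_names: tuple[str, ...]
    weights: np.ndarray = field(repr=True)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.class_names),):
            raise ValueError("one weight per class required")
        if not np.all(w > 0):
            raise ValueError("weights must be positive")
        object.__setattr__(self, "weights", w)

    def as_dict(self) -> dict[str, float]:
        return {c: float(w) for c, w in zip(self.class_names, self.weights)}

    def for_labels(self, label_indices: np.ndarray) -> np.ndarray:
        """Per-sample weights for integer class labels."""
        return self.weights[np.asarray(label_indices, dtype=np.int64)]


def compute_class_weights(
    label_counts: Mapping[str, int] | Sequence[int],
    class_names: Sequence[str] | None = None,
    n1_multiplier: float = 1.5,
    cap: float = 3.5,
) -> ClassWeights:
    """Inverse-frequency class weights with an N1 boost and a ratio cap.

    The raw weight of class k is ``max(counts) / counts[k]``.  If a class
    named ``N1`` is present its weight is then multiplied by
    ``n1_multiplier`` (N1 is the hardest, rarest stage).  Finally all
    weights are clipped into ``[min_w, cap * min_w]`` so that no class
    weight exceeds ``cap`` times any other.

    Parameters
    ----------
    label_counts : mapping class -> count, or a count vector
    class_names : class order when a bare count vector is given
    """
    if isinstance(label_counts, Mapping):
        names = tuple(label_counts.keys())
        counts = np.array([label_counts[c] for c in names], dtype=float)
    else:
        counts = np.asarray(label_counts, dtype=float)
        if class_names is None:
            raise ValueError("class_names required with a bare count vector")
        names = tuple(class_names)
    if counts.ndim != 1 or len(counts) != len(names):
        raise ValueError("one count per class required")
    if np.any(counts <= 0):
        bad = [n for n, c in zip(names, counts) if c <= 0]
        raise ValueError(f"zero epoch count for class(es) {bad}: weight undefined")

    weights = counts.max() / counts
    if "N1" in names:
        weights[names.index("N1")] *= n1_multiplier
    lo = weights.min()
    weights = np.clip(weights, lo, cap * lo)
    return ClassWeights(class_names=names, weights=weights)


@dataclass(frozen=True)
class StageCountReport:
    """Per-stage epoch bookkeeping emitted by the preprocessing pipeline."""

    counts: Mapping[str, int]

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def as_dict(self) -> dict[str, int]:
        d = {k: int(v) for k, v in self.counts.items()}
        d["total"] = self.total
        return d


def apply_record_exclusions(
    record_ids: Sequence[str], excluded: Sequence[str]
) -> list[str]:
    """Drop excluded record IDs (order-preserving).

    Study-specific exclusion lists (records with missing channels or with
    the signal shorter than the label) are configuration, never hard-coded.
    """
    excl = set(str(e) for e in excluded)
    return [r for r in record_ids if str(r) not in excl]
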