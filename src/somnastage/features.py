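"""Handcrafted six-feature baseline representation and classical classifiers.

Each 30 s epoch of each channel yields six features: time-domain mean and
standard deviation; frequency-domain spectral energy and dominant
frequency (Welch PSD, 2 s Hann windows, 50% overlap, restricted to the
1-40 Hz filtered band); and two nonlinear measures, Higuchi's fractal
dimension (kmax = 10) and Lempel-Ziv complexity (median binarization,
LZ76 phrase count normalized by n / log2 n).  Multi-channel epochs
concatenate the per-channel features.

The comparison classifiers are an RBF-kernel SVM (C = 1, features
z-scored on the training split) and a 100-tree random forest (Gini
impurity); both receive per-sample weights realizing the same capped
class weighting the network's loss uses.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .preprocess import EpochSet
from .stages import ClassWeights

FEATURE_NAMES = ("mean", "sd", "spectral_energy", "dominant_frequency",
                 "higuchi_fd", "lzc")


def time_features(epoch: np.ndarray) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (ddof=1)."""
    x = np.asarray(epoch, dtype=float)
    if x.size < 2:
        raise ValueError("epoch must have at least two samples")
    return float(np.mean(x)), float(np.std(x, ddof=1))


def spectral_features(epoch: np.ndarray, fs: float = 100.0,
                      band: tuple[float, float] = (1.0, 40.0),
                      ) -> tuple[float, float]:
    """Spectral energy (integrated PSD over the band, µV²) and the
    frequency of the PSD maximum within the band."""
    x = np.asarray(epoch, dtype=float)
    nperseg = min(int(2 * fs), len(x))
    f, psd = sps.welch(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2)
    mask = (f >= band[0]) & (f <= band[1])
    if not mask.any():
        raise ValueError(f"band {band} outside the resolvable range")
    df = f[1] - f[0]
    energy = float(psd[mask].sum() * df)
    dominant = float(f[mask][np.argmax(psd[mask])])
    return energy, dominant


def higuchi_fd(epoch: np.ndarray, kmax: int = 10) -> float:
    """Higuchi's fractal dimension.

    Mean normalized curve length L(k) is computed for lags k = 1..kmax;
    the dimension is the slope of log L(k) against log(1/k).  A smooth
    curve gives ~1, Gaussian white noise ~2.  Constant input returns the
    degenerate value 1.0.  The estimate is invariant to amplitude scaling.
    """
    x = np.asarray(epoch, dtype=float)
    n = len(x)
    if kmax < 2 or n <= kmax:
        raise ValueError("need length > kmax >= 2")
    if np.ptp(x) == 0:
        return 1.0
    lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / (len(idx) - 1) / k
            lengths.append(dist * norm / k)
        lk[k - 1] = np.mean(lengths)
    k_arr = np.arange(1, kmax + 1)
    slope, _ = np.polyfit(np.log(1.0 / k_arr), np.log(lk), 1)
    return float(slope)


def _lz76_phrases(bits: np.ndarray) -> int:
    """Number of phrases in the LZ76 parsing of a binary sequence.

    A new phrase ends at the first position where the current substring
    does not occur earlier in the sequence (allowing overlap with the
    phrase itself, per LZ76).
    """
    s = np.asarray(bits, dtype=np.uint8).tobytes()
    n = len(s)
    i, c = 0, 0
    while i < n:
        length = 1
        # grow until s[i:i+length] has no earlier occurrence
        while i + length <= n and s.find(s[i:i + length], 0,
                                         i + length - 1) != -1:
            length += 1
        c += 1
        i += length
    return c


def lempel_ziv_complexity(epoch: np.ndarray) -> float:
    """Normalized Lempel-Ziv (LZ76) complexity.

    The signal is binarized at its median; the phrase count c(n) is
    normalized by n / log2(n), so iid random bits approach 1.
    """
    x = np.asarray(epoch, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("epoch must have at least two samples")
    bits = (x > np.median(x)).astype(np.int8)
    c = _lz76_phrases(bits)
    return float(c / (n / np.log2(n)))


def epoch_features(epoch: np.ndarray, fs: float = 100.0,
                   kmax: int = 10) -> np.ndarray:
    """Six features for one single-channel epoch, in FEATURE_NAMES order."""
    mean, sd = time_features(epoch)
    energy, dominant = spectral_features(epoch, fs=fs)
    return np.array([mean, sd, energy, dominant,
                     higuchi_fd(epoch, kmax), lempel_ziv_complexity(epoch)])


def extract_features(epochs: EpochSet, fs: float = 100.0) -> np.ndarray:
    """Feature matrix [n_epochs, 6 * n_channels] (channels concatenated)."""
    n, n_ch, _ = epochs.data.shape
    out = np.empty((n, 6 * n_ch))
    for i in range(n):
        for c in range(n_ch):
            out[i, 6 * c: 6 * (c + 1)] = epoch_features(epochs.data[i, c], fs)
    return out


def features_to_frame(epochs: EpochSet, fs: float = 100.0):
    """Features as a DataFrame (record_id, epoch_index, features..., label)."""
    import pandas as pd

    feats = extract_features(epochs, fs)
    cols = [f"{ch}_{f}" for ch in epochs.channel_names
            for f in FEATURE_NAMES]
    df = pd.DataFrame(feats, columns=cols)
    df.insert(0, "epoch_index", np.arange(len(epochs)))
    df.insert(0, "record_id", epochs.record_ids)
    df["label"] = epochs.labels
    return df


def baseline_fit_predict(train_features: np.ndarray, train_labels: np.ndarray,
                         test_features: np.ndarray, model: str,
                         weights: ClassWeights | None = None,
                         seed: int = 0) -> np.ndarray:
    """Fit one of the two classical baselines and predict test labels.

    ``model``: ``"svm_rbf_C1"`` (RBF SVM, C=1, z-scored features) or
    ``"rf_100_gini"`` (100 trees, Gini impurity).  Class weighting is
    realized as per-sample weights.  Deterministic given ``seed``.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    y = np.asarray(train_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    sample_weight = None
    if weights is not None:
        lut = weights.as_dict()
        sample_weight = np.array([lut[str(lbl)] for lbl in y])

    if model == "svm_rbf_C1":
        clf = make_pipeline(StandardScaler(),
                            SVC(C=1.0, kernel="rbf", random_state=seed))
        clf.fit(train_features, y, svc__sample_weight=sample_weight)
    elif model == "rf_100_gini":
        clf = RandomForestClassifier(n_estimators=100, criterion="gini",
                                     random_state=seed)
        clf.fit(train_features, y, sample_weight=sample_weight)
    else:
        raise ValueError(f"unknown baseline model {model!r}")
    return clf.predict(test_features)
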