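"""Sliding-window extraction shared by both recognition models.

Windows are center-aligned: the window of length ``T`` around sample ``i``
spans ``[i - T//2, i - T//2 + T)``; at the series boundaries the window is
clamped to the first/last valid position, so every sample of the series
has a window and prediction length equals series length.
"""

from __future__ import annotations

import numpy as np

from .simulator import GeneratedSeries

__all__ = ["window_starts", "extract_windows", "sample_training_windows"]


def window_starts(n_samples: int, T: int) -> np.ndarray:
    """Clamped start index of the center-aligned window for every sample."""
    if n_samples < T:
        raise ValueError(f"series of {n_samples} samples is shorter than window T={T}")
    starts = np.arange(n_samples) - T // 2
    return np.clip(starts, 0, n_samples - T)


def extract_windows(features: np.ndarray, starts: np.ndarray, T: int) -> np.ndarray:
    """Gather (len(starts), T, F) windows from a (time, F) feature matrix."""
    idx = starts[:, None] + np.arange(T)[None, :]
    return features[idx]


def sample_training_windows(series: GeneratedSeries, T: int, n: int,
                            rng: np.random.Generator,
                            label_index: dict[str, int]) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` random windows with the label of their center sample."""
    starts = rng.integers(0, len(series) - T + 1, size=n)
    centers = starts + T // 2
    X = extract_windows(series.features, starts, T)
    y = np.asarray([label_index[series.behavior_labels[c]] for c in centers])
    return X, y
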