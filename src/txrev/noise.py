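"""Intensity-dependent replicate-noise model.

Replicated arrays show larger measurement scatter at low intensity. The
model here estimates the standard deviation of a *single* measurement as a
function of mean log2 intensity, from the spread of within-condition
replicate differences among probes of similar intensity: probes are sorted
by their replicate-pair mean, grouped into overlapping windows, and the SD
of the differences in each window is estimated robustly (scaled MAD, so
genuinely regulated probes act as outliers rather than inflating the
estimate). For a difference of two i.i.d. measurements Var(diff) = 2 Var(x),
hence the single-measurement SD is the difference-SD divided by sqrt(2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import median_abs_deviation

from .io import DesignTable, ExpressionMatrix

__all__ = ["IntensityNoiseModel", "fit_noise_model", "constant_noise_model"]

_MAD_SCALE = 1.4826  # consistency factor for normal data


@dataclass
class IntensityNoiseModel:
    """Piecewise-linear SD(intensity) curve with clamped extrapolation."""

    knot_intensities: np.ndarray  # strictly ascending log2 intensities
    knot_sd: np.ndarray  # SD of a single measurement at each knot
    window_size: int

    def __post_init__(self) -> None:
        self.knot_intensities = np.asarray(self.knot_intensities, dtype=float)
        self.knot_sd = np.asarray(self.knot_sd, dtype=float)
        if self.knot_intensities.ndim != 1 or len(self.knot_intensities) != len(self.knot_sd):
            raise ValueError("knot arrays must be 1-d and of equal length")
        if np.any(np.diff(self.knot_intensities) <= 0):
            raise ValueError("knot intensities must be strictly ascending")
        if np.any(self.knot_sd <= 0):
            raise ValueError("knot SDs must be positive")

    def sd_at(self, intensity) -> np.ndarray | float:
        """SD of one measurement at the given log2 intensity (clamped ends)."""
        out = np.interp(np.asarray(intensity, dtype=float),
                        self.knot_intensities, self.knot_sd)
        return out if out.ndim else float(out)


def constant_noise_model(sd: float) -> IntensityNoiseModel:
    """Homoscedastic model; handy for tests and degenerate designs."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    return IntensityNoiseModel(np.array([0.0, 1.0]), np.array([sd, sd]), window_size=0)


def _replicate_pairs(matrix: ExpressionMatrix, design: DesignTable):
    """Pooled (pair mean, pair difference) points over all replicated conditions."""
    means, diffs = [], []
    for cond in design.conditions:
        idx = [matrix.sample_index(s) for s in design.samples_for(cond)]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                x, y = matrix.values[:, idx[a]], matrix.values[:, idx[b]]
                means.append((x + y) / 2.0)
                diffs.append(x - y)
    if not means:
        raise ValueError("no condition has >= 2 replicates: cannot estimate noise")
    return np.concatenate(means), np.concatenate(diffs)


def fit_noise_model(
    matrix: ExpressionMatrix,
    design: DesignTable,
    window_size: int = 500,
) -> IntensityNoiseModel:
    """Fit the SD-vs-intensity curve from within-condition replicate pairs.

    Windows of ``window_size`` points slide with step ``window_size // 2``;
    each contributes one knot at its median intensity with SD =
    ``1.4826 * MAD(differences) / sqrt(2)``. Window SDs are floored at the
    1st percentile of all window SDs (1e-3 when everything is degenerate),
    so zero-variance stretches cannot produce infinite test statistics.
    """
    if window_size < 20:
        raise ValueError("window_size must be >= 20 for a stable SD estimate")
    if matrix.scale != "log2":
        raise ValueError("noise model expects log2-scale data")
    means, diffs = _replicate_pairs(matrix, design)
    n = len(means)
    if n < window_size:
        raise ValueError(f"only {n} replicate pairs available; need >= {window_size}")
    order = np.argsort(means, kind="stable")
    means, diffs = means[order], diffs[order]

    step = max(window_size // 2, 1)
    starts = list(range(0, n - window_size + 1, step))
    if starts[-1] != n - window_size:
        starts.append(n - window_size)
    knot_x = np.empty(len(starts))
    knot_s = np.empty(len(starts))
    for w, s in enumerate(starts):
        sl = slice(s, s + window_size)
        knot_x[w] = np.median(means[sl])
        knot_s[w] = _MAD_SCALE * median_abs_deviation(diffs[sl]) / np.sqrt(2.0)

    positive = knot_s[knot_s > 0]
    floor = np.percentile(positive, 1) if positive.size else 1e-3
    floor = max(floor, 1e-3) if not positive.size else max(floor, 1e-12)
    knot_s = np.maximum(knot_s, floor if positive.size else 1e-3)

    # collapse ties in knot position (flat stretches of identical intensity)
    keep_x, keep_s = [knot_x[0]], [knot_s[0]]
    for x, s_ in zip(knot_x[1:], knot_s[1:]):
        if x > keep_x[-1]:
            keep_x.append(x)
            keep_s.append(s_)
        else:
            keep_s[-1] = max(keep_s[-1], s_)
    if len(keep_x) == 1:
        keep_x.append(keep_x[0] + 1.0)
        keep_s.append(keep_s[0])
    return IntensityNoiseModel(np.array(keep_x), np.array(keep_s), window_size)
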