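"""Sample ordination by PCA and a quantitative rescue-shift metric.

The averaged conditions (points) are decomposed in the space of all probes
(features), centered per feature, without unit-variance scaling — scaling
would distort the fold-change structure the ordination is meant to show.
The rescue of a perturbation is quantified by the shift ratio: the distance
of the rescued condition from baseline divided by the distance of the
perturbed condition from baseline, in the retained component space. A ratio
near 0 means the counter-treatment returned expression to baseline; near 1
means no rescue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .preprocess import AveragedData

__all__ = ["SampleMap", "ShiftMetric", "pca", "shift_metric", "plot_sample_map"]


@dataclass
class SampleMap:
    condition_labels: list[str]
    coordinates: np.ndarray  # conditions x components
    explained_variance_fractions: np.ndarray
    components: np.ndarray  # components x features (orthonormal loadings)

    def coords_of(self, label: str) -> np.ndarray:
        try:
            i = self.condition_labels.index(label)
        except ValueError:
            raise KeyError(f"condition {label!r} not in the map") from None
        return self.coordinates[i]


@dataclass
class ShiftMetric:
    d_perturbed: float
    d_rescued: float

    @property
    def shift_ratio(self) -> float:
        if self.d_perturbed == 0:
            raise ZeroDivisionError("perturbed condition coincides with baseline")
        return self.d_rescued / self.d_perturbed


def pca(data: AveragedData, n_components: int = 2) -> SampleMap:
    """Project the condition points onto the top principal components.

    Component signs are fixed by making each component's largest-magnitude
    feature loading positive, so orientations are reproducible.
    """
    n_cond = len(data.condition_labels)
    if n_cond < 2:
        raise ValueError("PCA needs at least two conditions")
    if n_components > n_cond - 1:
        raise ValueError(
            f"n_components={n_components} exceeds the {n_cond - 1} informative "
            f"dimensions of {n_cond} centered conditions"
        )
    X = data.values.T  # conditions x features
    model = PCA(n_components=n_components, svd_solver="full")
    coords = model.fit_transform(X)
    components = model.components_
    for k in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[k])))
        if components[k, j] < 0:
            components[k] *= -1
            coords[:, k] *= -1
    return SampleMap(
        list(data.condition_labels),
        coords,
        model.explained_variance_ratio_,
        components,
    )


def shift_metric(
    sample_map: SampleMap, baseline: str, perturbed: str, rescued: str
) -> ShiftMetric:
    """Euclidean baseline distances of the perturbed and rescued conditions."""
    b = sample_map.coords_of(baseline)
    p = sample_map.coords_of(perturbed)
    r = sample_map.coords_of(rescued)
    return ShiftMetric(float(np.linalg.norm(p - b)), float(np.linalg.norm(r - b)))


def plot_sample_map(sample_map: SampleMap, path: str | None = None):
    """Labelled PC1/PC2 scatter of the conditions; writes ``path`` if given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    xy = sample_map.coordinates
    ax.scatter(xy[:, 0], xy[:, 1], s=40)
    for label, (x, y) in zip(sample_map.condition_labels, xy[:, :2]):
        ax.annotate(label, (x, y), textcoords="offset points", xytext=(5, 3))
    ev = sample_map.explained_variance_fractions
    ax.set_xlabel(f"PC1 ({100 * ev[0]:.0f}% var)")
    ax.set_ylabel(f"PC2 ({100 * ev[1]:.0f}% var)" if len(ev) > 1 else "PC2")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
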