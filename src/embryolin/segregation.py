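"""Lineage-segregation dynamics over developmental time.

Cells are embedded with a diffusion map on the lineage-specific genes, a
linear max-margin separator (SVM, C=1) is fitted on the matured cells of
the two lineages, and every cell — matured or not — is scored by its
signed distance to that decision surface.  Binning |distance| by embryo
pseudo-time shows when the transcriptional states separate; a two-level
piecewise-constant least-squares fit locates the rise.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.svm import SVC

from .datasets import ExpressionDataset
from .variability import diffusion_map


@dataclasses.dataclass
class SegregationSurface:
    w: np.ndarray
    b: float
    classes: tuple            # (negative-side label, positive-side label)
    center: np.ndarray        # training-cell standardisation
    scale: np.ndarray

    def signed_distance(self, coords: np.ndarray) -> np.ndarray:
        """Signed distance in normalised component units."""
        z = (coords - self.center) / self.scale
        return (z @ self.w + self.b) / np.linalg.norm(self.w)


def diffusion_embedding(dataset: ExpressionDataset, lineage_genes,
                        n_components: int = 3,
                        bandwidth: float | None = None) -> pd.DataFrame:
    """Diffusion-map coordinates of all cells on the lineage gene set."""
    genes = [g for g in lineage_genes if g in dataset.genes.index]
    if not genes:
        raise ValueError("no lineage genes present in the dataset")
    x = dataset.log_values(genes=genes).to_numpy().T
    comps = diffusion_map(x, n_components=n_components, bandwidth=bandwidth)
    cols = [f"DC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(comps, index=dataset.cells.index, columns=cols)


def fit_segregation_surface(coords: pd.DataFrame, labels: pd.Series,
                            C: float = 1.0):
    """Linear SVM on matured cells; signed distances for every cell.

    ``labels`` covers only the matured training cells (two classes, ≥5
    cells each).  Returns ``(surface, distances)`` where distances is a
    Series over all cells in ``coords``; training cells of the two classes
    get opposite signs.
    """
    labels = labels.dropna()
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError("exactly two classes are required")
    for c in classes:
        if (labels == c).sum() < 5:
            raise ValueError(f"class {c!r} has fewer than 5 cells")
    x = coords.loc[labels.index].to_numpy()
    # standardise on the training cells: the embedding's raw scale is
    # arbitrary and a fixed soft-margin C needs unit-order features
    center = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    y = (labels == classes[1]).astype(int).to_numpy()
    svm = SVC(kernel="linear", C=C)
    svm.fit((x - center) / scale, y)
    surface = SegregationSurface(w=svm.coef_.ravel().copy(),
                                 b=float(svm.intercept_[0]),
                                 classes=(classes[0], classes[1]),
                                 center=center, scale=scale)
    distances = pd.Series(surface.signed_distance(coords.to_numpy()),
                          index=coords.index, name="distance")
    return surface, distances


def segregation_vs_time(distances: pd.Series, embryo_ids: pd.Series,
                        embryo_pseudotime: pd.Series) -> dict:
    """Per-embryo mean |distance| versus embryo pseudo-time, with the
    segregation-onset changepoint.

    Fits every two-level piecewise-constant split of the embryos ordered
    by pseudo-time and keeps the least-squares best; the changepoint is
    reported as the pseudo-time of the first embryo on the high level.
    With a flat profile (no split improves on a constant fit by more than
    1%) the changepoint is flagged undefined.
    """
    per_embryo = distances.abs().groupby(
        embryo_ids.reindex(distances.index)).mean()
    times = embryo_pseudotime.reindex(per_embryo.index)
    if len(per_embryo) < 3:
        raise ValueError("need at least 3 embryos")
    order = np.argsort(times.to_numpy(), kind="stable")
    t = times.to_numpy()[order]
    y = per_embryo.to_numpy()[order]
    sse_const = float(((y - y.mean()) ** 2).sum())
    best = (np.inf, None)
    for split in range(1, len(y)):
        left, right = y[:split], y[split:]
        sse = float(((left - left.mean()) ** 2).sum()
                    + ((right - right.mean()) ** 2).sum())
        if sse < best[0]:
            best = (sse, split)
    defined = sse_const > 0 and (sse_const - best[0]) > 0.01 * sse_const
    split = best[1]
    changepoint = float(t[split]) if defined else None
    curve = pd.DataFrame({"pseudotime": t, "mean_abs_distance": y})
    return {"curve": curve, "changepoint": changepoint,
            "changepoint_defined": bool(defined),
            "pre_level": float(y[:split].mean()) if split else float("nan"),
            "post_level": float(y[split:].mean())}


def bootstrap_mean_ci(values: np.ndarray, n_boot: int = 1000,
                      alpha: float = 0.05, seed: int = 0) -> tuple:
    """Non-parametric bootstrap CI for a mean over cells (B resamples)."""
    rng = np.random.default_rng(seed)
    values = np.asarray(values, float)
    idx = rng.integers(0, len(values), (n_boot, len(values)))
    means = values[idx].mean(axis=1)
    return (float(np.quantile(means, alpha / 2)),
            float(np.quantile(means, 1 - alpha / 2)))
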