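"""Spike-in-calibrated variable-gene selection and 2-D embeddings.

Technical noise is modelled on the spike-ins as CV² = a1/μ + α0 (least
squares on 1/mean).  A gene's variability score is the ratio of its
observed CV² to the technical expectation plus an added biological CV
(default 0.5): genes whose variation exceeds what technical noise and
baseline biological noise explain rank highest.  An F-like tail
probability against that null accompanies the ratio.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.spatial.distance
import scipy.stats
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .datasets import ExpressionDataset


@dataclasses.dataclass
class NoiseFit:
    """Technical mean–CV² model fitted on spike-ins: CV² = a1/μ + α0."""
    a1: float
    alpha0: float
    cv_bio: float = 0.5

    def expected_cv2(self, mean, technical_only: bool = False):
        cv2 = self.a1 / np.asarray(mean, float) + self.alpha0
        if not technical_only:
            cv2 = cv2 + self.cv_bio ** 2
        return cv2


def fit_technical_noise(spikein_means, spikein_cv2,
                        cv_bio: float = 0.5) -> NoiseFit:
    """Least-squares fit of CV² = a1/μ + α0 over spike-ins.

    Two-pass weighted least squares: an ordinary fit provides predicted
    CV² values whose inverse squares weight the second pass.  Sample CV²
    noise scales with CV² itself, so unweighted OLS lets the noisy
    low-mean spike-ins dominate and biases α0; the reweighting restores
    near-uniform relative errors.  Requires at least ten spike-ins with
    positive mean; a1 is clipped at zero (technical noise cannot decrease
    with 1/mean).
    """
    means = np.asarray(spikein_means, float)
    cv2 = np.asarray(spikein_cv2, float)
    keep = means > 0
    means, cv2 = means[keep], cv2[keep]
    if len(means) < 10:
        raise ValueError("need at least 10 spike-ins with positive mean")
    X = np.column_stack([1.0 / means, np.ones_like(means)])
    coef, *_ = np.linalg.lstsq(X, cv2, rcond=None)
    pred = np.maximum(X @ coef, 1e-6)
    w = np.sqrt(1.0 / pred ** 2)
    coef, *_ = np.linalg.lstsq(X * w[:, None], cv2 * w, rcond=None)
    a1, alpha0 = float(coef[0]), float(coef[1])
    return NoiseFit(a1=max(a1, 0.0), alpha0=alpha0, cv_bio=cv_bio)


def fit_noise_from_dataset(dataset: ExpressionDataset,
                           cv_bio: float = 0.5) -> NoiseFit:
    spikes = dataset.spikeins()
    if spikes.n_genes == 0:
        raise ValueError("dataset has no spike-ins")
    v = spikes.values.to_numpy()
    mean = v.mean(axis=1)
    if np.all(mean == 0):
        raise ValueError("all spike-ins are zero")
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = v.var(axis=1, ddof=1) / mean ** 2
    keep = mean > 0
    return fit_technical_noise(mean[keep], cv2[keep], cv_bio=cv_bio)


def variability_scores(dataset: ExpressionDataset, fit: NoiseFit,
                       expressed_threshold: float = 1.0,
                       min_cells: int = 3) -> pd.DataFrame:
    """Per-gene variability ratio and rank, spike-ins excluded.

    score = observed CV² / (a1/μ + α0 + cv_bio²); ``p`` is the upper-tail
    chi-square probability of the observed variance given the expected CV²
    (a Brennecke-style test).  Genes expressed (RPKM ≥ threshold) in fewer
    than ``min_cells`` cells are dropped.  Ranks are descending by score
    with ties broken by gene ID.
    """
    bio = dataset.biological()
    v = bio.values.to_numpy()
    n = v.shape[1]
    mean = v.mean(axis=1)
    expressed = (v >= expressed_threshold).sum(axis=1) >= min_cells
    keep = expressed & (mean > 0)
    mean = mean[keep]
    var = v[keep].var(axis=1, ddof=1)
    cv2 = var / mean ** 2
    expected = fit.expected_cv2(mean)
    score = cv2 / expected
    # chi-square tail: (n-1) * cv2_obs / cv2_exp ~ chi2(n-1) under the null
    p = scipy.stats.chi2.sf((n - 1) * score, df=n - 1)
    out = pd.DataFrame({"mean": mean, "cv2": cv2, "expected_cv2": expected,
                        "score": score, "p": p},
                       index=bio.values.index[keep])
    out = out.iloc[np.lexsort((out.index.to_numpy(),
                               -out["score"].to_numpy()))]
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def top_variable_genes(scores: pd.DataFrame, n: int) -> list:
    """First ``n`` genes by variability rank (ties already broken by ID)."""
    if n > len(scores):
        raise ValueError(f"requested {n} genes, only {len(scores)} scored")
    return list(scores.index[:n])


# ---------------------------------------------------------------------------
# 2-D embeddings
# ---------------------------------------------------------------------------

def diffusion_map(x: np.ndarray, n_components: int,
                  bandwidth: float | None = None) -> np.ndarray:
    """Deterministic diffusion-map components of the rows of ``x``.

    Gaussian kernel with the median-pairwise-distance bandwidth heuristic,
    symmetric normalisation, dense eigendecomposition.  Component signs are
    fixed by making each component's largest-magnitude entry positive.
    """
    n = x.shape[0]
    if n_components > n - 1:
        raise ValueError("n_components must be < number of cells")
    d2 = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(x, "sqeuclidean"))
    if bandwidth is None:
        pos = d2[np.triu_indices(n, 1)]
        bandwidth = float(np.sqrt(np.median(pos[pos > 0]))) if np.any(
            pos > 0) else 1.0
    K = np.exp(-d2 / (2.0 * bandwidth ** 2))
    deg = K.sum(axis=1)
    if np.any(deg <= 0):
        raise ValueError("disconnected kernel graph; increase the bandwidth")
    inv_sqrt = 1.0 / np.sqrt(deg)
    A = K * inv_sqrt[:, None] * inv_sqrt[None, :]
    evals, evecs = np.linalg.eigh(A)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # drop the trivial stationary component, map back to the random-walk
    # eigenvectors and scale by the eigenvalues
    comps = evecs[:, 1:n_components + 1] * inv_sqrt[:, None]
    comps = comps * evals[1:n_components + 1][None, :]
    for j in range(comps.shape[1]):
        i = np.argmax(np.abs(comps[:, j]))
        if comps[i, j] < 0:
            comps[:, j] = -comps[:, j]
    return comps


def embed_2d(dataset: ExpressionDataset, genes, method: str = "tsne",
             seed: int = 0, perplexity: float = 30.0) -> pd.DataFrame:
    """Cell × 2 coordinates on log2(RPKM+1) over the given genes.

    ``method`` ∈ {"tsne", "pca", "diffusion"}; all three are deterministic
    given the seed (PCA and the diffusion map need no randomness at all).
    """
    x = dataset.log_values(genes=list(genes)).to_numpy().T
    if method == "pca":
        coords = PCA(n_components=2, svd_solver="full").fit_transform(x)
    elif method == "tsne":
        perplexity = min(perplexity, (x.shape[0] - 1) / 3.0)
        coords = TSNE(n_components=2, random_state=seed, init="pca",
                      perplexity=perplexity).fit_transform(x)
    elif method == "diffusion":
        coords = diffusion_map(x, n_components=2)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return pd.DataFrame(np.asarray(coords, float), index=dataset.cells.index,
                        columns=["dim1", "dim2"])
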