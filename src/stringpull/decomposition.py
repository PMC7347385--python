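"""PCA and fastICA of frame stacks.

A stack of ``N`` frames is reshaped to a ``(H*W) x N`` matrix — pixels are
observations, frames are variables — so the principal / independent
component *scores* are themselves images.  PC1 of an image sequence shows
the animal's dominant position; ICs pick out events of high spatiotemporal
contrast (hand and string appearance/disappearance), which is why max/min
projections of the ICs localise the hands.

fastICA uses the cubic nonlinearity with deflation on PCA-whitened data,
``tol = 5e-5`` and at most 1000 iterations; the number of components
defaults to half the number of frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning

__all__ = ["DecompResult", "pca_frames", "ica_frames", "ica_of_pcs",
           "minmax_projections"]


@dataclass
class DecompResult:
    """Components of a decomposition, as score images.

    ``components`` is ``H x W x K``.  ``explained_var`` (percent, PCA only)
    sums to 100 over all components.
    """

    components: np.ndarray
    method: str
    explained_var: np.ndarray | None = None
    n_iter: int | None = None
    seed: int | None = None
    converged: bool = True
    mean_image: np.ndarray | None = None   # per-frame means removed (PCA)
    loadings: np.ndarray | None = None     # N x K mixing/loading matrix

    @property
    def n_components(self) -> int:
        return self.components.shape[-1]

    def component(self, k: int) -> np.ndarray:
        return self.components[..., k]


def _as_matrix(stack) -> tuple[np.ndarray, tuple[int, int]]:
    frames = stack.frames if hasattr(stack, "frames") else np.asarray(stack)
    if frames.ndim != 3:
        raise ValueError("decomposition expects a grayscale HxWxN stack")
    H, W, N = frames.shape
    return frames.reshape(H * W, N).astype(np.float64), (H, W)


def pca_frames(stack, n_components: int | None = None) -> DecompResult:
    """Principal components of a stack (pixels x frames, column-centred).

    Component score vectors are reshaped to ``H x W`` images; explained
    variance is reported in percent per component.
    """
    X, (H, W) = _as_matrix(stack)
    N = X.shape[1]
    if N < 2:
        raise ValueError("PCA needs at least 2 frames")
    if np.allclose(X.var(axis=0), 0):
        warnings.warn("stack has zero variance; PCA is degenerate")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)           # (H*W, K)
    K = scores.shape[1]
    return DecompResult(
        components=scores.reshape(H, W, K),
        method="pca",
        explained_var=pca.explained_variance_ratio_ * 100.0,
        loadings=pca.components_.T,
    )


def ica_frames(stack, n_components: int | None = None, tol: float = 5e-5,
               max_iter: int = 1000, seed: int | None = 0) -> DecompResult:
    """Independent components of a stack by fastICA.

    ``n_components`` defaults to half the number of frames (rounded up),
    capped at the matrix rank.  Non-convergence is flagged on the result
    rather than raised; the partial result is still returned.
    """
    X, (H, W) = _as_matrix(stack)
    N = X.shape[1]
    if N < 4:
        raise ValueError("ICA needs at least 4 frames")
    if n_components is None:
        n_components = int(np.ceil(N / 2))
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    n_components = max(1, min(n_components, rank))
    ica = FastICA(
        n_components=n_components,
        algorithm="deflation",
        fun="cube",
        whiten="unit-variance",
        tol=tol,
        max_iter=max_iter,
        random_state=seed,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        sources = ica.fit_transform(X)      # (H*W, K)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
    K = sources.shape[1]
    return DecompResult(
        components=sources.reshape(H, W, K),
        method="ica",
        n_iter=int(ica.n_iter_),
        seed=seed,
        converged=converged,
        loadings=ica.mixing_,
    )


def ica_of_pcs(pca_result: DecompResult, n_components: int | None = None,
               tol: float = 5e-5, max_iter: int = 1000,
               seed: int | None = 0) -> DecompResult:
    """fastICA applied to the PC score images treated as an input stack."""
    if pca_result.method != "pca":
        raise ValueError("ica_of_pcs expects a PCA result")
    return ica_frames(pca_result.components, n_components=n_components,
                      tol=tol, max_iter=max_iter, seed=seed)


def minmax_projections(result: DecompResult) -> tuple[np.ndarray, np.ndarray]:
    """Pixelwise maximum and minimum across all component images."""
    if result.n_components < 1:
        raise ValueError("no components to project")
    return result.components.max(axis=-1), result.components.min(axis=-1)
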