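"""Saliency weight-map estimation and the max-pooled weight pyramid.

The network consumes a per-pixel prior ``W`` in [0, 1] estimating how
likely each pixel belongs to a vessel. Here the prior is estimated on a
superpixel graph by a small bound-constrained quadratic program combining
four ingredients:

* a data term pulling each superpixel saliency toward a foreground
  likelihood (vessel lumina are anechoic, so by default dark regions score
  high);
* a centre-distance term discounting superpixels far from the centroid of
  the foreground likelihood mass;
* a cost for assigning zero saliency to strongly foreground-like regions;
* a graph-Laplacian smoothness term over adjacent superpixels standing in
  for a connectedness prior.

Precomputed maps produced by any external saliency method are a
first-class bypass via :func:`load_weight_map`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from skimage.segmentation import slic
from skimage.transform import resize

from .nn import maxpool2

__all__ = [
    "SaliencyParams",
    "WeightMapPyramid",
    "estimate_weight_map",
    "load_weight_map",
    "build_pyramid",
]


@dataclass
class SaliencyParams:
    """Knobs of the superpixel quadratic program.

    ``polarity`` selects which intensities count as foreground: ``"dark"``
    for anechoic vessel lumina (the default), ``"bright"`` for echogenic
    targets. The lambda weights balance the data term (implicit weight 1)
    against the centre-distance discount, the zero-saliency cost and the
    Laplacian smoothness.
    """

    superpixels: int = 200
    compactness: float = 10.0
    lambda_center: float = 0.5
    lambda_zero_cost: float = 1.0
    lambda_smooth: float = 2.0
    affinity_sigma: float = 0.15
    polarity: str = "dark"
    tol: float = 1e-6
    max_iter: int = 500


@dataclass
class WeightMapPyramid:
    """Levels w_1..w_4 at sides S/2, S/4, S/8, S/16 (2x2 max pools)."""

    levels: list

    def __iter__(self):
        return iter(self.levels)

    def __getitem__(self, i):
        return self.levels[i]


def _superpixel_stats(frame: np.ndarray, params: SaliencyParams):
    labels = slic(frame, n_segments=params.superpixels,
                  compactness=params.compactness, channel_axis=None,
                  start_label=0, enforce_connectivity=True)
    k = int(labels.max()) + 1
    flat = labels.ravel()
    counts = np.bincount(flat, minlength=k).astype(np.float64)
    mean_i = np.bincount(flat, weights=frame.ravel(), minlength=k) / counts
    yy, xx = np.mgrid[0: frame.shape[0], 0: frame.shape[1]]
    cy = np.bincount(flat, weights=yy.ravel(), minlength=k) / counts
    cx = np.bincount(flat, weights=xx.ravel(), minlength=k) / counts
    return labels, k, mean_i, np.stack([cy, cx], axis=1)


def _adjacency(labels: np.ndarray, mean_i: np.ndarray, k: int,
               sigma: float) -> sparse.csr_matrix:
    pairs = set()
    for a, b in ((labels[:, :-1], labels[:, 1:]), (labels[:-1, :], labels[1:, :])):
        diff = a != b
        pairs.update(zip(a[diff].tolist(), b[diff].tolist()))
    if not pairs:
        return sparse.csr_matrix((k, k))
    i, j = np.array(sorted(pairs)).T
    w = np.exp(-((mean_i[i] - mean_i[j]) ** 2) / (2.0 * sigma**2))
    aff = sparse.coo_matrix((w, (i, j)), shape=(k, k))
    aff = aff.maximum(aff.T)
    return aff.tocsr()


def estimate_weight_map(
    frame: np.ndarray, params: SaliencyParams | None = None
) -> np.ndarray:
    """Estimate the [0, 1] saliency prior for one normalized frame.

    The superpixel saliencies solve, by projected gradient descent on the
    box [0, 1]^K,

        min_s  ||s - f||^2 + lc <d, s^2> + lz <f, (1-s)^2> + ls s^T L s

    with ``f`` the foreground likelihood, ``d`` the normalized distance to
    the foreground centroid and ``L`` the affinity-graph Laplacian. The
    solution is rasterized back to pixels and min-max rescaled. A constant
    frame carries no contrast signal and yields a uniform 0.5 map (with a
    warning).
    """
    p = params or SaliencyParams()
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError("expected a 2-D frame")
    span = float(frame.max() - frame.min())
    if span < 1e-12:
        warnings.warn("constant frame: returning uniform 0.5 weight map")
        return np.full(frame.shape, 0.5, dtype=np.float32)
    norm = (frame - frame.min()) / span  # intensity-scale invariance

    labels, k, mean_i, cents = _superpixel_stats(norm, p)
    f = 1.0 - mean_i if p.polarity == "dark" else mean_i
    f_span = f.max() - f.min()
    f = (f - f.min()) / f_span if f_span > 1e-12 else np.full(k, 0.5)

    fg_centroid = (f[:, None] * cents).sum(axis=0) / max(f.sum(), 1e-12)
    d = np.linalg.norm(cents - fg_centroid, axis=1)
    d /= max(d.max(), 1e-12)

    aff = _adjacency(labels, mean_i, k, p.affinity_sigma)
    deg = np.asarray(aff.sum(axis=1)).ravel()
    lap = sparse.diags(deg) - aff

    lc, lz, ls = p.lambda_center, p.lambda_zero_cost, p.lambda_smooth
    # Lipschitz bound of the gradient -> a safe fixed step size
    lip = 2.0 * (1.0 + lc * d.max() + lz * max(f.max(), 1e-12)
                 + ls * (2.0 * max(deg.max(), 0.0) if k > 1 else 0.0))
    step = 1.0 / lip
    s = f.copy()
    for _ in range(p.max_iter):
        grad = (2.0 * (s - f) + 2.0 * lc * d * s - 2.0 * lz * f * (1.0 - s)
                + 2.0 * ls * (lap @ s))
        s_new = np.clip(s - step * grad, 0.0, 1.0)
        if np.abs(s_new - s).max() < p.tol:
            s = s_new
            break
        s = s_new

    out = s[labels]
    o_span = out.max() - out.min()
    if o_span < 1e-12:
        warnings.warn("degenerate saliency solution: returning uniform 0.5 map")
        return np.full(frame.shape, 0.5, dtype=np.float32)
    return ((out - out.min()) / o_span).astype(np.float32)


def load_weight_map(path, shape: tuple[int, int] = (256, 256)) -> np.ndarray:
    """Read a precomputed weight map from an image file.

    8-bit maps are divided by 255; float maps (e.g. 32-bit TIFF) are
    clipped to [0, 1] with a warning if any value falls outside. The map is
    resized bilinearly to ``shape`` when needed.
    """
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim != 2:
        raise ValueError(f"weight map must be single-channel 2-D, got {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        out = arr.astype(np.float32) / float(np.iinfo(arr.dtype).max)
    else:
        if arr.min() < 0.0 or arr.max() > 1.0:
            warnings.warn("float weight map outside [0, 1]; clipping")
        out = np.clip(arr.astype(np.float32), 0.0, 1.0)
    if out.shape != tuple(shape):
        out = resize(out, shape, order=1, anti_aliasing=False,
                     preserve_range=True).astype(np.float32)
        if out.shape != tuple(shape):
            raise ValueError("weight map size mismatch after resize")
    return np.clip(out, 0.0, 1.0)


def build_pyramid(wmap: np.ndarray) -> WeightMapPyramid:
    """Four-level 2x2 max-pool pyramid of a weight map.

    For a 256 grid the level sides are 128, 64, 32, 16. Max pooling (rather
    than averaging) preserves small salient structures: a single bright
    pixel survives into every level.
    """
    wmap = np.asarray(wmap, dtype=np.float32)
    if wmap.ndim != 2 or wmap.shape[0] != wmap.shape[1]:
        raise ValueError("weight map must be square 2-D")
    if wmap.shape[0] % 16 != 0:
        raise ValueError("weight map side must be divisible by 16")
    levels, w = [], wmap
    for _ in range(4):
        w = maxpool2(w)
        levels.append(w)
    return WeightMapPyramid(levels)
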