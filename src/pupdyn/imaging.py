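"""Perisomatic-bouton coverage and axonal-branch segmentation.

Syt2 coverage quantifies the fraction of the CA1 pyramidal-layer image
covered by synaptotagmin-2-positive puncta: max-project the top 6 µm of the
confocal stack, remove background (rolling ball + mean of a user-drawn
background ROI), binarize with Kapur's maximum-entropy threshold, and keep
connected particles with area between 0.4 and 4 µm².

The axon pipeline extracts a skeleton from a summary image of the movie
(equalize, smooth, adaptive threshold, thinning), splits it into
morphological branches at junction pixels, validates branches by the
skewness of their pixel intensities during their largest transient
(uniformly illuminated branches only), and clusters branch activity traces
(1 - Spearman correlation, 2-D embedding, density clustering).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.stats import skew, spearmanr

from skimage import exposure, filters, measure, morphology, restoration


@dataclass
class CoverageResult:
    """Syt2 coverage of the analyzed area, with retained particle areas."""

    coverage_percent: float
    n_particles: int
    particle_areas_um2: np.ndarray
    pixel_size_um: float


@dataclass
class BranchSet:
    """Skeleton, branch pixel paths, activity traces, and cluster labels."""

    skeleton: np.ndarray
    branches: list[np.ndarray]                 # per-branch (n_px, 2) pixel coords
    traces: Optional[np.ndarray] = None        # (n_branches, n_frames)
    valid: Optional[np.ndarray] = None
    clusters: Optional[np.ndarray] = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Kapur maximum-entropy threshold
# ---------------------------------------------------------------------------

def threshold_max_entropy(image: np.ndarray, nbins: int = 256) -> float:
    """Kapur's maximum-entropy threshold on the image histogram.

    Chooses the level maximizing the sum of the Shannon entropies of the
    below- and above-threshold gray-level distributions.
    """
    image = np.asarray(image, dtype=float)
    hist, edges = np.histogram(image.ravel(), bins=nbins)
    p = hist.astype(float) / hist.sum()
    P = np.cumsum(p)
    best_t, best_h = 0, -np.inf
    for t in range(1, nbins):
        p0, p1 = P[t - 1], 1.0 - P[t - 1]
        if p0 <= 0 or p1 <= 0:
            continue
        lo = p[:t][p[:t] > 0] / p0
        hi = p[t:][p[t:] > 0] / p1
        h = -(lo * np.log(lo)).sum() - (hi * np.log(hi)).sum()
        if h > best_h:
            best_h, best_t = h, t
    return float(edges[best_t])


# ---------------------------------------------------------------------------
# Syt2 coverage
# ---------------------------------------------------------------------------

def syt2_coverage(
    stack: np.ndarray,
    pixel_size_um: float,
    background_roi: tuple[slice, slice],
    z_top_um: float = 6.0,
    z_step_um: float = 1.0,
    size_range_um2: tuple[float, float] = (0.4, 4.0),
    rolling_ball_radius_px: int = 25,
) -> CoverageResult:
    """Percentage of the field covered by size-filtered bright particles."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None, :, :]
    n_top = max(1, int(round(z_top_um / z_step_um)))
    projection = stack[: min(n_top, stack.shape[0])].max(axis=0)

    projection = projection - restoration.rolling_ball(projection, radius=rolling_ball_radius_px)
    roi = projection[background_roi]
    if roi.size == 0:
        raise ValueError("background ROI is empty")
    projection = np.clip(projection - roi.mean(), 0, None)

    if projection.max() <= 0:
        return CoverageResult(0.0, 0, np.array([]), pixel_size_um)
    thr = threshold_max_entropy(projection)
    binary = projection > thr

    labels = measure.label(binary, connectivity=2)
    px_area = pixel_size_um**2
    lo, hi = size_range_um2
    areas, retained_px = [], 0
    for region in measure.regionprops(labels):
        area_um2 = region.area * px_area
        if lo <= area_um2 <= hi:
            areas.append(area_um2)
            retained_px += region.area
    coverage = 100.0 * retained_px / projection.size
    return CoverageResult(coverage, len(areas), np.array(areas), pixel_size_um)


# ---------------------------------------------------------------------------
# axon skeletonization
# ---------------------------------------------------------------------------

def _neighbor_counts(skeleton: np.ndarray) -> np.ndarray:
    from scipy.ndimage import convolve

    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    return convolve(skeleton.astype(int), kernel, mode="constant")


def skeletonize_axons(
    movie: np.ndarray,
    smooth_sigma: float = 1.0,
    threshold_block_px: int = 51,
    threshold_offset: float = 0.0,
    min_branch_px: int = 5,
) -> BranchSet:
    """Skeletonize a movie summary and split the skeleton into branches.

    Summary image -> histogram equalization -> Gaussian smoothing ->
    adaptive threshold -> thinning; branches are the connected skeleton
    segments left after removing junction pixels (more than two skeleton
    neighbors).  Branch activity traces are the mean movie intensity along
    the branch per frame.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3 or movie.shape[0] < 10:
        raise ValueError("movie must be t x y x x with at least 10 frames")
    raw = gaussian_filter(movie, (1.0, smooth_sigma, smooth_sigma)).mean(axis=0)
    if raw.max() - raw.min() == 0:
        return BranchSet(np.zeros(raw.shape, dtype=bool), [])
    # contrast guard: a noise-only field splits at Otsu into two halves of
    # similar brightness; real axons stand many background-sigmas out
    otsu = filters.threshold_otsu(raw)
    fg, bg = raw[raw > otsu], raw[raw <= otsu]
    if fg.size == 0 or bg.size == 0 or fg.mean() - bg.mean() < 4.0 * bg.std():
        return BranchSet(np.zeros(raw.shape, dtype=bool), [])
    summary = exposure.equalize_hist(raw)
    summary = gaussian_filter(summary, smooth_sigma)
    block = min(threshold_block_px, summary.shape[0] // 2 * 2 + 1, summary.shape[1] // 2 * 2 + 1)
    local_thr = filters.threshold_local(summary, block_size=block, offset=threshold_offset)
    binary = summary > local_thr
    # adaptive thresholding of a noise-only field marks ~half the pixels;
    # require foreground to also stand out of the raw summary (equalization
    # stretches the background, so the guard uses the pre-equalized image)
    binary &= raw > filters.threshold_otsu(raw)
    skeleton = morphology.skeletonize(binary)
    if not skeleton.any():
        return BranchSet(skeleton, [])

    neighbors = _neighbor_counts(skeleton)
    junctions = skeleton & (neighbors > 2)
    segments = skeleton & ~junctions
    labels = measure.label(segments, connectivity=2)

    # a junction where exactly two segments meet is a thinning staircase
    # artifact, not a branch point: merge the pair across it
    parent = list(range(labels.max() + 1))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    h, w = labels.shape
    for jy, jx in np.argwhere(junctions):
        adjacent = set()
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                y, x = jy + dy, jx + dx
                if 0 <= y < h and 0 <= x < w and labels[y, x] > 0:
                    adjacent.add(find(labels[y, x]))
        if len(adjacent) == 2:
            a, b = adjacent
            parent[b] = a
            labels[jy, jx] = a  # the junction pixel joins the merged branch

    merged: dict[int, list] = {}
    for y, x in np.argwhere(labels > 0):
        merged.setdefault(find(labels[y, x]), []).append((y, x))
    branches = [
        np.array(coords) for coords in merged.values() if len(coords) >= min_branch_px
    ]

    traces = branch_traces(movie, branches) if branches else None
    return BranchSet(skeleton=skeleton, branches=branches, traces=traces)


def branch_traces(movie: np.ndarray, branches: Sequence[np.ndarray]) -> np.ndarray:
    """Mean movie intensity along each branch, per frame."""
    return np.stack([movie[:, b[:, 0], b[:, 1]].mean(axis=1) for b in branches])


def validate_branches(
    movie: np.ndarray,
    branches: Sequence[np.ndarray],
    skew_max: float = 1.0,
    min_branch_px: int = 5,
) -> np.ndarray:
    """Keep branches that illuminate uniformly during their largest transient.

    At the frame of the branch's largest (smoothed) trace excursion, the
    sample skewness of the pixel intensities along the branch must satisfy
    |skewness| <= ``skew_max``; constant-intensity branches have skewness 0
    by convention; branches shorter than ``min_branch_px`` are rejected.
    Pixels within 2 px of the branch tips are excluded: the optical point
    spread dims the tips of even a uniformly lit branch.
    """
    if len(branches) == 0:
        raise ValueError("no branches to validate")
    movie = np.asarray(movie, dtype=float)
    flags = np.zeros(len(branches), dtype=bool)
    for i, b in enumerate(branches):
        if len(b) < min_branch_px:
            continue
        trace = movie[:, b[:, 0], b[:, 1]].mean(axis=1)
        smoothed = gaussian_filter1d(trace, 2.0)
        frame = int(np.argmax(smoothed))
        core = _trim_branch_tips(b)
        pixels = movie[frame, core[:, 0], core[:, 1]]
        if np.allclose(pixels, pixels[0]):
            flags[i] = True
            continue
        flags[i] = abs(float(skew(pixels))) <= skew_max
    return flags


def _trim_branch_tips(coords: np.ndarray, margin: int = 2) -> np.ndarray:
    """Drop pixels within Chebyshev distance ``margin`` of a branch tip."""
    pts = {tuple(p) for p in coords}
    tips = []
    for y, x in coords:
        n = sum(
            (y + dy, x + dx) in pts
            for dy in (-1, 0, 1) for dx in (-1, 0, 1)
            if (dy, dx) != (0, 0)
        )
        if n <= 1:
            tips.append((y, x))
    if not tips:
        return coords
    keep = np.array([
        all(max(abs(y - ty), abs(x - tx)) > margin for ty, tx in tips)
        for y, x in coords
    ])
    return coords[keep] if keep.sum() >= 5 else coords


def cluster_branches(
    traces: np.ndarray,
    min_cluster_size: int = 2,
    seed: int = 0,
    perplexity: Optional[float] = None,
) -> np.ndarray:
    """Group branches with correlated activity; singletons get unique labels.

    Pairwise distance is 1 - Spearman correlation of the traces; branches
    are embedded in 2-D (t-SNE) and density-clustered (HDBSCAN).  Branches
    left unassigned by the density clustering are labelled as singleton
    clusters (consecutive negative labels).
    """
    from sklearn.cluster import HDBSCAN
    from sklearn.manifold import TSNE

    traces = np.asarray(traces, dtype=float)
    n = traces.shape[0]
    if n < 2:
        raise ValueError("need at least 2 branch traces")
    constant = np.array([np.allclose(t, t[0]) for t in traces])
    if constant.all():
        return -1 - np.arange(n)  # all singletons

    stat = spearmanr(traces, axis=1).statistic
    if np.ndim(stat) == 0:  # scipy returns a scalar for exactly two rows
        rho = np.array([[1.0, float(stat)], [float(stat), 1.0]])
    else:
        rho = np.asarray(stat)
    rho = np.nan_to_num(rho, nan=0.0)
    dist = np.clip(1.0 - rho, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)

    if dist.max() < 0.2:
        # all traces (near-)identical: a zero-distance matrix gives the
        # embedding no structure, so short-circuit to one cluster
        return np.zeros(n, dtype=int)
    if n <= 4:
        # too few points for an embedding: single-linkage on the distances
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        merged = fcluster(linkage(squareform(dist, checks=False), "single"),
                          t=0.5, criterion="distance")
        labels = merged - 1
        counts = np.bincount(labels)
        labels = np.where(counts[labels] >= min_cluster_size, labels, -1)
    else:
        if perplexity is None:
            perplexity = float(np.clip((n - 1) / 3.0, 2.0, 30.0))
        perplexity = min(perplexity, n - 1.0)
        embedding = TSNE(
            n_components=2,
            metric="precomputed",
            init="random",
            perplexity=perplexity,
            random_state=seed,
        ).fit_transform(dist)
        labels = HDBSCAN(min_cluster_size=max(2, min_cluster_size), copy=True).fit_predict(embedding)

    labels = labels.astype(int)
    next_singleton = -1
    for i in range(n):
        if labels[i] == -1 or constant[i]:
            labels[i] = next_singleton
            next_singleton -= 1
    return labels
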