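"""Histogram-based validation of phantom realism.

Three evaluation measures summarize a labeled lung as probability density
functions: the HU distribution inside the lung, the dispersion of internal
structures (Euclidean distances from parenchymal voxels to the nearest
vessel/airway), and the artery–airway relationship (distances from arterial
voxels to the nearest airway).  Pairs of PDFs are compared with the
histogram match distance (L1 between CDFs — the 1-D earth mover's distance)
and the Kolmogorov–Smirnov distance, and intra-class (real vs real) against
inter-class (real vs phantom) distance populations are tested with the
Wilcoxon rank-sum test, Cohen's d and the AUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import ndimage, stats

from .grid import PreconditionError, VoxelGrid
from .raster import LABEL_AIRWAY, LABEL_ARTERY, LABEL_VEIN

#: default binning: 64 bins over [-1024, 100] HU for intensities,
#: 64 bins over [0, 30] mm for distances
INTENSITY_RANGE = (-1024.0, 100.0)
DISTANCE_RANGE = (0.0, 30.0)
DEFAULT_BINS = 64


@dataclass
class HistogramPDF:
    """Normalized binned density on uniform-width bins."""

    edges: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.edges.ndim != 1 or np.any(np.diff(self.edges) <= 0):
            raise PreconditionError("bin edges must be strictly increasing")
        if self.density.size != self.edges.size - 1:
            raise PreconditionError("density/edge size mismatch")
        total = self.density.sum()
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise PreconditionError(f"densities must sum to 1, got {total}")

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def cdf(self) -> np.ndarray:
        return np.cumsum(self.density)

    @classmethod
    def from_samples(cls, samples: np.ndarray, bins: int, value_range) -> "HistogramPDF":
        samples = np.asarray(samples, dtype=float)
        if samples.size == 0:
            raise PreconditionError("no samples to histogram")
        counts, edges = np.histogram(
            np.clip(samples, value_range[0], value_range[1]), bins=bins, range=value_range
        )
        return cls(edges=edges, density=counts / counts.sum())


def _check_binning(p: HistogramPDF, q: HistogramPDF) -> None:
    if p.edges.shape != q.edges.shape or not np.allclose(p.edges, q.edges):
        raise PreconditionError("histograms use different binnings")


def intensity_pdf(
    ct: VoxelGrid, lung_mask: VoxelGrid, bins: int = DEFAULT_BINS, value_range=INTENSITY_RANGE
) -> HistogramPDF:
    """PDF of HU values at in-lung voxels."""
    mask = np.asarray(lung_mask.values) > 0
    if not mask.any():
        raise PreconditionError("empty lung mask")
    return HistogramPDF.from_samples(np.asarray(ct.values)[mask], bins, value_range)


def dispersion_pdf(
    labels: VoxelGrid, lung_mask: VoxelGrid, bins: int = DEFAULT_BINS, value_range=DISTANCE_RANGE
) -> HistogramPDF:
    """PDF of Euclidean distances (mm) from parenchymal voxels to the
    nearest vessel or airway voxel — the size of the 'holes' between
    internal structures."""
    lab = np.asarray(labels.values)
    lung = np.asarray(lung_mask.values) > 0
    structures = lab > 0
    paren = lung & ~structures
    if not structures.any() or not paren.any():
        raise PreconditionError("need at least one structure and one parenchymal voxel")
    d = ndimage.distance_transform_edt(~structures, sampling=labels.spacing)
    return HistogramPDF.from_samples(d[paren], bins, value_range)


def artery_airway_pdf(
    labels: VoxelGrid, bins: int = DEFAULT_BINS, value_range=DISTANCE_RANGE
) -> HistogramPDF:
    """PDF of distances (mm) from each arterial voxel to the nearest airway."""
    lab = np.asarray(labels.values)
    art = lab == LABEL_ARTERY
    air = lab == LABEL_AIRWAY
    if not art.any() or not air.any():
        raise PreconditionError("need nonempty artery and airway labels")
    d = ndimage.distance_transform_edt(~air, sampling=labels.spacing)
    return HistogramPDF.from_samples(d[art], bins, value_range)


def match_distance(p: HistogramPDF, q: HistogramPDF) -> float:
    """Histogram match distance: sum |CDF_p - CDF_q| x bin width (1-D EMD)."""
    _check_binning(p, q)
    return float(np.abs(p.cdf - q.cdf).sum() * p.bin_width)


def ks_distance(p: HistogramPDF, q: HistogramPDF) -> float:
    """Kolmogorov–Smirnov distance: max |CDF_p - CDF_q|, in [0, 1]."""
    _check_binning(p, q)
    return float(np.abs(p.cdf - q.cdf).max())


# ---------------------------------------------------------------------------
# population comparison
# ---------------------------------------------------------------------------


@dataclass
class ComparisonStats:
    p_value: float
    cohen_d: float
    auc: float
    intra_mean: float
    intra_sd: float
    inter_mean: float
    inter_sd: float


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p-value of the rank-sum statistic.

    Enumerates all assignments of the pooled midranks to the first sample;
    extremeness is measured by |T - E[T]| to make the test two-sided under
    ties.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    t_obs = ranks[:n1].sum()
    mu = n1 * ranks.sum() / len(pooled)
    extreme = 0
    total = 0
    for idx in combinations(range(len(pooled)), n1):
        t = ranks[list(idx)].sum()
        if abs(t - mu) >= abs(t_obs - mu) - 1e-12:
            extreme += 1
        total += 1
    return extreme / total


def _normal_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p via normal approximation with tie correction."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks = stats.rankdata(np.concatenate([x, y]))
    t_obs = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 1.0
    z = (t_obs - mu) / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def compare_populations(intra, inter) -> ComparisonStats:
    """Rank-sum p, Cohen's d (intra minus inter) and AUC (intra positive).

    Uses exact permutation enumeration when both samples have size <= 8,
    otherwise the tie-corrected normal approximation.  Two identical
    zero-variance samples yield the degenerate d = 0, AUC = 0.5, p = 1.
    """
    x = np.asarray(intra, dtype=float)
    y = np.asarray(inter, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise PreconditionError("both samples need size >= 2")

    s1 = x.std(ddof=1)
    s2 = y.std(ddof=1)
    pooled = math.sqrt(((len(x) - 1) * s1**2 + (len(y) - 1) * s2**2) / (len(x) + len(y) - 2))
    if pooled == 0 and np.array_equal(np.sort(x), np.sort(y)):
        return ComparisonStats(1.0, 0.0, 0.5, x.mean(), 0.0, y.mean(), 0.0)
    d = (x.mean() - y.mean()) / pooled if pooled > 0 else 0.0

    # AUC from the Mann-Whitney U statistic, ties counting one half
    greater = (x[:, None] > y[None, :]).sum()
    equal = (x[:, None] == y[None, :]).sum()
    auc = (greater + 0.5 * equal) / (len(x) * len(y))

    if len(x) <= 8 and len(y) <= 8:
        p = _exact_ranksum_p(x, y)
    else:
        p = _normal_ranksum_p(x, y)
    return ComparisonStats(
        p_value=float(p),
        cohen_d=float(d),
        auc=float(auc),
        intra_mean=float(x.mean()),
        intra_sd=float(s1),
        inter_mean=float(y.mean()),
        inter_sd=float(s2),
    )


def pairwise_distance_populations(real_pdfs, phantom_pdfs, metric) -> tuple[list, list]:
    """Intra-class (real vs real) and inter-class (real vs phantom)
    distances: R(R-1)/2 intra values and R*M inter values."""
    intra = [metric(p, q) for p, q in combinations(real_pdfs, 2)]
    inter = [metric(p, q) for p in real_pdfs for q in phantom_pdfs]
    return intra, inter
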