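"""CT realism post-processing for rasterized phantom structures.

Covers the second stage of phantom generation: hollowing airway lumens from
per-generation wall-thickness ratios, mapping occupancy to Hounsfield units,
bending the straight tubes with a diffeomorphic B-spline displacement field
anchored at tree nodes, filling lung parenchyma with textured noise, and
embedding the finished lung into a host CT.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

from .grid import InvalidConfigurationError, PreconditionError, VoxelGrid
from .raster import _block_mean, _supersample_occupancy
from .tree_growth import Tree


@dataclass
class WallThicknessTable:
    """Per-generation wall-thickness-to-outer-diameter ratios WT/D.

    The deepest listed generation is reused beyond the table end.  The
    default 0.20 corresponds to a luminal-diameter-to-wall-thickness ratio
    LD/WT = 3 (WT/D = 1/(3 + 2)).
    """

    ratios: tuple[float, ...] = (0.20,)

    def __post_init__(self) -> None:
        if not self.ratios or any(not (0.0 < r <= 0.5) for r in self.ratios):
            raise InvalidConfigurationError("WT/D ratios must lie in (0, 0.5]")

    def ratio(self, generation: int) -> float:
        return self.ratios[min(generation, len(self.ratios) - 1)]


@dataclass
class IntensityModel:
    """Per-compartment HU statistics and the segment-mode vessel window."""

    mu_art: float = 40.0
    sigma_art: float = 3.0
    mu_vein: float = 40.0
    sigma_vein: float = 3.0
    mu_air: float = 40.0
    sigma_air: float = 3.0
    mu_lung: float = -800.0
    sigma_lung: float = 150.0
    vessel_window: tuple[float, float] = (35.0, 45.0)

    def compartment(self, name: str) -> tuple[float, float]:
        key = {"artery": "art", "vein": "vein", "airway": "air", "lung": "lung"}[name]
        return getattr(self, f"mu_{key}"), getattr(self, f"sigma_{key}")


@dataclass
class NoiseParams:
    """Parenchyma texture and scanner noise parameters (HU, mm)."""

    parenchyma_mean_abs: float = 800.0
    parenchyma_sd: float = 150.0
    blur_sigma: float = 1.5
    gauss_sd: float = 20.0
    sp_density: float = 0.001
    sp_values: tuple[float, float] = (-1000.0, 100.0)  # pepper, salt
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.parenchyma_mean_abs, self.parenchyma_sd, self.blur_sigma, self.gauss_sd) < 0:
            raise InvalidConfigurationError("noise parameters must be nonnegative")
        if not (0.0 <= self.sp_density < 0.05):
            raise InvalidConfigurationError("sp_density must be in [0, 0.05)")


@dataclass
class DeformationParams:
    """Bending of the straight tubular segments.

    deform_dmax is the midpoint displacement bound in voxels; control_spacing
    is the B-spline control-grid spacing in mm.
    """

    deform_dmax: float = 3.0
    control_spacing: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.deform_dmax < 0:
            raise InvalidConfigurationError("deform_dmax must be >= 0")
        if self.control_spacing <= 0:
            raise InvalidConfigurationError("control_spacing must be > 0")


# ---------------------------------------------------------------------------
# airway hollowing
# ---------------------------------------------------------------------------


def hollow_airways(
    air_gray: VoxelGrid,
    tree: Tree,
    wt: WallThicknessTable | None = None,
    supersampling: int = 3,
) -> VoxelGrid:
    """Subtract the lumen from an opaque rasterized airway tree.

    Each segment of outer radius ``r`` and generation ``g`` keeps a wall of
    thickness ``WT = 2 r * (WT/D)(g)``; the lumen capsule of radius
    ``r - WT`` is removed with the same supersampled partial-volume scheme
    used by rasterization, so both lumen and outer boundaries stay
    fractional.  Ratios of 0.5 leave the segment opaque.
    """
    wt = wt or WallThicknessTable()
    lumen_segments = []
    for seg in tree.segment_ids:
        r = tree.radius[seg]
        lumen_r = r * (1.0 - 2.0 * wt.ratio(tree.generation(seg)))
        if lumen_r > 0:
            a, b = tree.segment_endpoints(seg)
            lumen_segments.append((a, b, lumen_r))
    if not lumen_segments:
        return air_gray.copy()
    occ = _supersample_occupancy(lumen_segments, air_gray, supersampling)
    lumen_frac = _block_mean(occ.astype(np.float64), supersampling)
    out = np.clip(np.asarray(air_gray.values) - lumen_frac, 0.0, 1.0)
    return air_gray.like(out)


# ---------------------------------------------------------------------------
# intensity mapping
# ---------------------------------------------------------------------------


def map_intensities(
    gray: VoxelGrid,
    mode: str,
    model: IntensityModel,
    compartment: str = "artery",
    rng: np.random.Generator | None = None,
) -> VoxelGrid:
    """Convert an occupancy gray volume to Hounsfield units.

    ``segment`` mode applies the affine map sending the minimum positive
    gray to the lower window bound and the maximum to the upper one
    (default 35–45 HU); values are stored only at structure voxels.
    ``anthro`` mode draws each structure voxel from the compartment's
    Normal(mu, sigma); partial-volume scaling happens at composition time
    through the occupancy weights.
    """
    g = np.asarray(gray.values, dtype=float)
    pos = g > 0
    out = np.zeros_like(g)
    if not pos.any():
        return gray.like(out)
    if mode == "segment":
        lo, hi = model.vessel_window
        gmin, gmax = g[pos].min(), g[pos].max()
        if gmax > gmin:
            out[pos] = lo + (g[pos] - gmin) / (gmax - gmin) * (hi - lo)
        else:
            out[pos] = hi
    elif mode == "anthro":
        if rng is None:
            raise PreconditionError("anthro intensity mapping needs an rng")
        mu, sd = model.compartment(compartment)
        out[pos] = rng.normal(mu, sd, size=int(pos.sum())) if sd > 0 else mu
    else:
        raise PreconditionError(f"unknown intensity mode {mode!r}")
    return gray.like(out)


# ---------------------------------------------------------------------------
# diffeomorphic B-spline deformation
# ---------------------------------------------------------------------------


def _bspline3(x: np.ndarray) -> np.ndarray:
    ax = np.abs(x)
    out = np.zeros_like(ax)
    m1 = ax < 1
    m2 = (ax >= 1) & (ax < 2)
    out[m1] = (4.0 - 6.0 * ax[m1] ** 2 + 3.0 * ax[m1] ** 3) / 6.0
    out[m2] = (2.0 - ax[m2]) ** 3 / 6.0
    return out


@dataclass
class BSplineField:
    """Cubic B-spline displacement field u(x) over world coordinates (mm).

    ``coeffs`` has shape (3, nx, ny, nz): control-point coefficients of the
    three displacement components on a lattice of spacing ``cs`` starting at
    ``lattice_origin``.
    """

    coeffs: np.ndarray
    lattice_origin: np.ndarray
    cs: float

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Displacements (mm) at an (n, 3) array of world points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        c = (pts - self.lattice_origin[None, :]) / self.cs
        out = np.empty_like(pts)
        for comp in range(3):
            out[:, comp] = ndimage.map_coordinates(
                self.coeffs[comp], c.T, order=3, prefilter=False, mode="constant", cval=0.0
            )
        return out

    def dense(self, grid: VoxelGrid) -> np.ndarray:
        """Field sampled at every voxel center: shape (3, *grid.shape)."""
        axes = grid.voxel_centers()
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=1)
        u = self.evaluate(pts)
        return u.T.reshape((3, *grid.shape))

    def scale(self, factor: float) -> None:
        self.coeffs *= factor


def _fit_bspline_field(
    anchors: np.ndarray,
    displacements: np.ndarray,
    weights: np.ndarray,
    bounds_lo: np.ndarray,
    bounds_hi: np.ndarray,
    cs: float,
    ridge: float = 1e-3,
) -> BSplineField:
    """Weighted ridge least-squares fit of control coefficients to scattered
    anchor displacements."""
    lattice_origin = bounds_lo - 2.0 * cs
    n_ctrl = np.ceil((bounds_hi - lattice_origin) / cs).astype(int) + 3
    c = (anchors - lattice_origin[None, :]) / cs
    base = np.floor(c).astype(int) - 1
    n = anchors.shape[0]

    rows, cols, vals = [], [], []
    offsets = np.arange(4)
    for i in range(n):
        wx = _bspline3(c[i, 0] - (base[i, 0] + offsets))
        wy = _bspline3(c[i, 1] - (base[i, 1] + offsets))
        wz = _bspline3(c[i, 2] - (base[i, 2] + offsets))
        w3 = wx[:, None, None] * wy[None, :, None] * wz[None, None, :]
        ix = (base[i, 0] + offsets)[:, None, None] * (n_ctrl[1] * n_ctrl[2])
        iy = (base[i, 1] + offsets)[None, :, None] * n_ctrl[2]
        iz = (base[i, 2] + offsets)[None, None, :]
        flat = (ix + iy + iz).ravel()
        rows.extend([i] * 64)
        cols.extend(flat.tolist())
        vals.extend(w3.ravel().tolist())
    a_mat = sparse.coo_matrix(
        (vals, (rows, cols)), shape=(n, int(np.prod(n_ctrl)))
    ).tocsr()
    w_mat = sparse.diags(weights)
    normal = (a_mat.T @ w_mat @ a_mat + ridge * sparse.eye(a_mat.shape[1])).tocsc()
    rhs = a_mat.T @ (weights[:, None] * displacements)
    coeffs_flat = spsolve(normal, rhs)
    coeffs = np.ascontiguousarray(
        coeffs_flat.reshape((*n_ctrl, 3)).transpose(3, 0, 1, 2)
    )
    return BSplineField(coeffs=coeffs, lattice_origin=lattice_origin, cs=cs)


def build_deformation_field(
    trees: dict[str, Tree], grid: VoxelGrid, params: DeformationParams
) -> BSplineField:
    """Displacement field with zero anchors at every tree node and random
    anchors (magnitude <= deform_dmax voxels) at every segment midpoint.

    Control-point displacements are capped at 0.4 x control spacing — a
    sufficient condition for a cubic B-spline field to remain diffeomorphic
    — and the whole field is rescaled if node anchors would move by 0.4
    voxel or more.
    """
    rng = np.random.default_rng(params.seed)
    vox = float(min(grid.spacing))
    dmax_mm = params.deform_dmax * vox

    anchors, disps, weights = [], [], []
    for name in sorted(trees):
        tree = trees[name]
        for nid in tree.node_ids:
            anchors.append(tree.positions[nid])
            disps.append(np.zeros(3))
            weights.append(10.0)
        for seg in tree.segment_ids:
            a, b = tree.segment_endpoints(seg)
            direction = rng.normal(size=3)
            direction /= max(np.linalg.norm(direction), 1e-12)
            magnitude = rng.uniform(0.0, dmax_mm)
            anchors.append(0.5 * (a + b))
            disps.append(magnitude * direction)
            weights.append(1.0)
    anchors_arr = np.asarray(anchors)
    disps_arr = np.asarray(disps)

    lo = np.asarray(grid.origin, dtype=float)
    hi = lo + (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing)
    field = _fit_bspline_field(
        anchors_arr, disps_arr, np.asarray(weights), lo, hi, params.control_spacing
    )

    cap = 0.4 * params.control_spacing
    cmax = float(np.linalg.norm(field.coeffs, axis=0).max())
    if cmax > cap:
        warnings.warn(
            "conflicting anchor displacements; field scaled down for invertibility",
            stacklevel=2,
        )
        field.scale(cap / cmax)

    node_pts = np.array(
        [t.positions[n] for t in trees.values() for n in t.node_ids]
    )
    node_disp = np.linalg.norm(field.evaluate(node_pts), axis=1).max() / vox
    if node_disp >= 0.4:
        field.scale(0.35 / node_disp)
    return field


def _warp_volume(vol: VoxelGrid, field: BSplineField, order: int) -> VoxelGrid:
    u = field.dense(vol)
    idx = np.meshgrid(*[np.arange(n, dtype=float) for n in vol.shape], indexing="ij")
    coords = [idx[a] + u[a] / vol.spacing[a] for a in range(3)]
    vals = np.asarray(vol.values)
    out = ndimage.map_coordinates(
        vals.astype(float), coords, order=order, mode="constant", cval=0.0
    )
    if vals.dtype.kind in "iu":
        out = np.rint(out).astype(vals.dtype)
    return vol.like(out)


def _warp_tree(tree: Tree, field: BSplineField, n_iter: int = 10) -> Tree:
    """Push tree points through the inverse of the resampling map.

    Images are pulled back by x -> x + u(x), so material points move by the
    inverse map; it is computed by the standard fixed-point iteration
    p' = p - u(p'), which converges because the field is contractive.
    """
    out = tree.copy()
    ids = out.node_ids
    p = np.array([out.positions[n] for n in ids])
    q = p.copy()
    for _ in range(n_iter):
        q = p - field.evaluate(q)
    for i, nid in enumerate(ids):
        out.positions[nid] = q[i]
    return out


def deform_structures(
    volumes: dict[str, VoxelGrid],
    trees: dict[str, Tree],
    params: DeformationParams,
    label_keys: tuple[str, ...] = ("labels",),
) -> tuple[dict[str, VoxelGrid], dict[str, Tree], BSplineField | None]:
    """Apply one shared diffeomorphic bending to all volumes and trees.

    Volumes named in ``label_keys`` are resampled with nearest-neighbor
    interpolation, all others trilinearly.  ``deform_dmax = 0`` returns the
    inputs unchanged (identity transform).
    """
    if params.deform_dmax == 0:
        return (
            {k: v.copy() for k, v in volumes.items()},
            {k: t.copy() for k, t in trees.items()},
            None,
        )
    ref = next(iter(volumes.values()))
    field = build_deformation_field(trees, ref, params)
    out_vols = {
        k: _warp_volume(v, field, order=0 if k in label_keys else 1)
        for k, v in volumes.items()
    }
    out_trees = {k: _warp_tree(t, field) for k, t in trees.items()}
    return out_vols, out_trees, field


def jacobian_determinants(field: BSplineField, grid: VoxelGrid, step: int = 2) -> np.ndarray:
    """Determinant of the Jacobian of x -> x + u(x) on a coarse lattice,
    via central finite differences with the given voxel step."""
    axes = [
        grid.origin[a] + np.arange(0, grid.shape[a], step) * grid.spacing[a]
        for a in range(3)
    ]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    h = np.asarray(grid.spacing)
    jac = np.empty((pts.shape[0], 3, 3))
    for a in range(3):
        dp = np.zeros(3)
        dp[a] = h[a]
        up = field.evaluate(pts + dp)
        um = field.evaluate(pts - dp)
        jac[:, :, a] = (up - um) / (2.0 * h[a])
        jac[:, a, a] += 1.0
    return np.linalg.det(jac)


# ---------------------------------------------------------------------------
# parenchyma, noise, embedding
# ---------------------------------------------------------------------------


@dataclass
class PhantomComposite:
    """Stages of the final CT assembly (all on the shared grid)."""

    pre_blur: VoxelGrid
    pre_noise: VoxelGrid
    final: VoxelGrid
    background_mask: np.ndarray
    sp_mask: np.ndarray


def compose_phantom(
    structures_hu: dict[str, VoxelGrid],
    occupancy: dict[str, VoxelGrid],
    lung_mask: VoxelGrid,
    noise: NoiseParams,
    outside_value: float = -1000.0,
) -> PhantomComposite:
    """Blend structure HU over textured parenchyma and add scanner noise.

    Parenchymal background voxels (inside the lung, zero structure
    occupancy) draw i.i.d. Normal(-parenchyma_mean_abs, parenchyma_sd); the
    composite is the occupancy-weighted blend of structure HU over the
    background, blurred with a Gaussian reconstruction kernel, then
    corrupted by additive Gaussian white noise and salt-and-pepper
    replacement.  Fully reproducible from ``noise.seed``.
    """
    rng = np.random.default_rng(noise.seed)
    ref = lung_mask
    lung = np.asarray(lung_mask.values) > 0
    tot = np.zeros(ref.shape, dtype=float)
    blend = np.zeros(ref.shape, dtype=float)
    for name, occ in occupancy.items():
        o = np.clip(np.asarray(occ.values, dtype=float), 0.0, 1.0)
        tot += o
        blend += o * np.asarray(structures_hu[name].values, dtype=float)
    np.clip(tot, 0.0, 1.0, out=tot)

    bg_mask = lung & (tot == 0)
    bg = rng.normal(-noise.parenchyma_mean_abs, noise.parenchyma_sd, size=ref.shape)
    composite = np.where(lung, bg * (1.0 - tot) + blend, outside_value)

    sigma_vox = [noise.blur_sigma / s for s in ref.spacing]
    pre_noise = ndimage.gaussian_filter(composite, sigma=sigma_vox)

    final = pre_noise
    if noise.gauss_sd > 0:
        final = final + rng.normal(0.0, noise.gauss_sd, size=ref.shape)
    sp_mask = np.zeros(ref.shape, dtype=bool)
    if noise.sp_density > 0:
        sp_mask = rng.random(ref.shape) < noise.sp_density
        pepper = rng.random(ref.shape) < 0.5
        final = np.where(sp_mask, np.where(pepper, noise.sp_values[0], noise.sp_values[1]), final)
    return PhantomComposite(
        pre_blur=ref.like(composite),
        pre_noise=ref.like(pre_noise),
        final=ref.like(final),
        background_mask=bg_mask,
        sp_mask=sp_mask,
    )


def embed_phantom(host_ct: VoxelGrid, lung_mask: VoxelGrid, phantom: VoxelGrid) -> VoxelGrid:
    """Substitute the host CT's lung region with the phantom, exactly."""
    if host_ct.shape != lung_mask.shape or host_ct.shape != phantom.shape:
        raise PreconditionError("host, mask and phantom shapes differ")
    if host_ct.spacing != phantom.spacing:
        raise PreconditionError("host and phantom spacing differ")
    mask = np.asarray(lung_mask.values) > 0
    out = np.where(mask, np.asarray(phantom.values), np.asarray(host_ct.values))
    return host_ct.like(out)
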