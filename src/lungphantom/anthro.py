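"""Feature extraction from labeled CT cases and growth-parameter adaptation.

An anthropomorphic phantom emulates a specific labeled case: lung geometry,
per-compartment intensity statistics, tree complexity (terminal counts read
off structure skeletons), and root locations (thickest skeleton endpoint).
These features parameterize the growth and intensity models so that phantoms
generated from the case fit its distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import convex_hull_image, skeletonize

from .grid import LungPhantomError, PreconditionError, VoxelGrid
from .realism import IntensityModel
from .tree_growth import GrowthParams, airway_terminal_count

STRUCTURES = ("artery", "vein", "airway")


class FeatureExtractionError(LungPhantomError):
    pass


class RootDetectionError(LungPhantomError):
    pass


@dataclass
class RealCaseFeatures:
    """Statistics extracted from one labeled lung case."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    lung_mask: VoxelGrid
    intensity: dict[str, tuple[float, float]]  # structure -> (mu, sigma)
    n_terminals: dict[str, int]
    roots: dict[str, np.ndarray]  # structure -> world position (mm)
    artery_centerline: VoxelGrid
    airway_hull: VoxelGrid

    def to_report(self) -> dict:
        """Key-value summary suitable for a JSON report."""
        return {
            "shape": list(self.shape),
            "spacing": list(self.spacing),
            "intensity": {k: list(map(float, v)) for k, v in self.intensity.items()},
            "n_terminals": {k: int(v) for k, v in self.n_terminals.items()},
            "roots": {k: [float(x) for x in v] for k, v in self.roots.items()},
        }


_NEIGHBOR_KERNEL = np.ones((3, 3, 3), dtype=int)
_NEIGHBOR_KERNEL[1, 1, 1] = 0


def count_skeleton_terminals(skeleton: VoxelGrid | np.ndarray) -> int:
    """Count skeleton voxels with exactly one 26-neighbor in the skeleton.

    Isolated voxels (zero neighbors) are not terminals by this rule.
    """
    sk = np.asarray(skeleton.values if isinstance(skeleton, VoxelGrid) else skeleton) > 0
    if not sk.any():
        return 0
    counts = ndimage.convolve(sk.astype(int), _NEIGHBOR_KERNEL, mode="constant", cval=0)
    return int(np.sum(sk & (counts == 1)))


def _skeleton_terminal_indices(sk: np.ndarray) -> np.ndarray:
    counts = ndimage.convolve(sk.astype(int), _NEIGHBOR_KERNEL, mode="constant", cval=0)
    return np.argwhere(sk & (counts == 1))


def locate_root(mask: VoxelGrid, skeleton: VoxelGrid | np.ndarray) -> np.ndarray:
    """Root location: the skeleton endpoint on the branch of largest caliber.

    Caliber is measured by sphere inflation — the maximal inscribed sphere
    radius, i.e. the Euclidean distance transform of the structure mask —
    maximized over each endpoint's 5-voxel skeleton neighborhood.  Ties
    break by lexicographic voxel order.  Returns a world position (mm).
    """
    sk = np.asarray(skeleton.values if isinstance(skeleton, VoxelGrid) else skeleton) > 0
    if not sk.any():
        raise RootDetectionError("empty skeleton")
    terminals = _skeleton_terminal_indices(sk)
    if terminals.size == 0:
        raise RootDetectionError("skeleton has no terminal voxels")
    edt = ndimage.distance_transform_edt(np.asarray(mask.values) > 0, sampling=mask.spacing)
    sk_idx = np.argwhere(sk)
    best: tuple[float, tuple] | None = None
    for t in terminals:
        cheb = np.abs(sk_idx - t[None, :]).max(axis=1)
        neigh = sk_idx[cheb <= 2]  # 5x5x5 skeleton neighborhood of the endpoint
        caliber = float(edt[neigh[:, 0], neigh[:, 1], neigh[:, 2]].max())
        key = (-caliber, tuple(int(x) for x in t))
        if best is None or key < best:
            best = key
    root_voxel = np.asarray(best[1])
    return mask.index_to_world(root_voxel)


def _stats(values: np.ndarray) -> tuple[float, float]:
    return float(values.mean()), float(values.std(ddof=1)) if values.size > 1 else 0.0


def extract_case_features(
    ct: VoxelGrid,
    lung: VoxelGrid,
    artery: VoxelGrid,
    vein: VoxelGrid,
    airway: VoxelGrid,
    parenchyma_guard_mm: float = 3.0,
) -> RealCaseFeatures:
    """Extract the full feature bundle from a labeled CT case.

    Parenchymal statistics are estimated on the lung interior only: voxels
    within ``parenchyma_guard_mm`` of the pleura or of any segmented
    structure are excluded, because partial volume and the reconstruction
    kernel bleed structure and chest-wall intensities into that guard zone
    and would bias the mean upward.
    """
    masks = {"artery": artery, "vein": vein, "airway": airway}
    ct_vals = np.asarray(ct.values)
    lung_mask = np.asarray(lung.values) > 0
    if not lung_mask.any():
        raise FeatureExtractionError("empty lung mask")

    intensity: dict[str, tuple[float, float]] = {}
    n_terminals: dict[str, int] = {}
    roots: dict[str, np.ndarray] = {}
    skeletons: dict[str, np.ndarray] = {}
    for name, grid in masks.items():
        m = np.asarray(grid.values) > 0
        if not m.any():
            raise FeatureExtractionError(f"empty {name} mask")
        intensity[name] = _stats(ct_vals[m])
        sk = skeletonize(m)
        skeletons[name] = sk
        n_terminals[name] = count_skeleton_terminals(sk)
        roots[name] = locate_root(grid, sk)

    struct_any = np.zeros(lung_mask.shape, dtype=bool)
    for grid in masks.values():
        struct_any |= np.asarray(grid.values) > 0
    guard = [max(1, int(round(parenchyma_guard_mm / s))) for s in ct.spacing]
    interior = ndimage.binary_erosion(lung_mask, iterations=max(guard))
    near_struct = ndimage.binary_dilation(struct_any, iterations=max(guard))
    paren = interior & ~near_struct
    if not paren.any():  # degenerate tiny lungs: fall back to plain parenchyma
        paren = lung_mask & ~struct_any
    intensity["lung"] = _stats(ct_vals[paren])

    return RealCaseFeatures(
        shape=ct.shape,
        spacing=ct.spacing,
        origin=ct.origin,
        lung_mask=lung,
        intensity=intensity,
        n_terminals=n_terminals,
        roots=roots,
        artery_centerline=artery.like(skeletons["artery"].astype(np.uint8)),
        airway_hull=airway.like(convex_hull_image(np.asarray(airway.values) > 0).astype(np.uint8)),
    )


def select_perfusion_point(
    map_: VoxelGrid, root: np.ndarray, radius_mm: float = 10.0
) -> np.ndarray:
    """Perfusion point: demand argmax restricted to a ball around the root.

    Falls back to the root itself when no positive demand lies in the ball.
    """
    vals = np.asarray(map_.values)
    lo = np.floor(map_.world_to_index(np.asarray(root) - radius_mm)).astype(int)
    hi = np.ceil(map_.world_to_index(np.asarray(root) + radius_mm)).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.asarray(map_.shape))
    if np.any(lo >= hi):
        return np.asarray(root, dtype=float)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    sub = vals[sl]
    grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij", sparse=True)
    d2 = sum(
        ((g * s + o) - r) ** 2
        for g, s, o, r in zip(grids, map_.spacing, map_.origin, np.asarray(root, float))
    )
    in_ball = d2 <= radius_mm**2
    if not (in_ball & (sub > 0)).any():
        return np.asarray(root, dtype=float)
    masked = np.where(in_ball, sub, -np.inf)
    idx_local = np.unravel_index(int(np.argmax(masked)), sub.shape)
    idx = np.asarray(idx_local) + lo
    return map_.index_to_world(idx)


def adapt_growth_params(
    features: RealCaseFeatures,
    overrides: dict | None = None,
    maps: dict[str, VoxelGrid] | None = None,
    base: GrowthParams | None = None,
) -> tuple[dict[str, GrowthParams], IntensityModel]:
    """Per-structure growth parameters and intensity model for a case.

    Terminal counts come from the extracted skeletons; an ``FA`` override
    caps the airway count by the airway-reduction rule.  Perfusion points
    are the demand argmax near the extracted roots where a map is already
    available (the maps for airways and veins depend on previously grown
    structures and are refined later in the pipeline).
    """
    overrides = overrides or {}
    maps = maps or {}
    base = base or GrowthParams()
    out: dict[str, GrowthParams] = {}
    from dataclasses import replace

    n_art = features.n_terminals["artery"]
    n_air = features.n_terminals["airway"]
    if "fa" in overrides and overrides["fa"] is not None:
        n_air = min(n_air, airway_terminal_count(n_art, int(overrides["fa"])))
    counts = {"artery": n_art, "vein": features.n_terminals["vein"], "airway": n_air}
    seeds = overrides.get("seeds", {})
    for name in STRUCTURES:
        p0 = features.roots[name]
        if name in maps:
            p0 = select_perfusion_point(maps[name], p0)
        out[name] = replace(
            base,
            n_terminals=max(1, counts[name]),
            p0=tuple(float(x) for x in p0),
            seed=int(seeds.get(name, base.seed)),
        )

    model = IntensityModel(
        mu_art=features.intensity["artery"][0],
        sigma_art=features.intensity["artery"][1],
        mu_vein=features.intensity["vein"][0],
        sigma_vein=features.intensity["vein"][1],
        mu_lung=features.intensity["lung"][0],
        sigma_lung=features.intensity["lung"][1],
    )
    return out, model
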