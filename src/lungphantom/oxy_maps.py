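"""Oxygen-demand maps that drive sequential artery / airway / vein tree growth.

A bronchopulmonary segment places arteries and airways centrally and veins
peripherally.  The maps built here encode that prior as a probability field
in [0, 1]: high demand where a structure should grow, zero demand on voxels
already occupied by previously generated structures (plus a security margin).

Segment-mode maps live on an abstract cubic volume and use a chessboard
(Chebyshev) distance gradient from a central core.  Anthropomorphic maps are
derived from a labeled real case: Euclidean distance to the real arterial
centerline, the convex hull of the real bronchial tree, and the medial locus
farthest from the synthetic arteries and airways for veins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import convex_hull_image, skeletonize

from .grid import InvalidConfigurationError, PreconditionError, VoxelGrid


@dataclass
class SegmentMapParams:
    """Parameters of the segment-phantom demand maps.

    core_fraction : fraction of each dimension forming the full-demand
        central core (arteries) / zero-demand center (veins).
    r_max : airway-proximity band scale in mm.  Demand around arteries is
        maximal out to a surface distance of ``2 * r_max`` and decays
        linearly to zero over a further ``r_max_decay``.
    margin : security margin, in voxels of binary dilation, where demand is
        forced to zero around occupied structures.
    """

    core_fraction: float = 1.0 / 3.0
    r_max: float = 3.0
    r_max_decay: float | None = None
    margin: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.core_fraction < 1.0):
            raise InvalidConfigurationError("core_fraction must be in (0, 1)")
        if self.r_max <= 0:
            raise InvalidConfigurationError("r_max must be > 0")
        if self.margin < 0:
            raise InvalidConfigurationError("margin must be >= 0")
        if self.r_max_decay is None:
            self.r_max_decay = self.r_max


@dataclass
class AnthroMapParams:
    """Parameters of the anthropomorphic demand maps.

    oxy_dmax : distance (mm) beyond which demand from a centerline is null.
    ox_min : demand floor inside the lung for the venous map.
    """

    oxy_dmax: float = 10.0
    ox_min: float = 0.001

    def __post_init__(self) -> None:
        if self.oxy_dmax <= 0:
            raise InvalidConfigurationError("oxy_dmax must be > 0")
        if not (0.0 < self.ox_min < 1.0):
            raise InvalidConfigurationError("ox_min must be in (0, 1)")


def _normalize(values: np.ndarray) -> np.ndarray:
    """Scale a nonnegative field so its maximum is exactly 1."""
    m = values.max()
    if m <= 0:
        raise PreconditionError("demand map has no positive values")
    out = values / m
    # guard against rounding pushing the max off 1
    np.clip(out, 0.0, 1.0, out=out)
    return out


def _dilate(mask: np.ndarray, margin: int) -> np.ndarray:
    """Binary dilation by `margin` steps of the 6-connected structuring element."""
    if margin == 0 or not mask.any():
        return mask.astype(bool)
    struct = ndimage.generate_binary_structure(3, 1)
    return ndimage.binary_dilation(mask, structure=struct, iterations=margin)

def _core_box(shape, core_fraction: float) -> np.ndarray:
    """Centered box occupying core_fraction of each dimension (at least 1 voxel)."""
    core = np.zeros(shape, dtype=bool)
    sl = []
    for n in shape:
        w = max(1, int(round(n * core_fraction)))
        lo = (n - w) // 2
        sl.append(slice(lo, lo + w))
    core[tuple(sl)] = True
    return core


def _chessboard_from(mask: np.ndarray) -> np.ndarray:
    """Chessboard (Chebyshev) distance of every voxel to a foreground mask."""
    return ndimage.distance_transform_cdt(~mask, metric="chessboard")


def _central_gradient(shape, core_fraction: float) -> np.ndarray:
    """Continuous ramp: 1 on the central core, falling linearly with chessboard
    distance to the global minimum at the volume faces."""
    core = _core_box(shape, core_fraction)
    d = _chessboard_from(core).astype(float)
    dmax = d.max()
    if dmax == 0:
        return np.ones(shape, dtype=float)
    return 1.0 - d / dmax


def build_segment_artery_map(shape, params: SegmentMapParams | None = None) -> VoxelGrid:
    """Central-core demand map for the arterial tree of a segment phantom.

    Demand is 1 on a centered core box and decreases linearly with chessboard
    distance from the core, reaching its minimum (0) at the volume faces.
    """
    params = params or SegmentMapParams()
    shape = tuple(int(n) for n in shape)
    if any(n < 3 for n in shape):
        raise InvalidConfigurationError(f"shape too small for a gradient map: {shape}")
    return VoxelGrid(_central_gradient(shape, params.core_fraction))


def _proximity_profile(surface_distance: np.ndarray, params: SegmentMapParams) -> np.ndarray:
    """Demand as a function of Euclidean distance (mm) to the artery surface:
    1 out to 2*r_max, then linear decay to 0 at 2*r_max + r_max_decay."""
    plateau = 2.0 * params.r_max
    cutoff = plateau + float(params.r_max_decay)
    prof = np.clip((cutoff - surface_distance) / (cutoff - plateau), 0.0, 1.0)
    return prof


def build_segment_airway_map(
    artery_labels: VoxelGrid, params: SegmentMapParams | None = None
) -> VoxelGrid:
    """Demand map promoting airway growth close and parallel to the arteries.

    Maximal demand in a shell around the arterial tree (surface distance up
    to ``2 * r_max``), decaying to zero farther out, multiplied by the
    central-core prior, and exactly zero on artery voxels dilated by the
    security margin.
    """
    params = params or SegmentMapParams()
    art = np.asarray(artery_labels.values) > 0
    if not art.any():
        raise PreconditionError("airway map requires a nonempty arterial volume")
    d = ndimage.distance_transform_edt(~art, sampling=artery_labels.spacing)
    demand = _proximity_profile(d, params)
    demand *= _central_gradient(art.shape, params.core_fraction)
    demand[_dilate(art, params.margin)] = 0.0
    return artery_labels.like(_normalize(demand))


def build_segment_vein_map(
    shape, occupied: VoxelGrid | None = None, params: SegmentMapParams | None = None
) -> VoxelGrid:
    """Peripheral demand map for veins: the inverse of the arterial gradient,
    zeroed on occupied (artery + airway) voxels plus the security margin."""
    params = params or SegmentMapParams()
    shape = tuple(int(n) for n in shape)
    if any(n < 3 for n in shape):
        raise InvalidConfigurationError(f"shape too small for a gradient map: {shape}")
    demand = 1.0 - _central_gradient(shape, params.core_fraction)
    if occupied is not None:
        occ = np.asarray(occupied.values) > 0
        if occ.shape != shape:
            raise PreconditionError(
                f"occupied shape {occ.shape} does not match map shape {shape}"
            )
        demand[_dilate(occ, params.margin)] = 0.0
    grid = occupied.like(_normalize(demand)) if occupied is not None else VoxelGrid(_normalize(demand))
    return grid


# ---------------------------------------------------------------------------
# anthropomorphic maps
# ---------------------------------------------------------------------------


def build_anthro_artery_map(
    artery_centerline: VoxelGrid,
    lung_mask: VoxelGrid,
    params: AnthroMapParams | None = None,
) -> VoxelGrid:
    """Demand 1 on the real arterial centerline, linearly decaying with
    Euclidean distance, null at >= oxy_dmax and outside the lung."""
    params = params or AnthroMapParams()
    cl = np.asarray(artery_centerline.values) > 0
    lung = np.asarray(lung_mask.values) > 0
    if not cl.any():
        raise PreconditionError("empty arterial centerline")
    d = ndimage.distance_transform_edt(~cl, sampling=artery_centerline.spacing)
    demand = np.clip(1.0 - d / params.oxy_dmax, 0.0, 1.0)
    demand[~lung] = 0.0
    return artery_centerline.like(_normalize(demand))


def build_anthro_airway_map(
    synthetic_arteries: VoxelGrid,
    real_airway_mask: VoxelGrid,
    lung_mask: VoxelGrid,
    params: SegmentMapParams | None = None,
) -> VoxelGrid:
    """Segment-style artery-proximity demand restricted to the convex hull of
    the real bronchial tree segmentation (and to the lung).

    The hull constraint reproduces the earlier CT invisibility of small
    peripheral airways: no airway growth outside the region where the real
    bronchial tree was actually observed.
    """
    params = params or SegmentMapParams()
    art = np.asarray(synthetic_arteries.values) > 0
    air = np.asarray(real_airway_mask.values) > 0
    lung = np.asarray(lung_mask.values) > 0
    if not art.any() or not air.any():
        raise PreconditionError("airway map requires nonempty artery and airway masks")
    d = ndimage.distance_transform_edt(~art, sampling=synthetic_arteries.spacing)
    base = _proximity_profile(d, params)
    hull = convex_hull_image(air)
    base[~hull] = 0.0
    base[~lung] = 0.0
    # the security margin must not consume the whole admissible region
    # (possible in small hulls); relax it stepwise if it does
    for margin in range(params.margin, -1, -1):
        demand = base.copy()
        demand[_dilate(art, margin)] = 0.0
        if demand.max() > 0:
            return synthetic_arteries.like(_normalize(demand))
    raise PreconditionError("airway demand empty: hull does not reach beyond arteries")


def venous_centerline_locus(
    occupancy: np.ndarray, lung: np.ndarray, spacing, ridge_fraction: float = 0.9
) -> tuple[np.ndarray, np.ndarray]:
    """Desired venous centerlines: skeleton of the ridge of the distance field.

    The distance-to-structures field is compared against a local maximum
    filter; voxels reaching at least ``ridge_fraction`` of the local maximum
    form a ridge region whose 3D skeleton is returned, together with the
    distance field itself.
    """
    d = ndimage.distance_transform_edt(~occupancy, sampling=spacing)
    d[~lung] = 0.0
    size = max(3, 2 * int(round(5.0 / min(spacing))) + 1)
    local_max = ndimage.maximum_filter(d, size=size)
    ridge = (d >= ridge_fraction * local_max) & lung & (d > 0)
    skel = skeletonize(ridge)
    if not skel.any():  # tiny lungs can skeletonize to nothing; fall back to ridge
        skel = ridge
    return skel.astype(bool), d


def build_anthro_vein_map(
    synthetic_arteries_airways: VoxelGrid,
    lung_mask: VoxelGrid,
    params: AnthroMapParams | None = None,
) -> VoxelGrid:
    """Venous demand: 1 on the locus farthest from synthetic arteries and
    airways, decaying with distance to ``ox_min`` at >= oxy_dmax; exactly 0
    outside the lung and on the occupied voxels themselves."""
    params = params or AnthroMapParams()
    occ = np.asarray(synthetic_arteries_airways.values) > 0
    lung = np.asarray(lung_mask.values) > 0
    if not occ.any():
        raise PreconditionError("vein map requires nonempty arteries+airways occupancy")
    if not (lung & ~occ).any():
        raise PreconditionError("lung entirely occupied; no room for veins")
    skel, _ = venous_centerline_locus(occ, lung, synthetic_arteries_airways.spacing)
    d_cl = ndimage.distance_transform_edt(~skel, sampling=synthetic_arteries_airways.spacing)
    ramp = np.clip(1.0 - d_cl / params.oxy_dmax, 0.0, 1.0)
    demand = params.ox_min + (1.0 - params.ox_min) * ramp
    demand[~lung] = 0.0
    demand[occ] = 0.0
    return synthetic_arteries_airways.like(_normalize(demand))
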