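"""Synthetic labeled lung cases for tests and anthropomorphic demos.

Real phantom adaptation starts from a labeled chest CT (lung mask plus
artery/vein/airway segmentations).  Such data is access-controlled, so this
module fabricates small stand-in cases: an ellipsoidal lung, three
hand-constructed bifurcating tube trees (arteries and airways interleaved
centrally, veins peripheral) voxelized with known radii and terminal
counts, and a CT assembled from per-compartment Normal intensity
statistics.  Every bundle is synthetic and deterministic given its seed;
between-case variability (intensity shifts, terminal-count and geometry
jitter) emulates inter-patient variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import PreconditionError, VoxelGrid
from .raster import rasterize_tree
from .realism import IntensityModel, NoiseParams, compose_phantom, map_intensities
from .tree_growth import Tree


@dataclass
class CompartmentStats:
    """Designed per-compartment HU statistics of a fixture case."""

    mu_art: float = 40.0
    sigma_art: float = 3.0
    mu_vein: float = 40.0
    sigma_vein: float = 3.0
    mu_air: float = 40.0
    sigma_air: float = 3.0
    mu_lung: float = -800.0
    sigma_lung: float = 150.0


@dataclass
class FixtureCase:
    """A synthetic labeled case bundle plus its design ground truth."""

    ct: VoxelGrid
    lung: VoxelGrid
    masks: dict[str, VoxelGrid]  # artery / vein / airway binary masks
    gray: dict[str, VoxelGrid]  # partial-volume occupancy per structure
    trees: dict[str, Tree]
    n_terminals: dict[str, int]
    stats: CompartmentStats
    roots: dict[str, np.ndarray]
    seed: int


def _sample_targets(
    n: int,
    rng: np.random.Generator,
    center: np.ndarray,
    semi: np.ndarray,
    accept,
    min_sep: float,
) -> np.ndarray:
    """Poisson-disk-style rejection sampling of leaf targets inside the lung."""
    targets: list[np.ndarray] = []
    attempts = 0
    sep = min_sep
    while len(targets) < n:
        attempts += 1
        if attempts % 400 == 0:  # relax separation if the region is crowded
            sep *= 0.85
        e = rng.uniform(-1.0, 1.0, size=3)
        if np.linalg.norm(e) > 0.85 or not accept(e):
            continue
        p = center + e * semi
        if all(np.linalg.norm(p - q) >= sep for q in targets):
            targets.append(p)
    return np.asarray(targets)


def _build_subtree(
    tree: Tree,
    parent_id: int,
    targets: np.ndarray,
    radius: float,
    taper: float,
    rng: np.random.Generator,
    min_radius: float = 1.0,
    post=None,
) -> None:
    """Recursive bisection: split leaf targets along their widest axis and
    place each internal node at a shrunk (slightly jittered) centroid.

    ``post`` optionally adjusts internal node positions (e.g. to keep the
    venous tree in the peripheral shell)."""
    if len(targets) == 1:
        tree.add_child(parent_id, targets[0], radius=max(radius, min_radius), flow=1.0)
        return
    axis = int(np.argmax(targets.std(axis=0)))
    order = np.argsort(targets[:, axis], kind="stable")
    half = len(targets) // 2
    groups = (targets[order[:half]], targets[order[half:]])
    start = tree.positions[parent_id]
    for group in groups:
        centroid = group.mean(axis=0)
        pos = start + 0.45 * (centroid - start) + rng.normal(0, 0.6, size=3)
        if post is not None:
            pos = post(pos)
        if len(group) == 1:
            tree.add_child(parent_id, group[0], radius=max(radius * taper, min_radius), flow=1.0)
        else:
            child = tree.add_child(
                parent_id, pos, radius=max(radius * taper, min_radius), flow=float(len(group))
            )
            _build_subtree(tree, child, group, radius * taper, taper, rng, min_radius, post)


def _fixture_tree(
    root: np.ndarray,
    targets: np.ndarray,
    rng: np.random.Generator,
    root_radius: float,
    taper: float = 0.72,
    min_radius: float = 1.0,
    post=None,
) -> Tree:
    tree = Tree.with_root(root)
    # a single dominant trunk toward the target cloud, then recursive splits
    trunk_end = root + 0.35 * (targets.mean(axis=0) - root)
    if post is not None:
        trunk_end = post(trunk_end)
    trunk = tree.add_child(tree.root_id, trunk_end, radius=root_radius, flow=float(len(targets)))
    _build_subtree(tree, trunk, targets, root_radius * taper, taper, rng, min_radius, post)
    tree.validate()
    return tree


def make_fixture_case(
    seed: int = 0,
    shape=(64, 64, 64),
    spacing=(1.0, 1.0, 1.0),
    n_terminals: dict[str, int] | None = None,
    stats: CompartmentStats | None = None,
    noise: NoiseParams | None = None,
    case_jitter: bool = True,
    mask_threshold: float = 0.35,
    min_radius: float = 1.0,
) -> FixtureCase:
    """Generate one synthetic labeled case.

    ``case_jitter`` adds seeded between-case variability: small shifts of
    the compartment means, +-1 terminal-count jitter and root jitter, so a
    population of fixtures spans a realistic spread of "patients".
    ``mask_threshold`` is the occupancy fraction above which a voxel enters
    a structure's binary segmentation mask.
    """
    shape = tuple(int(n) for n in shape)
    if min(shape) < 48:
        raise PreconditionError("fixture shape should be at least 48 voxels per axis")
    rng = np.random.default_rng(seed)
    base_counts = dict(n_terminals or {"artery": 6, "vein": 6, "airway": 5})
    stats = stats or CompartmentStats()
    if case_jitter:
        stats = CompartmentStats(
            mu_art=stats.mu_art + rng.normal(0, 4),
            sigma_art=stats.sigma_art,
            mu_vein=stats.mu_vein + rng.normal(0, 4),
            sigma_vein=stats.sigma_vein,
            mu_air=stats.mu_air,
            sigma_air=stats.sigma_air,
            mu_lung=stats.mu_lung + rng.normal(0, 30),
            sigma_lung=stats.sigma_lung * (1.0 + 0.1 * rng.standard_normal()),
        )
        base_counts = {
            k: max(4, v + int(rng.integers(-2, 3))) for k, v in base_counts.items()
        }

    grid = VoxelGrid(np.zeros(shape), spacing=spacing, origin=(0.0, 0.0, 0.0))
    extent = (np.asarray(shape) - 1) * np.asarray(spacing)
    center = extent / 2.0
    lung_scale = rng.uniform(0.42, 0.50) if case_jitter else 0.46
    semi = extent * lung_scale

    axes = grid.voxel_centers()
    gx, gy, gz = np.meshgrid(*axes, indexing="ij", sparse=True)
    lung_mask = (
        ((gx - center[0]) / semi[0]) ** 2
        + ((gy - center[1]) / semi[1]) ** 2
        + ((gz - center[2]) / semi[2]) ** 2
    ) <= 1.0
    lung = grid.like(lung_mask.astype(np.uint8))

    # roots near the "hilum" (low-x pole): artery slightly below the midline,
    # airway above it, vein well below — far enough apart that the trunks
    # never touch
    roots = {
        "artery": center + semi * np.array([-0.78, -0.08, 0.0]),
        "airway": center + semi * np.array([-0.70, 0.30, 0.0]),
        "vein": center + semi * np.array([-0.66, -0.45, 0.0]),
    }
    if case_jitter:
        for k in roots:
            roots[k] = roots[k] + rng.normal(0, 1.0, size=3)
    # leaf-target regions: arteries in the central core (below the midplane
    # so the accompanying bronchus fits above), veins in the peripheral
    # shell; airway targets are an offset copy of artery targets, mimicking
    # the artery-bronchus pairing of a bronchopulmonary segment
    accept = {
        "artery": lambda e: e[0] > -0.35 and np.linalg.norm(e) < 0.55 and e[1] < -0.08,
        "vein": lambda e: e[0] > -0.4 and 0.70 < np.linalg.norm(e) < 0.85,
    }
    airway_offset = np.array([0.0, 8.5, 0.0])
    # airways become CT-invisible before vessels do, so the visible bronchial
    # tree only accompanies the proximal part of the arterial tree
    airway_reach = 0.72
    if case_jitter:  # per-case artery-bronchus spacing, like real anatomy
        airway_offset = airway_offset * rng.uniform(0.7, 1.35) + np.array(
            [0.0, 0.0, rng.uniform(-2.0, 2.0)]
        )
        airway_reach = rng.uniform(0.45, 0.9)

    def _vein_post(pos):
        # keep venous internal nodes in the peripheral shell, away from the
        # central arteries and airways
        e = (pos - center) / semi
        r = np.linalg.norm(e)
        if r < 0.66:
            e = e / max(r, 1e-9) * 0.66
        return center + e * semi

    post = {"artery": None, "airway": None, "vein": _vein_post}
    root_radius = {"artery": 2.0, "airway": 2.4, "vein": 2.0}
    min_sep = {"artery": 10.0, "airway": 10.0, "vein": 10.0}

    # build-and-check loop: the bundle must actually carry its designed
    # ground truth (one connected component per structure, skeleton endpoint
    # count consistent with the designed terminal count), so the geometry is
    # re-drawn from a derived sub-seed until the checks pass
    from scipy import ndimage as _ndi
    from skimage.morphology import skeletonize as _skel

    from .anthro import count_skeleton_terminals as _endpoints

    order = ("artery", "airway", "vein")
    trees: dict[str, Tree] = {}
    gray: dict[str, VoxelGrid] = {}
    masks: dict[str, VoxelGrid] = {}
    struct26 = np.ones((3, 3, 3), dtype=bool)
    base_counts["airway"] = min(base_counts["airway"], base_counts["artery"])
    for attempt in range(12):
        geo_rng = np.random.default_rng((seed, attempt))
        art_targets = _sample_targets(
            base_counts["artery"], geo_rng, center, semi, accept["artery"], min_sep["artery"]
        )
        vein_targets = _sample_targets(
            base_counts["vein"], geo_rng, center, semi, accept["vein"], min_sep["vein"]
        )
        # accompanying bronchi: an offset copy of a spread-out artery subset
        k = base_counts["airway"]
        pick = np.round(np.linspace(0, len(art_targets) - 1, k)).astype(int)
        art_sub = art_targets[np.argsort(art_targets[:, 0], kind="stable")][pick]
        air_targets = (
            roots["artery"]
            + airway_reach * (art_sub - roots["artery"])
            + airway_offset
            + geo_rng.normal(0, 0.8, size=(k, 3))
        )
        targets = {"artery": art_targets, "airway": air_targets, "vein": vein_targets}
        trees = {}
        gray = {}
        masks = {}
        for name in order:
            trees[name] = _fixture_tree(
                roots[name],
                targets[name],
                geo_rng,
                root_radius[name],
                min_radius=min_radius,
                post=post[name],
            )
            g, _ = rasterize_tree(trees[name], grid, supersampling=3)
            gray[name] = g
        # pairwise-disjoint masks by the max-occupancy rule (ties fall to the
        # artery > airway > vein priority); only the losing structure's shell
        # is shaved at touching points, so tubes stay connected
        stack = np.stack([np.asarray(gray[n].values) for n in order])
        winner = np.argmax(stack, axis=0)
        for i, name in enumerate(order):
            g = np.asarray(gray[name].values)
            g[(winner != i) & (stack[(winner, *np.indices(shape))] >= 0.5)] = 0.0
            m = (g >= mask_threshold) & lung_mask & (winner == i)
            masks[name] = grid.like(m.astype(np.uint8))
        ok = True
        for name in order:
            m = np.asarray(masks[name].values) > 0
            if _ndi.label(m, structure=struct26)[1] != 1:
                ok = False
                break
            # skeleton endpoints = designed leaves + the root end, less at
            # most one merged tip
            n_ep = _endpoints(_skel(m))
            if not (base_counts[name] <= n_ep <= base_counts[name] + 1):
                ok = False
                break
        if ok:
            break
    else:
        raise PreconditionError(
            f"could not build a consistent fixture for seed {seed}; shape too small?"
        )

    # CT assembly with the same composition model used for phantoms
    # same composition model as phantom generation, so fixture "CT" texture
    # and phantom texture share one forward model
    noise = noise or NoiseParams(
        parenchyma_mean_abs=abs(stats.mu_lung),
        parenchyma_sd=stats.sigma_lung,
        seed=seed,
    )
    model = IntensityModel(
        mu_art=stats.mu_art,
        sigma_art=stats.sigma_art,
        mu_vein=stats.mu_vein,
        sigma_vein=stats.sigma_vein,
        mu_air=stats.mu_air,
        sigma_air=stats.sigma_air,
        mu_lung=stats.mu_lung,
        sigma_lung=stats.sigma_lung,
    )
    hu_rng = np.random.default_rng(seed + 977)
    structures_hu = {
        name: map_intensities(gray[name], "anthro", model, name, hu_rng)
        for name in ("artery", "airway", "vein")
    }
    composite = compose_phantom(structures_hu, gray, lung, noise, outside_value=20.0)
    ct = composite.final

    return FixtureCase(
        ct=ct,
        lung=lung,
        masks=masks,
        gray=gray,
        trees=trees,
        n_terminals=dict(base_counts),
        stats=stats,
        roots=roots,
        seed=seed,
    )
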