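"""End-to-end phantom generation pipelines and batch protocols.

``generate_segment_phantom`` produces one bronchopulmonary-segment phantom
from a configuration alone; ``generate_anthro_phantom`` adapts the pipeline
to a labeled case bundle.  The batch drivers reproduce the study protocols:
a grid of (N_f, FA) combinations with several repetitions for segment
phantoms, and several seeds per labeled lung for anthropomorphic ones.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .anthro import adapt_growth_params, extract_case_features, select_perfusion_point
from .fixtures import FixtureCase
from .grid import VoxelGrid
from .io import write_tree, write_volume
from .oxy_maps import (
    AnthroMapParams,
    SegmentMapParams,
    build_anthro_airway_map,
    build_anthro_artery_map,
    build_anthro_vein_map,
    build_segment_airway_map,
    build_segment_artery_map,
    build_segment_vein_map,
)
from .raster import LabeledVolumes, rasterize_tree, resolve_intersections
from .realism import (
    DeformationParams,
    IntensityModel,
    NoiseParams,
    PhantomComposite,
    WallThicknessTable,
    compose_phantom,
    embed_phantom,
    hollow_airways,
    map_intensities,
)
from .tree_growth import GrowthParams, Tree, airway_terminal_count, grow_tree

log = logging.getLogger("lungphantom")

#: perfusion points of the segment-phantom flow systems (mm, on the 101^3 grid)
SEGMENT_P0 = {
    "artery": (5.0, 50.0, 50.0),
    "vein": (5.0, 30.0, 50.0),
    "airway": (5.0, 40.0, 50.0),
}

STRUCTURES = ("artery", "airway", "vein")


def derive_seed(master_seed: int, stage: int) -> int:
    """Counter-based derivation of independent per-stage seeds (< 2^31)."""
    ss = np.random.SeedSequence((int(master_seed), int(stage)))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PhantomConfig:
    """Full configuration of one phantom generation run."""

    mode: str = "segment"
    shape: tuple[int, int, int] = (101, 101, 101)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_terminals: int = 50
    fa: int = 3
    growth: GrowthParams = field(default_factory=GrowthParams)
    map_params: SegmentMapParams = field(default_factory=SegmentMapParams)
    anthro_map_params: AnthroMapParams = field(default_factory=AnthroMapParams)
    wall_thickness: WallThicknessTable = field(default_factory=WallThicknessTable)
    intensity: IntensityModel = field(default_factory=IntensityModel)
    noise: NoiseParams = field(default_factory=NoiseParams)
    deformation: DeformationParams = field(default_factory=DeformationParams)
    supersampling: int = 3
    master_seed: int = 0
    output_dir: str | None = None

    def config_hash(self) -> str:
        return hashlib.md5(repr(self).encode()).hexdigest()[:12]


@dataclass
class PhantomResult:
    """Everything a generation run produces."""

    config: PhantomConfig
    trees: dict[str, Tree]
    gray: dict[str, VoxelGrid]
    labels: VoxelGrid
    hu: dict[str, VoxelGrid]
    composite: PhantomComposite
    final: VoxelGrid
    maps: dict[str, VoxelGrid] = field(default_factory=dict)
    features: object | None = None


def _scale_p0(p0, shape, spacing) -> tuple[float, float, float]:
    """Rescale the reference perfusion points (defined on the 101^3 lattice)
    to an arbitrary grid."""
    frac = np.asarray(p0) / 100.0
    return tuple(float(f * (n - 1) * s) for f, n, s in zip(frac, shape, spacing))


def generate_segment_phantom(config: PhantomConfig) -> PhantomResult:
    """Run the full segment-phantom pipeline for one configuration."""
    t0 = time.perf_counter()
    grid = VoxelGrid(np.zeros(config.shape, dtype=np.uint8), config.spacing, (0.0, 0.0, 0.0))
    mp = config.map_params
    counts = {
        "artery": config.n_terminals,
        "vein": config.n_terminals,
        "airway": airway_terminal_count(config.n_terminals, config.fa),
    }

    maps: dict[str, VoxelGrid] = {}
    trees: dict[str, Tree] = {}
    gray: dict[str, VoxelGrid] = {}
    occupied = np.zeros(config.shape, dtype=np.uint8)
    for stage, name in enumerate(STRUCTURES):
        if name == "artery":
            demand = build_segment_artery_map(config.shape, mp)
        elif name == "airway":
            demand = build_segment_airway_map(grid.like(occupied), mp)
        else:
            demand = build_segment_vein_map(config.shape, grid.like(occupied), mp)
        demand = VoxelGrid(demand.values, config.spacing, (0.0, 0.0, 0.0))
        maps[name] = demand
        params = replace(
            config.growth,
            n_terminals=counts[name],
            p0=_scale_p0(SEGMENT_P0[name], config.shape, config.spacing),
            seed=derive_seed(config.master_seed, stage),
        )
        trees[name] = grow_tree(demand, params)
        g, m = rasterize_tree(trees[name], grid, config.supersampling)
        gray[name] = g
        occupied |= np.asarray(m.values).astype(np.uint8)
        log.info("grew %s: %d terminals", name, trees[name].n_terminals)

    resolved = resolve_intersections(gray, trees)
    gray = resolved.gray
    gray["airway"] = hollow_airways(
        gray["airway"], trees["airway"], config.wall_thickness, config.supersampling
    )

    volumes = dict(gray)
    volumes["labels"] = resolved.labels
    deform = replace(config.deformation, seed=derive_seed(config.master_seed, 10))
    warped, trees, _ = _deform(volumes, trees, deform)
    labels = warped.pop("labels")
    gray = warped

    hu = {
        name: map_intensities(gray[name], "segment", config.intensity)
        for name in STRUCTURES
    }
    lung_all = grid.like(np.ones(config.shape, dtype=np.uint8))
    noise = replace(config.noise, seed=derive_seed(config.master_seed, 11))
    composite = compose_phantom(hu, gray, lung_all, noise)
    log.info("segment phantom done in %.1f s", time.perf_counter() - t0)

    result = PhantomResult(
        config=config,
        trees=trees,
        gray=gray,
        labels=labels,
        hu=hu,
        composite=composite,
        final=composite.final,
        maps=maps,
    )
    if config.output_dir:
        _write_result(result, Path(config.output_dir))
    return result


def _deform(volumes, trees, params):
    from .realism import deform_structures

    return deform_structures(volumes, trees, params, label_keys=("labels",))


def generate_anthro_phantom(
    case: FixtureCase | dict,
    config: PhantomConfig,
    overrides: dict | None = None,
) -> PhantomResult:
    """Generate one anthropomorphic phantom adapted to a labeled case.

    ``case`` is a FixtureCase or a dict with keys ct, lung, artery, vein,
    airway holding VoxelGrids.
    """
    t0 = time.perf_counter()
    if isinstance(case, FixtureCase):
        ct, lung = case.ct, case.lung
        masks = case.masks
    else:
        ct, lung = case["ct"], case["lung"]
        masks = {k: case[k] for k in ("artery", "vein", "airway")}

    features = extract_case_features(ct, lung, masks["artery"], masks["vein"], masks["airway"])
    amp = config.anthro_map_params
    art_map = build_anthro_artery_map(features.artery_centerline, lung, amp)
    overrides = dict(overrides or {})
    overrides.setdefault("fa", config.fa if config.fa > 1 else None)
    overrides["seeds"] = {
        name: derive_seed(config.master_seed, i) for i, name in enumerate(STRUCTURES)
    }
    growth, model = adapt_growth_params(
        features, overrides, maps={"artery": art_map}, base=config.growth
    )

    grid = lung
    maps = {"artery": art_map}
    trees: dict[str, Tree] = {}
    gray: dict[str, VoxelGrid] = {}
    occupied = np.zeros(ct.shape, dtype=np.uint8)

    for name in STRUCTURES:
        if name == "airway":
            maps[name] = build_anthro_airway_map(
                grid.like(occupied), masks["airway"], lung, config.map_params
            )
        elif name == "vein":
            maps[name] = build_anthro_vein_map(grid.like(occupied), lung, amp)
        if name != "artery":
            p0 = select_perfusion_point(maps[name], features.roots[name], amp.oxy_dmax)
            growth[name] = replace(growth[name], p0=tuple(float(x) for x in p0))
        trees[name] = grow_tree(maps[name], growth[name])
        g, m = rasterize_tree(trees[name], grid, config.supersampling)
        gray[name] = g
        occupied |= np.asarray(m.values).astype(np.uint8)
        log.info("grew %s: %d terminals", name, trees[name].n_terminals)

    resolved = resolve_intersections(gray, trees)
    gray = resolved.gray
    gray["airway"] = hollow_airways(
        gray["airway"], trees["airway"], config.wall_thickness, config.supersampling
    )

    volumes = dict(gray)
    volumes["labels"] = resolved.labels
    deform = replace(config.deformation, seed=derive_seed(config.master_seed, 10))
    warped, trees, _ = _deform(volumes, trees, deform)
    labels = warped.pop("labels")
    gray = warped

    hu_rng = np.random.default_rng(derive_seed(config.master_seed, 12))
    hu = {
        name: map_intensities(gray[name], "anthro", model, name, hu_rng)
        for name in STRUCTURES
    }
    noise = replace(
        config.noise,
        parenchyma_mean_abs=abs(features.intensity["lung"][0]),
        parenchyma_sd=features.intensity["lung"][1],
        seed=derive_seed(config.master_seed, 11),
    )
    # blur against the host's juxta-pleural intensity so the lung boundary
    # shell matches the real case after embedding
    from scipy import ndimage as _ndi

    lung_arr = np.asarray(lung.values) > 0
    near = _ndi.binary_dilation(lung_arr, iterations=3)
    band = _ndi.binary_dilation(near, iterations=4) & ~near  # beyond the kernel bleed
    outside = float(np.asarray(ct.values)[band].mean()) if band.any() else -1000.0
    composite = compose_phantom(hu, gray, lung, noise, outside_value=outside)
    final = embed_phantom(ct, lung, composite.final)
    log.info("anthro phantom done in %.1f s", time.perf_counter() - t0)

    result = PhantomResult(
        config=config,
        trees=trees,
        gray=gray,
        labels=labels,
        hu=hu,
        composite=composite,
        final=final,
        maps=maps,
        features=features,
    )
    if config.output_dir:
        _write_result(result, Path(config.output_dir))
    return result


_LABEL_METADATA = {
    "label.0": "background",
    "label.1": "artery",
    "label.2": "vein",
    "label.3": "airway",
}


def _write_result(result: PhantomResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    final = result.final.like(
        np.clip(np.asarray(result.final.values), -32768, 32767).astype(np.int16)
    )
    write_volume(final, str(outdir / "phantom.nrrd"))
    write_volume(result.labels, str(outdir / "labels.nrrd"), metadata=_LABEL_METADATA)
    if result.features is not None:
        lung = result.features.lung_mask
    else:  # segment mode: the whole grid is the simulated segment
        lung = result.labels.like(np.ones(result.labels.shape, dtype=np.uint8))
    write_volume(lung, str(outdir / "lung.nrrd"))
    for name, tree in result.trees.items():
        write_tree(tree, str(outdir / f"tree_{name}.txt"))


# ---------------------------------------------------------------------------
# batch protocols
# ---------------------------------------------------------------------------

#: the study's segment-phantom parameter grid
SEGMENT_NF_GRID = tuple(range(30, 101, 10))
SEGMENT_FA_GRID = (1, 2, 3)
SEGMENT_REPETITIONS = 4


def run_segment_batch(
    nf_values=SEGMENT_NF_GRID,
    fa_values=SEGMENT_FA_GRID,
    repetitions: int = SEGMENT_REPETITIONS,
    config: PhantomConfig | None = None,
    output_dir: str | None = None,
    execute: bool = True,
) -> pd.DataFrame:
    """Segment-phantom batch: one phantom per (N_f, FA, repetition).

    With ``execute=False`` only the manifest is enumerated (fast planning /
    counting mode).  Failures of individual runs are logged and recorded in
    the manifest; the batch continues.
    """
    config = config or PhantomConfig()
    rows = []
    for nf in nf_values:
        for fa in fa_values:
            for rep in range(repetitions):
                seed = derive_seed(config.master_seed, hash((nf, fa, rep)) % (2**31))
                cfg = replace(
                    config,
                    n_terminals=int(nf),
                    fa=int(fa),
                    master_seed=seed,
                    output_dir=(
                        str(Path(output_dir) / f"nf{nf}_fa{fa}_rep{rep}")
                        if output_dir
                        else None
                    ),
                )
                row = {
                    "nf": int(nf),
                    "fa": int(fa),
                    "repetition": rep,
                    "seed": seed,
                    "config_hash": cfg.config_hash(),
                    "output_dir": cfg.output_dir or "",
                    "status": "planned",
                }
                if execute:
                    try:
                        result = generate_segment_phantom(cfg)
                        row["status"] = "ok"
                        for name in STRUCTURES:
                            row[f"n_terminals_{name}"] = result.trees[name].n_terminals
                    except Exception as exc:  # noqa: BLE001 - batch must continue
                        log.error("segment phantom nf=%s fa=%s rep=%s failed: %s", nf, fa, rep, exc)
                        row["status"] = f"failed: {exc}"
                rows.append(row)
    manifest = pd.DataFrame(rows)
    if output_dir:
        Path(output_dir).mkdir(parents=True, exist_ok=True)
        manifest.to_csv(Path(output_dir) / "manifest.csv", index=False)
    return manifest


def run_anthro_batch(
    cases,
    seeds_per_lung: int = 4,
    config: PhantomConfig | None = None,
    output_dir: str | None = None,
    execute: bool = True,
):
    """Anthropomorphic batch: ``seeds_per_lung`` phantoms per labeled lung.

    Returns (manifest, results); results is empty when ``execute=False``.
    """
    config = config or PhantomConfig(mode="anthro")
    rows = []
    results = []
    for ci, case in enumerate(cases):
        for rep in range(seeds_per_lung):
            seed = derive_seed(config.master_seed, 1000 * (ci + 1) + rep)
            cfg = replace(
                config,
                master_seed=seed,
                output_dir=(
                    str(Path(output_dir) / f"case{ci}_rep{rep}") if output_dir else None
                ),
            )
            row = {
                "case": ci,
                "repetition": rep,
                "seed": seed,
                "config_hash": cfg.config_hash(),
                "output_dir": cfg.output_dir or "",
                "status": "planned",
            }
            if execute:
                try:
                    result = generate_anthro_phantom(case, cfg)
                    results.append(result)
                    row["status"] = "ok"
                    for name in STRUCTURES:
                        row[f"n_terminals_{name}"] = result.trees[name].n_terminals
                except Exception as exc:  # noqa: BLE001
                    log.error("anthro phantom case=%s rep=%s failed: %s", ci, rep, exc)
                    row["status"] = f"failed: {exc}"
            rows.append(row)
    manifest = pd.DataFrame(rows)
    if output_dir:
        Path(output_dir).mkdir(parents=True, exist_ok=True)
        manifest.to_csv(Path(output_dir) / "manifest.csv", index=False)
    return manifest, results
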