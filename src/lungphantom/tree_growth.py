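"""Iterative growth of binary tubular trees under an oxygen-demand map.

The generator follows the constrained-constructive-optimization family of
vascular synthesis methods: terminal sites are sampled proportionally to the
oxygen demand, each new terminal is connected through a bifurcation placed
on one of the nearest existing segments so as to minimize a global material
cost, and the whole tree is re-solved hemodynamically after every insertion.

Hemodynamics
------------
Blood is treated as a Poiseuille fluid: a straight cylindrical segment of
length ``l`` and radius ``r`` has resistance ``8 eta l / (pi r^4)``.  Every
terminal delivers the same flow ``Q_total / N_terminals`` and sees the same
pressure drop ``P_ini - P_fin`` from the root.  Child/parent radius ratios
``beta`` obey the bifurcation power law ``beta_l^gamma + beta_r^gamma = 1``
and are solved jointly with the equal-terminal-pressure condition using the
classic bottom-up *reduced resistance* scheme: for a subtree with root
radius ``r``, the actual resistance is ``R*/r^4`` with

    R*_i = 8 eta l_i / pi + ( beta_l^4 / R*_l  +  beta_r^4 / R*_r )^-1

and sibling ratios fixed by ``(beta_l/beta_r)^4 = (Q_l R*_l)/(Q_r R*_r)``.
The root radius then follows from ``dP = Q_root R*_root / r_root^4``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grid import LungPhantomError, PreconditionError, VoxelGrid

# unit conversions to SI
_MMHG_TO_PA = 133.322387415
_CCMIN_TO_M3S = 1e-6 / 60.0
_MPAS_TO_PAS = 1e-3
_MM_TO_M = 1e-3


class GrowthExhaustedError(LungPhantomError):
    """The demand map cannot support any further admissible terminal."""


class GeometryError(LungPhantomError):
    """Degenerate tree geometry (zero-length segment, candidate on a node, ...)."""


class DegenerateCandidateError(GeometryError):
    """Candidate terminal coincides with an existing tree node."""


@dataclass
class GrowthParams:
    """Physical and algorithmic parameters of tree growth.

    Pressures in mmHg, viscosity in mPa*s, flow in cc/min (the per-gram
    normalization of the physiological value is treated as an opaque total
    scale), lengths in mm.
    """

    p_ini: float = 25.0
    p_fin: float = 10.0
    eta: float = 36.0
    q_total: float = 138.83
    lambda_exp: float = 2.0
    gamma: float = 2.55
    mu_exp: float = 2.0
    d_t: float = 1.0
    k_closest: int = 5
    n_terminals: int = 50
    p0: tuple[float, float, float] = (5.0, 50.0, 50.0)
    seed: int = 0
    rejection_budget: int = 1000

    def __post_init__(self) -> None:
        if not (self.p_ini > self.p_fin > 0):
            raise PreconditionError("require P_ini > P_fin > 0")
        if self.eta <= 0 or self.gamma <= 0:
            raise PreconditionError("eta and gamma must be positive")
        if self.n_terminals < 1 or self.k_closest < 1:
            raise PreconditionError("N_f and k_closest must be >= 1")


@dataclass
class Tree:
    """Binary tree of straight cylindrical segments.

    Nodes are keyed by integer id; a segment is identified with its child
    node (the segment connects ``parent[child] -> child``).  The root node
    carries no segment.
    """

    positions: dict[int, np.ndarray] = field(default_factory=dict)
    parent: dict[int, int | None] = field(default_factory=dict)
    children: dict[int, list[int]] = field(default_factory=dict)
    radius: dict[int, float] = field(default_factory=dict)
    flow: dict[int, float] = field(default_factory=dict)
    root_id: int = 0
    _next_id: int = 0

    # ---- construction ---------------------------------------------------

    @classmethod
    def with_root(cls, p0) -> "Tree":
        t = cls()
        t.root_id = t._new_node(np.asarray(p0, dtype=float))
        return t

    def _new_node(self, position: np.ndarray) -> int:
        nid = self._next_id
        self._next_id += 1
        self.positions[nid] = np.asarray(position, dtype=float)
        self.parent[nid] = None
        self.children[nid] = []
        return nid

    def add_child(self, parent_id: int, position, radius: float = 0.0, flow: float = 0.0) -> int:
        nid = self._new_node(np.asarray(position, dtype=float))
        self.parent[nid] = parent_id
        self.children[parent_id].append(nid)
        self.radius[nid] = float(radius)
        self.flow[nid] = float(flow)
        return nid

    def copy(self) -> "Tree":
        t = Tree(
            positions={k: v.copy() for k, v in self.positions.items()},
            parent=dict(self.parent),
            children={k: list(v) for k, v in self.children.items()},
            radius=dict(self.radius),
            flow=dict(self.flow),
            root_id=self.root_id,
            _next_id=self._next_id,
        )
        return t

    # ---- queries ---------------------------------------------------------

    @property
    def node_ids(self) -> list[int]:
        return sorted(self.positions)

    @property
    def segment_ids(self) -> list[int]:
        """Segments keyed by child node id, ascending (deterministic order)."""
        return sorted(k for k, p in self.parent.items() if p is not None)

    @property
    def terminal_ids(self) -> list[int]:
        return sorted(k for k in self.positions if not self.children[k] and k != self.root_id)

    @property
    def bifurcation_ids(self) -> list[int]:
        return sorted(k for k in self.positions if len(self.children[k]) == 2)

    @property
    def n_terminals(self) -> int:
        return len(self.terminal_ids)

    @property
    def n_segments(self) -> int:
        return len(self.segment_ids)

    def segment_length(self, seg_id: int) -> float:
        p = self.parent[seg_id]
        return float(np.linalg.norm(self.positions[seg_id] - self.positions[p]))

    def segment_endpoints(self, seg_id: int) -> tuple[np.ndarray, np.ndarray]:
        return self.positions[self.parent[seg_id]], self.positions[seg_id]

    def role(self, node_id: int) -> str:
        if node_id == self.root_id:
            return "root"
        return "terminal" if not self.children[node_id] else "bifurcation"

    def generation(self, seg_id: int) -> int:
        """Number of bifurcation nodes strictly above the segment."""
        g = 0
        p = self.parent[seg_id]
        while p is not None:
            if len(self.children[p]) == 2:
                g += 1
            p = self.parent[p]
        return g

    def validate(self) -> None:
        """Assert the binary-tree invariants; raises GeometryError otherwise."""
        n_t = self.n_terminals
        n_b = len(self.bifurcation_ids)
        n_s = self.n_segments
        if n_t >= 1 and (n_b != n_t - 1 or n_s != 2 * n_t - 1):
            raise GeometryError(
                f"binary-tree identity violated: {n_t} terminals, {n_b} bifurcations, {n_s} segments"
            )
        for k in self.positions:
            if k != self.root_id and len(self.children[k]) not in (0, 2):
                raise GeometryError(f"node {k} has {len(self.children[k])} children")

    # ---- geometry --------------------------------------------------------

    def distance_to_segments(self, point) -> np.ndarray:
        """Euclidean distance from a point to each segment (capsule axis), in
        the order of ``segment_ids``."""
        p = np.asarray(point, dtype=float)
        segs = self.segment_ids
        if not segs:
            return np.empty(0)
        a = np.array([self.positions[self.parent[s]] for s in segs])
        b = np.array([self.positions[s] for s in segs])
        return _point_segment_distance(p, a, b)

    def min_distance(self, point) -> float:
        """Distance from a point to the tree (segments, or root node if empty)."""
        d = self.distance_to_segments(point)
        if d.size == 0:
            return float(np.linalg.norm(np.asarray(point, float) - self.positions[self.root_id]))
        return float(d.min())

    def min_surface_distance(self, point) -> float:
        """Distance from a point to the nearest segment *surface* (axis
        distance minus radius); candidates inside a tube come out negative."""
        segs = self.segment_ids
        if not segs:
            return self.min_distance(point)
        d = self.distance_to_segments(point)
        radii = np.array([self.radius.get(s, 0.0) for s in segs])
        return float((d - radii).min())


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distances from point p (3,) to segments a->b (n,3)."""
    ab = b - a
    ap = p[None, :] - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.where(denom > 0, np.einsum("ij,ij->i", ap, ab) / np.maximum(denom, 1e-300), 0.0)
    t = np.clip(t, 0.0, 1.0)
    closest = a + t[:, None] * ab
    return np.linalg.norm(p[None, :] - closest, axis=1)


# ---------------------------------------------------------------------------
# hemodynamics
# ---------------------------------------------------------------------------


def hemodynamic_update(tree: Tree, params: GrowthParams) -> Tree:
    """Re-solve flows and radii in place; returns the same tree.

    Terminal flows are ``Q_total / N_terminals``; the reduced-resistance
    recursion (module docstring) yields radii such that the pressure drop
    from root to every terminal equals ``P_ini - P_fin`` exactly.
    """
    terminals = tree.terminal_ids
    if not terminals:
        return tree
    q_term = tree_terminal_flow(tree, params)

    eta = params.eta * _MPAS_TO_PAS
    dp = (params.p_ini - params.p_fin) * _MMHG_TO_PA

    # postorder over segments (children before parents)
    order: list[int] = []
    stack = [c for c in tree.children[tree.root_id]]
    while stack:
        n = stack.pop()
        order.append(n)
        stack.extend(tree.children[n])
    order.reverse()

    rstar: dict[int, float] = {}
    beta: dict[int, float] = {}
    for seg in order:
        length = tree.segment_length(seg)
        if length <= 0:
            raise GeometryError(f"zero-length segment {seg}")
        r_seg = 8.0 * eta * (length * _MM_TO_M) / math.pi
        kids = tree.children[seg]
        if not kids:
            tree.flow[seg] = q_term
            rstar[seg] = r_seg
        else:
            left, right = kids
            ql, qr = tree.flow[left], tree.flow[right]
            tree.flow[seg] = ql + qr
            ratio = (ql * rstar[left] / (qr * rstar[right])) ** 0.25  # beta_l / beta_r
            br = (1.0 + ratio**params.gamma) ** (-1.0 / params.gamma)
            bl = ratio * br
            beta[left], beta[right] = bl, br
            rstar[seg] = r_seg + 1.0 / (bl**4 / rstar[left] + br**4 / rstar[right])

    # root radius from the full pressure drop, then top-down beta scaling
    roots = tree.children[tree.root_id]
    for root_seg in roots:
        q_root = tree.flow[root_seg] * _CCMIN_TO_M3S
        r4 = q_root * rstar[root_seg] / dp
        tree.radius[root_seg] = (r4**0.25) / _MM_TO_M
        stack = list(tree.children[root_seg])
        while stack:
            n = stack.pop()
            tree.radius[n] = beta[n] * tree.radius[tree.parent[n]]
            stack.extend(tree.children[n])
    return tree


def tree_terminal_flow(tree: Tree, params: GrowthParams) -> float:
    return params.q_total / max(1, tree.n_terminals)


def terminal_pressures(tree: Tree, params: GrowthParams) -> dict[int, float]:
    """Root-to-terminal pressure (mmHg) at each terminal, from Poiseuille drops."""
    eta = params.eta * _MPAS_TO_PAS
    out: dict[int, float] = {}

    def descend(node: int, pressure_pa: float) -> None:
        for c in tree.children[node]:
            length = tree.segment_length(c) * _MM_TO_M
            r = tree.radius[c] * _MM_TO_M
            q = tree.flow[c] * _CCMIN_TO_M3S
            drop = 8.0 * eta * length * q / (math.pi * r**4)
            p_child = pressure_pa - drop
            if not tree.children[c]:
                out[c] = p_child / _MMHG_TO_PA
            else:
                descend(c, p_child)

    descend(tree.root_id, params.p_ini * _MMHG_TO_PA)
    return out


def tree_cost(tree: Tree, params: GrowthParams) -> float:
    """Material cost: sum over segments of length^mu * radius^lambda."""
    return sum(
        tree.segment_length(s) ** params.mu_exp * tree.radius[s] ** params.lambda_exp
        for s in tree.segment_ids
    )


# ---------------------------------------------------------------------------
# candidate sampling
# ---------------------------------------------------------------------------


def _positive_components(map_: VoxelGrid) -> np.ndarray:
    struct = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labels, _ = ndimage.label(np.asarray(map_.values) > 0, structure=struct)
    return labels


def _tree_voxel_labels(map_: VoxelGrid, tree: Tree, labels: np.ndarray) -> set[int]:
    """Component labels of positive-demand voxels within one voxel of the tree."""
    touched: set[int] = set()
    shape = np.asarray(map_.shape)
    pts: list[np.ndarray] = []
    for seg in tree.segment_ids:
        a, b = tree.segment_endpoints(seg)
        n = max(2, int(np.ceil(np.linalg.norm(b - a) / (0.5 * min(map_.spacing)))) + 1)
        ts = np.linspace(0.0, 1.0, n)
        pts.append(a[None, :] + ts[:, None] * (b - a)[None, :])
    if not pts:
        pts.append(tree.positions[tree.root_id][None, :])
    idx = np.rint((np.vstack(pts) - np.asarray(map_.origin)) / np.asarray(map_.spacing)).astype(int)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                nb = idx + np.array([di, dj, dk])
                ok = np.all((nb >= 0) & (nb < shape), axis=1)
                if ok.any():
                    lv = labels[nb[ok, 0], nb[ok, 1], nb[ok, 2]]
                    touched.update(int(v) for v in np.unique(lv) if v > 0)
    return touched


def oxygen_path_exists(map_: VoxelGrid, candidate, tree: Tree | None) -> bool:
    """True iff a 26-connected path of strictly positive demand joins the
    candidate's voxel to a voxel within one voxel of the tree."""
    vals = np.asarray(map_.values)
    idx = np.rint(map_.world_to_index(candidate)).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(map_.shape)):
        return False
    if vals[tuple(idx)] <= 0:
        return False
    labels = _positive_components(map_)
    if tree is None or not tree.segment_ids:
        return True
    touched = _tree_voxel_labels(map_, tree, labels)
    return int(labels[tuple(idx)]) in touched


class _DemandSampler:
    """Draws voxels proportionally to demand, with incremental demand updates."""

    def __init__(self, map_: VoxelGrid, rng: np.random.Generator):
        self.map = map_
        self.demand = np.asarray(map_.values, dtype=float).copy()
        self.rng = rng
        self._refresh()

    def _refresh(self) -> None:
        self.flat = self.demand.ravel()
        self.cum = np.cumsum(self.flat)
        self.total = self.cum[-1] if self.cum.size else 0.0

    def draw_voxel(self) -> tuple[int, int, int]:
        if self.total <= 0:
            raise GrowthExhaustedError("demand map has no positive mass left")
        u = self.rng.random() * self.total
        flat_idx = int(np.searchsorted(self.cum, u, side="right"))
        flat_idx = min(flat_idx, self.flat.size - 1)
        return np.unravel_index(flat_idx, self.demand.shape)  # type: ignore[return-value]

    def satisfy(self, position: np.ndarray, radius_mm: float, factor: float = 0.5) -> None:
        """Attenuate demand in a ball around a newly supplied terminal."""
        lo = np.floor(self.map.world_to_index(position - radius_mm)).astype(int)
        hi = np.ceil(self.map.world_to_index(position + radius_mm)).astype(int) + 1
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, np.asarray(self.map.shape))
        if np.any(lo >= hi):
            return
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        grids = np.meshgrid(
            *[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij", sparse=True
        )
        d2 = sum(
            ((g * s + o) - p) ** 2
            for g, s, o, p in zip(grids, self.map.spacing, self.map.origin, position)
        )
        self.demand[sl][d2 <= radius_mm**2] *= factor
        self._refresh()


def sample_terminal_candidate(
    map_: VoxelGrid,
    tree: Tree | None,
    params: GrowthParams,
    rng: np.random.Generator,
    *,
    _sampler: "_DemandSampler | None" = None,
    _labels: np.ndarray | None = None,
    _tree_labels: set[int] | None = None,
) -> np.ndarray:
    """Sample an admissible terminal candidate position (a voxel center).

    Admissibility: positive demand, Euclidean distance to the existing
    tree's surface at least ``D_T`` (new terminals may not sit inside or
    graze existing tubes), and a 26-connected positive-demand path to the
    tree.
    Sampling is rejection-based, so the accepted law is demand-proportional
    over the admissible set.  Raises GrowthExhaustedError after the
    rejection budget is spent.
    """
    sampler = _sampler or _DemandSampler(map_, rng)
    labels = _labels if _labels is not None else _positive_components(map_)
    tree_labels = _tree_labels
    if tree_labels is None and tree is not None and tree.segment_ids:
        tree_labels = _tree_voxel_labels(map_, tree, labels)

    for _ in range(params.rejection_budget):
        vox = sampler.draw_voxel()
        pos = map_.index_to_world(vox)
        if tree is not None and tree.min_surface_distance(pos) < params.d_t:
            continue
        if tree_labels is not None and int(labels[vox]) not in tree_labels:
            continue
        return pos
    raise GrowthExhaustedError(
        f"no admissible candidate after {params.rejection_budget} rejections"
    )


# ---------------------------------------------------------------------------
# attachment optimization
# ---------------------------------------------------------------------------


def _cost_of_attachment(
    tree: Tree, seg_id: int, t: float, candidate: np.ndarray, params: GrowthParams
) -> float:
    trial = tree.copy()
    _insert_bifurcation(trial, seg_id, t, candidate)
    hemodynamic_update(trial, params)
    return tree_cost(trial, params)


def _insert_bifurcation(tree: Tree, seg_id: int, t: float, candidate: np.ndarray) -> int:
    """Split segment ``seg_id`` at parameter ``t`` and attach the candidate.

    Returns the id of the new terminal node.  Mutates the tree; radii/flows
    must be refreshed afterwards via ``hemodynamic_update``.
    """
    a, b = tree.segment_endpoints(seg_id)
    bif_pos = a + t * (b - a)
    parent_id = tree.parent[seg_id]
    # new bifurcation node takes the place of seg_id under parent_id
    bif_id = tree._new_node(bif_pos)
    tree.parent[bif_id] = parent_id
    kids = tree.children[parent_id]
    kids[kids.index(seg_id)] = bif_id
    tree.parent[seg_id] = bif_id
    tree.children[bif_id] = [seg_id]
    tree.radius[bif_id] = tree.radius.get(seg_id, 0.0)
    tree.flow[bif_id] = tree.flow.get(seg_id, 0.0)
    term_id = tree.add_child(bif_id, candidate)
    return term_id


def optimal_attachment(
    tree: Tree, candidate, map_: VoxelGrid | None, params: GrowthParams
) -> dict:
    """Choose the segment and in-segment bifurcation point minimizing the
    material cost of the updated tree.

    Only the ``k_closest`` segments nearest to the candidate are examined.
    Along each, the cost is scanned on a coarse grid of interior points and
    refined by golden-section search; ties break toward the lowest segment
    id.  Returns ``{"segment": id, "t": t, "point": xyz, "cost": c}``.
    """
    cand = np.asarray(candidate, dtype=float)
    segs = tree.segment_ids
    if not segs:
        raise PreconditionError("tree has no segments to attach to")
    for nid, pos in tree.positions.items():
        if np.linalg.norm(pos - cand) < 1e-9:
            raise DegenerateCandidateError(f"candidate coincides with node {nid}")

    d = tree.distance_to_segments(cand)
    order = np.argsort(d, kind="stable")[: params.k_closest]
    t_lo, t_hi = 0.05, 0.95
    best: dict | None = None
    for oi in sorted(order):  # ascending segment-id iteration fixes the tie-break
        seg = segs[oi]
        # coarse scan at the oracle's resolution, then golden-section refine
        ts = np.linspace(t_lo, t_hi, 19)
        costs = [_cost_of_attachment(tree, seg, t, cand, params) for t in ts]
        i_min = int(np.argmin(costs))
        lo = ts[max(0, i_min - 1)]
        hi = ts[min(len(ts) - 1, i_min + 1)]
        t_best, c_best = _golden_section(
            lambda t: _cost_of_attachment(tree, seg, t, cand, params), lo, hi
        )
        if costs[i_min] < c_best:
            t_best, c_best = ts[i_min], costs[i_min]
        if best is None or c_best < best["cost"]:
            a, b = tree.segment_endpoints(seg)
            best = {
                "segment": seg,
                "t": float(t_best),
                "point": a + t_best * (b - a),
                "cost": float(c_best),
            }
    assert best is not None
    return best


def _golden_section(f, lo: float, hi: float, tol: float = 1e-3, max_iter: int = 40):
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    x1 = hi - invphi * (hi - lo)
    x2 = lo + invphi * (hi - lo)
    f1, f2 = f(x1), f(x2)
    for _ in range(max_iter):
        if hi - lo < tol:
            break
        if f1 <= f2:
            hi, x2, f2 = x2, x1, f1
            x1 = hi - invphi * (hi - lo)
            f1 = f(x1)
        else:
            lo, x1, f1 = x1, x2, f2
            x2 = lo + invphi * (hi - lo)
            f2 = f(x2)
    return (x1, f1) if f1 <= f2 else (x2, f2)


# ---------------------------------------------------------------------------
# full growth loop
# ---------------------------------------------------------------------------


def grow_tree(map_: VoxelGrid, params: GrowthParams) -> Tree:
    """Grow a tree with exactly ``params.n_terminals`` terminals under the map.

    Reproducible for identical (map, params, seed).  Raises
    GrowthExhaustedError if the map cannot support the requested count.
    """
    rng = np.random.default_rng(params.seed)
    sampler = _DemandSampler(map_, rng)
    labels = _positive_components(map_)

    tree = Tree.with_root(np.asarray(params.p0, dtype=float))
    if not map_.contains(params.p0):
        raise PreconditionError(f"perfusion point {params.p0} outside grid")

    # first terminal: no path constraint yet (no segments exist)
    first = sample_terminal_candidate(
        map_, tree, params, rng, _sampler=sampler, _labels=labels, _tree_labels=None
    )
    first_id = tree.add_child(tree.root_id, first)
    hemodynamic_update(tree, params)
    sampler.satisfy(tree.positions[first_id], 2.0 * params.d_t)
    tree_labels = _tree_voxel_labels(map_, tree, labels)

    while tree.n_terminals < params.n_terminals:
        rejections = 0
        while True:
            cand = sample_terminal_candidate(
                map_,
                tree,
                params,
                rng,
                _sampler=sampler,
                _labels=labels,
                _tree_labels=tree_labels,
            )
            try:
                plan = optimal_attachment(tree, cand, map_, params)
            except DegenerateCandidateError:
                rejections += 1
                if rejections >= params.rejection_budget:
                    raise GrowthExhaustedError("all candidates degenerate")
                continue
            break
        term_id = _insert_bifurcation(tree, plan["segment"], plan["t"], cand)
        hemodynamic_update(tree, params)
        sampler.satisfy(tree.positions[term_id], 2.0 * params.d_t)
        # the two new segments may touch new demand components
        tree_labels |= _tree_voxel_labels(map_, tree, labels)

    tree.validate()
    return tree


def airway_terminal_count(n_f_art: int, fa: int) -> int:
    """Airway terminal count from the arterial count and the airway factor FA.

    Airways are given a fraction ``1/FA`` of the arterio-venous terminal
    count (rounded up), mimicking the earlier CT invisibility of small
    airways.
    """
    if n_f_art < 1 or fa < 1:
        raise PreconditionError("require N_f >= 1 and FA >= 1")
    return -(-n_f_art // fa)
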