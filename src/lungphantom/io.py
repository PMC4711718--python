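"""Volume and tree input/output.

Volumes are exchanged as NRRD, MetaImage (.mha/.mhd) or NIfTI through
SimpleITK, preserving spacing and origin.  Arrays are kept in (x, y, z)
index order matching :class:`~lungphantom.grid.VoxelGrid`.  Trees use a
line-oriented text format (one node per line) plus a GML export for graph
tooling.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .grid import FormatError, VoxelGrid
from .tree_growth import Tree

_VOLUME_EXTENSIONS = (".nrrd", ".mha", ".mhd", ".nii", ".nii.gz")


def _extension(path: str) -> str:
    name = str(path).lower()
    for ext in _VOLUME_EXTENSIONS:
        if name.endswith(ext):
            return ext
    raise FormatError(f"unsupported volume extension: {path}")


def _check_geometry_header(path: str, ext: str) -> None:
    """Fail loudly when a file carries no spacing information.

    SimpleITK silently substitutes unit spacing, so the text headers of
    NRRD/MetaImage files are sniffed for their geometry keys.
    """
    if ext in (".nii", ".nii.gz"):
        return  # NIfTI always stores pixdim
    with open(path, "rb") as fh:
        header = fh.read(4096)
    if ext == ".nrrd":
        if b"space directions" not in header and b"spacings" not in header:
            raise FormatError(f"{path}: NRRD header lacks spacing information")
    else:  # .mha / .mhd
        if b"ElementSpacing" not in header and b"ElementSize" not in header:
            raise FormatError(f"{path}: MetaImage header lacks ElementSpacing")


def read_volume(path: str) -> VoxelGrid:
    """Read a volume; raises FormatError on unknown or geometry-less files."""
    ext = _extension(path)
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    _check_geometry_header(path, ext)
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    values = np.ascontiguousarray(arr.transpose(2, 1, 0))
    return VoxelGrid(values, spacing=img.GetSpacing(), origin=img.GetOrigin())


def write_volume(grid: VoxelGrid, path: str, metadata: dict | None = None) -> None:
    """Write a volume (float arrays as float32, integer arrays unchanged)."""
    _extension(path)
    vals = np.asarray(grid.values)
    if vals.dtype.kind == "f":
        vals = vals.astype(np.float32)
    elif vals.dtype == bool:
        vals = vals.astype(np.uint8)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vals.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    for key, value in (metadata or {}).items():
        img.SetMetaData(str(key), str(value))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))


# ---------------------------------------------------------------------------
# tree serialization
# ---------------------------------------------------------------------------

_TREE_HEADER = "# id parent x y z radius flow role"


def write_tree(tree: Tree, path: str) -> None:
    lines = [_TREE_HEADER]
    for nid in tree.node_ids:
        parent = tree.parent[nid]
        x, y, z = (float(v) for v in tree.positions[nid])
        radius = float(tree.radius.get(nid, 0.0))
        flow = float(tree.flow.get(nid, 0.0))
        lines.append(
            f"{nid} {-1 if parent is None else parent} "
            f"{x!r} {y!r} {z!r} {radius!r} {flow!r} {tree.role(nid)}"
        )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n")


def read_tree(path: str) -> Tree:
    tree = Tree()
    max_id = -1
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        nid, parent = int(fields[0]), int(fields[1])
        pos = np.array([float(fields[2]), float(fields[3]), float(fields[4])])
        tree.positions[nid] = pos
        tree.parent[nid] = None if parent < 0 else parent
        tree.children.setdefault(nid, [])
        if parent >= 0:
            tree.children.setdefault(parent, []).append(nid)
            tree.radius[nid] = float(fields[5])
            tree.flow[nid] = float(fields[6])
        else:
            tree.root_id = nid
        max_id = max(max_id, nid)
    tree._next_id = max_id + 1
    # children insertion order must not depend on file order
    for k in tree.children:
        tree.children[k].sort()
    return tree


def tree_to_networkx(tree: Tree):
    """Directed graph view of the tree (for GML export and graph tooling)."""
    import networkx as nx

    g = nx.DiGraph()
    for nid in tree.node_ids:
        x, y, z = (float(v) for v in tree.positions[nid])
        g.add_node(nid, x=x, y=y, z=z, role=tree.role(nid))
    for seg in tree.segment_ids:
        g.add_edge(
            tree.parent[seg],
            seg,
            radius=float(tree.radius.get(seg, 0.0)),
            flow=float(tree.flow.get(seg, 0.0)),
        )
    return g


def write_tree_gml(tree: Tree, path: str) -> None:
    import networkx as nx

    nx.write_gml(tree_to_networkx(tree), str(path))
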