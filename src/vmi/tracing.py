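"""Vessel tree extraction from binary masks.

Replaces an interactive filament tracer with a deterministic pipeline:
topological thinning, skeleton-graph extraction, spur pruning, and rooted
traversal from the widest endpoint of each connected component.  Branch depth
starts at 1 for the root branch and increments at every junction; branch
diameter is estimated from the Euclidean distance transform along the
centerline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import skeletonize

from vmi.volume_io import VesselMask

logger = logging.getLogger(__name__)

_NEIGHBOR_OFFSETS = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
)


@dataclass
class Branch:
    """One traced vessel branch (centerline segment between tree nodes)."""

    id: int
    parent_id: int | None
    depth: int
    centerline: np.ndarray  # (n, 3) physical (z, y, x) coordinates in µm
    mean_diameter: float  # µm
    length: float  # µm
    is_terminal: bool
    component: int = 0

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=np.float64)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 3:
            raise ValueError("centerline must be an (n, 3) array")


@dataclass
class VesselTree:
    """A rooted branch forest: one root branch per connected component."""

    branches: list[Branch]
    root_ids: list[int]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.spacing = tuple(float(s) for s in self.spacing)
        self._by_id = {b.id: b for b in self.branches}
        if len(self._by_id) != len(self.branches):
            raise ValueError("duplicate branch ids")

    def branch(self, branch_id: int) -> Branch:
        return self._by_id[branch_id]

    def children(self, branch_id: int) -> list[Branch]:
        return [b for b in self.branches if b.parent_id == branch_id]

    def children_map(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {b.id: [] for b in self.branches}
        for b in self.branches:
            if b.parent_id is not None:
                out[b.parent_id].append(b.id)
        return out

    @property
    def max_depth(self) -> int:
        return max((b.depth for b in self.branches), default=0)

    def validate(self) -> None:
        """Assert forest structure, the depth law, and positive lengths."""
        ids = set(self._by_id)
        for b in self.branches:
            if b.parent_id is None:
                if b.id not in self.root_ids:
                    raise AssertionError(f"parentless branch {b.id} not listed as root")
                if b.depth != 1:
                    raise AssertionError(f"root branch {b.id} has depth {b.depth} != 1")
            else:
                if b.parent_id not in ids:
                    raise AssertionError(f"branch {b.id} has unknown parent {b.parent_id}")
                parent = self._by_id[b.parent_id]
                if b.depth != parent.depth + 1:
                    raise AssertionError(
                        f"depth law violated: {b.id} depth {b.depth}, parent depth {parent.depth}"
                    )
            if b.length <= 0:
                raise AssertionError(f"branch {b.id} has non-positive length")
        cmap = self.children_map()
        for b in self.branches:
            if b.is_terminal != (len(cmap[b.id]) == 0):
                raise AssertionError(f"is_terminal flag wrong on branch {b.id}")
        # acyclicity: parent pointers must reach a root without revisiting
        for b in self.branches:
            seen = set()
            cur: Branch | None = b
            while cur is not None and cur.parent_id is not None:
                if cur.id in seen:
                    raise AssertionError("cycle in parent pointers")
                seen.add(cur.id)
                cur = self._by_id[cur.parent_id]


def skeletonize_mask(mask: VesselMask) -> np.ndarray:
    """3D topological thinning; returns a boolean skeleton grid inside the mask.

    Raises
    ------
    ValueError
        If the mask is empty.
    """
    if not mask.voxels.any():
        raise ValueError("cannot skeletonize an empty mask")
    skel = skeletonize(mask.voxels)
    return skel.astype(bool)


def _resample_isotropic(mask: VesselMask) -> tuple[np.ndarray, float]:
    """Resample an anisotropic mask to the finest spacing; returns (grid, iso µm)."""
    sz, sy, sx = mask.spacing
    iso = min(mask.spacing)
    if max(mask.spacing) / iso <= 1.01:
        return mask.voxels, float(np.mean(mask.spacing))
    zoom = (sz / iso, sy / iso, sx / iso)
    grid = ndi.zoom(mask.voxels.astype(np.float32), zoom, order=1) > 0.5
    logger.info("resampled %s -> %s at %.3g µm isotropic", mask.shape, grid.shape, iso)
    return grid, iso


def _voxel_graph(skel: np.ndarray) -> tuple[nx.Graph, np.ndarray]:
    """26-connectivity graph over skeleton voxels; nodes are coordinate tuples."""
    coords = np.argwhere(skel)
    coord_set = {tuple(c) for c in coords.tolist()}
    g = nx.Graph()
    g.add_nodes_from(coord_set)
    for c in sorted(coord_set):
        cz, cy, cx = c
        for dz, dy, dx in _NEIGHBOR_OFFSETS:
            n = (cz + dz, cy + dy, cx + dx)
            if n > c and n in coord_set:
                g.add_edge(c, n)
    return g, coords


class _SegmentGraph:
    """Intermediate skeleton topology: nodes are endpoints or merged junction
    clusters, edges carry centerline voxel paths."""

    def __init__(self) -> None:
        self.graph = nx.MultiGraph()

    @staticmethod
    def from_voxel_graph(g: nx.Graph) -> "_SegmentGraph":
        deg = dict(g.degree())
        junction_voxels = {v for v, d in deg.items() if d >= 3}
        end_voxels = {v for v, d in deg.items() if d == 1}
        sg = _SegmentGraph()
        h = sg.graph

        # merge adjacent junction voxels into single nodes
        jcomp: dict[tuple, int] = {}
        for i, comp in enumerate(
            sorted(nx.connected_components(g.subgraph(junction_voxels)), key=min)
        ):
            for v in comp:
                jcomp[v] = i
            rep = min(comp)
            h.add_node(("j", i), voxels=sorted(comp), rep=rep)
        for v in sorted(end_voxels):
            h.add_node(("e", v), voxels=[v], rep=v)

        def node_of(v):
            if v in jcomp:
                return ("j", jcomp[v])
            if v in end_voxels:
                return ("e", v)
            return None

        visited_edges = set()

        def walk(start_voxel, first_step):
            """Follow a degree-2 chain from start_voxel through first_step."""
            path = [start_voxel, first_step]
            prev, cur = start_voxel, first_step
            while node_of(cur) is None:
                nxt = None
                for n in sorted(g.neighbors(cur)):
                    if n != prev and (node_of(n) is not None or deg[n] == 2):
                        nxt = n
                        break
                if nxt is None:
                    break  # dead end inside a chain (shouldn't happen)
                path.append(nxt)
                prev, cur = cur, nxt
            return path

        for v in sorted(g.nodes):
            a = node_of(v)
            if a is None:
                continue
            for nb in sorted(g.neighbors(v)):
                if node_of(nb) == a:
                    continue  # internal junction-cluster edge
                key = (min(v, nb), max(v, nb))
                if key in visited_edges:
                    continue
                if node_of(nb) is not None:
                    # direct node-to-node contact
                    visited_edges.add(key)
                    h.add_edge(a, node_of(nb), path=[v, nb])
                else:
                    path = walk(v, nb)
                    for p, q in zip(path, path[1:]):
                        visited_edges.add((min(p, q), max(p, q)))
                    b = node_of(path[-1])
                    if b is None:
                        continue  # open chain fragment; ignore
                    h.add_edge(a, b, path=path)
        return sg

    def merge_degree2_junctions(self) -> None:
        """Collapse junction nodes left with exactly two segments into one segment."""
        h = self.graph
        changed = True
        while changed:
            changed = False
            for node in sorted(n for n in h.nodes if n[0] == "j"):
                if h.degree(node) != 2:
                    continue
                edges = list(h.edges(node, keys=True, data=True))
                if len(edges) != 2:
                    continue
                (u1, v1, k1, d1), (u2, v2, k2, d2) = edges
                o1 = v1 if u1 == node else u1
                o2 = v2 if u2 == node else u2
                if o1 == node or o2 == node:
                    continue  # self loop; leave alone
                p1 = d1["path"] if d1["path"][-1] in _voxset(h, node) else d1["path"][::-1]
                p2 = d2["path"] if d2["path"][0] in _voxset(h, node) else d2["path"][::-1]
                merged = p1 + [v for v in h.nodes[node]["voxels"] if v not in (p1[-1], p2[0])] + p2
                h.remove_edge(u1, v1, k1)
                h.remove_edge(u2, v2, k2)
                h.remove_node(node)
                h.add_edge(o1, o2, path=merged)
                changed = True
                break

    def prune_spurs(
        self, edt: np.ndarray, iso: float, prune_below: float | None
    ) -> int:
        """Iteratively remove terminal segments shorter than the threshold.

        With ``prune_below=None`` the threshold adapts to the local vessel
        size: a spur is dropped when shorter than four times the inscribed
        radius at its junction (i.e. twice the local diameter).
        Returns the number of segments removed.
        """
        h = self.graph
        removed = 0
        while True:
            victims = []
            for u, v, k, d in h.edges(keys=True, data=True):
                du, dv = h.degree(u), h.degree(v)
                if du != 1 and dv != 1:
                    continue
                if du == 1 and dv == 1:
                    continue  # lone segment: never prune a whole component
                leaf, junc = (u, v) if du == 1 else (v, u)
                if junc[0] != "j":
                    continue
                length = _path_length(d["path"], iso)
                if prune_below is not None:
                    thr = prune_below
                else:
                    jr = max(edt[vox] for vox in h.nodes[junc]["voxels"])
                    thr = 4.0 * jr  # 2 × local diameter
                if length < thr:
                    victims.append((u, v, k, leaf))
            if not victims:
                break
            for u, v, k, leaf in victims:
                if h.has_edge(u, v, k):
                    h.remove_edge(u, v, k)
                    removed += 1
                if leaf in h.nodes and h.degree(leaf) == 0:
                    h.remove_node(leaf)
            self.merge_degree2_junctions()
        # drop junction nodes orphaned by pruning
        for node in list(self.graph.nodes):
            if self.graph.degree(node) == 0 and node[0] == "j":
                self.graph.remove_node(node)
        return removed


def _voxset(h: nx.MultiGraph, node) -> set:
    return set(h.nodes[node]["voxels"])


def _path_length(path: list[tuple], iso: float) -> float:
    pts = np.asarray(path, dtype=np.float64) * iso
    if len(pts) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def _segment_diameter(path: list[tuple], edt: np.ndarray, iso: float) -> float:
    """2 × upper-quartile inscribed radius along the centerline.

    End voxels are trimmed by one local radius (they sit inside junction
    blobs or terminal caps where the distance transform tapers).  The 75th
    percentile rather than the mean counters the downward bias of discrete
    skeletons: thinning places voxels up to half a voxel off the true axis,
    which depresses the distance-transform reading everywhere along the
    branch (measured ~10% at 2-3 voxel radii on rasterized cylinders).
    """
    vals = np.array([edt[v] for v in path], dtype=np.float64)
    k = max(1, int(np.ceil(vals.max() / iso)))
    if len(vals) - 2 * k >= 3:
        core = vals[k:-k]
    elif len(vals) >= 5:
        core = vals[1:-1]
    else:
        core = vals
    return float(2.0 * np.percentile(core, 75))


def build_tree(
    mask: VesselMask,
    prune_below: float | None = None,
) -> VesselTree:
    """Trace a binary vessel mask into a rooted branch forest.

    Steps: resample to isotropic resolution if needed, thin to a skeleton,
    extract the segment graph, iteratively prune short spurs, root each
    connected component at the endpoint with the largest inscribed radius,
    and assign depths by traversal (root branch depth 1, +1 at each junction).

    Parameters
    ----------
    mask : VesselMask
    prune_below : float or None
        Fixed spur-length threshold in µm; ``None`` (default) adapts the
        threshold to twice the local vessel diameter.

    Raises
    ------
    ValueError
        If the mask is empty or ``prune_below`` is negative.
    """
    if not mask.voxels.any():
        raise ValueError("cannot trace an empty mask")
    if prune_below is not None and prune_below < 0:
        raise ValueError("prune_below must be >= 0")

    grid, iso = _resample_isotropic(mask)
    skel = skeletonize(grid).astype(bool)
    edt = ndi.distance_transform_edt(grid, sampling=(iso, iso, iso))

    g, _ = _voxel_graph(skel)
    sg = _SegmentGraph.from_voxel_graph(g)
    sg.merge_degree2_junctions()
    n_pruned = sg.prune_spurs(edt, iso, prune_below)
    if n_pruned:
        logger.info("pruned %d spur segments", n_pruned)
    h = sg.graph

    branches: list[Branch] = []
    root_ids: list[int] = []
    next_id = 0
    n_cycle_edges = 0

    components = sorted(nx.connected_components(h), key=lambda c: min(h.nodes[n]["rep"] for n in c))
    for comp_idx, comp in enumerate(components):
        sub = h.subgraph(comp)
        endpoints = [n for n in sub.nodes if sub.degree(n) == 1]
        if not endpoints:
            if sub.number_of_edges() > 0:
                logger.warning("component %d is a pure loop; skipped", comp_idx)
            continue
        # root = endpoint with largest inscribed radius; ties by voxel order
        root_node = min(endpoints, key=lambda n: (-edt[h.nodes[n]["rep"]], h.nodes[n]["rep"]))

        visited_nodes = {root_node}
        visited_edges = set()
        # stack entries: (node, incoming branch id, incoming depth)
        stack = [(root_node, None, 0)]
        while stack:
            node, parent_branch, depth = stack.pop()
            # deterministic order by the far node's representative voxel
            out_edges = sorted(
                sub.edges(node, keys=True),
                key=lambda e: (h.nodes[e[1] if e[0] == node else e[0]]["rep"], e[2]),
            )
            for u, v, k in out_edges:
                ekey = (frozenset((u, v)), k)
                if ekey in visited_edges:
                    continue
                other = v if u == node else u
                if other in visited_nodes:
                    n_cycle_edges += 1
                    visited_edges.add(ekey)
                    continue
                visited_edges.add(ekey)
                visited_nodes.add(other)
                d = sub.get_edge_data(u, v, k)
                path = d["path"]
                if path[0] not in _voxset(h, node):
                    path = path[::-1]
                length = _path_length(path, iso)
                if length <= 0:
                    continue
                b = Branch(
                    id=next_id,
                    parent_id=parent_branch,
                    depth=depth + 1,
                    centerline=np.asarray(path, dtype=np.float64) * iso,
                    mean_diameter=_segment_diameter(path, edt, iso),
                    length=length,
                    is_terminal=True,  # fixed after traversal
                    component=comp_idx,
                )
                branches.append(b)
                if parent_branch is None:
                    root_ids.append(b.id)
                next_id += 1
                stack.append((other, b.id, b.depth))

    if n_cycle_edges:
        logger.warning("broke %d cycle edge(s) during traversal", n_cycle_edges)

    has_children = {b.parent_id for b in branches if b.parent_id is not None}
    for b in branches:
        b.is_terminal = b.id not in has_children

    tree = VesselTree(branches=branches, root_ids=root_ids, spacing=mask.spacing)
    tree.validate()
    return tree


def branch_table(tree: VesselTree) -> pd.DataFrame:
    """One row per branch, deterministically ordered (component, depth, id)."""
    rows = [
        {
            "branch_id": b.id,
            "parent_id": b.parent_id,
            "component": b.component,
            "depth": b.depth,
            "mean_diameter_um": b.mean_diameter,
            "length_um": b.length,
            "is_terminal": b.is_terminal,
            "n_points": len(b.centerline),
        }
        for b in tree.branches
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "branch_id",
            "parent_id",
            "component",
            "depth",
            "mean_diameter_um",
            "length_um",
            "is_terminal",
            "n_points",
        ],
    )
    df["parent_id"] = df["parent_id"].astype("Int64")
    return df.sort_values(["component", "depth", "branch_id"]).reset_index(drop=True)


# --- SWC export / import -----------------------------------------------------

_SWC_TYPE = 2  # fixed structure code for all vessel samples


def write_swc(tree: VesselTree, path) -> None:
    """Write the tree as SWC: one sample per centerline point, radius = diameter/2.

    SWC columns: id, type, x, y, z, radius, parent (coordinates in µm,
    x/y/z from the volume's x/y/z axes).
    """
    lines = ["# id type x y z radius parent"]
    sample_id = 1
    last_sample_of_branch: dict[int, int] = {}
    for b in sorted(tree.branches, key=lambda b: b.id):
        r = b.mean_diameter / 2.0
        pts = b.centerline
        start = 0
        if b.parent_id is not None:
            parent_sample = last_sample_of_branch[b.parent_id]
        else:
            parent_sample = -1
        for i in range(start, len(pts)):
            z, y, x = pts[i]
            lines.append(
                f"{sample_id} {_SWC_TYPE} {x:.6g} {y:.6g} {z:.6g} {r:.6g} {parent_sample}"
            )
            parent_sample = sample_id
            sample_id += 1
        last_sample_of_branch[b.id] = sample_id - 1
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_swc(path, spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> VesselTree:
    """Read an SWC file back into a branch forest.

    Branches are split wherever a sample has multiple children; depths are
    recomputed from the topology (roots at depth 1).
    """
    samples: dict[int, tuple[float, float, float, float, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            sid, _t = int(parts[0]), int(parts[1])
            x, y, z, r = (float(p) for p in parts[2:6])
            parent = int(parts[6])
            samples[sid] = (z, y, x, r, parent)

    children: dict[int, list[int]] = {sid: [] for sid in samples}
    roots = []
    for sid, (_, _, _, _, parent) in samples.items():
        if parent == -1:
            roots.append(sid)
        else:
            children[parent].append(sid)

    branches: list[Branch] = []
    root_ids: list[int] = []
    next_id = 0
    for comp_idx, root in enumerate(sorted(roots)):
        stack = [(root, None, 1)]
        while stack:
            start, parent_branch, depth = stack.pop()
            pts = []
            radii = []
            cur = start
            while True:
                z, y, x, r, _ = samples[cur]
                pts.append((z, y, x))
                radii.append(r)
                kids = children[cur]
                if len(kids) == 1:
                    cur = kids[0]
                else:
                    break
            arr = np.asarray(pts, dtype=np.float64)
            seg = np.diff(arr, axis=0)
            length = float(np.sum(np.linalg.norm(seg, axis=1))) if len(arr) > 1 else 0.0
            b = Branch(
                id=next_id,
                parent_id=parent_branch,
                depth=depth,
                centerline=arr,
                mean_diameter=float(2 * np.mean(radii)),
                length=length if length > 0 else 1e-9,
                is_terminal=len(children[cur]) == 0,
                component=comp_idx,
            )
            branches.append(b)
            if parent_branch is None:
                root_ids.append(b.id)
            next_id += 1
            for kid in sorted(children[cur]):
                stack.append((kid, b.id, depth + 1))
    return VesselTree(branches=branches, root_ids=root_ids, spacing=spacing)
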