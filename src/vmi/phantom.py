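"""Synthetic vascular phantoms: cube-law branching trees rasterized as dark
tubes in a noisy, unevenly illuminated fluorescent foreground.

The generator is the validation surface for the whole pipeline: it emits the
intensity volume, the ground-truth vessel mask, and the generating tree, all
deterministic functions of the spec and its seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from vmi.tracing import Branch, VesselTree
from vmi.volume_io import ImageVolume, VesselMask

logger = logging.getLogger(__name__)


@dataclass
class PhantomSpec:
    """Generative parameters for a synthetic organ volume.

    Daughter diameters at each bifurcation satisfy
    ``d1**m + d2**m == D**m`` with ``m = murray_exponent``; the split between
    daughters is controlled by ``asymmetry`` (0 = equal daughters).  Branch
    length scales with diameter via ``branch_length_ratio``.  Vessels are dark
    tubes (hemoglobin quenches the autofluorescent foreground).
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (10.0, 10.0, 10.0)
    levels: int = 4
    root_diameter: float = 60.0  # µm
    murray_exponent: float = 3.0
    asymmetry: float = 0.15
    terminal_prob: float = 0.5
    branch_length_ratio: float = 8.0
    tortuosity: float = 0.15  # radians of angular jitter
    branching_angle: float = 0.6  # radians, half-angle between daughters
    foreground_intensity: float = 30000.0
    vessel_intensity: float = 6000.0
    noise_sd: float = 1500.0
    illumination_amplitude: float = 0.2
    noise_model: str = "gaussian"  # or "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.root_diameter <= 0:
            raise ValueError("root_diameter must be > 0")
        if self.murray_exponent <= 0:
            raise ValueError("murray_exponent must be > 0")
        if not (0 <= self.asymmetry < 1):
            raise ValueError("asymmetry must be in [0, 1)")
        if not (0 <= self.terminal_prob <= 1):
            raise ValueError("terminal_prob must be in [0, 1]")
        if self.vessel_intensity >= self.foreground_intensity:
            raise ValueError("vessel_intensity must be below foreground_intensity")
        if not (0 <= self.illumination_amplitude < 1):
            raise ValueError("illumination_amplitude must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError("noise_model must be 'gaussian' or 'poisson'")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @staticmethod
    def from_json(text: str) -> "PhantomSpec":
        return PhantomSpec(**json.loads(text))


def _daughter_diameters(d: float, m: float, asymmetry: float) -> tuple[float, float]:
    """Split a parent of diameter d into two daughters conserving d**m."""
    w1 = (1.0 + asymmetry) / 2.0
    w2 = (1.0 - asymmetry) / 2.0
    return d * w1 ** (1.0 / m), d * w2 ** (1.0 / m)


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)


def _perpendicular(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A random unit vector perpendicular to v."""
    while True:
        r = rng.normal(size=3)
        p = r - np.dot(r, v) * v
        n = np.linalg.norm(p)
        if n > 1e-6:
            return p / n


def generate_tree(spec: PhantomSpec) -> VesselTree:
    """Generate a binary branching tree obeying the configured diameter law.

    The root starts near one corner of the volume and grows toward the
    opposite corner; daughters branch at ``branching_angle`` on either side of
    the parent direction with seeded angular jitter.  If the tree escapes the
    volume, branch lengths are shrunk geometrically and generation retried;
    an error is raised if it still cannot fit.
    """
    extent = np.array(spec.shape, dtype=float) * np.array(spec.spacing, dtype=float)
    for attempt in range(12):
        scale = 0.85**attempt
        tree = _generate_tree_once(spec, scale)
        _center_in_volume(tree, extent)
        if _fits(tree, extent):
            if attempt:
                logger.info("tree fitted after shrinking lengths by %.3f", scale)
            return tree
    raise ValueError("tree escapes the volume even after rescaling attempts")


def _center_in_volume(tree: VesselTree, extent: np.ndarray) -> None:
    """Translate the tree so its radius-padded bounding box is centered."""
    lo = np.full(3, np.inf)
    hi = np.full(3, -np.inf)
    for b in tree.branches:
        r = b.mean_diameter / 2.0
        lo = np.minimum(lo, b.centerline.min(axis=0) - r)
        hi = np.maximum(hi, b.centerline.max(axis=0) + r)
    shift = (extent - (hi + lo)) / 2.0 - 0.0
    for b in tree.branches:
        b.centerline = b.centerline + shift


def _generate_tree_once(spec: PhantomSpec, length_scale: float) -> VesselTree:
    rng = np.random.default_rng(spec.seed)
    extent = np.array(spec.shape, dtype=float) * np.array(spec.spacing, dtype=float)

    margin = spec.root_diameter
    start = np.full(3, 1.0) * margin
    direction = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)

    branches: list[Branch] = []
    next_id = [0]

    def grow(
        p0: np.ndarray,
        d: np.ndarray,
        diameter: float,
        depth: int,
        parent: int | None,
        may_terminate: bool,
    ):
        # Early termination makes the forest depth-heterogeneous, so the
        # per-depth cubed-diameter sums vary and a branching-law line can be
        # fitted.  The first daughter of every bifurcation never terminates
        # early, guaranteeing at least one path reaching `levels`.
        terminal_here = (
            may_terminate
            and depth < spec.levels
            and spec.terminal_prob > 0
            and rng.random() < spec.terminal_prob
        )
        length = spec.branch_length_ratio * diameter * length_scale
        # gentle pull toward the volume center keeps deep branches inside
        center_pull = extent / 2.0 - p0
        norm = np.linalg.norm(center_pull)
        if norm > 0:
            d = d + 0.15 * center_pull / norm
            d = d / np.linalg.norm(d)
        if spec.tortuosity > 0:
            axis = _perpendicular(d, rng)
            d = _rotate(d, axis, rng.normal(0.0, spec.tortuosity))
            d = d / np.linalg.norm(d)
        p1 = p0 + d * length
        b = Branch(
            id=next_id[0],
            parent_id=parent,
            depth=depth,
            centerline=np.stack([p0, p1]),
            mean_diameter=diameter,
            length=length,
            is_terminal=(depth == spec.levels or terminal_here),
            component=0,
        )
        branches.append(b)
        my_id = next_id[0]
        next_id[0] += 1
        if not b.is_terminal:
            d1, d2 = _daughter_diameters(diameter, spec.murray_exponent, spec.asymmetry)
            axis = _perpendicular(d, rng)
            jitter1 = rng.normal(0.0, spec.tortuosity) if spec.tortuosity > 0 else 0.0
            jitter2 = rng.normal(0.0, spec.tortuosity) if spec.tortuosity > 0 else 0.0
            dir1 = _rotate(d, axis, spec.branching_angle + jitter1)
            dir2 = _rotate(d, axis, -spec.branching_angle + jitter2)
            grow(p1, dir1 / np.linalg.norm(dir1), d1, depth + 1, my_id, False)
            grow(p1, dir2 / np.linalg.norm(dir2), d2, depth + 1, my_id, True)

    grow(start, direction, spec.root_diameter, 1, None, False)
    tree = VesselTree(branches=branches, root_ids=[0], spacing=spec.spacing)
    tree.validate()
    return tree


def _fits(tree: VesselTree, extent: np.ndarray) -> bool:
    for b in tree.branches:
        r = b.mean_diameter / 2.0
        lo = b.centerline.min(axis=0) - r
        hi = b.centerline.max(axis=0) + r
        if (lo < 0).any() or (hi > extent).any():
            return False
    return True


def rasterize_tree(tree: VesselTree, spec: PhantomSpec) -> tuple[ImageVolume, VesselMask]:
    """Rasterize a tree into (intensity volume, ground-truth mask).

    The mask is the union of capsules (cylinders with hemispherical caps)
    along each branch centerline.  The image is foreground outside vessels and
    vessel intensity inside, modulated by a smooth separable illumination
    field and corrupted by seeded noise, clipped to the 16-bit range.
    """
    shape = spec.shape
    sp = np.array(spec.spacing)
    mask = np.zeros(shape, dtype=bool)

    # voxel-center physical coordinates per axis
    axes = [np.arange(n) * s for n, s in zip(shape, sp)]

    for b in tree.branches:
        r = b.mean_diameter / 2.0
        for p0, p1 in zip(b.centerline[:-1], b.centerline[1:]):
            lo = np.minimum(p0, p1) - r - sp
            hi = np.maximum(p0, p1) + r + sp
            sl = tuple(
                slice(
                    max(int(np.floor(lo[i] / sp[i])), 0),
                    min(int(np.ceil(hi[i] / sp[i])) + 1, shape[i]),
                )
                for i in range(3)
            )
            zz = axes[0][sl[0]][:, None, None]
            yy = axes[1][sl[1]][None, :, None]
            xx = axes[2][sl[2]][None, None, :]
            seg = p1 - p0
            seg_len2 = float(seg @ seg)
            dz, dy, dx = zz - p0[0], yy - p0[1], xx - p0[2]
            if seg_len2 == 0:
                dist2 = dz**2 + dy**2 + dx**2
            else:
                t = (dz * seg[0] + dy * seg[1] + dx * seg[2]) / seg_len2
                t = np.clip(t, 0.0, 1.0)
                dist2 = (
                    (dz - t * seg[0]) ** 2 + (dy - t * seg[1]) ** 2 + (dx - t * seg[2]) ** 2
                )
            mask[sl] |= dist2 <= r * r

    img = np.where(mask, spec.vessel_intensity, spec.foreground_intensity).astype(np.float64)

    if spec.illumination_amplitude > 0:
        field = np.ones(shape)
        for ax in range(3):
            u = np.linspace(-1.0, 1.0, shape[ax])
            # low-order polynomial, peaked mid-volume: 1 - a/3·u²  per axis
            mod = 1.0 - (spec.illumination_amplitude / 3.0) * u**2
            shp = [1, 1, 1]
            shp[ax] = shape[ax]
            field = field * mod.reshape(shp)
        img *= field / field.max()

    rng = np.random.default_rng([spec.seed, 0xA5])  # independent noise stream
    if spec.noise_model == "poisson":
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=shape)
    elif spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=shape)

    img = np.clip(img, 0.0, 65535.0)
    voxels = np.floor(img + 0.5).astype(np.uint16)
    volume = ImageVolume(voxels, spec.spacing, channel="NADH", bit_depth=16)
    return volume, VesselMask(mask, spec.spacing, source_channel="NADH")


def make_phantom(spec: PhantomSpec) -> tuple[ImageVolume, VesselMask, VesselTree]:
    """Generate and rasterize a phantom; deterministic given the spec (incl. seed)."""
    tree = generate_tree(spec)
    volume, mask = rasterize_tree(tree, spec)
    return volume, mask, tree
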