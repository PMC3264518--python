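"""Seeded synthetic line-scan scenes with known ground truth.

The generator emulates what the inspection cameras see: bright, roughly
elliptical rice kernels lying flat on a dark conveyor belt, occasionally
touching in small clusters, together with thin branch fragments and
sub-kernel hull fragments left over from threshing. A whole per-plant series
is rendered on one tall canvas (the belt) and then cut into frames, which is
what a continuously acquiring line camera does and is why objects can span
consecutive tiles.

Default kernel geometry follows long-grain indica rice at the camera
calibration of 0.23 mm/px: a 7.3 x 3.3 mm grain is a 31.9 x 14.4 px ellipse.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as _draw_ellipse, polygon as _draw_polygon
from skimage.measure import label as _sk_label

from .segmentation import DEFAULT_MM_PER_PX, GrayTile


class SceneOverflowError(RuntimeError):
    """Raised when requested objects cannot be placed without collisions."""


@dataclass(frozen=True)
class SceneParams:
    """Rendering parameters for one synthetic tile (or tall series canvas)."""

    tile_height_px: int = 1000
    tile_width_px: int = 512
    n_isolated: int = 40
    touching_clusters: tuple[int, ...] = ()
    n_branches: int = 2
    n_broken_hulls: int = 2
    kernel_axes_px: tuple[float, float] = (31.9, 14.4)  # full major/minor axis
    axis_jitter: float = 0.05
    belt_gray: int = 20
    kernel_gray: int = 200
    noise_sd: float = 8.0
    border_spanning: bool = False
    seed: int = 0
    max_attempts: int = 300
    branch_width_px: float = 3.0
    branch_length_px: tuple[float, float] = (40.0, 120.0)
    fragment_area_range: tuple[float, float] = (0.20, 0.45)

    def validate(self) -> None:
        if self.tile_height_px < 8 or self.tile_width_px < 8:
            raise ValueError("tile dimensions too small")
        if min(self.n_isolated, self.n_branches, self.n_broken_hulls) < 0:
            raise ValueError("object counts must be non-negative")
        if any(size < 2 for size in self.touching_clusters):
            raise ValueError("touching cluster sizes must be >= 2")
        if not (0 <= self.belt_gray <= 255 and 0 <= self.kernel_gray <= 255):
            raise ValueError("gray levels must lie in [0, 255]")
        if self.kernel_gray <= self.belt_gray:
            raise ValueError("kernels must be brighter than the belt")
        if self.kernel_axes_px[0] < self.kernel_axes_px[1]:
            raise ValueError("kernel major axis must be >= minor axis")
        lo, hi = self.fragment_area_range
        if not 0 < lo < hi < 0.5:
            raise ValueError("fragment areas must lie strictly below half a kernel")

    @property
    def mean_kernel_area(self) -> float:
        major, minor = self.kernel_axes_px
        return float(np.pi * (major / 2) * (minor / 2))


@dataclass
class PlacedObject:
    """One rendered object with its geometry in canvas coordinates."""

    kind: str  # "kernel" | "branch" | "fragment"
    coords: np.ndarray  # (n, 2) pixel coordinates, canvas frame
    center: tuple[float, float]
    major_px: float = 0.0
    minor_px: float = 0.0
    cluster_id: int | None = None

    @property
    def row_span(self) -> tuple[int, int]:
        rows = self.coords[:, 0]
        return int(rows.min()), int(rows.max())


@dataclass
class SceneTruth:
    """Ground truth for one tile or one rendered series."""

    n_kernels: int
    n_isolated: int
    cluster_sizes: list[int]
    objects: list[PlacedObject]
    tile_shape: tuple[int, int]
    per_tile_counts: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.n_kernels == self.n_isolated + sum(self.cluster_sizes)

    @property
    def kernels(self) -> list[PlacedObject]:
        return [o for o in self.objects if o.kind == "kernel"]

    @property
    def impurities(self) -> list[PlacedObject]:
        return [o for o in self.objects if o.kind != "kernel"]

    @property
    def kernel_axes_px(self) -> np.ndarray:
        """(n_kernels, 2) array of true full major/minor axes in px."""
        return np.array([[k.major_px, k.minor_px] for k in self.kernels])

    def to_dict(self) -> dict:
        return {
            "n_kernels": self.n_kernels,
            "n_isolated": self.n_isolated,
            "cluster_sizes": list(self.cluster_sizes),
            "per_tile_counts": list(self.per_tile_counts),
            "tile_shape": list(self.tile_shape),
            "kernel_axes_px": self.kernel_axes_px.tolist(),
            "impurities": [
                {"kind": o.kind, "center": list(o.center), "area": len(o.coords)}
                for o in self.impurities
            ],
        }


@dataclass
class PlantTruth:
    """Ground truth for a whole plant: one total and one filled series."""

    total: SceneTruth
    filled: SceneTruth
    mm_per_px: float = DEFAULT_MM_PER_PX

    @property
    def nts(self) -> int:
        return self.total.n_kernels

    @property
    def nfs(self) -> int:
        return self.filled.n_kernels

    @property
    def seed_setting_rate(self) -> float:
        return self.nfs / self.nts

    @property
    def mean_gl_mm(self) -> float:
        return float(self.filled.kernel_axes_px[:, 0].mean() * self.mm_per_px)

    @property
    def mean_gw_mm(self) -> float:
        return float(self.filled.kernel_axes_px[:, 1].mean() * self.mm_per_px)

    def to_dict(self) -> dict:
        return {
            "nts": self.nts,
            "nfs": self.nfs,
            "seed_setting_rate": self.seed_setting_rate,
            "mean_gl_mm": self.mean_gl_mm,
            "mean_gw_mm": self.mean_gw_mm,
            "total": self.total.to_dict(),
            "filled": self.filled.to_dict(),
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


# ---------------------------------------------------------------------------
# placement engine

_GAP_PX = 2  # minimum background gap between distinct objects


def _directional_radius(semi_major: float, semi_minor: float, phi: float) -> float:
    """Radius of an ellipse along direction phi measured from its major axis."""
    return semi_major * semi_minor / np.hypot(
        semi_minor * np.cos(phi), semi_major * np.sin(phi)
    )


def _collides(occupied: np.ndarray, rr: np.ndarray, cc: np.ndarray) -> bool:
    r0 = max(int(rr.min()) - _GAP_PX, 0)
    r1 = min(int(rr.max()) + _GAP_PX + 1, occupied.shape[0])
    c0 = max(int(cc.min()) - _GAP_PX, 0)
    c1 = min(int(cc.max()) + _GAP_PX + 1, occupied.shape[1])
    sub = occupied[r0:r1, c0:c1]
    if not sub.any():
        return False
    cand = np.zeros(sub.shape, dtype=bool)
    cand[rr - r0, cc - c0] = True
    struct = np.ones((2 * _GAP_PX + 1,) * 2, dtype=bool)
    return bool((ndimage.binary_dilation(cand, structure=struct) & sub).any())


def _valid(
    shape: tuple[int, int],
    forbidden_rows: np.ndarray,
    rr: np.ndarray,
    cc: np.ndarray,
) -> bool:
    if rr.size == 0:
        return False
    if rr.min() < 0 or rr.max() >= shape[0]:
        return False
    if cc.min() < _GAP_PX or cc.max() >= shape[1] - _GAP_PX:
        return False
    return not forbidden_rows[rr].any()


class _Placer:
    def __init__(
        self,
        shape: tuple[int, int],
        params: SceneParams,
        rng: np.random.Generator,
        forbidden_rows: np.ndarray,
    ):
        self.shape = shape
        self.params = params
        self.rng = rng
        self.forbidden_rows = forbidden_rows
        self.occupied = np.zeros(shape, dtype=bool)
        self.objects: list[PlacedObject] = []
        self._next_cluster = 0

    # -- samplers -----------------------------------------------------------
    def _sample_axes(self) -> tuple[float, float]:
        j = self.params.axis_jitter
        major = self.params.kernel_axes_px[0] * self.rng.uniform(1 - j, 1 + j)
        minor = self.params.kernel_axes_px[1] * self.rng.uniform(1 - j, 1 + j)
        return max(major, minor), min(major, minor)

    def _sample_center(self, half_extent: float) -> tuple[float, float]:
        h, w = self.shape
        r = self.rng.uniform(half_extent + 1, h - half_extent - 2)
        c = self.rng.uniform(half_extent + _GAP_PX + 1, w - half_extent - _GAP_PX - 2)
        return r, c

    def _paint(self, obj: PlacedObject) -> None:
        self.occupied[obj.coords[:, 0], obj.coords[:, 1]] = True
        self.objects.append(obj)

    def _fail(self, what: str) -> SceneOverflowError:
        return SceneOverflowError(
            f"could not place {what} after {self.params.max_attempts} attempts; "
            "the scene is overcrowded"
        )

    # -- kernels ------------------------------------------------------------
    def _kernel_pixels(
        self, center: tuple[float, float], major: float, minor: float, theta: float
    ) -> tuple[np.ndarray, np.ndarray]:
        return _draw_ellipse(
            center[0], center[1], major / 2, minor / 2, rotation=theta
        )

    def place_kernel(
        self, cluster_id: int | None = None, center_row: float | None = None
    ) -> PlacedObject:
        for _ in range(self.params.max_attempts):
            major, minor = self._sample_axes()
            theta = self.rng.uniform(0, np.pi)
            r, c = self._sample_center(major / 2)
            if center_row is not None:
                r = center_row
            rr, cc = self._kernel_pixels((r, c), major, minor, theta)
            if not _valid(self.shape, self.forbidden_rows, rr, cc):
                continue
            if _collides(self.occupied, rr, cc):
                continue
            obj = PlacedObject(
                kind="kernel",
                coords=np.column_stack([rr, cc]),
                center=(r, c),
                major_px=major,
                minor_px=minor,
                cluster_id=cluster_id,
            )
            self._paint(obj)
            return obj
        raise self._fail("an isolated kernel")

    def place_cluster(self, size: int) -> list[PlacedObject]:
        """Place ``size`` kernels forming one connected component.

        Members are appended next to a random existing member so the
        component connects while interpenetration stays small: real touching
        kernels abut rather than overlap, which is what keeps cluster areas
        approximately additive and the area quotient meaningful.
        """
        cluster_id = self._next_cluster
        self._next_cluster += 1
        max_overlap = 0.05  # fraction of a new member's area
        local = np.zeros(self.shape, dtype=bool)  # scratch, reset per attempt
        for _ in range(self.params.max_attempts):
            members: list[tuple[tuple[float, float], float, float, float, np.ndarray]] = []
            ok = True
            for i in range(size):
                placed = False
                for _ in range(self.params.max_attempts):
                    major, minor = self._sample_axes()
                    theta = self.rng.uniform(0, np.pi)
                    if i == 0:
                        r, c = self._sample_center(major * size / 2)
                    else:
                        anc_center, anc_maj, anc_min, anc_th, _ = members[
                            self.rng.integers(len(members))
                        ]
                        phi = self.rng.uniform(0, 2 * np.pi)
                        d = self.rng.uniform(0.92, 1.05) * (
                            _directional_radius(anc_maj / 2, anc_min / 2, phi - anc_th)
                            + _directional_radius(major / 2, minor / 2, phi - theta)
                        )
                        r = anc_center[0] + d * np.sin(phi)
                        c = anc_center[1] + d * np.cos(phi)
                    rr, cc = self._kernel_pixels((r, c), major, minor, theta)
                    if not _valid(self.shape, self.forbidden_rows, rr, cc):
                        continue
                    if _collides(self.occupied, rr, cc):
                        continue
                    if i > 0:
                        overlap = int(local[rr, cc].sum())
                        if overlap > max_overlap * rr.size:
                            continue  # interpenetrating too deeply
                        touching = overlap > 0
                        if not touching:
                            for dr in (-1, 0, 1):
                                for dc in (-1, 0, 1):
                                    if local[
                                        np.clip(rr + dr, 0, self.shape[0] - 1),
                                        np.clip(cc + dc, 0, self.shape[1] - 1),
                                    ].any():
                                        touching = True
                                        break
                                if touching:
                                    break
                        if not touching:
                            continue
                    members.append(((r, c), major, minor, theta, np.column_stack([rr, cc])))
                    local[rr, cc] = True
                    placed = True
                    break
                if not placed:
                    ok = False
                    break
            if not ok:
                if members:
                    painted = np.vstack([m[4] for m in members])
                    local[painted[:, 0], painted[:, 1]] = False
                continue
            allc = np.vstack([m[4] for m in members])
            r0, c0 = allc.min(axis=0)
            crop = local[r0 : allc[:, 0].max() + 1, c0 : allc[:, 1].max() + 1]
            connected = _sk_label(crop, connectivity=2).max() == 1
            local[allc[:, 0], allc[:, 1]] = False  # reset scratch
            if not connected:
                continue  # discretization gap split the cluster; retry
            placed_objs = []
            for (center, major, minor, _theta, coords) in members:
                obj = PlacedObject(
                    kind="kernel",
                    coords=coords,
                    center=center,
                    major_px=major,
                    minor_px=minor,
                    cluster_id=cluster_id,
                )
                self._paint(obj)
                placed_objs.append(obj)
            return placed_objs
        raise self._fail(f"a touching cluster of size {size}")

    # -- impurities ---------------------------------------------------------
    def place_branch(self) -> PlacedObject:
        for _ in range(self.params.max_attempts):
            length = self.rng.uniform(*self.params.branch_length_px)
            width = self.params.branch_width_px
            alpha = self.rng.uniform(0, np.pi)
            r, c = self._sample_center(length / 2)
            u = np.array([np.sin(alpha), np.cos(alpha)])
            v = np.array([-np.cos(alpha), np.sin(alpha)])
            corners = np.array(
                [
                    [r, c] + (length / 2) * u + (width / 2) * v,
                    [r, c] + (length / 2) * u - (width / 2) * v,
                    [r, c] - (length / 2) * u - (width / 2) * v,
                    [r, c] - (length / 2) * u + (width / 2) * v,
                ]
            )
            rr, cc = _draw_polygon(corners[:, 0], corners[:, 1])
            if not _valid(self.shape, self.forbidden_rows, rr, cc):
                continue
            if _collides(self.occupied, rr, cc):
                continue
            obj = PlacedObject(
                kind="branch", coords=np.column_stack([rr, cc]), center=(r, c)
            )
            self._paint(obj)
            return obj
        raise self._fail("a branch")

    def place_fragment(self) -> PlacedObject:
        """Half-ellipse crescent with area a configured fraction of a kernel."""
        for _ in range(self.params.max_attempts):
            frac = self.rng.uniform(*self.params.fragment_area_range)
            scale = np.sqrt(2 * frac)
            major, minor = self._sample_axes()
            a, b = scale * major / 2, scale * minor / 2
            theta = self.rng.uniform(0, np.pi)
            r, c = self._sample_center(a)
            rr, cc = _draw_ellipse(r, c, a, b, rotation=theta)
            # keep one side of the major axis
            normal = np.array([np.cos(theta), np.sin(theta)])
            side = (rr - r) * normal[0] + (cc - c) * normal[1] >= 0
            rr, cc = rr[side], cc[side]
            if not _valid(self.shape, self.forbidden_rows, rr, cc):
                continue
            if _collides(self.occupied, rr, cc):
                continue
            obj = PlacedObject(
                kind="fragment", coords=np.column_stack([rr, cc]), center=(r, c)
            )
            self._paint(obj)
            return obj
        raise self._fail("a hull fragment")


def _render(
    shape: tuple[int, int],
    params: SceneParams,
    placer: _Placer,
    rng: np.random.Generator,
) -> np.ndarray:
    img = np.full(shape, float(params.belt_gray))
    img[placer.occupied] = float(params.kernel_gray)
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _edge_forbidden(height: int) -> np.ndarray:
    forbidden = np.zeros(height, dtype=bool)
    forbidden[:2] = True
    forbidden[-2:] = True
    return forbidden


def generate_tile(params: SceneParams) -> tuple[GrayTile, SceneTruth]:
    """Render one tile and its ground truth; bit-identical for a fixed seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    shape = (params.tile_height_px, params.tile_width_px)
    placer = _Placer(shape, params, rng, _edge_forbidden(shape[0]))
    for _ in range(params.n_isolated):
        placer.place_kernel()
    for size in params.touching_clusters:
        placer.place_cluster(size)
    for _ in range(params.n_branches):
        placer.place_branch()
    for _ in range(params.n_broken_hulls):
        placer.place_fragment()
    img = _render(shape, params, placer, rng)
    n_kernels = params.n_isolated + sum(params.touching_clusters)
    truth = SceneTruth(
        n_kernels=n_kernels,
        n_isolated=params.n_isolated,
        cluster_sizes=list(params.touching_clusters),
        objects=placer.objects,
        tile_shape=shape,
        per_tile_counts=[n_kernels],
    )
    return GrayTile(img, tile_index=0), truth


def _cluster_sizes_for(
    n_kernels: int,
    cluster_fraction: float,
    size_range: tuple[int, int],
    rng: np.random.Generator,
) -> tuple[int, list[int]]:
    target = int(np.floor(cluster_fraction * n_kernels))
    sizes: list[int] = []
    remaining = target
    while remaining >= size_range[0]:
        s = int(rng.integers(size_range[0], size_range[1] + 1))
        s = min(s, remaining)
        if s < size_range[0]:
            break
        sizes.append(s)
        remaining -= s
    return n_kernels - sum(sizes), sizes


def _generate_series(
    params: SceneParams,
    n_tiles: int,
    n_isolated: int,
    cluster_sizes: list[int],
    seed: int,
) -> tuple[list[GrayTile], SceneTruth]:
    """Render one camera series on a tall belt canvas and cut it into tiles."""
    h, w = params.tile_height_px, params.tile_width_px
    tall = (n_tiles * h, w)
    rng = np.random.default_rng(seed)
    forbidden = _edge_forbidden(tall[0])
    if not params.border_spanning:
        for k in range(1, n_tiles):
            forbidden[k * h - _GAP_PX : k * h + _GAP_PX] = True
    placer = _Placer(tall, params, rng, forbidden)

    spans_placed = 0
    if params.border_spanning and n_isolated > 0 and n_tiles > 1:
        # guarantee at least one kernel straddling a tile border
        cut = int(rng.integers(1, n_tiles)) * h
        placer.place_kernel(center_row=cut + rng.uniform(-2, 2))
        spans_placed = 1
    for _ in range(n_isolated - spans_placed):
        placer.place_kernel()
    for size in cluster_sizes:
        placer.place_cluster(size)
    for _ in range(params.n_branches * n_tiles):
        placer.place_branch()
    for _ in range(params.n_broken_hulls * n_tiles):
        placer.place_fragment()

    img = _render(tall, params, placer, rng)
    tiles = [
        GrayTile(img[k * h : (k + 1) * h], tile_index=k) for k in range(n_tiles)
    ]
    per_tile = [0] * n_tiles
    for obj in placer.objects:
        if obj.kind == "kernel":
            per_tile[obj.row_span[0] // h] += 1
    truth = SceneTruth(
        n_kernels=n_isolated + sum(cluster_sizes),
        n_isolated=n_isolated,
        cluster_sizes=cluster_sizes,
        objects=placer.objects,
        tile_shape=(h, w),
        per_tile_counts=per_tile,
    )
    return tiles, truth


def generate_plant_series(
    params: SceneParams,
    n_total_tiles: int = 14,
    n_filled_tiles: int = 20,
    *,
    n_total_kernels: int | None = None,
    fill_fraction: float = 0.8,
    cluster_fraction: float = 0.2,
    cluster_size_range: tuple[int, int] = (2, 4),
    seed: int = 0,
) -> tuple[list[GrayTile], list[GrayTile], PlantTruth]:
    """Render the two camera series of one plant.

    When ``n_total_kernels`` is given, that many kernels (with
    ``cluster_fraction`` of them grouped into touching clusters) are spread
    over the total series and ``round(fill_fraction * NTS)`` over the filled
    series; otherwise each tile carries the composition stated in ``params``.
    """
    params.validate()
    if n_total_tiles < 1 or n_filled_tiles < 1:
        raise ValueError("each series needs at least one tile")
    if not 0 < fill_fraction <= 1:
        raise ValueError("fill_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    seed_total, seed_filled = rng.integers(0, 2**31 - 1, size=2)

    if n_total_kernels is None:
        per_tile = params.n_isolated + sum(params.touching_clusters)
        nts = per_tile * n_total_tiles
        iso_t = params.n_isolated * n_total_tiles
        clus_t = list(params.touching_clusters) * n_total_tiles
    else:
        nts = int(n_total_kernels)
        iso_t, clus_t = _cluster_sizes_for(
            nts, cluster_fraction, cluster_size_range, rng
        )
    nfs = int(round(fill_fraction * nts))
    iso_f, clus_f = _cluster_sizes_for(nfs, cluster_fraction, cluster_size_range, rng)

    total_tiles, total_truth = _generate_series(
        params, n_total_tiles, iso_t, clus_t, int(seed_total)
    )
    filled_tiles, filled_truth = _generate_series(
        params, n_filled_tiles, iso_f, clus_f, int(seed_filled)
    )
    return total_tiles, filled_tiles, PlantTruth(total_truth, filled_truth)
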