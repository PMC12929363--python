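"""Multi-scale markers: pattern family, schedules, projector-frame rendering.

A multi-scale marker (MSM) is one projector-image location ``p`` at which
the same square fiducial symbol is projected at several scales
``lambda in Lambda``, every instance obtained from the base pattern by the
planar scaling ``s(x) = lambda * (x - p) + p``. The scaling fixes ``p``
exactly, so every instance shares one center and a camera that can decode
*any* scale localizes the same physical floor point.

The fiducial family used here (``msq25``) is a square binary marker: a
7x7 cell grid with a one-cell black border and a 5x5 payload encoding a
12-bit symbol id plus a 13-bit checksum. Ids whose payload could be confused
with another valid codeword under a 90-degree rotation are excluded from the
usable id list, making decoding rotation-unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .exceptions import ScheduleError
from .geometry import Homography, apply_homography, scaling_homography

__all__ = [
    "MarkerDictionary",
    "PatternSpec",
    "MSMSpec",
    "ProjectionSchedule",
    "make_msm",
    "make_schedule",
    "render_projector_frame",
    "floor_coordinates",
    "DEFAULT_SCALES",
    "FAST_SCALES",
]

# Seven scale factors spanning 5 cm to 40 cm markers at a 5 cm base side.
DEFAULT_SCALES = (1.0, 1.4, 2.0, 3.0, 4.0, 6.0, 8.0)
# Three scales are sufficient in most scenarios and cut projection time.
FAST_SCALES = (1.0, 2.8, 8.0)

_GRID = 7  # cells per marker side (border included)
_PAYLOAD = 5  # payload cells per side
_ID_BITS = 12
_CHECK_BITS = 13


def _checksum(ids: np.ndarray) -> np.ndarray:
    """13-bit mixing checksum of a 12-bit id (splitmix-style)."""
    x = ids.astype(np.uint64)
    x = (x + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x ^= x >> np.uint64(30)
    x = (x * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x ^= x >> np.uint64(27)
    x = (x * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x ^= x >> np.uint64(31)
    return (x & np.uint64((1 << _CHECK_BITS) - 1)).astype(np.int64)


def _codewords(ids: np.ndarray) -> np.ndarray:
    """25-bit codewords (id << 13 | checksum) for an array of ids."""
    ids = np.asarray(ids, dtype=np.int64)
    return (ids << _CHECK_BITS) | _checksum(ids)


def _bits_from_code(code: int) -> np.ndarray:
    """Codeword -> 5x5 payload bit grid, MSB first, row-major."""
    bits = (code >> np.arange(_PAYLOAD * _PAYLOAD - 1, -1, -1)) & 1
    return bits.reshape(_PAYLOAD, _PAYLOAD).astype(np.uint8)


def _code_from_bits(bits: np.ndarray) -> int:
    weights = 1 << np.arange(_PAYLOAD * _PAYLOAD - 1, -1, -1, dtype=np.int64)
    return int((bits.ravel().astype(np.int64) * weights).sum())


class MarkerDictionary:
    """The ``msq25`` square binary fiducial family.

    Provides bit grids for rendering, codeword decoding with rotation
    disambiguation, and the list of rotation-safe symbol ids.
    """

    name = "msq25"
    grid = _GRID
    id_range = 1 << _ID_BITS

    def __init__(self):
        ids = np.arange(self.id_range)
        codes = _codewords(ids)
        valid = set(codes.tolist())
        # mark ids whose rotated payload decodes as some valid codeword
        bits = np.array([_bits_from_code(int(c)) for c in codes])
        unsafe = np.zeros(self.id_range, dtype=bool)
        # near-solid payloads render as featureless blobs; exclude them
        popcount = bits.reshape(self.id_range, -1).sum(axis=1)
        unsafe |= (popcount < 5) | (popcount > 20)
        for rot in (1, 2, 3):
            rb = np.rot90(bits, k=rot, axes=(1, 2))
            rcodes = [
                _code_from_bits(rb[i]) for i in range(self.id_range)
            ]
            for i, rc in enumerate(rcodes):
                if rc in valid:
                    unsafe[i] = True
                    unsafe[rc >> _CHECK_BITS] = True
        self.safe_ids = ids[~unsafe]
        self._code_to_id = {int(c): int(i) for i, c in zip(ids, codes)}

    def bit_grid(self, symbol_id: int) -> np.ndarray:
        """Full 7x7 cell grid (0=black, 1=white) including the border."""
        if not 0 <= symbol_id < self.id_range:
            raise ValueError(f"symbol id {symbol_id} out of range")
        g = np.zeros((_GRID, _GRID), dtype=np.uint8)
        g[1:-1, 1:-1] = _bits_from_code(int(_codewords(np.array([symbol_id]))[0]))
        return g

    def decode(self, payload_bits: np.ndarray) -> tuple[int, int] | None:
        """Decode a 5x5 payload; returns (symbol_id, rotation) or None.

        ``rotation`` is the number of counterclockwise 90-degree turns that
        maps the observed payload onto the canonical orientation.
        """
        for rot in range(4):
            code = _code_from_bits(np.rot90(payload_bits, k=rot))
            sid = self._code_to_id.get(code)
            if sid is not None and sid in self._safe_set:
                return sid, rot
        return None

    @property
    def _safe_set(self):
        s = getattr(self, "_safe_cache", None)
        if s is None:
            s = set(self.safe_ids.tolist())
            self._safe_cache = s
        return s


@lru_cache(maxsize=1)
def default_dictionary() -> MarkerDictionary:
    return MarkerDictionary()


@dataclass(frozen=True)
class PatternSpec:
    """A square fiducial symbol with its geometric center.

    ``base_side`` is the physical side length on the floor (meters) of the
    unit-scale instance.
    """

    family: str = "msq25"
    symbol_id: int = 0
    base_side: float = 0.05

    def __post_init__(self):
        if self.base_side <= 0:
            raise ValueError("base_side must be positive")

    def corners(self, side: float, center: np.ndarray) -> np.ndarray:
        """Axis-aligned outer corners (TL, TR, BR, BL) at a given side."""
        c = np.asarray(center, dtype=float)
        h = side / 2.0
        return c + np.array([[-h, -h], [h, -h], [h, h], [-h, h]])


@dataclass(frozen=True)
class MSMSpec:
    """One multi-scale marker: a center, a symbol, and its scale set."""

    marker_id: int
    pattern: PatternSpec
    center_p: tuple[float, float]
    scales: tuple[float, ...]

    def __post_init__(self):
        sc = tuple(float(s) for s in self.scales)
        if len(sc) < 1 or any(s <= 0 for s in sc):
            raise ValueError("scales must be non-empty and positive")
        if any(b <= a for a, b in zip(sc, sc[1:])):
            raise ValueError("scales must be strictly increasing")
        object.__setattr__(self, "scales", sc)
        object.__setattr__(self, "center_p", tuple(float(c) for c in self.center_p))

    def instance_corners(self, scale_idx: int, base_px: float) -> np.ndarray:
        """Outer corners (projector px) of the instance at ``scales[scale_idx]``.

        Obtained by applying the scaling homography fixed at ``center_p`` to
        the unit-scale corners, which is what guarantees the common center.
        """
        lam = self.scales[scale_idx]
        p = np.asarray(self.center_p)
        base = self.pattern.corners(base_px, p)
        S = scaling_homography(p, lam)
        return S(base)

    def side_lengths_m(self) -> np.ndarray:
        """Physical side length on the floor for every scale."""
        return self.pattern.base_side * np.asarray(self.scales)


@dataclass
class ProjectionSchedule:
    """Timed sequence of MSM arrays projected onto the floor.

    ``arrays[i]`` is the list of MSMs projected together in slot ``i``;
    within a slot the scales are projected in ascending order.
    """

    arrays: list[list[MSMSpec]]
    scales: tuple[float, ...]
    projector_resolution: tuple[int, int] = (1920, 1080)
    base_px: float = 40.0  # marker side in projector px at scale 1
    slot_duration: float = 0.1  # seconds per (array, scale) projection
    array_offsets: np.ndarray = field(default_factory=lambda: np.zeros((1, 2)))

    def __post_init__(self):
        ids = [m.marker_id for arr in self.arrays for m in arr]
        if len(set(ids)) != len(ids):
            raise ScheduleError("duplicate marker ids in schedule")
        centers = {m.center_p for arr in self.arrays for m in arr}
        if len(centers) != len(ids):
            raise ScheduleError("duplicate marker centers after offsetting")

    @property
    def n_arrays(self) -> int:
        return len(self.arrays)

    @property
    def markers_per_array(self) -> int:
        return len(self.arrays[0]) if self.arrays else 0

    def all_markers(self) -> list[MSMSpec]:
        return [m for arr in self.arrays for m in arr]

    def centers(self) -> np.ndarray:
        """(N, 2) projector-pixel centers ordered by marker_id."""
        ms = sorted(self.all_markers(), key=lambda m: m.marker_id)
        return np.array([m.center_p for m in ms])

    def marker_by_symbol(self) -> dict[int, MSMSpec]:
        return {m.pattern.symbol_id: m for m in self.all_markers()}


def make_msm(
    pattern: PatternSpec, p, scales=DEFAULT_SCALES, marker_id: int = 0
) -> MSMSpec:
    """Build one MSM whose scaled instances all fix the center ``p``."""
    return MSMSpec(
        marker_id=marker_id,
        pattern=pattern,
        center_p=tuple(np.asarray(p, dtype=float)),
        scales=tuple(sorted(float(s) for s in scales)),
    )


def make_schedule(
    n_arrays: int = 100,
    markers_per_array: int = 32,
    grid_shape: tuple[int, int] = (8, 4),
    projector_resolution: tuple[int, int] = (1920, 1080),
    scales=DEFAULT_SCALES,
    base_side: float = 0.05,
    base_px: float = 40.0,
    slot_duration: float = 0.1,
    margin_px: float = 60.0,
    dictionary: MarkerDictionary | None = None,
) -> ProjectionSchedule:
    """Dense floor-grid schedule: a base grid of markers, offset per array.

    The base array is a ``grid_shape`` grid spanning the projector image
    inside ``margin_px``. Per-array offsets cycle through a near-square
    sub-grid of one base cell, so ``n_arrays`` arrays tile each cell densely;
    the default 100 arrays x 32 markers yield 3200 distinct centers.
    Marker ids encode (array, within-array) position injectively as
    ``array_idx * markers_per_array + within_idx``.
    """
    nx, ny = grid_shape
    if nx * ny != markers_per_array:
        raise ScheduleError(
            f"grid {nx}x{ny} does not hold {markers_per_array} markers"
        )
    dictionary = dictionary or default_dictionary()
    n_markers = n_arrays * markers_per_array
    if n_markers > len(dictionary.safe_ids):
        raise ScheduleError(
            f"schedule needs {n_markers} symbols, dictionary has "
            f"{len(dictionary.safe_ids)} rotation-safe ids"
        )
    W, H = projector_resolution
    cw = (W - 2 * margin_px) / nx
    ch = (H - 2 * margin_px) / ny
    # offsets cycle an ox x oy sub-grid of the base cell
    ox = int(np.ceil(np.sqrt(n_arrays)))
    oy = int(np.ceil(n_arrays / ox))
    offsets = np.array(
        [((a % ox) * cw / ox, (a // ox) * ch / oy) for a in range(n_arrays)]
    )
    scales = tuple(sorted(float(s) for s in scales))
    arrays: list[list[MSMSpec]] = []
    for a in range(n_arrays):
        arr = []
        for w in range(markers_per_array):
            i, j = w % nx, w // nx
            cx = margin_px + i * cw + cw / (2 * ox) + offsets[a, 0]
            cy = margin_px + j * ch + ch / (2 * oy) + offsets[a, 1]
            mid = a * markers_per_array + w
            pat = PatternSpec(
                family=dictionary.name,
                symbol_id=int(dictionary.safe_ids[mid]),
                base_side=base_side,
            )
            arr.append(
                MSMSpec(marker_id=mid, pattern=pat, center_p=(cx, cy), scales=scales)
            )
        arrays.append(arr)
    return ProjectionSchedule(
        arrays=arrays,
        scales=scales,
        projector_resolution=projector_resolution,
        base_px=base_px,
        slot_duration=slot_duration,
        array_offsets=offsets,
    )


def _rasterize_marker(frame, corners, grid, supersample=4):
    """Draw one axis-aligned square marker into ``frame`` with antialiasing.

    ``corners`` are the outer quad (TL, TR, BR, BL) in pixel coordinates;
    cells are sampled at ``supersample^2`` points per pixel.
    """
    H, W = frame.shape
    x0 = max(int(np.floor(corners[:, 0].min())), 0)
    x1 = min(int(np.ceil(corners[:, 0].max())) + 1, W)
    y0 = max(int(np.floor(corners[:, 1].min())), 0)
    y1 = min(int(np.ceil(corners[:, 1].max())) + 1, H)
    if x0 >= x1 or y0 >= y1:
        return
    side = corners[1, 0] - corners[0, 0]
    ox, oy = corners[0]
    n = _GRID
    ss = supersample
    xs = np.arange(x0, x1)
    ys = np.arange(y0, y1)
    sub = (np.arange(ss) + 0.5) / ss - 0.5
    gx = (xs[None, :, None] + sub[None, None, :]).reshape(1, -1)  # (1, w*ss)
    gy = (ys[:, None, None] + sub[None, None, :]).reshape(-1, 1)  # (h*ss, 1)
    u = (gx - ox) / side * n
    v = (gy - oy) / side * n
    inside = (u >= 0) & (u < n) & (v >= 0) & (v < n)
    ui = np.clip(u.astype(int), 0, n - 1)
    vi = np.clip(v.astype(int), 0, n - 1)
    val = np.where(inside, grid[np.broadcast_arrays(vi, ui)[0], np.broadcast_arrays(vi, ui)[1]], 1.0)
    val = val.reshape(y1 - y0, ss, x1 - x0, ss).mean(axis=(1, 3))
    region = frame[y0:y1, x0:x1]
    # markers darken the white background; overlapping markers multiply
    frame[y0:y1, x0:x1] = np.minimum(region, val)


def render_projector_frame(
    schedule: ProjectionSchedule,
    array_idx: int,
    scale_idx: int,
    dictionary: MarkerDictionary | None = None,
    supersample: int = 4,
) -> tuple[np.ndarray, list[dict]]:
    """Rasterize one (array, scale) slot to a grayscale projector frame.

    Returns ``(image, metadata)``: image is float in [0, 1] at projector
    resolution (white background, dark marker cells); metadata carries, per
    marker, its id, stored center, outer corners, and a ``clipped`` flag set
    when the instance exceeds the frame boundary.
    """
    dictionary = dictionary or default_dictionary()
    W, H = schedule.projector_resolution
    frame = np.ones((H, W))
    meta = []
    for m in schedule.arrays[array_idx]:
        corners = m.instance_corners(scale_idx, schedule.base_px)
        clipped = bool(
            corners[:, 0].min() < 0
            or corners[:, 1].min() < 0
            or corners[:, 0].max() > W
            or corners[:, 1].max() > H
        )
        grid = dictionary.bit_grid(m.pattern.symbol_id).astype(float)
        _rasterize_marker(frame, corners, grid, supersample=supersample)
        meta.append(
            {
                "marker_id": m.marker_id,
                "symbol_id": m.pattern.symbol_id,
                "center": m.center_p,
                "corners": corners,
                "clipped": clipped,
            }
        )
    return frame, meta


def default_floor_homography(
    schedule: ProjectionSchedule, px_per_meter: float = 800.0
) -> Homography:
    """Canonical projector-pixel -> floor-meters map for a ceiling projector.

    Centered on the projector image, x right. The v (image-down) axis maps
    to -Y: a projector aimed straight down inverts its vertical axis on the
    floor, which is what makes cameras above the floor observe the markers
    in canonical (unmirrored) orientation.
    """
    W, H = schedule.projector_resolution
    s = 1.0 / px_per_meter
    return Homography(
        np.array(
            [
                [s, 0.0, -W / 2.0 * s],
                [0.0, -s, H / 2.0 * s],
                [0.0, 0.0, 1.0],
            ]
        )
    )


def floor_coordinates(
    schedule: ProjectionSchedule, g_proj: Homography | np.ndarray
) -> list[tuple[int, np.ndarray]]:
    """Map marker centers through the projector-to-floor homography.

    Returns ``(marker_id, X)`` with ``X`` a 3-point in the floor frame,
    ``z = 0`` exactly.
    """
    Hm = g_proj.matrix if isinstance(g_proj, Homography) else np.asarray(g_proj)
    if abs(np.linalg.det(Hm)) < 1e-15:
        raise ValueError("projector-to-floor homography is singular")
    out = []
    for m in sorted(schedule.all_markers(), key=lambda m: m.marker_id):
        xy = apply_homography(Hm, np.asarray(m.center_p))
        out.append((m.marker_id, np.array([xy[0], xy[1], 0.0])))
    return out
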