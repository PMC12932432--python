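"""Stimulation regions and pulse protocols.

A :class:`RegionMask` is a polygonal region of the 2D substrate; its
member neurons are those whose positions fall inside the polygon
(computed exactly, independent of any raster resolution). A
:class:`StimulusProtocol` delivers periodic voltage pulses to the
members (or a fixed random subset of them): at each pulse onset every
targeted neuron's membrane potential is incremented by ``amplitude`` mV
for one time step.

Optionally a per-neuron response latency (in ms, added to every onset)
models heterogeneous activation timing of the stimulated population;
latencies are fixed per neuron so repeated pulses preserve their
relative order.

Fixture shapes ship with fixed parametric definitions (a face-shaped
polygon with eye/nose/mouth openings, cue rectangles covering 20% of the
trained region, square/triangle projection regions, an association
rectangle pair, and a circular partial cue) so every experiment is
reproducible from a seed; no analysis statistic depends on the specific
shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import shapely
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union

from .geometry import NetworkGeometry
from .params import ConfigurationError


@dataclass(frozen=True)
class RegionMask:
    """Polygonal spatial mask (um coordinates)."""

    polygon: object  # shapely (Multi)Polygon
    name: str = "region"

    @property
    def area_um2(self) -> float:
        return float(self.polygon.area)

    def members(self, geometry: NetworkGeometry) -> np.ndarray:
        """Ids of neurons strictly inside the polygon."""
        x, y = geometry.positions[:, 0], geometry.positions[:, 1]
        inside = shapely.contains_xy(self.polygon, x, y)
        return np.nonzero(inside)[0].astype(np.int32)

    def raster(self, area: tuple, cell_um: float = 10.0) -> np.ndarray:
        """Boolean occupancy grid over the network area (cell centers)."""
        w, h = area
        nx, ny = int(round(w / cell_um)), int(round(h / cell_um))
        cx = (np.arange(nx) + 0.5) * cell_um
        cy = (np.arange(ny) + 0.5) * cell_um
        gx, gy = np.meshgrid(cx, cy, indexing="ij")
        return shapely.contains_xy(self.polygon, gx.ravel(), gy.ravel()
                                   ).reshape(nx, ny)

    def validate_within(self, area: tuple) -> None:
        minx, miny, maxx, maxy = self.polygon.bounds
        if minx < 0 or miny < 0 or maxx > area[0] or maxy > area[1]:
            raise ConfigurationError(f"mask {self.name!r} exceeds network area")


@dataclass(frozen=True)
class StimulusProtocol:
    """Periodic pulse train over a region.

    Pulses start at ``t_start + delay`` and repeat every
    ``1000 / pulse_rate`` ms until ``t_end``. ``subset_fraction`` < 1
    targets a fixed random subset of ``floor(frac * n_members)`` member
    neurons, identical for every pulse (seeded).
    """

    mask: RegionMask
    amplitude: float = 2.0        # mV per pulse
    pulse_rate: float = 50.0      # Hz
    pulse_width: float = 0.1      # ms (one step)
    t_start: float = 0.0          # ms
    t_end: float = 1000.0         # ms
    delay: float = 0.0            # ms relative to protocol reference
    subset_fraction: float = 1.0
    seed: int = 0
    # response realization (compiled path): suprathreshold pulses may
    # evoke a short burst of n_burst response spikes per neuron, and
    # response times may carry a per-pulse jitter on top of the fixed
    # per-neuron latency.
    n_burst: int = 1
    burst_isi_ms: float = 1.0
    pulse_jitter_ms: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.subset_fraction <= 1.0):
            raise ConfigurationError("subset_fraction must be in (0, 1]")
        if self.pulse_rate <= 0:
            raise ConfigurationError("pulse_rate must be positive")
        if self.t_end <= self.t_start:
            raise ConfigurationError("t_end must exceed t_start")

    def onsets_ms(self) -> np.ndarray:
        period = 1000.0 / self.pulse_rate
        first = self.t_start + self.delay
        n = int(np.floor((self.t_end - first) / period - 1e-9)) + 1
        if n <= 0:
            return np.zeros(0)
        return first + period * np.arange(n)

    def targets(self, geometry: NetworkGeometry) -> np.ndarray:
        members = self.mask.members(geometry)
        if len(members) == 0:
            raise ConfigurationError(
                f"protocol mask {self.mask.name!r} has no member neurons")
        if self.subset_fraction >= 1.0:
            return members
        n_t = int(np.floor(self.subset_fraction * len(members)))
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(23,)))
        return np.sort(members[rng.permutation(len(members))[:n_t]])


def apply_protocol(n_neurons: int, protocol: StimulusProtocol,
                   geometry: NetworkGeometry, t_ms: float,
                   dt_ms: float) -> np.ndarray:
    """Per-neuron external-voltage increments (mV) at time ``t_ms``.

    Nonzero only when ``t_ms`` falls on a pulse-onset step.
    """
    out = np.zeros(n_neurons)
    onsets = protocol.onsets_ms()
    k = int(round(t_ms / dt_ms))
    on_steps = np.round(onsets / dt_ms).astype(int)
    if k in set(on_steps.tolist()):
        out[protocol.targets(geometry)] += protocol.amplitude
    return out


def compile_protocol(protocol: StimulusProtocol, geometry: NetworkGeometry,
                     dt_ms: float,
                     latencies_ms: Optional[np.ndarray] = None):
    """Flatten a protocol into ``(steps, ids, amps)`` event arrays.

    ``latencies_ms`` is an optional per-neuron response latency added to
    every onset for that neuron.
    """
    targets = protocol.targets(geometry)
    onsets = protocol.onsets_ms()
    if len(onsets) == 0:
        z = np.zeros(0, dtype=np.int64)
        return z, z.astype(np.int32), np.zeros(0)
    lat = np.zeros(len(targets)) if latencies_ms is None else \
        np.asarray(latencies_ms)[targets]
    times = onsets[:, None] + lat[None, :]          # (n_onsets, n_targets)
    if protocol.pulse_jitter_ms > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=protocol.seed, spawn_key=(37,)))
        times = times + rng.uniform(0.0, protocol.pulse_jitter_ms,
                                    size=times.shape)
    if protocol.n_burst > 1:
        times = (times[..., None] +
                 protocol.burst_isi_ms * np.arange(protocol.n_burst))
    steps = np.floor(times / dt_ms + 1e-9).astype(np.int64).ravel()
    ids = np.broadcast_to(targets, times.shape[:2]
                          if protocol.n_burst > 1 else times.shape)
    if protocol.n_burst > 1:
        ids = np.repeat(ids.reshape(-1), protocol.n_burst)
    else:
        ids = ids.ravel()
    amps = np.full(steps.shape, protocol.amplitude)
    return steps, ids.astype(np.int32), amps


def draw_latencies(n_neurons: int, jitter_ms: float, seed: int) -> np.ndarray:
    """Fixed per-neuron stimulus-response latencies, uniform on
    [0, jitter_ms)."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(29,)))
    return rng.uniform(0.0, jitter_ms, size=n_neurons)


# ---------------------------------------------------------------------------
# fixture shapes


def _face_polygon(area: tuple, scale: float = 1.27) -> Polygon:
    """Parametric face: elliptical head with eye/nose/mouth openings.

    ``scale`` sets the head size relative to the network area (the
    default head spans roughly 0.56 x 0.66 of the substrate, keeping
    every member pair within typical combined neurite reach).
    """
    w, h = area
    cx, cy = 0.5 * w, 0.52 * h
    rx, ry = 0.22 * scale * w, 0.26 * scale * h
    head = shapely.affinity.scale(Point(cx, cy).buffer(1.0, quad_segs=48),
                                  rx, ry)
    eye_r = 0.035 * scale * w
    dx, dy = 0.09 * scale * w, 0.09 * scale * h
    eye_l = shapely.affinity.scale(
        Point(cx - dx, cy + dy).buffer(1.0, quad_segs=24),
        eye_r, eye_r * 0.7)
    eye_r_p = shapely.affinity.scale(
        Point(cx + dx, cy + dy).buffer(1.0, quad_segs=24),
        eye_r, eye_r * 0.7)
    nose = Polygon([(cx, cy + 0.02 * scale * h),
                    (cx - 0.03 * scale * w, cy - 0.06 * scale * h),
                    (cx + 0.03 * scale * w, cy - 0.06 * scale * h)])
    mouth = box(cx - 0.09 * scale * w, cy - 0.155 * scale * h,
                cx + 0.09 * scale * w, cy - 0.115 * scale * h)
    return head.difference(unary_union([eye_l, eye_r_p, nose, mouth]))


def _cue_rectangles(area: tuple, seed: int, coverage: float = 0.20,
                    n_rect: int = 3, tol: float = 0.01):
    """Rectangular cues whose union covers ``coverage`` of the face."""
    face = _face_polygon(area)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(31,)))
    target = coverage * face.area
    aspect = 1.6
    h0 = np.sqrt(target / n_rect / aspect)
    # keep cues interior: centers well inside the face, rectangles mostly
    # covered by it, so cue efficacy does not hinge on a lucky draw
    interior = face.buffer(-0.4 * h0)
    if interior.is_empty:
        interior = face
    minx, miny, maxx, maxy = interior.bounds
    best = None
    best_inside = -1.0
    fallback = None
    fallback_err = np.inf
    for _ in range(300):
        centers = rng.uniform((minx, miny), (maxx, maxy), size=(n_rect, 2))
        if not all(interior.contains(Point(*c)) for c in centers):
            continue
        lo, hi = 0.2, 4.0
        for _ in range(60):
            lam = 0.5 * (lo + hi)
            rects = [box(cx - lam * h0 * aspect / 2, cy - lam * h0 / 2,
                         cx + lam * h0 * aspect / 2, cy + lam * h0 / 2)
                     for cx, cy in centers]
            cov = unary_union(rects).intersection(face).area / face.area
            if cov < coverage:
                lo = lam
            else:
                hi = lam
        union_clip = unary_union(rects).intersection(face)
        if abs(cov - coverage) < fallback_err:
            fallback_err = abs(cov - coverage)
            fallback = union_clip
        if abs(cov - coverage) > tol:
            continue
        inside = min(r.intersection(face).area / r.area for r in rects)
        if inside >= 0.7:
            return union_clip
        if inside > best_inside:
            best_inside = inside
            best = union_clip
    if best is not None:
        return best
    if fallback is None:
        raise ConfigurationError("could not satisfy cue coverage constraint")
    return fallback


def make_fixture_mask(kind: str, geometry: NetworkGeometry,
                      params: Optional[dict] = None,
                      seed: int = 0) -> RegionMask:
    """Construct one of the standard experiment regions.

    Kinds: ``face`` (trained pattern), ``cue_rectangles`` (partial cues
    jointly covering 20% +- 1% of the face), ``square`` / ``triangle``
    (projection regions A and B), ``control`` (uninvolved region C),
    ``rect_pair_left`` / ``rect_pair_right`` (association pair), and
    ``circle_cue`` (circular partial cue inside the trained region).
    """
    params = params or {}
    area = geometry.area if geometry is not None else params.get("area")
    w, h = area
    if kind == "face":
        poly = _face_polygon(area)
    elif kind == "cue_rectangles":
        poly = _cue_rectangles(area, seed,
                               coverage=params.get("coverage", 0.20))
    elif kind == "square":
        side = params.get("side", 0.24 * w)
        cx, cy = params.get("center", (0.30 * w, 0.50 * h))
        poly = box(cx - side / 2, cy - side / 2, cx + side / 2, cy + side / 2)
    elif kind == "triangle":
        s = params.get("side", 0.34 * w)
        cx, cy = params.get("center", (0.58 * w, 0.50 * h))
        poly = Polygon([(cx - s / 2, cy - s / 2), (cx + s / 2, cy - s / 2),
                        (cx, cy + s / 2)])
    elif kind == "control":
        side = params.get("side", 0.18 * w)
        cx, cy = params.get("center", (0.50 * w, 0.13 * h))
        poly = box(cx - side / 2, cy - side / 2, cx + side / 2, cy + side / 2)
    elif kind in ("rect_pair_left", "rect_pair_right"):
        rw, rh = params.get("rect", (0.26 * w, 0.36 * h))
        cy = 0.5 * h
        cx = 0.31 * w if kind == "rect_pair_left" else 0.69 * w
        poly = box(cx - rw / 2, cy - rh / 2, cx + rw / 2, cy + rh / 2)
    elif kind == "circle_cue":
        r = params.get("radius", 0.075 * min(w, h))
        cx, cy = params.get("center", (0.46 * w, 0.56 * h))
        poly = Point(cx, cy).buffer(r, quad_segs=32)
    else:
        raise ConfigurationError(f"unknown mask kind {kind!r}")
    mask = RegionMask(polygon=poly, name=kind)
    mask.validate_within(area)
    return mask
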