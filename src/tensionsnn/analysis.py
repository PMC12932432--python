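"""Statistics computed from spike records.

All quantities operate on a :class:`~tensionsnn.dynamics.SpikeRecord`
plus region membership, and are independent of how the spikes were
produced.

* population rate: distinct spiking members per time window, normalized
  by region size (Hz);
* activation time: delay until a stated fraction of a region's members
  has fired after a cue (censored if never reached);
* assembly events: maximal chains of member spikes with inter-spike
  gaps below 0.5 ms whose central instantaneous rate clears a threshold;
* synchrony index: normalized cross-correlation of binary event
  participation vectors of two assemblies on a merged event timeline;
* DBSCAN clustering of spiking-neuron positions and the
  intersection-over-union of the cluster footprint with a trained
  region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from .dynamics import SpikeRecord
from .params import ConfigurationError
from .stimulation import RegionMask

DBSCAN_EPS_UM = 120.0
DBSCAN_MIN_PTS = 20
RASTER_CELL_UM = 10.0


# ---------------------------------------------------------------------------
# rates and activation


def population_rate(spikes: SpikeRecord, region_members: Sequence[int],
                    window_ms: float = 1.0, t0_ms: float = 0.0,
                    t1_ms: Optional[float] = None):
    """Normalized population firing rate time series.

    Counts the *distinct* member neurons spiking in each successive
    window and divides by ``len(members) * window``; returned in Hz
    (one spike per member per ms equals 1000 Hz). Returns
    ``(window_starts_ms, rates_hz)``.
    """
    members = np.asarray(region_members)
    if window_ms <= 0:
        raise ConfigurationError("window must be positive")
    if len(members) == 0:
        raise ConfigurationError("empty region")
    if t1_ms is None:
        t1_ms = float(spikes.times_ms[-1]) + window_ms if len(spikes) else \
            t0_ms + window_ms
    n_win = max(1, int(np.ceil((t1_ms - t0_ms) / window_ms - 1e-9)))
    starts = t0_ms + window_ms * np.arange(n_win)
    rates = np.zeros(n_win)
    sub = spikes.restrict(members).window(t0_ms, t0_ms + n_win * window_ms)
    if len(sub):
        wi = np.floor((sub.times_ms - t0_ms) / window_ms).astype(int)
        # distinct neurons per window
        key = wi.astype(np.int64) * (int(sub.neuron_ids.max()) + 1) + sub.neuron_ids
        uniq_wi = wi[np.unique(key, return_index=True)[1]]
        counts = np.bincount(uniq_wi, minlength=n_win)
        rates = counts / (len(members) * window_ms) * 1000.0
    return starts, rates


def activation_time(spikes: SpikeRecord, region_members: Sequence[int],
                    cue_time_ms: float, fraction: float = 0.7,
                    window_ms: Optional[float] = None) -> Optional[float]:
    """Time (ms) until ``fraction`` of the region's members have fired
    at least once strictly after ``cue_time_ms``.

    Returns ``None`` (censored) if the fraction is never reached --
    within ``cue_time + window_ms`` when a window is given, else within
    the record.
    """
    if not (0.0 < fraction <= 1.0):
        raise ConfigurationError("fraction must be in (0, 1]")
    members = np.asarray(region_members)
    if len(members) == 0:
        raise ConfigurationError("empty region")
    t_hi = np.inf if window_ms is None else cue_time_ms + window_ms
    sub = spikes.restrict(members)
    m = (sub.times_ms > cue_time_ms) & (sub.times_ms <= t_hi)
    ids, times = sub.neuron_ids[m], sub.times_ms[m]
    if len(ids) == 0:
        return None
    # first spike time per member
    order = np.argsort(times, kind="stable")
    ids, times = ids[order], times[order]
    _, first_idx = np.unique(ids, return_index=True)
    firsts = np.sort(times[first_idx])
    need = int(np.ceil(fraction * len(members) - 1e-9))
    if len(firsts) < need:
        return None
    return float(firsts[need - 1] - cue_time_ms)


# ---------------------------------------------------------------------------
# assembly events and synchrony


@dataclass(frozen=True)
class AssemblyEvent:
    """One burst of tightly packed assembly spikes."""

    t_start: float
    t_end: float
    n_spikes: int
    center_rate: float  # Hz, per member

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def detect_assembly_events(spikes: SpikeRecord,
                           assembly_members: Sequence[int],
                           isi_max_ms: float = 0.5,
                           center_rate_min_hz: float = 100.0,
                           center_window_ms: float = 1.0
                           ) -> List[AssemblyEvent]:
    """Maximal spike chains of an assembly.

    A chain extends while the gap to the next member spike is strictly
    below ``isi_max_ms``. A chain is kept as an event only if the
    instantaneous rate in a ``center_window_ms`` window centred at the
    chain's temporal midpoint -- spike count divided by window length
    and by the number of assembly members -- exceeds
    ``center_rate_min_hz``.
    """
    if isi_max_ms <= 0:
        raise ConfigurationError("isi_max must be positive")
    members = np.asarray(assembly_members)
    sub = spikes.restrict(members)
    t = np.sort(sub.times_ms)
    if len(t) == 0:
        return []
    gaps = np.diff(t)
    breaks = np.nonzero(gaps >= isi_max_ms)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(t) - 1]])
    events = []
    n_mem = len(members)
    for a, b in zip(starts, ends):
        t0, t1 = t[a], t[b]
        mid = 0.5 * (t0 + t1)
        lo, hi = mid - center_window_ms / 2, mid + center_window_ms / 2
        count = int(np.sum((t >= lo) & (t <= hi)))
        rate = count / (n_mem * center_window_ms) * 1000.0
        if rate > center_rate_min_hz:
            events.append(AssemblyEvent(float(t0), float(t1),
                                        int(b - a + 1), float(rate)))
    return events


def synchrony_index(events_a: Sequence[AssemblyEvent],
                    events_b: Sequence[AssemblyEvent],
                    tol_ms: float = 0.5) -> float:
    """Normalized cross-correlation of binary event vectors.

    All events from both assemblies are merged into a timeline of event
    slots: events whose intervals overlap within ``+-tol_ms`` share a
    slot. ``x_i`` (``y_i``) marks assembly A's (B's) participation in
    slot i; the index is ``sum(x y) / sqrt(sum(x^2) sum(y^2))``, 1 for
    perfect synchrony and 0 for complete asynchrony (or when either
    assembly has no events).
    """
    evs = [(e.t_start, e.t_end, 0) for e in events_a] + \
          [(e.t_start, e.t_end, 1) for e in events_b]
    if not evs or not events_a or not events_b:
        return 0.0
    evs.sort()
    x, y = [], []
    cur_end = -np.inf
    for t0, t1, who in evs:
        if t0 - tol_ms > cur_end:      # new slot
            x.append(0)
            y.append(0)
            cur_end = t1 + tol_ms
        else:
            cur_end = max(cur_end, t1 + tol_ms)
        (x if who == 0 else y)[-1] = 1
    x = np.array(x, dtype=float)
    y = np.array(y, dtype=float)
    denom = np.sqrt(x.sum() * y.sum())
    return float((x * y).sum() / denom) if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# spatial clustering and IoU


@dataclass
class ClusterResult:
    """DBSCAN labelling of spiking-neuron positions."""

    point_ids: np.ndarray     # neuron ids of the clustered points
    positions: np.ndarray     # (P, 2) um
    labels: np.ndarray        # cluster label per point, -1 = noise
    leak_mask: np.ndarray     # boolean raster of the cluster footprint
    cell_um: float

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels >= 0])))

    @property
    def leak_area_um2(self) -> float:
        return float(self.leak_mask.sum()) * self.cell_um ** 2


def dbscan_cluster(spikes: SpikeRecord, geometry, t0_ms: float,
                   window_ms: float = 5.0, eps_um: float = DBSCAN_EPS_UM,
                   min_pts: int = DBSCAN_MIN_PTS,
                   cell_um: float = RASTER_CELL_UM) -> ClusterResult:
    """Cluster the positions of neurons spiking in a window.

    Every neuron with at least one spike in ``[t0, t0 + window)``
    contributes one point at its position. A core point needs at least
    ``min_pts`` *neighbors* (excluding itself) within ``eps_um``. The
    leak footprint is the union of discs of radius ``eps_um / 2`` around
    clustered points, rasterized at ``cell_um``.
    """
    if eps_um <= 0 or min_pts < 1:
        raise ConfigurationError("eps_um > 0 and min_pts >= 1 required")
    sub = spikes.window(t0_ms, t0_ms + window_ms)
    ids = np.unique(sub.neuron_ids)
    pos = geometry.positions[ids] if len(ids) else np.zeros((0, 2))
    if len(ids) == 0:
        labels = np.zeros(0, dtype=int)
    else:
        labels = DBSCAN(eps=eps_um, min_samples=min_pts + 1).fit(pos).labels_
    leak = cluster_footprint(pos[labels >= 0], geometry.area,
                             radius_um=eps_um / 2, cell_um=cell_um)
    return ClusterResult(point_ids=ids.astype(np.int32), positions=pos,
                         labels=labels, leak_mask=leak, cell_um=cell_um)


def cluster_footprint(points: np.ndarray, area: tuple,
                      radius_um: float = DBSCAN_EPS_UM / 2,
                      cell_um: float = RASTER_CELL_UM) -> np.ndarray:
    """Union of discs around points, rasterized (cell-center test)."""
    w, h = area
    nx, ny = int(round(w / cell_um)), int(round(h / cell_um))
    mask = np.zeros((nx, ny), dtype=bool)
    if len(points) == 0:
        return mask
    cx = (np.arange(nx) + 0.5) * cell_um
    cy = (np.arange(ny) + 0.5) * cell_um
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    tree = cKDTree(points)
    d, _ = tree.query(np.column_stack([gx.ravel(), gy.ravel()]),
                      k=1, distance_upper_bound=radius_um)
    return (d <= radius_um).reshape(nx, ny)


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union of two boolean rasters on a common grid."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ConfigurationError("masks must share a raster")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ConfigurationError("both masks empty")
    return float(np.logical_and(a, b).sum() / union)


def region_iou(region: RegionMask, cluster: ClusterResult,
               area: tuple) -> float:
    """IoU between a trained region and a cluster leak footprint."""
    return iou(region.raster(area, cell_um=cluster.cell_um),
               cluster.leak_mask)
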