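"""Spatially embedded network construction.

Neurons are placed uniformly at random in a bounded 2D rectangle and
labelled excitatory or inhibitory. Each neuron carries one effective
neurite length drawn from a truncated normal distribution. A directed
synapse j -> i may form only between *eligible* pairs -- pairs whose
combined neurite lengths strictly exceed their Euclidean distance -- and
does so independently with probability ``p_syn`` per ordered pair. Self
connections are forbidden and an ordered pair carries at most one
synapse.

The default area (1000 x 1000 um for 5,000 neurons) keeps the cell
density at 5,000 cells/mm^2 when the network is scaled four-fold to
20,000 neurons over 4 mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .params import ConfigurationError

DEFAULT_AREA = (1000.0, 1000.0)
DEFAULT_NEURITE_MEAN = 200.0
DEFAULT_NEURITE_SD = 40.0
DEFAULT_P_SYN = 0.1


@dataclass(frozen=True)
class NetworkGeometry:
    """Immutable geometry of one network realization.

    ``synapses`` is an ``(M, 2)`` int array of directed pairs
    ``(pre_j, post_i)``, sorted lexicographically.
    """

    positions: np.ndarray      # (N, 2) um
    is_inhibitory: np.ndarray  # (N,) bool
    neurite_length: np.ndarray # (N,) um
    synapses: np.ndarray       # (M, 2) int32, directed (pre, post)
    area: tuple                # (width_um, height_um)
    seed: int

    @property
    def n_neurons(self) -> int:
        return self.positions.shape[0]

    @property
    def n_synapses(self) -> int:
        return self.synapses.shape[0]

    @property
    def n_inhibitory(self) -> int:
        return int(self.is_inhibitory.sum())

    def validate(self) -> None:
        """Assert the structural invariants; raises AssertionError."""
        pre, post = self.synapses[:, 0], self.synapses[:, 1]
        assert not np.any(pre == post), "self-connections forbidden"
        assert len(np.unique(self.synapses, axis=0)) == self.n_synapses, \
            "at most one synapse per ordered pair"
        d = np.linalg.norm(self.positions[pre] - self.positions[post], axis=1)
        assert np.all(d < self.neurite_length[pre] + self.neurite_length[post]), \
            "synapse between ineligible pair"
        w, h = self.area
        assert np.all((self.positions[:, 0] >= 0) & (self.positions[:, 0] <= w))
        assert np.all((self.positions[:, 1] >= 0) & (self.positions[:, 1] <= h))


def eligible(pos_j, pos_i, len_j: float, len_i: float) -> bool:
    """True iff the Euclidean distance is strictly below the combined
    neurite length (a tie is ineligible)."""
    if len_j < 0 or len_i < 0:
        raise ConfigurationError("neurite lengths must be non-negative")
    d = float(np.hypot(pos_j[0] - pos_i[0], pos_j[1] - pos_i[1]))
    return d < len_j + len_i


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int) -> np.ndarray:
    """Normal draws truncated at 0 by resampling."""
    out = rng.normal(mean, sd, size)
    bad = out < 0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < 0
    return out


def eligible_pairs(positions: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """All unordered eligible pairs ``(a, b)`` with a < b, sorted.

    Uses a KD-tree radius query at twice the maximum neurite length,
    then filters on the strict per-pair criterion.
    """
    tree = cKDTree(positions)
    r_max = 2.0 * float(lengths.max()) if len(lengths) else 0.0
    cand = tree.query_pairs(r=r_max, output_type="ndarray")
    if cand.size == 0:
        return cand.reshape(0, 2).astype(np.int64)
    a, b = cand[:, 0], cand[:, 1]
    d2 = np.sum((positions[a] - positions[b]) ** 2, axis=1)
    lsum = lengths[a] + lengths[b]
    keep = d2 < lsum * lsum
    pairs = cand[keep]
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[order]


def build_network(n_exc: int = 4000, n_inh: int = 1000,
                  area: tuple = DEFAULT_AREA,
                  neurite_mean: float = DEFAULT_NEURITE_MEAN,
                  neurite_sd: float = DEFAULT_NEURITE_SD,
                  p_syn: float = DEFAULT_P_SYN,
                  seed: int = 0) -> NetworkGeometry:
    """Build a random spatial network.

    Both orientations of an eligible pair are sampled independently with
    probability ``p_syn``, so reciprocal connections can coexist but an
    ordered pair never carries more than one synapse.
    """
    n = n_exc + n_inh
    if n < 2:
        raise ConfigurationError("need at least two neurons")
    if n_exc < 0 or n_inh < 0:
        raise ConfigurationError("neuron counts must be non-negative")
    w, h = float(area[0]), float(area[1])
    if w <= 0 or h <= 0:
        raise ConfigurationError("area dimensions must be positive")
    if not (0.0 <= p_syn <= 1.0):
        raise ConfigurationError("p_syn must be a probability")
    if neurite_mean <= 0:
        raise ConfigurationError("neurite_mean must be positive")

    ss = np.random.SeedSequence(seed)
    rng_pos, rng_len, rng_lab, rng_syn = (
        np.random.default_rng(s) for s in ss.spawn(4))

    positions = rng_pos.uniform((0.0, 0.0), (w, h), size=(n, 2))
    lengths = _truncated_normal(rng_len, neurite_mean, neurite_sd, n)
    # inhibitory labels independent of placement
    is_inh = np.zeros(n, dtype=bool)
    is_inh[rng_lab.permutation(n)[:n_inh]] = True

    pairs = eligible_pairs(positions, lengths)
    # independent Bernoulli draws per orientation
    fwd = rng_syn.random(len(pairs)) < p_syn
    rev = rng_syn.random(len(pairs)) < p_syn
    syn = np.concatenate([pairs[fwd], pairs[rev][:, ::-1]], axis=0)
    if syn.size:
        order = np.lexsort((syn[:, 1], syn[:, 0]))
        syn = np.ascontiguousarray(syn[order], dtype=np.int32)
    else:
        syn = np.zeros((0, 2), dtype=np.int32)

    return NetworkGeometry(positions=positions, is_inhibitory=is_inh,
                           neurite_length=lengths, synapses=syn,
                           area=(w, h), seed=seed)


# ---------------------------------------------------------------------------
# serialization (plain-text CSV round trip)

def write_geometry(geom: NetworkGeometry, neurons_path, synapses_path) -> None:
    import pandas as pd
    pd.DataFrame({
        "id": np.arange(geom.n_neurons),
        "x_um": geom.positions[:, 0],
        "y_um": geom.positions[:, 1],
        "inhibitory": geom.is_inhibitory.astype(int),
        "neurite_um": geom.neurite_length,
    }).to_csv(neurons_path, index=False)
    pd.DataFrame({
        "pre_id": geom.synapses[:, 0],
        "post_id": geom.synapses[:, 1],
    }).to_csv(synapses_path, index=False)


def read_geometry(neurons_path, synapses_path,
                  area: tuple = DEFAULT_AREA, seed: int = -1) -> NetworkGeometry:
    import pandas as pd
    nd = pd.read_csv(neurons_path)
    sd = pd.read_csv(synapses_path)
    positions = np.column_stack([nd["x_um"].to_numpy(), nd["y_um"].to_numpy()])
    syn = np.column_stack([sd["pre_id"].to_numpy(np.int32),
                           sd["post_id"].to_numpy(np.int32)])
    return NetworkGeometry(
        positions=positions,
        is_inhibitory=nd["inhibitory"].to_numpy(bool),
        neurite_length=nd["neurite_um"].to_numpy(float),
        synapses=syn, area=area, seed=seed)
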