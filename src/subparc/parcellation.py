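"""Winner-take-all connectivity parcellation of structure surface vertices.

Each vertex is assigned to the cortical target receiving the most of its
streamlines, provided the winning count reaches a minimum fibre limit;
otherwise the vertex stays unassigned (label 0). The terminal label of a
streamline is the label of the voxel containing its final point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from subparc.errors import ConfigError, DataError
from subparc.streamlines import StreamlineSet
from subparc.volume import ScalarVolume

__all__ = [
    "ConnectivityCounts",
    "VertexParcellation",
    "terminal_label",
    "terminal_labels",
    "count_connections",
    "assign",
    "subregion_vertex_sets",
]

TIE_POLICIES = ("lowest", "unassigned", "random")


@dataclass
class ConnectivityCounts:
    """Streamline termination counts: C[vertex, target]."""

    matrix: np.ndarray  # (V, T) nonnegative ints
    n_targets: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or np.any(self.matrix < 0):
            raise DataError("counts must be a nonnegative 2D matrix")


@dataclass
class VertexParcellation:
    """Per-vertex winner-take-all labels (0 = unassigned)."""

    labels: np.ndarray
    min_count: int
    tie_policy: str
    provenance: dict = field(default_factory=dict)

    @property
    def n_vertices(self) -> int:
        return len(self.labels)


def terminal_labels(streams: StreamlineSet, cortical_labels: ScalarVolume) -> np.ndarray:
    """Cortical label of each streamline's final point (0 outside/background)."""
    if len(streams) == 0:
        return np.zeros(0, dtype=int)
    for line in streams.lines:
        if len(line) < 2:
            raise DataError("streamline has fewer than 2 points")
    return cortical_labels.label_at_world(streams.endpoints)


def terminal_label(streamline: np.ndarray, cortical_labels: ScalarVolume) -> int:
    """Terminal label of a single polyline."""
    line = np.asarray(streamline, dtype=float)
    if len(line) < 2:
        raise DataError("streamline has fewer than 2 points")
    return int(cortical_labels.label_at_world(line[-1:])[0])


def count_connections(
    streams: StreamlineSet,
    cortical_labels: ScalarVolume,
    n_vertices: int | None = None,
    n_targets: int = 6,
) -> ConnectivityCounts:
    """Tally streamline terminations per (seed vertex, cortical target).

    Background terminations (label 0, or labels above ``n_targets``) are
    excluded from every column.
    """
    if len(streams) and np.any(streams.seed_vertices < 0):
        raise DataError("streamline lacking seed-vertex annotation")
    if n_vertices is None:
        n_vertices = int(streams.seed_vertices.max()) + 1 if len(streams) else 0
    C = np.zeros((n_vertices, n_targets), dtype=int)
    if len(streams):
        labels = (
            streams.terminal_labels
            if streams.terminal_labels is not None
            else terminal_labels(streams, cortical_labels)
        )
        ok = (labels >= 1) & (labels <= n_targets)
        np.add.at(C, (streams.seed_vertices[ok], labels[ok] - 1), 1)
    return ConnectivityCounts(C, n_targets)


def assign(
    counts: ConnectivityCounts,
    min_count: int = 10,
    tie_policy: str = "lowest",
    seed: int = 0,
) -> VertexParcellation:
    """Winner-take-all vertex assignment with a minimum fibre-count limit.

    Ties are resolved by ``tie_policy``: ``"lowest"`` (lowest target index
    wins, deterministic), ``"unassigned"`` (tied vertices stay 0) or
    ``"random"`` (seeded uniform choice among the tied maxima).
    """
    if min_count < 1:
        raise ConfigError("min_count must be >= 1")
    if tie_policy not in TIE_POLICIES:
        raise ConfigError(f"unknown tie policy {tie_policy!r}")
    C = counts.matrix
    if C.shape[0] == 0:
        return VertexParcellation(np.zeros(0, dtype=int), min_count, tie_policy)
    winners = np.argmax(C, axis=1) + 1
    top = C.max(axis=1)
    is_tie = (C == top[:, None]).sum(axis=1) > 1
    if tie_policy == "unassigned":
        winners[is_tie] = 0
    elif tie_policy == "random":
        rng = np.random.default_rng(seed)
        for v in np.flatnonzero(is_tie):
            winners[v] = rng.choice(np.flatnonzero(C[v] == top[v])) + 1
    winners[top < min_count] = 0
    return VertexParcellation(
        winners.astype(int),
        min_count,
        tie_policy,
        provenance={"min_count": min_count, "tie_policy": tie_policy},
    )


def subregion_vertex_sets(parc: VertexParcellation, n_targets: int = 6) -> dict:
    """Disjoint per-subregion vertex index arrays plus ``"total"`` (all)."""
    out = {
        t: np.flatnonzero(parc.labels == t) for t in range(1, n_targets + 1)
    }
    out["total"] = np.arange(parc.n_vertices)
    out["unassigned"] = np.flatnonzero(parc.labels == 0)
    return out
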