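"""Streamline sets: ordered world-mm polylines annotated with seed vertices.

TCK and TRK round-tripping is delegated to :mod:`nibabel.streamlines`; the
seed-vertex annotation (which neither format stores natively) travels in a
JSON sidecar written next to the tractogram.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import nibabel as nib
import numpy as np
from nibabel.streamlines import Tractogram
from nibabel.streamlines.tck import TckFile
from nibabel.streamlines.trk import TrkFile

from subparc.errors import DataError

__all__ = ["StreamlineSet", "load_streamlines", "save_streamlines"]


@dataclass
class StreamlineSet:
    """Ordered polylines in world mm with per-streamline annotations.

    Attributes
    ----------
    lines : list of ndarray, each (N_i, 3)
        Polyline point coordinates in world mm.
    seed_vertices : ndarray of int, shape (n,)
        Index of the mesh vertex each streamline was seeded from
        (-1 if unknown).
    terminal_labels : ndarray of int or None
        Cortical label of each streamline's final point; filled in by the
        parcellation stage (0 = background / out of grid).
    """

    lines: list[np.ndarray]
    seed_vertices: np.ndarray = field(default=None)  # type: ignore[assignment]
    terminal_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lines = [np.asarray(l, dtype=float).reshape(-1, 3) for l in self.lines]
        if self.seed_vertices is None:
            self.seed_vertices = np.full(len(self.lines), -1, dtype=int)
        else:
            self.seed_vertices = np.asarray(self.seed_vertices, dtype=int)
        if len(self.seed_vertices) != len(self.lines):
            raise DataError("seed_vertices length does not match streamline count")
        if self.terminal_labels is not None:
            self.terminal_labels = np.asarray(self.terminal_labels, dtype=int)
            if len(self.terminal_labels) != len(self.lines):
                raise DataError("terminal_labels length does not match streamline count")

    def __len__(self) -> int:
        return len(self.lines)

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.lines)

    @property
    def endpoints(self) -> np.ndarray:
        """(n, 3) array of final points."""
        if not self.lines:
            return np.empty((0, 3))
        return np.array([l[-1] for l in self.lines])

    def subset(self, idx: Sequence[int] | np.ndarray) -> "StreamlineSet":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return StreamlineSet(
            [self.lines[i] for i in idx],
            self.seed_vertices[idx],
            None if self.terminal_labels is None else self.terminal_labels[idx],
        )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_streamlines(streams: StreamlineSet, path) -> None:
    """Write TCK or TRK (by extension) plus a JSON annotation sidecar."""
    path = Path(path)
    tractogram = Tractogram(streams.lines, affine_to_rasmm=np.eye(4))
    if path.suffix == ".tck":
        TckFile(tractogram).save(str(path))
    elif path.suffix == ".trk":
        header = {
            "voxel_to_rasmm": np.eye(4),
            "voxel_sizes": np.ones(3),
            "dimensions": np.array([1, 1, 1], dtype=np.int16),
            "voxel_order": "RAS",
        }
        TrkFile(tractogram, header=header).save(str(path))
    else:
        raise DataError(f"unknown streamline format {path.suffix!r}")
    meta = {"seed_vertices": streams.seed_vertices.tolist()}
    if streams.terminal_labels is not None:
        meta["terminal_labels"] = streams.terminal_labels.tolist()
    _sidecar_path(path).write_text(json.dumps(meta))


def load_streamlines(path) -> StreamlineSet:
    """Read TCK or TRK; both are converted to world-mm polylines."""
    path = Path(path)
    try:
        tf = nib.streamlines.load(str(path))
    except Exception as exc:  # nibabel raises assorted header errors
        raise DataError(f"cannot parse streamline file {path}: {exc}") from exc
    lines = [np.asarray(s) for s in tf.tractogram.streamlines]
    seeds = None
    labels = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        seeds = np.asarray(meta.get("seed_vertices"), dtype=int)
        if "terminal_labels" in meta:
            labels = np.asarray(meta["terminal_labels"], dtype=int)
    return StreamlineSet(lines, seeds, labels)
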