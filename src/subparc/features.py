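"""Bundle and surface MD/FA features and the subject x feature table.

Four features per region: bundle MD and bundle FA are means of the scalar
map over voxels traversed by the region's streamline bundle; surface MD
and surface FA are means of the scalar map sampled at the region's surface
vertices (trilinear by default). Empty bundles and all-outside vertex sets
yield nulls, never zeros.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from subparc.errors import ConfigError, DataError
from subparc.naming import (
    FEATURE_KINDS,
    METRICS,
    N_TARGETS,
    TARGET_IDS,
    feature_column,
    subregions,
)
from subparc.parcellation import VertexParcellation, subregion_vertex_sets
from subparc.streamlines import StreamlineSet
from subparc.surface import SurfaceMesh
from subparc.volume import ScalarVolume

log = logging.getLogger(__name__)

__all__ = [
    "extract_bundle",
    "voxelize_bundle",
    "bundle_mean",
    "surface_mean",
    "subject_features",
    "build_feature_table",
]


def extract_bundle(
    streams: StreamlineSet, parc: VertexParcellation, subregion: int | str
) -> StreamlineSet:
    """Streamlines seeded in a subregion that reach its matched target.

    ``subregion`` may be a target index (1..T) or a canonical name. The
    matched cortical target of subregion ``t`` is target ``t`` itself.
    """
    if isinstance(subregion, str):
        if subregion not in TARGET_IDS:
            raise ConfigError(f"unknown subregion {subregion!r}")
        subregion = TARGET_IDS[subregion]
    if not 1 <= int(subregion) <= max(N_TARGETS.values()):
        raise ConfigError(f"unknown subregion id {subregion}")
    if streams.terminal_labels is None:
        raise DataError("streamlines lack terminal labels; classify them first")
    seed_label = parc.labels[streams.seed_vertices]
    keep = (seed_label == subregion) & (streams.terminal_labels == subregion)
    return streams.subset(keep)


def voxelize_bundle(
    bundle: StreamlineSet, grid: ScalarVolume, step: float | None = None
) -> np.ndarray:
    """Binary mask of voxels visited by any bundle streamline.

    Every polyline segment is subdivided so that consecutive sample points
    are at most ``step`` apart (default: half the smallest voxel edge); a
    voxel enters the mask iff it contains a sample point. Streamlines are
    batched by point count so the subdivision is fully vectorised.
    """
    mask = np.zeros(grid.shape, dtype=bool)
    if len(bundle) == 0:
        return mask
    if step is None:
        step = 0.5 * float(grid.voxel_size.min())
    shape = np.array(grid.shape)

    by_len: dict[int, list[np.ndarray]] = {}
    for line in bundle.lines:
        by_len.setdefault(len(line), []).append(line)
    for n_pts, lines in by_len.items():
        arr = np.stack(lines)  # (m, n_pts, 3)
        if n_pts == 1:
            pts = arr.reshape(-1, 3)
        else:
            seg = arr[:, 1:] - arr[:, :-1]
            max_len = float(np.linalg.norm(seg, axis=2).max())
            k = max(int(np.ceil(max_len / step)), 1)
            f = np.linspace(0.0, 1.0, k + 1)
            # (m, n_seg, k+1, 3); duplicated segment endpoints are harmless
            pts = arr[:, :-1, None, :] + f[None, None, :, None] * seg[:, :, None, :]
            pts = pts.reshape(-1, 3)
        for start in range(0, len(pts), 2_000_000):
            chunk = pts[start : start + 2_000_000]
            ijk = np.rint(grid.world_to_voxel(chunk)).astype(int)
            ok = np.all((ijk >= 0) & (ijk < shape), axis=1)
            ijk = ijk[ok]
            mask[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = True
    return mask


def bundle_mean(mask: np.ndarray, scalar: ScalarVolume) -> float | None:
    """Unweighted mean of the scalar over mask voxels; None if mask empty."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != scalar.shape:
        raise DataError(
            f"grid mismatch: mask {mask.shape} vs scalar {scalar.shape}"
        )
    if not mask.any():
        return None
    return float(scalar.data[mask].mean())


def surface_mean(
    mesh: SurfaceMesh,
    vertex_set: np.ndarray,
    scalar: ScalarVolume,
    interpolation: str = "trilinear",
) -> float | None:
    """Mean scalar sampled at the world coordinates of a vertex subset.

    Vertices falling outside the scalar grid are excluded (count logged);
    returns None when the set is empty or fully outside.
    """
    vertex_set = np.asarray(vertex_set, dtype=int)
    if vertex_set.size == 0:
        return None
    samples = scalar.sample_world(mesh.vertices[vertex_set], interpolation)
    n_out = int(np.isnan(samples).sum())
    if n_out:
        log.warning("surface_mean: %d/%d vertices outside grid", n_out, len(samples))
    if n_out == len(samples):
        return None
    return float(np.nanmean(samples))


def subject_features(
    mesh: SurfaceMesh,
    parc: VertexParcellation,
    streams: StreamlineSet,
    md: ScalarVolume,
    fa: ScalarVolume,
    structure: str,
    interpolation: str = "trilinear",
) -> dict[str, float | None]:
    """All (subregion x kind x metric) features for one structure/hemisphere."""
    structure = structure.lower()
    n_t = N_TARGETS[structure]
    if not md.same_grid(fa):
        raise DataError("MD and FA maps disagree on grid geometry")
    vsets = subregion_vertex_sets(parc, n_targets=n_t)
    out: dict[str, float | None] = {}
    scalars = {"md": md, "fa": fa}
    for sub in subregions(structure):
        if sub == "total":
            vset = vsets["total"]
            bundle = streams.subset(
                (parc.labels[streams.seed_vertices] > 0)
                & (streams.terminal_labels > 0)
                & (streams.terminal_labels <= n_t)
            ) if len(streams) else streams
        else:
            t = TARGET_IDS[sub]
            vset = vsets[t]
            bundle = extract_bundle(streams, parc, t) if len(streams) else streams
        mask = voxelize_bundle(bundle, md)
        for metric in METRICS:
            out[feature_column(structure, sub, "bundle", metric)] = bundle_mean(
                mask, scalars[metric]
            )
            out[feature_column(structure, sub, "surface", metric)] = surface_mean(
                mesh, vset, scalars[metric], interpolation
            )
    return out


def _combine_hemispheres(
    per_hemi: dict[str, dict[str, float | None]],
    weights: dict[str, dict[str, int]],
    policy: str,
) -> dict[str, float | None]:
    """Merge L/R feature dicts according to the hemisphere policy."""
    if policy == "separate":
        out = {}
        for h, feats in per_hemi.items():
            out.update({f"{k}_{h.lower()}": v for k, v in feats.items()})
        return out
    if policy != "average":
        raise ConfigError(f"unknown hemisphere policy {policy!r}")
    keys = set()
    for feats in per_hemi.values():
        keys.update(feats)
    out = {}
    for k in sorted(keys):
        num = den = 0.0
        for h, feats in per_hemi.items():
            v = feats.get(k)
            if v is None:
                continue
            w = weights.get(h, {}).get(k, 1)
            num += w * v
            den += w
        out[k] = num / den if den else None
    return out


def build_feature_table(
    cohort: pd.DataFrame,
    subject_data: dict[str, dict],
    hemisphere_policy: str = "average",
    interpolation: str = "trilinear",
) -> pd.DataFrame:
    """Assemble the subject x feature table.

    ``subject_data`` maps subject id to a dict keyed by
    ``(structure, hemisphere)`` whose values provide ``mesh``, ``parc``,
    ``streams``, ``md`` and ``fa``. Hemispheres are combined per
    ``hemisphere_policy`` (vertex-count-weighted average by default).
    Missing modalities leave nulls and a warning.
    """
    rows = []
    for sid in cohort["subject_id"]:
        data = subject_data.get(sid)
        row: dict[str, float | None] = {}
        if data is None:
            log.warning("subject %s missing all modalities", sid)
        else:
            by_structure: dict[str, dict[str, dict]] = {}
            for (structure, hemi), d in data.items():
                by_structure.setdefault(structure.lower(), {})[hemi] = d
            for structure, hemis in by_structure.items():
                per_hemi, weights = {}, {}
                for hemi, d in hemis.items():
                    feats = subject_features(
                        d["mesh"], d["parc"], d["streams"], d["md"], d["fa"],
                        structure, interpolation,
                    )
                    per_hemi[hemi] = feats
                    n_t = N_TARGETS[structure]
                    vsets = subregion_vertex_sets(d["parc"], n_targets=n_t)
                    w = {}
                    for sub in subregions(structure):
                        n_v = len(vsets["total"] if sub == "total" else vsets[TARGET_IDS[sub]])
                        for kind in FEATURE_KINDS:
                            for metric in METRICS:
                                w[feature_column(structure, sub, kind, metric)] = max(n_v, 1)
                    weights[hemi] = w
                row.update(_combine_hemispheres(per_hemi, weights, hemisphere_policy))
        row["subject_id"] = sid
        rows.append(row)
    table = pd.DataFrame(rows).set_index("subject_id")
    table.attrs["hemisphere_policy"] = hemisphere_policy
    table.attrs["interpolation"] = interpolation
    return table
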