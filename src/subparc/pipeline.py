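"""End-to-end pipeline: synthetic (or prepared) study -> stats + classifiers.

A run directory receives stage artefacts (cohort table, atlas volumes,
feature table, stats report, classifier reports), a frozen copy of the
resolved configuration, a JSON-lines log and a provenance manifest. Stages
are keyed by a content hash of the configuration slice they depend on, so
unchanged reruns are cache hits; the master seed scopes only the
split/search/bootstrap randomness, never the synthetic data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from subparc import classify as clf
from subparc import features as feat
from subparc import parcellation as parc
from subparc import stats as st
from subparc import synthio
from subparc.errors import ConfigError
from subparc.naming import N_TARGETS
from subparc.streamlines import save_streamlines
from subparc.surface import extract_surface

__all__ = ["RunConfig", "run_pipeline", "child_seed", "write_fixture_study"]

MESH_DEFAULTS = {
    "striatum": {"threshold": 0.5, "upsample_pct": 100.0, "decimate_fraction": 0.25},
    "snc": {"threshold": 0.3, "upsample_pct": 200.0, "decimate_fraction": 0.0},
    "vta": {"threshold": 0.3, "upsample_pct": 200.0, "decimate_fraction": 0.0},
}


@dataclass
class RunConfig:
    out_root: str = "runs"
    seed: int = 0  # master seed: split / search / bootstrap only
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: float = 1.0
    structures: tuple[str, ...] = ("snc",)
    hemispheres: tuple[str, ...] = ("R",)
    n_per_group: dict = field(default_factory=lambda: {"HC": 6, "iRBD": 3, "ePD": 3})
    data_seed: int = 0
    effect: dict | None = None
    mesh: dict = field(default_factory=dict)
    n_seeds_per_vertex: int = 25
    dominant_p: float = 0.85
    fail_p: float = 0.05
    min_count: int = 2
    tie_policy: str = "lowest"
    interpolation: str = "trilinear"
    hemisphere_policy: str = "average"
    correction: str = "bonferroni"
    family_size: int = 96
    covariates: tuple[str, ...] = ("age", "sex")
    classifiers: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for s in self.structures:
            if s.lower() not in N_TARGETS:
                raise ConfigError(f"unknown structure {s!r}")
        if not 0 <= self.fail_p < 1:
            raise ConfigError("fail_p must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def resolved(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self), default=str))


def child_seed(master_seed: int, scope: str) -> int:
    """Deterministic per-stage child seed derived from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{scope}".encode()).digest()
    return int.from_bytes(h[:4], "little")


def _hash_dict(d: dict) -> str:
    return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()


class _Log:
    def __init__(self, path: Path):
        self.path = path
        self.path.parent.mkdir(parents=True, exist_ok=True)

    def event(self, stage: str, **kw) -> None:
        rec = {"t": time.time(), "stage": stage, **kw}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")


def _stage_cached(run_dir: Path, stage: str, key: str, outputs: list[Path]) -> bool:
    key_file = run_dir / f".{stage}.key"
    return (
        key_file.exists()
        and key_file.read_text() == key
        and all(p.exists() for p in outputs)
    )


def _mark_stage(run_dir: Path, stage: str, key: str) -> None:
    (run_dir / f".{stage}.key").write_text(key)


def run_pipeline(config: RunConfig, run_name: str = "run") -> Path:
    """Execute all stages into ``out_root/run_name``; returns the run dir."""
    run_dir = Path(config.out_root) / run_name
    run_dir.mkdir(parents=True, exist_ok=True)
    log = _Log(run_dir / "log.jsonl")
    resolved = config.resolved()
    (run_dir / "config.yaml").write_text(yaml.safe_dump(resolved))

    data_cfg = {k: v for k, v in resolved.items() if k not in ("seed", "classifiers", "out_root")}
    data_key = _hash_dict(data_cfg)

    phantom = synthio.PhantomSpec(
        grid_shape=tuple(config.grid_shape), voxel_size=config.voxel_size,
        blobs={s.lower(): synthio.DEFAULT_BLOBS[s.lower()] for s in config.structures},
        seed=config.data_seed,
    )
    effect = synthio.EffectSpec(**config.effect) if config.effect else None
    cohort_spec = synthio.CohortSpec(
        n_per_group=dict(config.n_per_group), seed=config.data_seed
    )

    features_csv = run_dir / "features.csv"
    cohort_csv = run_dir / "cohort.csv"
    t0 = time.time()
    if _stage_cached(run_dir, "features", data_key, [features_csv, cohort_csv]):
        log.event("features", cache="hit")
        cohort = pd.read_csv(cohort_csv)
        table = pd.read_csv(features_csv, index_col="subject_id")
    else:
        cohort = synthio.generate_cohort(cohort_spec)
        cohort.to_csv(cohort_csv, index=False)
        probs, cortical = synthio.generate_atlas(phantom)
        atlas_dir = run_dir / "atlas"
        atlas_dir.mkdir(exist_ok=True)
        cortical.save(atlas_dir / "cortical_labels.nii.gz")
        meshes = {}
        for s in config.structures:
            params = dict(MESH_DEFAULTS[s.lower()], **config.mesh.get(s, {}))
            for h in config.hemispheres:
                probs[(s.lower(), h)].save(atlas_dir / f"{s}_{h}_prob.nii.gz")
                meshes[(s.lower(), h)] = extract_surface(
                    probs[(s.lower(), h)], structure=s, hemisphere=h, **params
                )
                meshes[(s.lower(), h)].save(atlas_dir / f"{s}_{h}.ply")
        subject_data = {}
        for i, row in cohort.iterrows():
            sid = row["subject_id"]
            maps = synthio.generate_subject_maps(
                phantom, effect, row["group"],
                subject_seed=[config.data_seed, 1000 + i],
            )
            per_structure = {}
            for (s, h), mesh in meshes.items():
                profile = synthio.target_profile(
                    phantom, s, h, mesh.vertices,
                    dominant_p=config.dominant_p, fail_p=config.fail_p,
                )
                streams = synthio.generate_streamlines(
                    mesh.vertices, cortical, profile,
                    config.n_seeds_per_vertex,
                    seed=child_seed(config.data_seed, f"streams:{sid}:{s}:{h}"),
                )
                streams.terminal_labels = parc.terminal_labels(streams, cortical)
                counts = parc.count_connections(
                    streams, cortical, n_vertices=mesh.n_vertices,
                    n_targets=N_TARGETS[s],
                )
                vparc = parc.assign(counts, config.min_count, config.tie_policy)
                per_structure[(s, h)] = {
                    "mesh": mesh, "parc": vparc, "streams": streams,
                    "md": maps.md, "fa": maps.fa,
                }
            subject_data[sid] = per_structure
        table = feat.build_feature_table(
            cohort, subject_data,
            hemisphere_policy=config.hemisphere_policy,
            interpolation=config.interpolation,
        )
        table.to_csv(features_csv)
        (run_dir / "features.json").write_text(json.dumps({
            "columns": list(table.columns),
            "hemisphere_policy": config.hemisphere_policy,
            "interpolation": config.interpolation,
            "config_hash": data_key,
        }, indent=2))
        _mark_stage(run_dir, "features", data_key)
        log.event("features", cache="miss", seconds=time.time() - t0,
                  n_subjects=len(cohort))

    stats_key = _hash_dict({**data_cfg, "correction": config.correction,
                            "family_size": config.family_size})
    stats_csv = run_dir / "stats.csv"
    t0 = time.time()
    if _stage_cached(run_dir, "stats", stats_key, [stats_csv]):
        log.event("stats", cache="hit")
    else:
        report = st.run_battery(
            table, cohort, covariate_names=config.covariates,
            correction=config.correction, family_size=config.family_size,
        )
        report.to_csv(stats_csv, index=False)
        _mark_stage(run_dir, "stats", stats_key)
        log.event("stats", cache="miss", seconds=time.time() - t0)

    manifest = {"master_seed": config.seed, "data_seed": config.data_seed,
                "child_seeds": {}, "config_hash": _hash_dict(resolved)}
    for spec_dict in config.classifiers:
        name = spec_dict.get("name", spec_dict["positive_class"])
        cls_key = _hash_dict({**resolved, "classifier": spec_dict})
        out_json = run_dir / f"classify_{name}.json"
        t0 = time.time()
        if _stage_cached(run_dir, f"classify_{name}", cls_key, [out_json]):
            log.event("classify", name=name, cache="hit")
            continue
        seed = child_seed(config.seed, f"classify:{name}")
        manifest["child_seeds"][f"classify:{name}"] = seed
        cspec = clf.ClassifierSpec(
            feature_columns=spec_dict["feature_columns"],
            positive_class=spec_dict["positive_class"],
            test_fraction=spec_dict.get("test_fraction", 0.2),
            cv_folds=spec_dict.get("cv_folds", 5),
            n_trials=spec_dict.get("n_trials", 20),
            n_boot=spec_dict.get("n_boot", 50),
            seed=seed,
        )
        report = clf.run_classifier(table, cohort, cspec)
        out_json.write_text(json.dumps(dataclasses.asdict(report), indent=2))
        _mark_stage(run_dir, f"classify_{name}", cls_key)
        log.event("classify", name=name, cache="miss", seconds=time.time() - t0)

    (run_dir / "provenance.json").write_text(json.dumps(manifest, indent=2))
    return run_dir


# ---------------------------------------------------------------------------
# fixtures

def write_fixture_study(
    out_dir,
    phantom: synthio.PhantomSpec | None = None,
    cohort_spec: synthio.CohortSpec | None = None,
    effect: synthio.EffectSpec | None = None,
    structures=("snc",),
    hemispheres=("R",),
    n_seeds_per_vertex: int = 10,
) -> Path:
    """Materialise a complete toy study directory (BIDS-like layout)."""
    out_dir = Path(out_dir)
    phantom = phantom or synthio.PhantomSpec(
        grid_shape=(32, 32, 32),
        blobs={s.lower(): synthio.DEFAULT_BLOBS[s.lower()] for s in structures},
    )
    cohort_spec = cohort_spec or synthio.CohortSpec(
        n_per_group={"HC": 3, "iRBD": 2, "ePD": 2}
    )
    cohort = synthio.generate_cohort(cohort_spec)
    (out_dir / "atlas").mkdir(parents=True, exist_ok=True)
    probs, cortical = synthio.generate_atlas(phantom)
    cortical.save(out_dir / "atlas" / "cortical_labels.nii.gz")
    meshes = {}
    for s in structures:
        params = MESH_DEFAULTS[s.lower()]
        for h in hemispheres:
            probs[(s.lower(), h)].save(out_dir / "atlas" / f"{s}_{h}_prob.nii.gz")
            mesh = extract_surface(probs[(s.lower(), h)], structure=s, hemisphere=h, **params)
            mesh.save(out_dir / "atlas" / f"{s}_{h}.ply")
            meshes[(s, h)] = mesh
    cohort.to_csv(out_dir / "participants.csv", index=False)
    for i, row in cohort.iterrows():
        sid = row["subject_id"]
        sub_dir = out_dir / sid / "dwi"
        sub_dir.mkdir(parents=True, exist_ok=True)
        maps = synthio.generate_subject_maps(
            phantom, effect, row["group"], subject_seed=[cohort_spec.seed, 1000 + i]
        )
        maps.md.save(sub_dir / f"{sid}_MD.nii.gz")
        maps.fa.save(sub_dir / f"{sid}_FA.nii.gz")
        tract_dir = out_dir / sid / "tract"
        tract_dir.mkdir(parents=True, exist_ok=True)
        for (s, h), mesh in meshes.items():
            profile = synthio.target_profile(phantom, s, h, mesh.vertices,
                                             dominant_p=0.9, fail_p=0.05)
            streams = synthio.generate_streamlines(
                mesh.vertices, cortical, profile, n_seeds_per_vertex,
                seed=child_seed(cohort_spec.seed, f"fixture:{sid}:{s}:{h}"),
            )
            save_streamlines(streams, tract_dir / f"{sid}_{s}_{h}.tck")
    return out_dir
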