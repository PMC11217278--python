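"""Canonical structure / subregion / feature-column naming.

The cortical target enumeration is fixed: integer labels 1-6 map to
limbic, executive, rostral motor, caudal motor, parietal, occipital.
Midbrain structures (VTA, SNc) connect to the first four targets only;
the striatum connects to all six.
"""

from __future__ import annotations

TARGET_NAMES: dict[int, str] = {
    1: "limbic",
    2: "executive",
    3: "rostral_motor",
    4: "caudal_motor",
    5: "parietal",
    6: "occipital",
}
TARGET_IDS: dict[str, int] = {v: k for k, v in TARGET_NAMES.items()}

STRUCTURES = ("vta", "snc", "striatum")

N_TARGETS: dict[str, int] = {"vta": 4, "snc": 4, "striatum": 6}

FEATURE_KINDS = ("bundle", "surface")
METRICS = ("md", "fa")


def subregions(structure: str, include_total: bool = True) -> list[str]:
    """Subregion names for a structure, optionally with the ``total`` entry."""
    n = N_TARGETS[structure.lower()]
    out = [TARGET_NAMES[i] for i in range(1, n + 1)]
    if include_total:
        out = ["total"] + out
    return out


def feature_column(structure: str, subregion: str, kind: str, metric: str,
                   hemisphere: str | None = None) -> str:
    """Canonical feature-column name, e.g. ``snc_caudal_motor_surface_md``."""
    parts = [structure.lower(), subregion, kind, metric]
    if hemisphere:
        parts.append(hemisphere.lower())
    return "_".join(parts)


def feature_columns(structures=STRUCTURES, hemisphere_policy: str = "average") -> list[str]:
    """The full, ordered feature-column namespace."""
    hemis = [None] if hemisphere_policy == "average" else ["L", "R"]
    cols = []
    for s in structures:
        for sub in subregions(s):
            for kind in FEATURE_KINDS:
                for metric in METRICS:
                    for h in hemis:
                        cols.append(feature_column(s, sub, kind, metric, h))
    return cols
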