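"""Region atlas tables.

An atlas is a :class:`pandas.DataFrame` with columns ``region_id``,
``region_name`` and ``tissue`` (``"GM"`` or ``"WM"``). The default atlas
combines the 62 cortical gray-matter regions of the Desikan-Killiany-Tourville
parcellation (31 per hemisphere) with the 48 white-matter tract regions of the
ICBM DTI-81 label atlas, the standard parcellations for regional cortical
thickness and fractional anisotropy respectively.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

GM = "GM"
WM = "WM"

_DKT_REGIONS = [
    "caudal anterior cingulate",
    "caudal middle frontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferior parietal",
    "inferior temporal",
    "isthmus cingulate",
    "lateral occipital",
    "lateral orbitofrontal",
    "lingual",
    "medial orbitofrontal",
    "middle temporal",
    "parahippocampal",
    "paracentral",
    "pars opercularis",
    "pars orbitalis",
    "pars triangularis",
    "pericalcarine",
    "postcentral",
    "posterior cingulate",
    "precentral",
    "precuneus",
    "rostral anterior cingulate",
    "rostral middle frontal",
    "superior frontal",
    "superior parietal",
    "superior temporal",
    "supramarginal",
    "transverse temporal",
    "insula",
]

_ICBM_DTI81_MIDLINE = [
    "middle cerebellar peduncle",
    "pontine crossing tract",
    "genu of corpus callosum",
    "body of corpus callosum",
    "splenium of corpus callosum",
    "fornix (column and body)",
]

_ICBM_DTI81_PAIRED = [
    "corticospinal tract",
    "medial lemniscus",
    "inferior cerebellar peduncle",
    "superior cerebellar peduncle",
    "cerebral peduncle",
    "anterior limb of internal capsule",
    "posterior limb of internal capsule",
    "retrolenticular part of internal capsule",
    "anterior corona radiata",
    "superior corona radiata",
    "posterior corona radiata",
    "posterior thalamic radiation",
    "sagittal stratum",
    "external capsule",
    "cingulum (cingulate gyrus)",
    "cingulum (hippocampus)",
    "fornix (cres) / stria terminalis",
    "superior longitudinal fasciculus",
    "superior fronto-occipital fasciculus",
    "uncinate fasciculus",
    "tapetum",
]


def default_atlas() -> pd.DataFrame:
    """Build the default 110-region atlas (62 cortical GM + 48 WM)."""
    rows = []
    for hemi in ("lh", "rh"):
        for name in _DKT_REGIONS:
            rows.append(
                {
                    "region_id": f"gm_{hemi}_{name.replace(' ', '_')}",
                    "region_name": f"{name} ({hemi})",
                    "tissue": GM,
                }
            )
    for name in _ICBM_DTI81_MIDLINE:
        rows.append(
            {
                "region_id": f"wm_{name.replace(' ', '_').replace('(', '').replace(')', '').replace('/', '')}",
                "region_name": name,
                "tissue": WM,
            }
        )
    for side in ("r", "l"):
        for name in _ICBM_DTI81_PAIRED:
            clean = (
                name.replace(" ", "_").replace("(", "").replace(")", "").replace("/", "")
            )
            rows.append(
                {
                    "region_id": f"wm_{side}_{clean}",
                    "region_name": f"{name} ({side.upper()})",
                    "tissue": WM,
                }
            )
    return pd.DataFrame(rows)


def synthetic_atlas(n_gm: int, n_wm: int) -> pd.DataFrame:
    """Build a small synthetic atlas with generic region names."""
    rows = [
        {"region_id": f"gm_{i:03d}", "region_name": f"GM region {i}", "tissue": GM}
        for i in range(n_gm)
    ]
    rows += [
        {"region_id": f"wm_{i:03d}", "region_name": f"WM region {i}", "tissue": WM}
        for i in range(n_wm)
    ]
    return pd.DataFrame(rows)


def validate_atlas(atlas: pd.DataFrame) -> None:
    missing = {"region_id", "region_name", "tissue"} - set(atlas.columns)
    if missing:
        raise ValueError(f"atlas missing columns: {sorted(missing)}")
    if atlas["region_id"].duplicated().any():
        dup = atlas.loc[atlas["region_id"].duplicated(), "region_id"].iloc[0]
        raise ValueError(f"duplicate region_id in atlas: {dup!r}")
    bad = set(atlas["tissue"].unique()) - {GM, WM}
    if bad:
        raise ValueError(f"unknown tissue classes in atlas: {sorted(bad)}")


def read_atlas(path: str | Path) -> pd.DataFrame:
    atlas = pd.read_csv(path)
    validate_atlas(atlas)
    return atlas


def write_atlas(atlas: pd.DataFrame, path: str | Path) -> None:
    atlas.to_csv(path, index=False)


def tissue_of(atlas: pd.DataFrame) -> pd.Series:
    """Tissue class indexed by region_id."""
    return atlas.set_index("region_id")["tissue"]
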