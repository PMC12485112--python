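"""Readers and writers for the pipeline's on-disk formats.

Tabular data are tidy CSV (one measurement per row); FOVs are multi-page
TIFF (one page per channel) with a sidecar JSON recording the explicit
channel order and acquisition metadata — channel identity is never inferred
from image statistics; ground truth and reports are JSON; configs are YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from .synthetic import ImageFOV

__all__ = [
    "read_fraction_profile",
    "write_fraction_profile",
    "read_peptide_table",
    "write_peptide_table",
    "read_annotation_map",
    "write_fov",
    "read_fov",
    "write_json",
    "read_json",
    "load_yaml_config",
]

FRACTION_COLUMNS = ["fraction_index", "fluorescence", "absorbance", "refractive_index"]
PEPTIDE_COLUMNS = [
    "peptide_id",
    "protein_accession",
    "condition",
    "replicate_id",
    "batch_id",
    "intensity",
]


def read_fraction_profile(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = set(FRACTION_COLUMNS[:2]) - set(df.columns)
    if missing:
        raise ValueError(f"fraction table missing columns: {sorted(missing)}")
    return df


def write_fraction_profile(profile: pd.DataFrame, path: str | Path) -> None:
    profile.to_csv(path, index=False)


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = set(PEPTIDE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peptide table missing columns: {sorted(missing)}")
    return df


def write_peptide_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_annotation_map(path: str | Path):
    """Two-column TSV (term_id, accession) -> AnnotationMap with the union of
    all accessions as background unless a `background` pseudo-term is given."""
    from .proteomics import AnnotationMap

    df = pd.read_csv(path, sep="\t", header=None, names=["term_id", "accession"])
    terms: dict[str, set[str]] = {}
    for term, grp in df.groupby("term_id"):
        terms[str(term)] = set(grp["accession"])
    background = terms.pop("background", set().union(*terms.values()) if terms else set())
    return AnnotationMap(terms=terms, background=background)


def write_fov(fov: ImageFOV, path: str | Path) -> None:
    """Multi-page float32 TIFF plus `<stem>.json` sidecar with channel order."""
    path = Path(path)
    order = list(fov.channels)
    stack = np.stack([fov.channels[c].astype(np.float32) for c in order])
    tifffile.imwrite(path, stack)
    sidecar = {
        "channel_order": order,
        "pixel_size_um": fov.pixel_size,
        "condition": fov.condition,
        "biological_replicate": fov.biological_replicate,
        "technical_replicate": fov.technical_replicate,
        "fov_index": fov.fov_index,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_fov(path: str | Path) -> ImageFOV:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    stack = tifffile.imread(path)
    channels = {
        name: np.asarray(stack[i], dtype=float)
        for i, name in enumerate(sidecar["channel_order"])
    }
    return ImageFOV(
        channels=channels,
        pixel_size=sidecar.get("pixel_size_um", 1.0),
        condition=sidecar.get("condition", "unknown"),
        biological_replicate=sidecar.get("biological_replicate", "bio1"),
        technical_replicate=sidecar.get("technical_replicate", "tech1"),
        fov_index=sidecar.get("fov_index", 0),
    )


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        if hasattr(obj, "to_dict"):
            return _jsonable(obj.to_dict())
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, set):
        return sorted(_jsonable(v) for v in obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True))


def read_json(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
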