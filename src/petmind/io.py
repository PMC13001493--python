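"""Readers and writers for the pipeline's plain-text formats.

All tabular artifacts are tab-separated text with a header row; floats
are written with Python's shortest round-tripping repr, so write -> read
reproduces values exactly. Matrices can additionally be stored in a
compact binary container (``.npy`` plus a JSON sidecar carrying subject
id, modality and diagonal convention).

Formats
-------
cohort      subject_id, age, sex, tiv
TACs        region_id, then one column per frame headed by its mid-time (s)
features    vertex_id, region_id, thickness, curvature, sulc, area, volume
geometry    region_id, x, y, z, sx, sy, sz, hemisphere, laminar_class
matrix      region_ids as header row and first column
truth       JSON
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (FEATURE_NAMES, ParcelGeometry, SimilarityMatrix, TACSet,
                        VertexFeatureSet, validate_cohort)
from .errors import ValidationError
from .synthetic import SyntheticTruth

_SEP = "\t"


def _fmt(x: float) -> str:
    return repr(float(x))


# --------------------------------------------------------------------------- cohort

def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(cohort).to_csv(path, sep=_SEP, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path, sep=_SEP, float_precision="round_trip"))


# --------------------------------------------------------------------------- TACs

def write_tacs(tacs: TACSet, path: str | Path) -> None:
    tacs.validate()
    with open(path, "w") as fh:
        fh.write(_SEP.join(["region_id"] + [_fmt(t) for t in tacs.frame_midtimes]) + "\n")
        for region, row in zip(tacs.region_ids, tacs.activities):
            fh.write(_SEP.join([region] + [_fmt(v) for v in row]) + "\n")


def read_tacs(path: str | Path, subject_id: str | None = None) -> TACSet:
    df = pd.read_csv(path, sep=_SEP, dtype={"region_id": str}, float_precision="round_trip")
    if df.columns[0] != "region_id":
        raise ValidationError(f"{path}: first column must be 'region_id'")
    midtimes = np.array([float(c) for c in df.columns[1:]])
    return TACSet(
        subject_id=subject_id or Path(path).stem,
        region_ids=df["region_id"].tolist(),
        activities=df.iloc[:, 1:].to_numpy(dtype=float),
        frame_midtimes=midtimes,
    ).validate()


# --------------------------------------------------------------------------- vertex features

def write_vertex_features(features: VertexFeatureSet, path: str | Path) -> None:
    features.validate()
    cols = ["vertex_id", "region_id", *FEATURE_NAMES]
    with open(path, "w") as fh:
        fh.write(_SEP.join(cols) + "\n")
        v = 0
        for region, mat in features.features.items():
            for row in mat:
                fh.write(_SEP.join([str(v), region] + [_fmt(x) for x in row]) + "\n")
                v += 1


def read_vertex_features(path: str | Path, subject_id: str | None = None,
                         region_order: list[str] | None = None) -> VertexFeatureSet:
    df = pd.read_csv(path, sep=_SEP, dtype={"region_id": str}, float_precision="round_trip")
    expected = {"vertex_id", "region_id", *FEATURE_NAMES}
    if not expected <= set(df.columns):
        raise ValidationError(f"{path}: missing columns {sorted(expected - set(df.columns))}")
    order = region_order or list(dict.fromkeys(df["region_id"]))
    feats = {}
    grouped = dict(tuple(df.groupby("region_id", sort=False)))
    for region in order:
        if region not in grouped:
            raise ValidationError(f"{path}: region {region!r} missing from feature table")
        feats[region] = grouped[region][list(FEATURE_NAMES)].to_numpy(dtype=float)
    return VertexFeatureSet(subject_id=subject_id or Path(path).stem,
                            features=feats, standardized=False).validate()


# --------------------------------------------------------------------------- geometry

def write_geometry(geom: ParcelGeometry, path: str | Path) -> None:
    geom.validate()
    laminar = geom.laminar_class if geom.laminar_class is not None \
        else np.array([""] * geom.n_regions, dtype=object)
    with open(path, "w") as fh:
        fh.write(_SEP.join(["region_id", "x", "y", "z", "sx", "sy", "sz",
                            "hemisphere", "laminar_class"]) + "\n")
        for i, region in enumerate(geom.region_ids):
            fields = [region] + [_fmt(v) for v in geom.centroid_xyz[i]] \
                + [_fmt(v) for v in geom.sphere_xyz[i]] \
                + [str(geom.hemisphere[i]), str(laminar[i])]
            fh.write(_SEP.join(fields) + "\n")


def read_geometry(path: str | Path) -> ParcelGeometry:
    df = pd.read_csv(path, sep=_SEP, dtype={"region_id": str}, keep_default_na=False,
                     float_precision="round_trip")
    laminar = df["laminar_class"].to_numpy(dtype=object)
    if np.all(laminar == ""):
        laminar = None
    return ParcelGeometry(
        region_ids=df["region_id"].tolist(),
        centroid_xyz=df[["x", "y", "z"]].to_numpy(dtype=float),
        sphere_xyz=df[["sx", "sy", "sz"]].to_numpy(dtype=float),
        hemisphere=df["hemisphere"].to_numpy(dtype=object),
        laminar_class=laminar,
    ).validate()


# --------------------------------------------------------------------------- matrices

def write_matrix(m: SimilarityMatrix, path: str | Path, subject_id: str | None = None) -> None:
    """TSV matrix with region ids as header row/column plus JSON sidecar."""
    pd.DataFrame(m.values, index=m.region_ids, columns=m.region_ids) \
        .to_csv(path, sep=_SEP, index_label="region_id",
                float_format=None)
    _write_sidecar(path, m, subject_id)


def write_matrix_binary(m: SimilarityMatrix, path: str | Path,
                        subject_id: str | None = None) -> None:
    """Compact binary container: ``.npy`` values + JSON sidecar metadata."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), m.values)
    _write_sidecar(path.with_suffix(".npy"), m, subject_id, region_ids=True)


def _write_sidecar(path: str | Path, m: SimilarityMatrix, subject_id: str | None,
                   region_ids: bool = False) -> None:
    meta = {"modality": m.modality, "diagonal_convention": m.diagonal_convention,
            "subject_id": subject_id}
    if region_ids:
        meta["region_ids"] = list(m.region_ids)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_matrix(path: str | Path) -> SimilarityMatrix:
    path = Path(path)
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() \
        else {"modality": "residual", "diagonal_convention": "one"}
    if path.suffix == ".npy":
        values = np.load(path)
        region_ids = meta.get("region_ids") or [f"region_{i}" for i in range(values.shape[0])]
    else:
        df = pd.read_csv(path, sep=_SEP, index_col=0, float_precision="round_trip")
        values = df.to_numpy(dtype=float)
        region_ids = [str(c) for c in df.columns]
    return SimilarityMatrix(region_ids=region_ids, values=values,
                            modality=meta["modality"],
                            diagonal_convention=meta["diagonal_convention"]).validate()


# --------------------------------------------------------------------------- truth

def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "latent_embeddings": np.asarray(truth.latent_embeddings).tolist(),
        "per_subject_mixing": np.asarray(truth.per_subject_mixing).tolist(),
        "planted_decay": list(truth.planted_decay),
        "seeds_used": list(truth.seeds_used),
    }
    Path(path).write_text(json.dumps(payload))


def read_truth(path: str | Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(
        latent_embeddings=np.asarray(payload["latent_embeddings"], dtype=float),
        per_subject_mixing=np.asarray(payload["per_subject_mixing"], dtype=float),
        planted_decay=tuple(payload["planted_decay"]),
        seeds_used=list(payload["seeds_used"]),
    )
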