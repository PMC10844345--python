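"""File I/O: GIFTI surfaces/metrics/labels via nibabel, plus neutral
dense-array storage (``.npy`` + JSON sidecar) and cohort TSV/JSON writers."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .surface import ParcellationAtlas, SurfaceMesh

__all__ = [
    "save_mesh_gifti", "load_mesh_gifti",
    "save_metric_gifti", "load_metric_gifti",
    "save_label_gifti", "load_label_gifti",
    "save_dense", "load_dense",
    "write_cohort",
]


def save_mesh_gifti(mesh: SurfaceMesh, path: str | Path) -> None:
    img = nib.gifti.GiftiImage(darrays=[
        nib.gifti.GiftiDataArray(mesh.coords.astype(np.float32),
                                 intent="NIFTI_INTENT_POINTSET"),
        nib.gifti.GiftiDataArray(mesh.triangles.astype(np.int32),
                                 intent="NIFTI_INTENT_TRIANGLE"),
    ])
    nib.save(img, str(path))


def load_mesh_gifti(path: str | Path, hemisphere: str = "single") -> SurfaceMesh:
    img = nib.load(str(path))
    coords = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
    tris = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
    return SurfaceMesh(np.asarray(coords, float), np.asarray(tris, np.int64),
                       hemisphere)


def save_metric_gifti(values: np.ndarray, path: str | Path,
                      meta: dict | None = None) -> None:
    """Write one or more per-vertex scalar maps (rows = maps for 2-D input)."""
    values = np.asarray(values, dtype=np.float32)
    if values.ndim == 1:
        values = values[None, :]
    darrays = [nib.gifti.GiftiDataArray(row, intent="NIFTI_INTENT_NONE")
               for row in values]
    img = nib.gifti.GiftiImage(darrays=darrays)
    if meta:
        img.meta = nib.gifti.GiftiMetaData(
            {k: str(v) for k, v in meta.items()})
    nib.save(img, str(path))


def load_metric_gifti(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    arr = np.asarray([d.data for d in img.darrays], dtype=float)
    return arr[0] if arr.shape[0] == 1 else arr


def save_label_gifti(atlas: ParcellationAtlas, path: str | Path) -> None:
    da = nib.gifti.GiftiDataArray(atlas.labels.astype(np.int32),
                                  intent="NIFTI_INTENT_LABEL")
    img = nib.gifti.GiftiImage(darrays=[da])
    table = nib.gifti.GiftiLabelTable()
    for lab in np.unique(atlas.labels):
        gl = nib.gifti.GiftiLabel(key=int(lab))
        gl.label = (atlas.label_names or {}).get(int(lab), str(int(lab)))
        table.labels.append(gl)
    img.labeltable = table
    nib.save(img, str(path))


def load_label_gifti(path: str | Path) -> ParcellationAtlas:
    img = nib.load(str(path))
    labels = np.asarray(img.darrays[0].data, dtype=np.int64)
    names = {}
    if img.labeltable is not None:
        for gl in img.labeltable.labels:
            if gl.label is not None:
                names[int(gl.key)] = gl.label
    return ParcellationAtlas(labels, names or None)


def save_dense(prefix: str | Path, data: np.ndarray, **sidecar) -> None:
    """Neutral fallback: binary array + human-readable JSON sidecar."""
    prefix = Path(prefix)
    np.save(prefix.with_suffix(".npy"), np.asarray(data))
    meta = {"shape": list(np.shape(data))}
    meta.update(sidecar)
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_dense(prefix: str | Path) -> tuple[np.ndarray, dict]:
    prefix = Path(prefix)
    data = np.load(prefix.with_suffix(".npy"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return data, meta


def write_cohort(cohort, out_dir: str | Path, use_gifti: bool = True) -> None:
    """Materialise a synthetic cohort: mesh + atlas, per-subject BOLD metric
    files, motion TSVs, the subject table, and the ground truth as JSON."""
    import dataclasses

    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if use_gifti:
        save_mesh_gifti(cohort.mesh, out / "mesh.surf.gii")
        save_label_gifti(cohort.atlas, out / "atlas.label.gii")
    np.savetxt(out / "mask.tsv", cohort.mask.astype(int), fmt="%d")
    for s in cohort.subjects:
        if use_gifti:
            save_metric_gifti(s.bold.data, out / f"{s.subject_id}.func.gii",
                              meta={"tr_s": s.bold.tr_s})
        else:
            save_dense(out / s.subject_id, s.bold.data, tr_s=s.bold.tr_s,
                       hemisphere=s.bold.hemisphere)
        pd.DataFrame(
            s.motion.params,
            columns=["trans_x", "trans_y", "trans_z",
                     "rot_x", "rot_y", "rot_z"],
        ).to_csv(out / f"{s.subject_id}_motion.tsv", sep="\t", index=False)
    cohort.design.to_csv(out / "participants.tsv", sep="\t", index=False)
    truth = dataclasses.asdict(cohort.truth)
    truth["effect_parcels"] = list(truth["effect_parcels"])
    truth["stationary"] = {str(k): bool(v)
                           for k, v in truth["stationary"].items()}
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
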