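"""Reading and writing the pipeline's text and NIfTI artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .perceptual_space import DissimilarityMatrix, PerceptualEmbedding
from .searchlight import SearchlightMap, VoxelDataset


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, sep="\t", index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"participant", "target_id", "distractor_id", "label", "rt_seconds", "correct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial table {path} is missing columns {sorted(missing)}")
    return df


def write_dissimilarity(d: DissimilarityMatrix, path) -> None:
    pd.DataFrame(d.d, index=d.objects, columns=d.objects).to_csv(path, sep="\t")


def read_dissimilarity(path) -> DissimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DissimilarityMatrix(objects=[str(o) for o in df.columns], d=df.to_numpy())


def write_embedding(emb: PerceptualEmbedding, tsv_path, meta_path=None) -> None:
    cols = {f"dim_{i + 1}": emb.coords[:, i] for i in range(emb.k)}
    pd.DataFrame({"object_id": emb.objects, **cols}).to_csv(tsv_path, sep="\t", index=False)
    if meta_path is not None:
        meta = {"k": emb.k, "stress": emb.stress, "fit_r": emb.fit_r,
                "criterion": emb.criterion, "seed": emb.seed}
        Path(meta_path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_embedding(tsv_path, meta_path=None) -> PerceptualEmbedding:
    df = pd.read_csv(tsv_path, sep="\t")
    dims = [c for c in df.columns if c.startswith("dim_")]
    meta = json.loads(Path(meta_path).read_text()) if meta_path else {}
    return PerceptualEmbedding(
        objects=[str(o) for o in df["object_id"]],
        coords=df[dims].to_numpy(dtype=float),
        k=len(dims),
        stress=meta.get("stress", float("nan")),
        fit_r=meta.get("fit_r", float("nan")),
        criterion=meta.get("criterion", "metric_stress"),
        seed=meta.get("seed"),
    )


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def write_voxel_dataset(data: VoxelDataset, out_dir, affine: np.ndarray | None = None) -> None:
    """One NIfTI volume per condition, a mask volume, and a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(data.voxel_size) if affine is None else affine
    nib.save(nib.Nifti1Image(data.mask.astype(np.uint8), aff), out / "mask.nii")
    for name, vol in zip(data.conditions, data.betas):
        nib.save(nib.Nifti1Image(vol.astype(np.float32), aff), out / f"beta_{name}.nii")
    sidecar = {"conditions": list(data.conditions),
               "voxel_size": list(data.voxel_size)}
    (out / "conditions.json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_voxel_dataset(in_dir) -> VoxelDataset:
    src = Path(in_dir)
    sidecar = json.loads((src / "conditions.json").read_text())
    mask = np.asanyarray(nib.load(src / "mask.nii").dataobj).astype(bool)
    betas = np.stack(
        [np.asanyarray(nib.load(src / f"beta_{c}.nii").dataobj).astype(float)
         for c in sidecar["conditions"]]
    )
    return VoxelDataset(mask=mask, conditions=sidecar["conditions"], betas=betas,
                        voxel_size=tuple(sidecar.get("voxel_size", (3.0, 3.0, 3.0))))


def write_map(slmap: SearchlightMap, path, voxel_size=(3.0, 3.0, 3.0),
              affine: np.ndarray | None = None) -> None:
    aff = _affine(voxel_size) if affine is None else affine
    nib.save(nib.Nifti1Image(slmap.values.astype(np.float32), aff), path)


def write_regions(regions, path) -> None:
    """Region voxel sets as TSV: region index, size, and 0-based grid indices."""
    rows = []
    for i, reg in enumerate(regions):
        for vox in reg.voxels:
            rows.append({"region": i, "size": reg.size,
                         "x": int(vox[0]), "y": int(vox[1]), "z": int(vox[2])})
    pd.DataFrame(rows, columns=["region", "size", "x", "y", "z"]).to_csv(
        path, sep="\t", index=False
    )


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
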