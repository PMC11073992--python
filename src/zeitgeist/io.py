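"""Tabular and volume I/O with stable column schemas."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .similarity import PatternMatrix

__all__ = [
    "write_pattern_tsv", "read_pattern_tsv",
    "write_meta_csv", "read_meta_csv",
    "write_halves_nifti", "read_halves_nifti",
    "write_json",
]


def write_pattern_tsv(patterns: PatternMatrix, path) -> Path:
    """Pattern matrix as TSV: participant id column + one column per feature."""
    path = Path(path)
    df = pd.DataFrame(patterns.values,
                      columns=[f"f{k}" for k in range(patterns.n_features)])
    df.insert(0, "participant", patterns.participant_ids)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_pattern_tsv(path, target_id=None, space="neural") -> PatternMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    ids = df["participant"].astype(str).tolist()
    values = df.drop(columns=["participant"]).to_numpy(dtype=float)
    return PatternMatrix(values, ids, target_id or path.stem, space=space)


def write_meta_csv(meta: pd.DataFrame, path) -> Path:
    path = Path(path)
    meta.to_csv(path, index=False)
    return path


def read_meta_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "participant" in df.columns:
        df["participant"] = df["participant"].astype(str)
    return df


def write_halves_nifti(half1, half2, grid_shape, out_dir,
                       truth: dict | None = None) -> list[Path]:
    """Split-half estimates as 4-D NIfTI (conditions on the 4th axis).

    One pair of files per participant plus a JSON truth sidecar.
    """
    import nibabel as nib
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for h, arr in (("half1", half1), ("half2", half2)):
        for p in range(arr.shape[0]):
            vol = np.moveaxis(arr[p].reshape((-1,) + tuple(grid_shape)), 0, -1)
            img = nib.Nifti1Image(vol.astype(np.float32), affine=np.eye(4))
            fp = out_dir / f"sub-{p:03d}_{h}.nii.gz"
            nib.save(img, fp)
            paths.append(fp)
    if truth is not None:
        write_json(truth, out_dir / "truth.json")
    return paths


def read_halves_nifti(out_dir):
    """Read back split-half volumes written by :func:`write_halves_nifti`."""
    import nibabel as nib
    out_dir = Path(out_dir)
    halves = []
    for h in ("half1", "half2"):
        arrs = []
        for fp in sorted(out_dir.glob(f"sub-*_{h}.nii.gz")):
            vol = np.asarray(nib.load(fp).dataobj, dtype=float)
            arrs.append(np.moveaxis(vol, -1, 0).reshape(vol.shape[-1], -1))
        halves.append(np.stack(arrs))
    grid_shape = nib.load(sorted(out_dir.glob("sub-*_half1.nii.gz"))[0]
                          ).shape[:3]
    return halves[0], halves[1], grid_shape


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder))
    return path
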