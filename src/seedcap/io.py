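"""File I/O: NIfTI volumes, TSV motion traces, cohort manifests, result files.

A cohort manifest is a JSON file::

    {
      "mask": "mask.nii.gz",
      "parcellation": "parcellation.nii.gz",
      "clinical": "clinical.csv",
      "tr_seconds": 2.0,
      "subjects": [
        {"subject_id": "reference-000", "group": "reference",
         "bold": "reference-000_bold.nii.gz",
         "motion": "reference-000_motion.tsv"},
        ...
      ]
    }

Relative paths resolve against the manifest's directory.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from ._errors import FormatError
from .preprocess import Bold4D, MotionTrace
from .stats import ParcellationOverlay

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def load_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a binary grey-matter mask; returns (mask, affine)."""
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj) > 0, img.affine


def load_bold(path: str | Path, mask: np.ndarray, tr_seconds: float) -> Bold4D:
    """Load a 4-D NIfTI and mask it to a (n_voxels, n_frames) matrix."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError(f"{path}: expected a 4-D image, got shape {data.shape}")
    return Bold4D(
        data=data[mask].astype(float),
        mask=mask,
        affine=img.affine,
        tr_seconds=tr_seconds,
    )


def load_motion(path: str | Path) -> MotionTrace:
    """Load a TSV motion trace with the six canonical columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing motion columns {missing}")
    return MotionTrace(params=df[MOTION_COLUMNS].to_numpy(float))


def load_parcellation(path: str | Path, mask: np.ndarray) -> ParcellationOverlay:
    img = nib.load(str(path))
    vol = np.asanyarray(img.dataobj).astype(int)
    return ParcellationOverlay(labels=vol[mask])


def load_manifest(path: str | Path) -> dict:
    path = Path(path)
    manifest = json.loads(path.read_text())
    base = path.parent

    def _resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    manifest["mask"] = _resolve(manifest["mask"])
    if manifest.get("parcellation"):
        manifest["parcellation"] = _resolve(manifest["parcellation"])
    if manifest.get("clinical"):
        manifest["clinical"] = _resolve(manifest["clinical"])
    for s in manifest["subjects"]:
        s["bold"] = _resolve(s["bold"])
        s["motion"] = _resolve(s["motion"])
    return manifest


def save_cap_maps(
    maps: np.ndarray,
    mask: np.ndarray,
    affine: np.ndarray,
    out_dir: str | Path,
    prefix: str = "cap",
    config_hash: str = "",
) -> list[Path]:
    """Write each z-scored CAP map as a 3-D NIfTI volume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for c in range(maps.shape[0]):
        vol = np.zeros(mask.shape, dtype=np.float32)
        vol[mask] = maps[c]
        img = nib.Nifti1Image(vol, affine)
        if config_hash:
            img.header["descrip"] = f"seedcap cfg={config_hash}".encode()[:80]
        p = out / f"{prefix}{c + 1}_z.nii.gz"
        nib.save(img, p)
        paths.append(p)
    return paths
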