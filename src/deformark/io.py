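"""File I/O: NIfTI-1 images and fields, CSV labels/landmarks, JSON results.

All on-disk artifacts are deterministic given identical inputs (NIfTI
gzip streams carry no timestamps; JSON is written with sorted keys), so
pipeline manifests can compare runs by checksum.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .registration import DeformationField, Image2D

_LABEL_CODES = {"control": 0, "disease": 1}


def save_image(img: Image2D, path: str | Path) -> None:
    """Write a 2D image as single-slice NIfTI-1 (or 16-bit PNG)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".png":
        from PIL import Image as PILImage

        arr = np.clip(img.pixels, 0.0, 1.0)
        PILImage.fromarray((arr * 65535.0 + 0.5).astype(np.uint16)).save(path)
        return
    affine = np.diag([img.spacing[0], img.spacing[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(img.pixels.astype(np.float32), affine), str(path))


def load_image(path: str | Path) -> Image2D:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    if path.suffix == ".png":
        from PIL import Image as PILImage

        arr = np.asarray(PILImage.open(path), dtype=float)
        return Image2D(arr / 65535.0)
    nii = nib.load(str(path))
    data = np.asarray(nii.dataobj, dtype=float)
    data = np.squeeze(data)
    spacing = tuple(float(z) for z in nii.header.get_zooms()[:2])
    return Image2D(data, spacing)


def save_field(field: DeformationField, path: str | Path) -> None:
    """Write a displacement field as two-volume NIfTI (vol 0 = drow, 1 = dcol)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # (H, W, 2) -> (H, W, 1, 2): third axis is the (singleton) slice axis
    data = field.d.astype(np.float32)[:, :, np.newaxis, :]
    nib.save(nib.Nifti1Image(data, np.eye(4)), str(path))


def load_field(path: str | Path) -> DeformationField:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"field not found: {path}")
    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    data = np.squeeze(data)
    if data.ndim != 3 or data.shape[-1] != 2:
        raise ValueError(f"expected a two-volume field in {path}, got shape {data.shape}")
    return DeformationField(data)


def save_labels(labels: dict[str, str], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"subject_id": list(labels), "label": list(labels.values())})
    df.to_csv(path, index=False)


def load_labels(path: str | Path) -> dict[str, str]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"labels file not found: {path}")
    df = pd.read_csv(path, dtype={"subject_id": str, "label": str})
    bad = set(df["label"]) - set(_LABEL_CODES)
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)} in {path}; expected control/disease")
    return dict(zip(df["subject_id"], df["label"]))


def label_codes(labels: dict[str, str], subject_ids: list[str]) -> np.ndarray:
    """Map control/disease to 0/1 in the given subject order."""
    return np.array([_LABEL_CODES[labels[s]] for s in subject_ids], dtype=int)


def save_landmarks(landmarks: dict[str, np.ndarray], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid, pts in landmarks.items():
        for i, (r, c) in enumerate(np.asarray(pts), start=1):
            rows.append((sid, i, float(r), float(c)))
    pd.DataFrame(rows, columns=["subject_id", "landmark_index", "row", "col"]).to_csv(
        path, index=False
    )


def load_landmarks(path: str | Path) -> dict[str, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"landmarks file not found: {path}")
    df = pd.read_csv(path, dtype={"subject_id": str})
    out: dict[str, np.ndarray] = {}
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("landmark_index")
        if list(grp["landmark_index"]) != list(range(1, 8)):
            raise ValueError(f"subject {sid}: expected landmark indices 1..7")
        out[sid] = grp[["row", "col"]].to_numpy(dtype=float)
    return out


def save_json(obj, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def _json_default(o):
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def load_json(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    return json.loads(path.read_text())
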