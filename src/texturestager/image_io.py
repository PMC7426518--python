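"""Reading and writing of images, masks, manifests and feature tables.

Conventions
-----------
* Pixel coordinates are (row, col), 0-based.
* Masks are inclusion maps: ``True`` marks a pixel inside the ROI.
* 16-bit PNG intensities are used as stored; intensity normalization is a
  pipeline stage (:mod:`texturestager.preprocess`), not an I/O concern.
* Manifest CSVs have columns ``subject_id, sequence, reader, image_path,
  mask_path``; image/mask paths are resolved relative to the manifest
  file's directory when not absolute.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

SEQUENCES = ("sagittal", "axial")
READERS = (1, 2)


@dataclass
class ROISample:
    """One subject's image + ROI mask for one sequence and one reader.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    sequence : str
        MRI sequence name, one of ``{"sagittal", "axial"}``.
    reader : int
        Reader (radiologist) index, 1 or 2.
    image : ndarray
        2D non-negative intensity array.
    mask : ndarray of bool
        2D inclusion map, same shape as ``image``, with >= 1 true pixel.
    class_label : int or None
        Binary outcome (0 = node-negative, 1 = node-positive); ``None``
        when the subject has no label.
    """

    subject_id: str
    sequence: str
    reader: int
    image: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)
    class_label: Optional[int] = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.sequence not in SEQUENCES:
            raise ValueError(
                f"unknown sequence {self.sequence!r} for subject {self.subject_id}"
                f" (expected one of {SEQUENCES})"
            )
        if self.reader not in READERS:
            raise ValueError(
                f"unknown reader {self.reader!r} for subject {self.subject_id}"
            )
        if self.image.ndim != 2:
            raise ValueError(f"image for subject {self.subject_id} is not 2D")
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image/mask shape mismatch for subject {self.subject_id}, "
                f"sequence {self.sequence}: {self.image.shape} vs {self.mask.shape}"
            )
        if not self.mask.any():
            raise ValueError(
                f"empty ROI for subject {self.subject_id}, sequence {self.sequence}"
            )
        if not np.all(np.isfinite(self.image)):
            raise ValueError(f"non-finite intensities for subject {self.subject_id}")
        if self.image.min() < 0:
            raise ValueError(f"negative intensities for subject {self.subject_id}")
        if self.class_label is not None and self.class_label not in (0, 1):
            raise ValueError(
                f"class_label for subject {self.subject_id} must be 0, 1 or missing"
            )


def _read_image_array(path: Path) -> np.ndarray:
    """Read a grayscale image or mask as a 2D array (PNG or NIfTI)."""
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        arr = np.asanyarray(nib.load(str(path)).dataobj)
        # a single-slice volume stored as (H, W, 1) is squeezed to 2D
        if arr.ndim == 3 and arr.shape[2] == 1:
            arr = arr[:, :, 0]
        if arr.ndim != 2:
            raise ValueError(f"{path}: expected a 2D (or single-slice 3D) image")
        return np.asarray(arr)
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im)


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Load a 2D intensity image from PNG or NIfTI as float64."""
    return _read_image_array(Path(path)).astype(np.float64)


def load_mask(path: str | os.PathLike) -> np.ndarray:
    """Load a binary ROI mask (any nonzero pixel counts as inside)."""
    return _read_image_array(Path(path)) > 0


def load_manifest(
    manifest_path: str | os.PathLike,
    labels_path: str | os.PathLike | None = None,
) -> list[ROISample]:
    """Load all ROI samples listed in a manifest CSV.

    The manifest must contain columns ``subject_id, sequence, reader,
    image_path, mask_path``. The optional labels CSV maps ``subject_id``
    to ``class_label``; subjects absent from it get ``class_label=None``.

    Raises
    ------
    ValueError
        On missing columns, duplicate (subject, sequence, reader) rows,
        unknown sequence/reader values, shape mismatches or empty masks.
    FileNotFoundError
        When an image or mask file named in the manifest does not exist;
        the message names the offending manifest row.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path, dtype={"subject_id": str})
    required = {"subject_id", "sequence", "reader", "image_path", "mask_path"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest {manifest_path} missing columns: {sorted(missing)}")

    labels: dict[str, int] = {}
    if labels_path is not None:
        lab = pd.read_csv(labels_path, dtype={"subject_id": str})
        if not {"subject_id", "class_label"} <= set(lab.columns):
            raise ValueError(f"labels file {labels_path} needs subject_id, class_label")
        labels = dict(zip(lab["subject_id"], lab["class_label"].astype(int)))

    keys = list(zip(manifest["subject_id"], manifest["sequence"], manifest["reader"]))
    if len(keys) != len(set(keys)):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate (subject, sequence, reader) rows: {dupes[:5]}")

    samples = []
    for idx, row in manifest.iterrows():
        paths = {}
        for col in ("image_path", "mask_path"):
            p = Path(row[col])
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise FileNotFoundError(
                    f"manifest row {idx} (subject {row['subject_id']}, "
                    f"sequence {row['sequence']}, reader {row['reader']}): "
                    f"missing file {p}"
                )
            paths[col] = p
        samples.append(
            ROISample(
                subject_id=str(row["subject_id"]),
                sequence=str(row["sequence"]),
                reader=int(row["reader"]),
                image=load_image(paths["image_path"]),
                mask=load_mask(paths["mask_path"]),
                class_label=labels.get(str(row["subject_id"])),
            )
        )
    return samples


def write_feature_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a subjects x features table to CSV.

    Columns are ``subject_id``, ``class_label``, then one
    ``<sequence>_<FEATURE>`` column per (sequence, feature) pair. Floats
    are written with full round-trip precision.
    """
    table.to_csv(path, index=False)


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise ValueError(f"feature table {path} has no subject_id column")
    return df


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the feature columns (everything but id and label)."""
    return [c for c in table.columns if c not in ("subject_id", "class_label")]
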