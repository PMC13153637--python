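"""File I/O: volumes, projection images, tables, models and cohorts.

Formats
-------
* volumes: MetaImage ``.mha`` or NIfTI ``.nii.gz`` via SimpleITK
  (lossless round trip of array, spacing and origin),
* 2D images: 32-bit float TIFF (lossless) or 16-bit PNG with the linear
  scale stored in a text chunk,
* tables: CSV with units in the column headers (mm, Gy),
* motion models: JSON (the full 105 x 3 coefficient matrix).

Coordinates in all files are patient-frame mm with 0-based voxel
indexing and half-open bounds (see docs/FORMATS.md).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile
import yaml
from PIL import Image, PngImagePlugin

from kvtrack.motion_model import MotionModel

__all__ = [
    "write_volume",
    "read_volume",
    "write_image",
    "read_image",
    "write_truth_table",
    "read_truth_table",
    "write_model",
    "read_model",
    "write_cohort",
    "read_cohort",
]


# -- volumes -----------------------------------------------------------------


def write_volume(path, array: np.ndarray, spacing, origin=(0.0, 0.0, 0.0)) -> None:
    """Write a 3D array (.mha or .nii.gz) with spacing/origin metadata.

    The array is stored with axis order (x, y, z) preserved: SimpleITK
    images index (z, y, x) internally, so the array is transposed on the
    way in and back on the way out.
    """
    spacing = (spacing,) * 3 if np.isscalar(spacing) else tuple(spacing)
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(array, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    sitk.WriteImage(img, str(path))


def read_volume(path):
    """Read a volume; returns (array (x, y, z), spacing, origin)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = sitk.ReadImage(str(path))
    arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    return arr, img.GetSpacing(), img.GetOrigin()


# -- 2D images ---------------------------------------------------------------


def write_image(path, image: np.ndarray, pixel_spacing: float = 1.0) -> None:
    """Write a projection image: float TIFF (lossless) or 16-bit PNG.

    PNG quantizes to 16 bits; the affine scale (vmin, vmax) and the pixel
    spacing are stored in PNG text chunks / TIFF metadata.
    """
    path = Path(path)
    image = np.asarray(image, dtype=np.float32)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(
            path, image, metadata={"pixel_spacing_mm": float(pixel_spacing)}
        )
    elif path.suffix.lower() == ".png":
        vmin, vmax = float(image.min()), float(image.max())
        scale = (vmax - vmin) or 1.0
        q = np.round((image - vmin) / scale * 65535.0).astype(np.uint16)
        meta = PngImagePlugin.PngInfo()
        meta.add_text("vmin", repr(vmin))
        meta.add_text("vmax", repr(vmax))
        meta.add_text("pixel_spacing_mm", repr(float(pixel_spacing)))
        Image.fromarray(q).save(path, pnginfo=meta)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")


def read_image(path):
    """Read a projection image; returns (float array, pixel_spacing_mm)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray().astype(float)
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        return arr, float(meta.get("pixel_spacing_mm", 1.0))
    if path.suffix.lower() == ".png":
        with Image.open(path) as im:
            q = np.asarray(im, dtype=float)
            vmin = float(im.text.get("vmin", "0.0"))
            vmax = float(im.text.get("vmax", "1.0"))
            spacing = float(im.text.get("pixel_spacing_mm", "1.0"))
        return q / 65535.0 * (vmax - vmin) + vmin, spacing
    raise ValueError(f"unsupported image format: {path.suffix}")


# -- tables ------------------------------------------------------------------

_TRUTH_COLUMNS = ["patient", "fraction", "image", "x_mm", "y_mm", "z_mm"]


def write_truth_table(path, truth: pd.DataFrame) -> None:
    truth[_TRUTH_COLUMNS].to_csv(path, index=False)


def read_truth_table(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise FileNotFoundError(f"truth table not found: {path}")
    missing = set(_TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    for col in ("x_mm", "y_mm", "z_mm"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.flatnonzero(bad | df[col].isna())[0])
            raise ValueError(f"{path}: non-numeric value in column {col!r}, row {row}")
    return df


# -- models ------------------------------------------------------------------


def write_model(path, model: MotionModel) -> None:
    payload = {
        "coef": model.coef.tolist(),
        "cutoff_ratio": model.cutoff_ratio,
        "kind": model.kind,
        "n_retained": model.n_retained,
        "n_train": model.n_train,
    }
    Path(path).write_text(json.dumps(payload))


def read_model(path) -> MotionModel:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except FileNotFoundError:
        raise FileNotFoundError(f"model file not found: {path}")
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed model JSON {path}: {exc}") from exc
    return MotionModel(
        coef=np.asarray(payload["coef"], dtype=float),
        cutoff_ratio=payload["cutoff_ratio"],
        kind=payload.get("kind", "inter"),
        n_retained=payload.get("n_retained", 0),
        n_train=payload.get("n_train", 0),
    )


# -- cohorts -----------------------------------------------------------------


def write_cohort(cohort, out_dir) -> None:
    """Write a cohort to the on-disk layout.

    cohort/patientXX/{drr_A.tiff, drr_B.tiff, phantom.yaml,
    fractions/fYY/img_NNNN_{A,B}.tiff}, truth.csv and cohort.yaml at the
    root.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sp = cohort.geometry.pixel_spacing
    meta = {
        "spec": dataclasses.asdict(cohort.spec),
        "geometry": {
            "image_size": cohort.geometry.image_size,
            "pixel_spacing_mm": sp,
        },
    }
    (out / "cohort.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    for p in cohort.patients:
        pdir = out / f"patient{p.patient:02d}"
        pdir.mkdir(exist_ok=True)
        (pdir / "phantom.yaml").write_text(
            yaml.safe_dump(dataclasses.asdict(p.phantom.config), sort_keys=False)
        )
        for view in ("A", "B"):
            write_image(pdir / f"drr_{view}.tiff", p.drr[view], sp)
        for (m, n), pair in p.images.items():
            fdir = pdir / "fractions" / f"f{m:02d}"
            fdir.mkdir(parents=True, exist_ok=True)
            for view in ("A", "B"):
                write_image(fdir / f"img_{n:04d}_{view}.tiff", pair[view], sp)
    write_truth_table(out / "truth.csv", cohort.truth)


def read_cohort(cohort_dir):
    """Read a cohort written by :func:`write_cohort`."""
    from kvtrack.geometry import ImagingGeometry
    from kvtrack.phantom import (
        Cohort,
        CohortSpec,
        PatientData,
        PhantomConfig,
        build_phantom,
    )

    root = Path(cohort_dir)
    meta_path = root / "cohort.yaml"
    if not meta_path.exists():
        raise FileNotFoundError(f"not a cohort directory (no cohort.yaml): {root}")
    meta = yaml.safe_load(meta_path.read_text())
    spec_kwargs = meta["spec"]
    spec_kwargs["amplitude_ranges"] = tuple(
        tuple(r) for r in spec_kwargs["amplitude_ranges"]
    )
    spec = CohortSpec(**spec_kwargs)
    geometry = ImagingGeometry(
        image_size=meta["geometry"]["image_size"],
        pixel_spacing=meta["geometry"]["pixel_spacing_mm"],
    )
    truth = read_truth_table(root / "truth.csv")
    patients = []
    for pdir in sorted(root.glob("patient*")):
        pid = int(pdir.name.replace("patient", ""))
        cfg_data = yaml.safe_load((pdir / "phantom.yaml").read_text())
        for key in ("shape", "body_semiaxes", "spine_center", "target_center"):
            cfg_data[key] = tuple(cfg_data[key])
        phantom = build_phantom(PhantomConfig(**cfg_data))
        drr = {v: read_image(pdir / f"drr_{v}.tiff")[0] for v in ("A", "B")}
        images = {}
        for fdir in sorted((pdir / "fractions").glob("f*")):
            m = int(fdir.name[1:])
            for img_path in sorted(fdir.glob("img_*_A.tiff")):
                n = int(img_path.stem.split("_")[1])
                images[(m, n)] = {
                    v: read_image(fdir / f"img_{n:04d}_{v}.tiff")[0]
                    for v in ("A", "B")
                }
        patients.append(
            PatientData(
                patient=pid,
                phantom=phantom,
                geometry=geometry,
                drr=drr,
                images=images,
                truth=truth[truth.patient == pid].reset_index(drop=True),
            )
        )
    return Cohort(spec=spec, geometry=geometry, patients=patients)
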