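"""Reading and writing images, masks and dataset manifests.

Images go out as 16-bit grayscale PNG (intensities in [0, 1] scaled to
[0, 65535]) or single-slice NIfTI; masks as 8-bit indexed PNG or NIfTI.
A dataset manifest (JSON) records file paths, split assignment, the seed and
an echo of the generating spec, so any run can be reproduced from disk.
"""

from __future__ import annotations

import dataclasses
import json
import os

import nibabel as nib
import numpy as np
from PIL import Image

from .phantoms import LabeledImage, PhantomSpec


def write_image_png(path: str, image: np.ndarray) -> None:
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    Image.fromarray((arr * 65535.0 + 0.5).astype(np.uint16)).save(path)


def read_image_png(path: str) -> np.ndarray:
    arr = np.asarray(Image.open(path))
    scale = 65535.0 if arr.dtype == np.uint16 else 255.0
    return (arr.astype(np.float32) / scale)


def write_mask_png(path: str, mask: np.ndarray) -> None:
    img = Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="P")
    # simple high-contrast palette for quick visual checks
    palette = []
    for c in range(256):
        palette += [(c * 67) % 256, (c * 151) % 256, (c * 211) % 256]
    palette[:3] = [0, 0, 0]
    img.putpalette(palette)
    img.save(path)


def read_mask_png(path: str) -> np.ndarray:
    return np.asarray(Image.open(path), dtype=np.uint8)


def write_nifti(path: str, array: np.ndarray, pixel_size_mm: float = 1.0) -> None:
    affine = np.diag([pixel_size_mm, pixel_size_mm, 1.0, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(array)[..., None], affine), path)


def read_nifti(path: str) -> tuple[np.ndarray, float]:
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    spacing = float(img.header.get_zooms()[0])
    return data, spacing


def save_dataset(images: list[LabeledImage], out_dir: str,
                 spec: PhantomSpec | None = None,
                 splits: dict[str, list[str]] | None = None,
                 fmt: str = "png") -> str:
    """Write a dataset plus its JSON manifest; returns the manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    entries = []
    for im in images:
        stem = im.ident or f"image-{len(entries):05d}"
        if fmt == "png":
            ip, mp = f"{stem}.png", f"{stem}_mask.png"
            write_image_png(os.path.join(out_dir, ip), im.image)
            write_mask_png(os.path.join(out_dir, mp), im.mask)
        elif fmt == "nifti":
            ip, mp = f"{stem}.nii.gz", f"{stem}_mask.nii.gz"
            write_nifti(os.path.join(out_dir, ip), im.image, im.pixel_size_mm)
            write_nifti(os.path.join(out_dir, mp), im.mask, im.pixel_size_mm)
        else:
            raise ValueError(f"unknown format {fmt!r}")
        entries.append({"ident": stem, "image": ip, "mask": mp,
                        "pixel_size_mm": im.pixel_size_mm})
    manifest = {
        "format": fmt,
        "n_images": len(entries),
        "entries": entries,
        "splits": splits or {},
        "spec": dataclasses.asdict(spec) if spec is not None else None,
        "seed": spec.seed if spec is not None else None,
    }
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest_path


def load_dataset(manifest_path: str) -> list[LabeledImage]:
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    root = os.path.dirname(manifest_path)
    images = []
    for e in manifest["entries"]:
        if manifest["format"] == "png":
            img = read_image_png(os.path.join(root, e["image"]))
            mask = read_mask_png(os.path.join(root, e["mask"]))
            spacing = e.get("pixel_size_mm", 1.0)
        else:
            img, spacing = read_nifti(os.path.join(root, e["image"]))
            mask, _ = read_nifti(os.path.join(root, e["mask"]))
        images.append(LabeledImage(np.asarray(img, np.float32),
                                   np.asarray(mask, np.uint8),
                                   pixel_size_mm=spacing, ident=e["ident"]))
    return images


def save_arrays(path: str, **arrays: np.ndarray) -> None:
    """Logit/embedding array container (compressed npz + JSON header)."""
    np.savez_compressed(path, **arrays)
    with open(path + ".json", "w") as fh:
        json.dump({k: list(v.shape) for k, v in arrays.items()}, fh)


def load_arrays(path: str) -> dict[str, np.ndarray]:
    with np.load(path) as data:
        return {k: data[k] for k in data.files}
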