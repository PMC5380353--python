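"""Image readers/writers and result serialization.

Readers accept 8/16-bit grayscale PNG/TIFF (RGB reduced by luminance) and
single-slice NIfTI; all intensities are returned as floats on the 0-255
scale.  Writers emit text- and image-format artifacts for a finished fit:
a paletted label PNG, per-phase binary masks, the bias field and corrected
image as 32-bit TIFF (plus 8-bit previews), an iteration log CSV and a
config snapshot JSON.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["read_image", "read_mask", "write_outputs", "write_phantom"]

#: ITU-R 601 luminance weights for RGB -> gray reduction
_LUMA = np.array([0.299, 0.587, 0.114])


def read_image(path, slice_index: int | None = None) -> np.ndarray:
    """Load a 2-D grayscale image as float64 on the 0-255 scale.

    PNG/TIFF: 8-bit values pass through unchanged; 16-bit values are
    rescaled linearly so 65535 maps to 255; RGB(A) is reduced by luminance.
    NIfTI (.nii/.nii.gz): a 2-D volume loads directly, a 3-D volume needs
    ``slice_index`` (axial slice); intensities are rescaled so the volume
    max maps to 255.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        data = np.asanyarray(nib.load(path).dataobj).astype(float)
        if data.ndim == 3:
            if slice_index is None:
                raise IOError(
                    f"{path} holds a 3-D volume; a slice index is required")
            data = data[:, :, slice_index]
        elif data.ndim != 2:
            raise IOError(f"{path}: unsupported NIfTI dimensionality {data.ndim}")
        peak = data.max()
        if peak > 0:
            data = data * (255.0 / peak)
        logger.info("read NIfTI %s -> %s", path, data.shape)
        return np.ascontiguousarray(data)

    import imageio.v3 as iio

    raw = iio.imread(path)
    if raw.ndim == 3:  # RGB(A) -> luminance
        raw = raw[..., :3].astype(float) @ _LUMA
    arr = raw.astype(float)
    if np.issubdtype(np.asarray(raw).dtype, np.integer) and raw.dtype.itemsize > 1:
        arr = arr * (255.0 / 65535.0)
    elif arr.size and arr.max() <= 1.0 and arr.min() >= 0:
        logger.info("float image in [0, 1]; rescaling to 0-255")
        arr = arr * 255.0
    if arr.ndim != 2:
        raise IOError(f"{path}: expected a 2-D grayscale image")
    logger.info("read image %s -> %s", path, arr.shape)
    return arr


def read_mask(path) -> np.ndarray:
    """Load a binary mask image (any nonzero pixel counts as inside)."""
    return read_image(path) > 0


def _to_uint8(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    lo, hi = a.min(), a.max()
    if hi <= lo:
        return np.zeros(a.shape, dtype=np.uint8)
    return np.round(255.0 * (a - lo) / (hi - lo)).astype(np.uint8)


_PALETTE = [
    (0, 0, 0), (230, 70, 60), (70, 160, 230), (90, 200, 120), (240, 200, 60),
]


def _write_label_png(labels: np.ndarray, path: Path):
    from PIL import Image

    img = Image.fromarray(labels.astype(np.uint8), mode="P")
    palette = []
    for rgb in _PALETTE:
        palette.extend(rgb)
    img.putpalette(palette + [0] * (768 - 3 * len(_PALETTE)))
    img.save(path)


def write_outputs(result, out_dir) -> dict[str, Path]:
    """Serialize an :class:`~lgfiseg.model.LGFIResults` to ``out_dir``.

    Returns a name -> path map of everything written.
    """
    import imageio.v3 as iio
    import tifffile

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise IOError(f"cannot write to {out_dir}: {exc}") from exc

    files: dict[str, Path] = {}

    files["labels"] = out_dir / "labels.png"
    _write_label_png(result.labels, files["labels"])

    for i in range(1, int(result.labels.max()) + 1):
        key = f"phase_{i}_mask"
        files[key] = out_dir / f"phase_{i}_mask.png"
        iio.imwrite(files[key],
                    ((result.labels == i) * 255).astype(np.uint8))

    files["bias"] = out_dir / "bias_field.tif"
    tifffile.imwrite(files["bias"], result.bias.astype(np.float32))
    files["bias_preview"] = out_dir / "bias_field_preview.png"
    iio.imwrite(files["bias_preview"], _to_uint8(result.bias))

    files["corrected"] = out_dir / "bias_corrected.tif"
    tifffile.imwrite(files["corrected"], result.corrected.astype(np.float32))
    files["corrected_preview"] = out_dir / "bias_corrected_preview.png"
    iio.imwrite(files["corrected_preview"], _to_uint8(result.corrected))

    files["iterations"] = out_dir / "iterations.csv"
    with open(files["iterations"], "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["iteration", "sign_flips", "mean_abs_dphi"])
        for row in result.diagnostics.itertuples(index=False):
            writer.writerow([row.iteration, row.sign_flips, row.mean_abs_dphi])

    files["config"] = out_dir / "config.json"
    snapshot = {
        "config": result.model.config.to_dict(),
        "phases": result.model.phases,
        "iterations": result.n_iter,
        "converged": result.converged,
    }
    files["config"].write_text(json.dumps(snapshot, indent=2))
    logger.info("wrote %d output files to %s", len(files), out_dir)
    return files


def write_phantom(phantom, out_dir, stem: str = "phantom") -> dict[str, Path]:
    """Write a phantom's image (8-bit PNG), labels (paletted PNG), true
    bias (32-bit TIFF) and generation spec (JSON sidecar)."""
    import imageio.v3 as iio
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {
        "image": out_dir / f"{stem}.png",
        "labels": out_dir / f"{stem}_labels.png",
        "bias": out_dir / f"{stem}_bias.tif",
        "spec": out_dir / f"{stem}.json",
    }
    iio.imwrite(files["image"], np.round(phantom.image).astype(np.uint8))
    _write_label_png(phantom.labels, files["labels"])
    tifffile.imwrite(files["bias"], phantom.true_bias.astype(np.float32))
    files["spec"].write_text(json.dumps(
        {"seed": phantom.seed, "noise_sigma": phantom.noise_sigma,
         "shape": list(phantom.shape), **dict(phantom.spec)}, indent=2))
    return files
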