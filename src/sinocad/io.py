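"""File formats: NIfTI volumes/masks, patch archives, sinogram archives."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import CTVolume, ROIPatch
from .sinogram import ChannelStack


def save_volume(volume: CTVolume, path: str | Path) -> None:
    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(volume.intensities.astype(np.float32), affine), str(path))


def load_volume(path: str | Path) -> CTVolume:
    img = nib.load(str(path))
    spacing = tuple(float(abs(z)) for z in np.diag(img.affine)[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return CTVolume(np.asarray(img.get_fdata(), dtype=np.float64),
                    spacing=spacing, origin=origin)


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), np.eye(4)), str(path))


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata()) > 0.5


def save_patches(patches: list[ROIPatch], directory: str | Path,
                 source: str = "synthetic", seed: int | None = None) -> None:
    """Compressed array archive plus a CSV index (patch_id, label, source, seed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {p.roi_id: p.pixels.astype(np.float32) for p in patches}
    np.savez_compressed(directory / "patches.npz", **arrays)
    pd.DataFrame({
        "patch_id": [p.roi_id for p in patches],
        "label": [p.label if p.label is not None else -1 for p in patches],
        "source": source,
        "seed": seed if seed is not None else -1,
    }).to_csv(directory / "index.csv", index=False)


def load_patches(directory: str | Path) -> list[ROIPatch]:
    directory = Path(directory)
    arrays = np.load(directory / "patches.npz")
    index = pd.read_csv(directory / "index.csv")
    out = []
    for _, row in index.iterrows():
        label = None if row["label"] < 0 else int(row["label"])
        out.append(ROIPatch(np.asarray(arrays[row["patch_id"]], dtype=np.float64),
                            roi_id=str(row["patch_id"]), label=label, normalized=True))
    return out


def save_stacks(stacks: dict[str, ChannelStack], directory: str | Path) -> None:
    """Channel stacks as a compressed archive with a JSON geometry sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(directory / "stacks.npz",
                        **{k: s.values.astype(np.float32) for k, s in stacks.items()})
    meta = {k: {"scheme": s.scheme, "step": s.step,
                "view_map": [m.tolist() for m in s.view_map]}
            for k, s in stacks.items()}
    (directory / "stacks.json").write_text(json.dumps(meta))


def load_stacks(directory: str | Path) -> dict[str, ChannelStack]:
    directory = Path(directory)
    arrays = np.load(directory / "stacks.npz")
    meta = json.loads((directory / "stacks.json").read_text())
    return {k: ChannelStack(np.asarray(arrays[k], dtype=np.float64),
                            scheme=m["scheme"], step=m["step"],
                            view_map=[np.asarray(v) for v in m["view_map"]])
            for k, m in meta.items()}
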