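"""Dataset and feature I/O.

Datasets are directories of class-named subfolders holding PNG/TIFF/BMP
images; class label = subfolder name.  Features are written as full-precision
CSV with a JSON sidecar recording the descriptor configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .base import MomentSpec

__all__ = [
    "DatasetManifest",
    "load_image",
    "read_dataset",
    "write_features",
    "read_features",
    "write_images",
    "load_config",
]

IMAGE_EXTENSIONS = (".png", ".tif", ".tiff", ".bmp")

# Rec. 601 luminance weights for RGB reduction
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class DatasetManifest:
    root: Path
    classes: Dict[str, List[Path]]  # class name -> sorted file list

    @property
    def class_names(self) -> List[str]:
        return sorted(self.classes)

    def counts(self) -> Dict[str, int]:
        return {c: len(v) for c, v in self.classes.items()}


def load_image(path) -> np.ndarray:
    """Decode an image file to a float grayscale array in [0, 1].

    RGB(A) input is reduced with Rec. 601 luminance weights; integer dtypes
    are rescaled by their full range (255 / 65535).
    """
    raw = iio.imread(path)
    arr = raw[..., :3].astype(float) @ _LUMA if raw.ndim == 3 else raw.astype(float)
    if np.issubdtype(raw.dtype, np.integer):
        arr = arr / np.iinfo(raw.dtype).max
    return np.clip(arr, 0.0, 1.0)


def read_dataset(root, skip_bad: bool = False):
    """Read a class-subfolder image directory.

    Returns ``(manifest, images, labels)`` with deterministic lexicographic
    ordering of classes and files.  Unreadable files abort the run with the
    offending path unless ``skip_bad`` is set.
    """
    root = Path(root)
    if not root.is_dir():
        raise ValueError(f"dataset root {root} is not a directory")
    classes: Dict[str, List[Path]] = {}
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        files = sorted(
            p for p in sub.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS
        )
        if not files:
            raise ValueError(f"dataset subfolder {sub} contains no images")
        classes[sub.name] = files
    if not classes:
        raise ValueError(f"dataset root {root} has no class subfolders")
    images, labels = [], []
    for cname in sorted(classes):
        kept = []
        for f in classes[cname]:
            try:
                images.append(load_image(f))
            except Exception as exc:
                if skip_bad:
                    continue
                raise ValueError(f"unreadable image file {f}: {exc}") from exc
            kept.append(f)
            labels.append(cname)
        classes[cname] = kept
    return DatasetManifest(root=root, classes=classes), images, np.asarray(labels)


def write_features(
    matrix: np.ndarray,
    labels: Sequence,
    paths: Sequence,
    feature_labels: Sequence[str],
    out_path,
    descriptor: str = "",
    spec: Optional[MomentSpec] = None,
    seed: Optional[int] = None,
) -> Path:
    """Write a feature matrix as full-precision CSV plus a JSON sidecar."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] != len(labels) or matrix.shape[0] != len(paths):
        raise ValueError("row count must equal the number of images")
    if matrix.shape[1] != len(feature_labels):
        raise ValueError("column count must equal the number of feature labels")
    out_path = Path(out_path)
    df = pd.DataFrame(matrix, columns=list(feature_labels))
    df.insert(0, "label", list(labels))
    df.insert(0, "path", [str(p) for p in paths])
    # %.17e round-trips float64 exactly through pandas' default csv parser
    df.to_csv(out_path, index=False, float_format="%.17e")
    meta = {
        "descriptor": descriptor,
        "spec": spec.to_dict() if spec is not None else None,
        "seed": seed,
        "version": _pkg_version(),
        "n_rows": int(matrix.shape[0]),
        "n_features": int(matrix.shape[1]),
    }
    out_path.with_suffix(out_path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True)
    )
    return out_path


def read_features(path) -> Tuple[np.ndarray, np.ndarray, List[str], List[str]]:
    """Inverse of :func:`write_features`.

    Returns ``(matrix, labels, paths, feature_labels)``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    paths = df.pop("path").tolist()
    labels = df.pop("label").to_numpy()
    return df.to_numpy(dtype=float), labels, paths, list(df.columns)


def write_images(images, labels, out_dir, class_names: Optional[Sequence[str]] = None) -> Path:
    """Write images as 16-bit PNGs into class-named subfolders."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counters: Dict[str, int] = {}
    for img, lab in zip(images, labels):
        cname = class_names[int(lab)] if class_names is not None else f"class{lab}"
        sub = out_dir / cname
        sub.mkdir(exist_ok=True)
        i = counters.get(cname, 0)
        counters[cname] = i + 1
        data = np.round(np.clip(img, 0, 1) * 65535).astype(np.uint16)
        iio.imwrite(sub / f"img_{i:04d}.png", data)
    return out_dir


def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def _pkg_version() -> str:
    from . import __version__

    return __version__
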