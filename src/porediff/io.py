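"""Serialization: samples, fields, datasets and manifests.

Geometry is stored losslessly as compressed ``.npz`` (grid + provenance) and
optionally rendered to 1-bit PNG with the display convention white = solid,
black = fluid.  Fields go to compressed ``.npz`` with the fluid mask and
solver diagnostics; datasets are bundled into a single ``.npz`` container to
avoid thousands of small files.  The manifest is a CSV table with one row
per sample: id, type, seed, target_phi, phi, D, split, paths.

Coordinate convention in every file: 0-based, x = column = transport axis,
origin top-left.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .geometry import PorousSample, SampleType
from .lbm import ConcentrationField

__all__ = [
    "save_sample",
    "load_sample",
    "sample_to_png",
    "sample_from_png",
    "save_field",
    "load_field",
    "write_manifest",
    "read_manifest",
    "manifest_hash",
]

_HEADER = {"coords": "0-based, x=column=transport axis, origin top-left"}


def save_sample(path, sample: PorousSample) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        grid=np.packbits(sample.grid),
        side=sample.side_length,
        sample_type=str(sample.sample_type.value),
        target_porosity=sample.target_porosity,
        seed=sample.seed,
        meta=json.dumps({**_HEADER, **sample.meta}),
    )


def load_sample(path) -> PorousSample:
    try:
        with np.load(path, allow_pickle=False) as z:
            side = int(z["side"])
            grid = np.unpackbits(z["grid"], count=side * side).reshape(side, side)
            meta = json.loads(str(z["meta"]))
            return PorousSample(
                grid.astype(bool),
                sample_type=SampleType(str(z["sample_type"])),
                target_porosity=float(z["target_porosity"]),
                seed=int(z["seed"]),
                meta=meta,
            )
    except KeyError as exc:
        raise ValueError(f"corrupt sample file {path}: missing field {exc}") from exc


def sample_to_png(path, sample: PorousSample) -> None:
    """Render: white = solid, black = fluid."""
    img = Image.fromarray(np.where(sample.grid, 0, 255).astype(np.uint8), mode="L")
    img.convert("1").save(path)


def sample_from_png(path, **kwargs) -> PorousSample:
    arr = np.asarray(Image.open(path).convert("L"))
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"geometry image must be square, got shape {arr.shape}")
    return PorousSample(arr < 128, **kwargs)


def save_field(path, field: ConcentrationField) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        values=field.values,
        fluid_mask=np.packbits(field.fluid_mask),
        side=field.values.shape[0],
        iterations_run=field.iterations_run,
        final_delta=field.final_delta,
        converged=field.converged,
        meta=json.dumps({**_HEADER, **{k: str(v) for k, v in field.meta.items()}}),
    )


def load_field(path) -> ConcentrationField:
    with np.load(path, allow_pickle=False) as z:
        side = int(z["side"])
        mask = np.unpackbits(z["fluid_mask"], count=side * side).reshape(side, side)
        return ConcentrationField(
            values=z["values"],
            fluid_mask=mask.astype(bool),
            iterations_run=int(z["iterations_run"]),
            final_delta=float(z["final_delta"]),
            converged=bool(z["converged"]),
            meta=json.loads(str(z["meta"])),
        )


def field_to_png(path, field: ConcentrationField) -> None:
    """Grayscale render of the concentration map (0 -> black, 1 -> white)."""
    v = np.clip(field.values, 0.0, 1.0)
    Image.fromarray((v * 255).astype(np.uint8), mode="L").save(path)


MANIFEST_COLUMNS = [
    "sample_id", "type", "seed", "target_phi", "phi", "D", "split",
    "geometry_path", "field_path",
]


def write_manifest(path, rows: list[dict]) -> None:
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path)


def manifest_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
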