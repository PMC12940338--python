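"""File interchange: TIFF stacks with JSON sidecars, CSV tables, oracles.

Image data travel as multi-page TIFF with the physical scale and the
reference planes recorded in a JSON sidecar next to the image file
(same stem, ``.json`` suffix); tables are plain CSV with a header row.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .csg import CrossSectionImage
from .dental import LabeledToothVolume
from .synthetic import ImageStack

__all__ = [
    "sidecar_path",
    "save_section_stack",
    "load_section_stack",
    "save_labeled_volume",
    "load_labeled_volume",
    "save_oracle_json",
    "read_trait_matrix",
]


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def save_section_stack(stack: ImageStack, path: str | Path) -> None:
    """Write sections as multi-page TIFF plus a JSON sidecar.

    The sidecar records spacing (mm/pixel), the section fractions in page
    order, total length, and the closed-form oracle per section.
    """
    path = Path(path)
    fractions = sorted(stack.sections)
    pages = [stack.sections[f].mask.astype(np.uint8) for f in fractions]
    spacings = {stack.sections[f].spacing for f in fractions}
    if len(spacings) != 1:
        raise ValueError("all sections in one stack must share a pixel spacing")
    tifffile.imwrite(path, np.stack(pages))
    meta = {
        "spacing_mm": spacings.pop(),
        "fractions": fractions,
        "total_length_mm": stack.total_length,
        "oracles": {
            str(f): dataclasses.asdict(stack.oracles[f])
            for f in fractions
            if f in stack.oracles
        },
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=1))


def load_section_stack(path: str | Path) -> dict[float, CrossSectionImage]:
    """Read a section stack written by :func:`save_section_stack`."""
    path = Path(path)
    meta = json.loads(sidecar_path(path).read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    out = {}
    for page, frac in zip(pages, meta["fractions"]):
        out[float(frac)] = CrossSectionImage(
            mask=page > 0,
            spacing=float(meta["spacing_mm"]),
            section_fraction=float(frac),
        )
    return out


def save_labeled_volume(lab: LabeledToothVolume, path: str | Path) -> None:
    """Write a labeled tooth volume as multi-page TIFF (pages along z)."""
    path = Path(path)
    tifffile.imwrite(path, np.moveaxis(lab.labels, 2, 0))
    meta = {
        "voxel_mm": lab.voxel,
        "cervical_z": lab.cervical_z,
        "bifurcation_z": lab.bifurcation_z,
        "origin_z": lab.origin_z,
        "labels": {"background": 0, "enamel": 1, "dentine": 2, "pulp": 3},
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=1))


def load_labeled_volume(path: str | Path) -> LabeledToothVolume:
    """Read a labeled tooth volume written by :func:`save_labeled_volume`."""
    path = Path(path)
    meta = json.loads(sidecar_path(path).read_text())
    pages = tifffile.imread(path)
    return LabeledToothVolume(
        labels=np.moveaxis(pages, 0, 2),
        voxel=float(meta["voxel_mm"]),
        cervical_z=float(meta["cervical_z"]),
        bifurcation_z=float(meta["bifurcation_z"]),
        origin_z=float(meta.get("origin_z", 0.0)),
    )


def save_oracle_json(oracle, path: str | Path) -> None:
    """Serialize any phantom oracle dataclass to JSON."""
    Path(path).write_text(json.dumps(dataclasses.asdict(oracle), indent=1))


def read_trait_matrix(path: str | Path) -> pd.DataFrame:
    """Read an individuals x traits CSV with cells in {0, 1, NA}."""
    frame = pd.read_csv(path, index_col=0)
    return frame.apply(pd.to_numeric)
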