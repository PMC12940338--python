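"""Cross-sectional geometry (CSG) of long-bone diaphyses.

Biomechanical section properties of a cortical-bone cross section:
total subperiosteal area TA (outer contour including the medullary
cavity), cortical area CA, percent cortical area %CA = 100*CA/TA,
second moments of area Ix (about the mediolateral axis) and Iy (about
the anteroposterior axis), the product moment Ixy, principal moments
Imax/Imin, the principal-axis angle, and the polar moment J = Ix + Iy.
Also the Martin external-diameter shaft indices (pilastric, platymeric)
and multi-level diaphyseal profiles at standard section fractions.

Axis convention: image columns are the mediolateral (x) direction,
image rows the anteroposterior (y) direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "CrossSectionImage",
    "CSGResult",
    "ExternalDiameters",
    "DiaphysisProfile",
    "DEFAULT_SECTION_FRACTIONS",
    "fill_subperiosteal",
    "compute_csg",
    "pilastric_index",
    "platymeric_index",
    "platymeric_band",
    "profile_csg",
]

#: Standard femoral section levels, as fractions of total bone length.
DEFAULT_SECTION_FRACTIONS = (0.20, 0.35, 0.50, 0.65, 0.80)


@dataclass
class CrossSectionImage:
    """A binary cortical-bone section with physical pixel spacing.

    ``mask[row, col]`` is True on cortical bone; ``spacing`` is the pixel
    edge length in mm.  ``section_fraction`` optionally records where along
    the diaphysis the section was taken (fraction of total length).
    """

    mask: np.ndarray
    spacing: float
    section_fraction: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a 2-D array")
        if not self.spacing > 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.section_fraction is not None and not 0 < self.section_fraction < 1:
            raise ValueError("section_fraction must lie in (0, 1)")


@dataclass
class CSGResult:
    """Full set of section properties, in mm / mm**2 / mm**4 / degrees."""

    TA: float
    CA: float
    pctCA: float
    centroid: tuple[float, float]
    Ix: float
    Iy: float
    Ixy: float
    Imax: float
    Imin: float
    theta_deg: float
    J: float
    shape_ratio: float


@dataclass
class ExternalDiameters:
    """External shaft diameters (mm) at midshaft and subtrochanteric levels."""

    AP_mid: float
    ML_mid: float
    AP_subtroch: float
    ML_subtroch: float

    def __post_init__(self) -> None:
        for name in ("AP_mid", "ML_mid", "AP_subtroch", "ML_subtroch"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class DiaphysisProfile:
    """Per-level section properties along the diaphysis."""

    results: dict[float, CSGResult]
    total_length: float | None = None

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for frac in sorted(self.results):
            r = self.results[frac]
            rows.append(
                {
                    "fraction": frac,
                    "TA": r.TA,
                    "CA": r.CA,
                    "pctCA": r.pctCA,
                    "Ix": r.Ix,
                    "Iy": r.Iy,
                    "Ixy": r.Ixy,
                    "Imax": r.Imax,
                    "Imin": r.Imin,
                    "theta_deg": r.theta_deg,
                    "J": r.J,
                    "Imax_over_Imin": r.shape_ratio,
                }
            )
        return pd.DataFrame(rows)


# cortical bone 8-connected, background 4-connected: the standard digital
# topology pairing, so a diagonally-connected cortex cannot leak the cavity.
_CORTEX_STRUCTURE = np.ones((3, 3), dtype=bool)
_BACKGROUND_STRUCTURE = ndimage.generate_binary_structure(2, 1)


def fill_subperiosteal(mask: np.ndarray) -> np.ndarray:
    """Fill the medullary cavity of a single cortical ring.

    Returns the total subperiosteal region: cortical pixels plus every
    enclosed cavity pixel.  The outer contour is unchanged.

    Raises
    ------
    ValueError
        If the mask is empty, contains more than one 8-connected cortical
        component, or touches the image border (in which case closure of
        the ring cannot be guaranteed and the cavity may leak outside).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: no cortical pixels")
    _, n_comp = ndimage.label(mask, structure=_CORTEX_STRUCTURE)
    if n_comp != 1:
        raise ValueError(
            f"expected exactly one cortical ring, found {n_comp} disjoint components"
        )
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    if (mask & border).any():
        raise ValueError(
            "cortical mask touches the image border; cannot verify a closed ring"
        )
    return ndimage.binary_fill_holes(mask, structure=_BACKGROUND_STRUCTURE)


def compute_csg(section: CrossSectionImage) -> CSGResult:
    """Compute all section properties of a cortical cross section.

    Each cortical pixel contributes as a solid square of side ``spacing``:
    its own second moment s**4/12 is added to the parallel-axis term, so
    the estimate converges to the continuum value as spacing shrinks.
    Moments are taken about centroidal axes of the cortical area.
    """
    mask = np.asarray(section.mask, dtype=bool)
    s = section.spacing
    n_cort = int(mask.sum())
    if n_cort == 0:
        raise ValueError("empty mask: nothing to measure")
    if n_cort == 1:
        raise ValueError("degenerate section: a single cortical pixel")

    filled = fill_subperiosteal(mask)
    TA = float(filled.sum()) * s * s
    CA = float(n_cort) * s * s

    rows, cols = np.nonzero(mask)
    # pixel-center coordinates in mm; x along columns (ML), y along rows (AP)
    x = (cols + 0.5) * s
    y = (rows + 0.5) * s
    xc, yc = float(x.mean()), float(y.mean())
    dx = x - xc
    dy = y - yc
    cell = s**4 / 12.0  # self-moment of a solid square pixel
    Ix = float(np.sum(dy * dy) * s * s + n_cort * cell)
    Iy = float(np.sum(dx * dx) * s * s + n_cort * cell)
    Ixy = float(np.sum(dx * dy) * s * s)

    tensor = np.array([[Ix, -Ixy], [-Ixy, Iy]])
    eigvals = np.linalg.eigvalsh(tensor)
    Imin, Imax = float(eigvals[0]), float(eigvals[1])
    theta = 0.5 * np.degrees(np.arctan2(2.0 * Ixy, Ix - Iy))
    if theta <= -90.0:
        theta += 180.0
    J = Ix + Iy
    return CSGResult(
        TA=TA,
        CA=CA,
        pctCA=100.0 * CA / TA,
        centroid=(xc, yc),
        Ix=Ix,
        Iy=Iy,
        Ixy=Ixy,
        Imax=Imax,
        Imin=Imin,
        theta_deg=float(theta),
        J=J,
        shape_ratio=Imax / Imin if Imin > 0 else np.inf,
    )


def pilastric_index(d: ExternalDiameters) -> float:
    """Midshaft pilastric index, 100 * AP / ML (Martin convention)."""
    return 100.0 * d.AP_mid / d.ML_mid


def platymeric_index(d: ExternalDiameters) -> float:
    """Subtrochanteric platymeric index, 100 * AP / ML (Martin convention)."""
    return 100.0 * d.AP_subtroch / d.ML_subtroch


def platymeric_band(index: float) -> str:
    """Martin band for the platymeric index: values below 85 are platymeric."""
    if index < 85.0:
        return "platymeric"
    if index < 100.0:
        return "eurymeric"
    return "stenomeric"


def profile_csg(
    stack: Mapping[float, CrossSectionImage],
    fractions: Sequence[float] = DEFAULT_SECTION_FRACTIONS,
    total_length: float | None = None,
) -> DiaphysisProfile:
    """Compute section properties at each requested level of a diaphysis.

    ``stack`` maps section fraction -> section image.  Every requested
    fraction must be present; missing levels raise with the absent list.
    """
    missing = [f for f in fractions if f not in stack]
    if missing:
        raise ValueError(f"stack is missing sections at fractions {sorted(missing)}")
    results = {float(f): compute_csg(stack[f]) for f in fractions}
    return DiaphysisProfile(results=results, total_length=total_length)
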