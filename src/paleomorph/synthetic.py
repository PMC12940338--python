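"""Synthetic phantoms and simulated tables with closed-form ground truth.

Every downstream stage of the package is exercisable without fossil data:

* hollow elliptical diaphysis sections whose areas and second moments of
  area have exact closed forms (optionally rotated; rotation handled by
  tensor rotation of the axis-aligned moments, exact at any angle);
* a shell-model tooth — hemispherical enamel cap over a dentine
  hemisphere with hemispherical pulp chamber, on a cylindrical root whose
  canal splits into two half-radius branches below the bifurcation
  plane — with sphere/cylinder closed forms for every tissue volume and
  for the EDJ surface;
* binary trait matrices with planted cluster prototypes, label-flip
  noise and appended dummy (all-present / all-absent) columns;
* multi-group multivariate-normal craniometric tables with controllable
  missingness.

Rasterization rule everywhere: a pixel/voxel belongs to a material iff
its center lies inside the analytic region (an unbiased area estimator).
All generators are deterministic given their spec (and seed, where one
exists).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .csg import CrossSectionImage
from .dental import (
    BACKGROUND,
    DENTINE,
    ENAMEL,
    PULP,
    GrayToothVolume,
    LabeledToothVolume,
)

__all__ = [
    "AnnulusSpec",
    "ClosedFormMoments",
    "make_annulus_section",
    "ImageStack",
    "make_phantom_diaphysis",
    "ShellToothSpec",
    "ShellToothOracle",
    "make_shell_tooth",
    "balanced_vbi_spec",
    "make_gray_tooth",
    "TraitSimSpec",
    "make_trait_matrix",
    "CranioSimSpec",
    "make_craniometric_table",
]


# ---------------------------------------------------------------------------
# elliptical-annulus diaphysis sections


@dataclass(frozen=True)
class AnnulusSpec:
    """Hollow elliptical cross section: outer/inner semi-axes (mm),
    rotation (degrees CCW), raster spacing (mm/pixel), margin (pixels)."""

    a_out: float
    b_out: float
    a_in: float = 0.0
    b_in: float = 0.0
    rotation: float = 0.0
    spacing: float = 0.1
    image_margin: int = 3

    def __post_init__(self) -> None:
        if not (self.a_out > 0 and self.b_out > 0):
            raise ValueError("outer semi-axes must be positive")
        if self.a_in < 0 or self.b_in < 0:
            raise ValueError("inner semi-axes must be non-negative")
        if (self.a_in > 0) != (self.b_in > 0):
            raise ValueError("degenerate inner ellipse: one semi-axis is zero")
        if self.a_in > 0 and (self.a_in >= self.a_out or self.b_in >= self.b_out):
            raise ValueError("inner ellipse must lie strictly inside the outer")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        if self.image_margin < 0:
            raise ValueError("image_margin must be non-negative")


@dataclass
class ClosedFormMoments:
    """Exact section properties of an elliptical annulus (mm^2 / mm^4)."""

    TA: float
    CA: float
    pctCA: float
    Ix: float
    Iy: float
    Ixy: float
    Imax: float
    Imin: float
    J: float


def _annulus_closed_form(spec: AnnulusSpec) -> ClosedFormMoments:
    ao, bo, ai, bi = spec.a_out, spec.b_out, spec.a_in, spec.b_in
    TA = math.pi * ao * bo
    CA = math.pi * (ao * bo - ai * bi)
    # centroidal moments of the axis-aligned annulus (x = ML semi-axis a)
    Ix0 = math.pi / 4.0 * (ao * bo**3 - ai * bi**3)
    Iy0 = math.pi / 4.0 * (ao**3 * bo - ai**3 * bi)
    # rotate the second-moment tensor S = [[Int x^2, Int xy], [Int xy, Int y^2]]
    th = math.radians(spec.rotation)
    c, s = math.cos(th), math.sin(th)
    R = np.array([[c, -s], [s, c]])
    S = R @ np.diag([Iy0, Ix0]) @ R.T
    Iy, Ix, Ixy = float(S[0, 0]), float(S[1, 1]), float(S[0, 1])
    eig = np.linalg.eigvalsh(np.array([[Ix, -Ixy], [-Ixy, Iy]]))
    return ClosedFormMoments(
        TA=TA, CA=CA, pctCA=100.0 * CA / TA,
        Ix=Ix, Iy=Iy, Ixy=Ixy,
        Imax=float(eig[1]), Imin=float(eig[0]), J=Ix + Iy,
    )


def make_annulus_section(
    spec: AnnulusSpec,
) -> tuple[CrossSectionImage, ClosedFormMoments]:
    """Rasterize a hollow elliptical section and return its exact moments.

    Cortical pixels are those whose centers lie between the two ellipses.
    """
    th = math.radians(spec.rotation)
    c, s = math.cos(th), math.sin(th)
    hx = math.sqrt((spec.a_out * c) ** 2 + (spec.b_out * s) ** 2)
    hy = math.sqrt((spec.a_out * s) ** 2 + (spec.b_out * c) ** 2)
    sp = spec.spacing
    nx = int(math.ceil(2 * hx / sp)) + 2 * spec.image_margin
    ny = int(math.ceil(2 * hy / sp)) + 2 * spec.image_margin
    # pixel-center coordinates relative to the grid center
    xs = (np.arange(nx) - (nx - 1) / 2.0) * sp
    ys = (np.arange(ny) - (ny - 1) / 2.0) * sp
    X, Y = np.meshgrid(xs, ys)  # X varies along columns, Y along rows
    # rotate back into the ellipse frame
    u = c * X + s * Y
    v = -s * X + c * Y
    inside_out = (u / spec.a_out) ** 2 + (v / spec.b_out) ** 2 <= 1.0
    if spec.a_in > 0:
        inside_in = (u / spec.a_in) ** 2 + (v / spec.b_in) ** 2 < 1.0
    else:
        inside_in = np.zeros_like(inside_out)
    mask = inside_out & ~inside_in
    return CrossSectionImage(mask=mask, spacing=sp), _annulus_closed_form(spec)


@dataclass
class ImageStack:
    """Sections at given fractions of total length, with their oracles."""

    sections: dict[float, CrossSectionImage]
    oracles: dict[float, ClosedFormMoments]
    total_length: float


def make_phantom_diaphysis(
    specs_by_fraction: Mapping[float, AnnulusSpec] | Iterable[tuple[float, AnnulusSpec]],
    length: float,
) -> ImageStack:
    """Build a multi-section diaphysis phantom, one section per fraction."""
    if not isinstance(specs_by_fraction, Mapping):
        pairs = list(specs_by_fraction)
        fracs = [f for f, _ in pairs]
        if len(set(fracs)) != len(fracs):
            raise ValueError("duplicate section fractions")
        specs_by_fraction = dict(pairs)
    if not length > 0:
        raise ValueError("length must be positive")
    sections: dict[float, CrossSectionImage] = {}
    oracles: dict[float, ClosedFormMoments] = {}
    for frac, spec in specs_by_fraction.items():
        if not 0 < frac < 1:
            raise ValueError(f"section fraction {frac} not in (0, 1)")
        img, oracle = make_annulus_section(spec)
        img.section_fraction = frac
        sections[float(frac)] = img
        oracles[float(frac)] = oracle
    return ImageStack(sections=sections, oracles=oracles, total_length=length)


# ---------------------------------------------------------------------------
# shell-model tooth


@dataclass(frozen=True)
class ShellToothSpec:
    """Shell-model tooth phantom (all lengths in mm).

    Crown: enamel cap of thickness ``enamel_thickness`` over a dentine
    hemisphere of radius ``dentine_radius`` holding a hemispherical pulp
    chamber of radius ``pulp_radius``, flat face on the cervical plane.
    Root: cylinder of ``root_radius`` and ``root_length`` below the
    cervical plane; its canal (radius ``pulp_radius``) splits at
    ``bifurcation_offset`` below the CEJ into two branch canals of half
    the radius running to the apex.  Optionally a spherical-cap dimple of
    depth ``basin_dimple_depth`` (carved by a sphere of radius
    ``basin_dimple_radius``) marks an occlusal basin in the enamel cap.
    """

    dentine_radius: float = 5.0
    enamel_thickness: float = 1.0
    pulp_radius: float = 1.5
    root_length: float = 12.0
    root_radius: float = 3.0
    bifurcation_offset: float = 4.0
    voxel: float = 0.15
    basin_dimple_depth: float = 0.0
    basin_dimple_radius: float = 0.0

    def __post_init__(self) -> None:
        if not (self.dentine_radius > 0 and self.enamel_thickness > 0):
            raise ValueError("dentine radius and enamel thickness must be positive")
        if not 0 <= self.pulp_radius < self.dentine_radius:
            raise ValueError("pulp radius must be smaller than the dentine radius")
        if not 0 < self.bifurcation_offset < self.root_length:
            raise ValueError("bifurcation offset must lie within the root length")
        if not self.pulp_radius < self.root_radius:
            raise ValueError("canal (pulp) radius must fit inside the root")
        if not self.voxel > 0:
            raise ValueError("voxel size must be positive")
        if self.basin_dimple_depth < 0 or self.basin_dimple_radius < 0:
            raise ValueError("dimple parameters must be non-negative")
        if self.basin_dimple_depth > 0:
            if self.basin_dimple_depth >= self.enamel_thickness:
                raise ValueError("dimple must not cut through the enamel cap")
            if self.basin_dimple_radius < self.basin_dimple_depth / 2:
                raise ValueError("dimple radius too small for the requested depth")


@dataclass
class ShellToothOracle:
    """Closed-form tissue volumes (mm^3), EDJ area (mm^2) and VBI (%)."""

    Ve: float
    Vcdp: float
    Vpc: float
    Vc: float
    Vcervix: float
    Vbranch: float
    Vt: float
    SEDJ: float
    VBI: float
    cervical_z: float
    bifurcation_z: float
    basin_floor_z: float | None
    coarse_voxel_warning: bool


def _sphere_lens_volume(r1: float, r2: float, d: float) -> float:
    """Volume of the intersection of two spheres with center distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return 4.0 / 3.0 * math.pi * r**3
    return (
        math.pi
        * (r1 + r2 - d) ** 2
        * (d**2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
        / (12.0 * d)
    )


def _shell_tooth_oracle(spec: ShellToothSpec) -> ShellToothOracle:
    R = spec.dentine_radius
    t = spec.enamel_thickness
    p = spec.pulp_radius
    L = spec.root_length
    rr = spec.root_radius
    b = spec.bifurcation_offset
    hemi = lambda r: 2.0 / 3.0 * math.pi * r**3

    Ve = hemi(R + t) - hemi(R)
    basin_floor_z: float | None = None
    if spec.basin_dimple_depth > 0:
        d = spec.basin_dimple_depth
        rd = spec.basin_dimple_radius
        center = (R + t) + rd - d  # dimple sphere center height on the axis
        Ve -= _sphere_lens_volume(R + t, rd, center)
        basin_floor_z = (R + t) - d
    Vpc = hemi(p)
    Vcdp = hemi(R)  # coronal dentine + pulp chamber fill the dentine hemisphere
    Vc = Ve + Vcdp
    Vcervix = Vpc + math.pi * p**2 * b
    Vbranch = 2.0 * math.pi * (p / 2.0) ** 2 * (L - b)
    Vt = Vc + math.pi * rr**2 * L
    total = Vcervix + Vbranch
    return ShellToothOracle(
        Ve=Ve, Vcdp=Vcdp, Vpc=Vpc, Vc=Vc,
        Vcervix=Vcervix, Vbranch=Vbranch, Vt=Vt,
        SEDJ=2.0 * math.pi * R**2,
        VBI=100.0 * Vcervix / total if total > 0 else float("nan"),
        cervical_z=0.0,
        bifurcation_z=-b,
        basin_floor_z=basin_floor_z,
        coarse_voxel_warning=(2.0 * p / spec.voxel) < 8.0,
    )


def make_shell_tooth(
    spec: ShellToothSpec,
) -> tuple[LabeledToothVolume, ShellToothOracle]:
    """Voxelize the shell-model tooth and return closed-form ground truth.

    The grid is aligned so that voxel boundaries fall on integer multiples
    of the voxel size along the occlusal axis with the cervical plane at
    z = 0, making plane-based voxel partitions unambiguous.  If the pulp
    chamber spans fewer than 8 voxels the oracle carries a coarse-voxel
    warning flag.
    """
    oracle = _shell_tooth_oracle(spec)
    R, t, p = spec.dentine_radius, spec.enamel_thickness, spec.pulp_radius
    L, rr, b = spec.root_length, spec.root_radius, spec.bifurcation_offset
    v = spec.voxel

    hx = max(R + t, rr) + 2 * v
    nx = int(math.ceil(2 * hx / v))
    xs = (np.arange(nx) - (nx - 1) / 2.0) * v
    # z voxel centers at (k + 1/2) * v, spanning the root tip to the crown top
    k_lo = -int(math.ceil(L / v)) - 1
    k_hi = int(math.ceil((R + t) / v)) + 1
    zs = (np.arange(k_lo, k_hi) + 0.5) * v

    X = xs[:, None, None]
    Y = xs[None, :, None]
    Z = zs[None, None, :]
    rho2 = X**2 + Y**2  # squared distance to the occlusal axis
    rsph2 = rho2 + Z**2

    labels = np.full((nx, nx, len(zs)), BACKGROUND, dtype=np.uint8)
    crown = Z >= 0.0
    labels[crown & (rsph2 <= (R + t) ** 2)] = ENAMEL
    labels[crown & (rsph2 <= R**2)] = DENTINE
    if p > 0:
        labels[crown & (rsph2 <= p**2)] = PULP
    if spec.basin_dimple_depth > 0:
        rd = spec.basin_dimple_radius
        zc = (R + t) + rd - spec.basin_dimple_depth
        labels[(X**2 + Y**2 + (Z - zc) ** 2) <= rd**2] = BACKGROUND

    root = (Z < 0.0) & (Z >= -L)
    in_root = root & (rho2 <= rr**2)
    labels[in_root] = DENTINE
    if p > 0:
        cervix_canal = in_root & (Z >= -b) & (rho2 <= p**2)
        labels[cervix_canal] = PULP
        off = rr / 2.0  # branch canal centers at +/- root_radius/2 on x
        for sgn in (1.0, -1.0):
            branch = (
                in_root
                & (Z < -b)
                & ((X - sgn * off) ** 2 + Y**2 <= (p / 2.0) ** 2)
            )
            labels[branch] = PULP

    lab = LabeledToothVolume(
        labels=labels,
        voxel=v,
        cervical_z=0.0,
        bifurcation_z=-b,
        origin_z=float(zs[0]),
    )
    return lab, oracle


def balanced_vbi_spec(
    pulp_radius: float = 1.5,
    bifurcation_offset: float = 3.625,
    voxel: float | None = None,
    **kwargs,
) -> ShellToothSpec:
    """Shell-tooth spec whose cervix pulp volume equals its branch volume.

    Solving Vcervix = Vbranch for the root length gives
    L = 3*b + 4*p/3, so the closed-form VBI is exactly 50% and the Keene
    class mesotaurodont sits on its lower band edge.  The defaults put
    24 voxels across the pulp radius with the bifurcation offset and
    root length exact voxel multiples, so the voxel-counted index stays
    within a fraction of a percent of the constructed value.
    """
    p, b = pulp_radius, bifurcation_offset
    root_length = 3.0 * b + 4.0 * p / 3.0
    if voxel is None:
        voxel = p / 24.0
    return ShellToothSpec(
        pulp_radius=p,
        bifurcation_offset=b,
        root_length=root_length,
        voxel=voxel,
        **kwargs,
    )


def make_gray_tooth(
    lab: LabeledToothVolume,
    levels: Mapping[int, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> GrayToothVolume:
    """Grayscale volume from labels: plateau intensities plus Gaussian noise.

    Default plateaus follow micro-CT attenuation order (enamel brightest,
    pulp darkest tissue, background 0); ``noise_sd`` is the noise standard
    deviation on the same intensity scale.
    """
    if levels is None:
        levels = {BACKGROUND: 0.0, PULP: 0.35, DENTINE: 0.65, ENAMEL: 1.0}
    lut = np.zeros(max(levels) + 1, dtype=float)
    for code, value in levels.items():
        lut[code] = value
    intensities = lut[lab.labels]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensities = intensities + rng.normal(0.0, noise_sd, size=intensities.shape)
    return GrayToothVolume(intensities=intensities, voxel=lab.voxel)


# ---------------------------------------------------------------------------
# binary trait matrices


@dataclass(frozen=True)
class TraitSimSpec:
    """Planted-cluster binary trait simulation parameters."""

    n_clusters: int = 2
    n_per_cluster: int = 10
    n_traits: int = 30
    flip_prob: float = 0.05
    n_dummy_present: int = 0
    n_dummy_absent: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_clusters, self.n_per_cluster, self.n_traits) < 1:
            raise ValueError("cluster, individual and trait counts must be >= 1")
        if self.n_dummy_present < 0 or self.n_dummy_absent < 0:
            raise ValueError("dummy column counts must be >= 0")
        if not 0 <= self.flip_prob < 0.5:
            raise ValueError("flip_prob must lie in [0, 0.5)")
        if self.n_traits < self.n_clusters:
            raise ValueError("need at least as many traits as clusters for "
                             "distinct prototypes")


def make_trait_matrix(spec: TraitSimSpec) -> pd.DataFrame:
    """Simulate an individuals x traits binary table with planted clusters.

    Each cluster gets a distinct random binary prototype; entries are
    flipped independently with ``flip_prob``; dummy all-present and
    all-absent columns are appended after the informative traits.  Row
    labels encode the planted cluster (``c<k>_i<j>``).
    """
    rng = np.random.default_rng(spec.seed)
    for _ in range(1000):
        protos = rng.integers(0, 2, size=(spec.n_clusters, spec.n_traits))
        if len({tuple(row) for row in protos}) == spec.n_clusters:
            break
    else:  # pragma: no cover - astronomically unlikely with n_traits >= n_clusters
        raise RuntimeError("could not draw distinct cluster prototypes")

    rows = []
    index = []
    for k in range(spec.n_clusters):
        flips = rng.random((spec.n_per_cluster, spec.n_traits)) < spec.flip_prob
        rows.append(np.abs(protos[k][None, :] - flips.astype(int)))
        index.extend(f"c{k}_i{j}" for j in range(spec.n_per_cluster))
    values = np.vstack(rows)

    columns = [f"T{j + 1:02d}" for j in range(spec.n_traits)]
    frame = pd.DataFrame(values, index=index, columns=columns, dtype=float)
    for j in range(spec.n_dummy_present):
        frame[f"DP{j + 1}"] = 1.0
    for j in range(spec.n_dummy_absent):
        frame[f"DA{j + 1}"] = 0.0
    return frame


# ---------------------------------------------------------------------------
# craniometric tables


@dataclass(frozen=True)
class CranioSimSpec:
    """Multi-group multivariate-normal craniometric simulation parameters.

    ``group_means`` maps group label -> mean vector (one entry per
    variable); ``covariance`` is the shared positive-definite covariance;
    missing entries are inserted independently at ``missing_rate``.
    """

    group_means: Mapping[str, np.ndarray]
    covariance: np.ndarray
    n_per_group: int = 50
    missing_rate: float = 0.0
    seed: int = 0
    variable_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.group_means:
            raise ValueError("at least one group is required")
        cov = np.asarray(self.covariance, dtype=float)
        p = cov.shape[0]
        if cov.shape != (p, p) or not np.allclose(cov, cov.T):
            raise ValueError("covariance must be a symmetric square matrix")
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            raise ValueError("covariance must be positive definite") from None
        for name, mu in self.group_means.items():
            if np.asarray(mu, dtype=float).shape != (p,):
                raise ValueError(f"group {name!r} mean has wrong length")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1 (empty table otherwise)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.variable_names is not None and len(self.variable_names) != p:
            raise ValueError("variable_names length must match covariance size")


def make_craniometric_table(spec: CranioSimSpec) -> pd.DataFrame:
    """Simulate a measurement table with a ``group`` label column.

    Rows are multivariate-normal draws per group; entries are blanked to
    NaN independently at the spec's missing rate.
    """
    rng = np.random.default_rng(spec.seed)
    cov = np.asarray(spec.covariance, dtype=float)
    p = cov.shape[0]
    names = (
        list(spec.variable_names)
        if spec.variable_names is not None
        else [f"V{j + 1:02d}" for j in range(p)]
    )
    blocks = []
    index = []
    groups = []
    for gname, mu in spec.group_means.items():
        draws = rng.multivariate_normal(
            np.asarray(mu, dtype=float), cov, size=spec.n_per_group
        )
        blocks.append(draws)
        index.extend(f"{gname}_{j}" for j in range(spec.n_per_group))
        groups.extend([gname] * spec.n_per_group)
    values = np.vstack(blocks)
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values = np.where(mask, np.nan, values)
    frame = pd.DataFrame(values, index=index, columns=names)
    frame["group"] = groups
    return frame
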