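"""Synthetic head phantom, lesions, and their exposure-driven evolution.

Stand-ins for everything a clinical dosimetry study obtains from
patients and licensed anatomical models: a labelled multi-tissue head
(concentric, optionally ellipsoidal shells of skin, skull, CSF, grey
and white matter), an MRI-like grey-scale rendering with a strongly
hyperintense lesion, and paired pre/post-treatment lesion masks whose
voxel-wise survival follows a configurable ground-truth dose-response
law.  Because the generator's law is known exactly, the analysis
chain can be validated end-to-end by parameter recovery.

Grid conventions: 0-based voxel indices, voxel centers at integer grid
coordinates, world coordinates in millimetres via the affine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import nifti
from .errors import ConfigurationError, PemfDoseError
from .tissues import (
    AIR,
    GREY,
    LABEL_NAMES,
    LESION,
    NAME_LABELS,
    WHITE,
    TissueProperties,
    default_tissue_table,
)

__all__ = [
    "VoxelPhantom",
    "LesionPair",
    "build_layered_head",
    "generate_lesion",
    "evolve_lesion",
    "render_mri_like",
    "lesion_cnr",
    "DEFAULT_LAYERS",
]

# Outside-in shell thicknesses (mm); the core fills the rest.
DEFAULT_LAYERS = (("skin", 4.0), ("skull", 7.0), ("csf", 3.0), ("grey", 15.0))
DEFAULT_CORE = "white"

BRAIN_LABELS = (GREY, WHITE)


@dataclass
class VoxelPhantom:
    """Labelled voxel grid with per-label dispersive electrical properties."""

    labels: np.ndarray
    voxel_size: float  # mm, isotropic
    affine: np.ndarray  # 4x4 grid->world (mm)
    tissue_table: dict  # label -> TissueProperties
    name: str = "phantom"

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.labels.ndim != 3 or min(self.labels.shape) < 8:
            raise ConfigurationError("label volume must be 3-D, >= 8 per axis")
        if self.voxel_size <= 0:
            raise ConfigurationError("voxel_size must be positive")
        present = set(np.unique(self.labels)) - {AIR}
        missing = present - set(self.tissue_table)
        if missing:
            raise ConfigurationError(
                f"labels {sorted(missing)} present but absent from tissue table"
            )

    @property
    def shape(self):
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size ** 3)

    def label_name(self, label: int) -> str:
        props = self.tissue_table.get(label)
        if props is not None:
            return props.name
        return LABEL_NAMES.get(label, str(label))

    # -- geometry ------------------------------------------------------

    def voxel_to_world(self, ijk) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        hom = np.column_stack([ijk, np.ones(len(ijk))])
        return (hom @ self.affine.T)[:, :3]

    def world_to_voxel(self, points_mm) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        hom = np.column_stack([pts, np.ones(len(pts))])
        return (hom @ inv.T)[:, :3]

    def labels_at(self, points_mm) -> np.ndarray:
        """Nearest-voxel label at world points; outside the grid -> air."""
        idx = np.round(self.world_to_voxel(points_mm)).astype(int)
        inside = np.all((idx >= 0) & (idx < np.asarray(self.shape)), axis=1)
        out = np.zeros(len(idx), dtype=self.labels.dtype)
        ii = idx[inside]
        out[inside] = self.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    def voxel_centers_mm(self, mask=None) -> np.ndarray:
        """World coordinates of voxel centers (optionally masked)."""
        if mask is None:
            grids = np.indices(self.shape).reshape(3, -1).T
        else:
            grids = np.argwhere(mask)
        return self.voxel_to_world(grids)

    def mask_voxel_centers_mm(self, mask) -> np.ndarray:
        self._check_congruent(mask)
        return self.voxel_centers_mm(mask)

    def mask_centroid_mm(self, mask) -> np.ndarray:
        self._check_congruent(mask)
        return self.mask_voxel_centers_mm(mask).mean(axis=0)

    def _check_congruent(self, mask):
        if np.asarray(mask).shape != self.shape:
            raise ConfigurationError(
                f"mask shape {np.asarray(mask).shape} does not match "
                f"phantom grid {self.shape}"
            )

    # -- electrical properties ----------------------------------------

    def sigma_star_volume(self, frequency_hz: float,
                          include_displacement: bool = True) -> np.ndarray:
        """Complex conductivity per voxel at one frequency (air = 0)."""
        out = np.zeros(self.shape, dtype=complex)
        for label, props in self.tissue_table.items():
            if label == AIR:
                continue
            region = self.labels == label
            if np.any(region):
                out[region] = props.complex_conductivity(
                    frequency_hz, include_displacement=include_displacement
                )
        return out

    def conducting_mask(self) -> np.ndarray:
        return self.labels != AIR

    def with_lesion(self, mask, properties: TissueProperties | None = None,
                    label: int = LESION) -> "VoxelPhantom":
        """Return a copy with the lesion voxels relabelled as edema."""
        self._check_congruent(mask)
        if properties is None:
            grey = self.tissue_table.get(GREY)
            if grey is None:
                raise ConfigurationError("phantom has no grey matter to copy "
                                         "permittivity from")
            from .tissues import edema_properties

            properties = edema_properties(grey)
        labels = self.labels.copy()
        labels[np.asarray(mask, dtype=bool)] = label
        table = dict(self.tissue_table)
        table[label] = properties
        return VoxelPhantom(labels, self.voxel_size, self.affine.copy(),
                            table, name=self.name)

    # -- persistence ---------------------------------------------------

    def save(self, path):
        """Write labels as NIfTI plus the tissue table CSV alongside."""
        path = Path(path)
        nifti.write_volume(path, self.labels.astype(np.int16), self.affine,
                           dtype=np.int16)
        nifti.write_tissue_table(_tissue_csv_path(path), self.tissue_table)
        return path

    @classmethod
    def load(cls, path, name: str = "phantom") -> "VoxelPhantom":
        path = Path(path)
        labels, affine = nifti.read_volume(path)
        table = nifti.read_tissue_table(_tissue_csv_path(path))
        voxel = float(np.abs(affine[0, 0]))
        return cls(np.asarray(labels).astype(np.int16), voxel, affine, table,
                   name=name)


def _tissue_csv_path(path: Path) -> Path:
    stem = path.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return path.with_name(stem + "_tissues.csv")


@dataclass
class LesionPair:
    """Congruent pre/post-treatment lesion masks plus generation metadata."""

    pre_mask: np.ndarray
    post_mask: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pre_mask = np.asarray(self.pre_mask, dtype=bool)
        self.post_mask = np.asarray(self.post_mask, dtype=bool)
        if self.pre_mask.shape != self.post_mask.shape:
            raise ConfigurationError("pre/post masks are not congruent")


def build_layered_head(
    radius_mm: float = 90.0,
    layers=DEFAULT_LAYERS,
    core: str = DEFAULT_CORE,
    voxel_size_mm: float = 2.0,
    tissue_table: dict | None = None,
    margin_voxels: int = 2,
    semiaxis_scale=(1.0, 1.0, 1.0),
    name: str = "layered-head",
) -> VoxelPhantom:
    """Concentric-shell head phantom (optionally ellipsoidal).

    ``layers`` lists (tissue name, thickness mm) outside-in starting at
    the skin; the ``core`` tissue fills the interior.  Zero-thickness
    layers are skipped.  Refuses voxel sizes coarser than the thinnest
    layer, which could not be resolved on the grid.
    """
    layers = [(str(n), float(t)) for n, t in layers]
    thick = [t for _, t in layers if t > 0]
    if thick and voxel_size_mm > min(thick):
        raise ConfigurationError(
            f"voxel size {voxel_size_mm} mm exceeds the thinnest layer "
            f"({min(thick)} mm); it cannot be resolved"
        )
    if sum(t for _, t in layers) >= radius_mm:
        raise ConfigurationError("layer thicknesses must sum to less than the radius")

    scale = np.asarray(semiaxis_scale, dtype=float)
    if np.any(scale <= 0):
        raise ConfigurationError("semiaxis scales must be positive")

    dims = tuple(
        int(np.ceil(2.0 * radius_mm * s / voxel_size_mm)) + 2 * margin_voxels
        for s in scale
    )
    labels = np.zeros(dims, dtype=np.int16)
    # Head centered at world origin; voxel centers at integer indices.
    translation = -(np.asarray(dims) - 1) / 2.0 * voxel_size_mm
    affine = np.eye(4)
    affine[:3, :3] = np.eye(3) * voxel_size_mm
    affine[:3, 3] = translation

    grids = np.indices(dims, dtype=float)
    coords = [grids[i] * voxel_size_mm + translation[i] for i in range(3)]
    # Generalized radius: points with r <= radius lie inside the head.
    r = np.sqrt(sum((c / s) ** 2 for c, s in zip(coords, scale)))

    table = dict(tissue_table) if tissue_table is not None else default_tissue_table()
    next_free = max([*table.keys(), *LABEL_NAMES.keys()]) + 1

    def label_for(tissue_name: str) -> int:
        nonlocal next_free
        if tissue_name in NAME_LABELS:
            return NAME_LABELS[tissue_name]
        for lbl, props in table.items():
            if props.name == tissue_name:
                return lbl
        lbl = next_free
        next_free += 1
        return lbl

    outer = radius_mm
    for tissue_name, thickness in layers:
        if thickness <= 0:
            continue
        inner = outer - thickness
        shell = (r <= outer) & (r > inner)
        labels[shell] = label_for(tissue_name)
        outer = inner
    labels[r <= outer] = label_for(core)

    return VoxelPhantom(labels, voxel_size_mm, affine, table, name=name)


def generate_lesion(
    phantom: VoxelPhantom,
    centroid_mm,
    principal_radii_mm,
    irregularity: float = 0.25,
    seed: int = 0,
    brain_labels=BRAIN_LABELS,
    strict: bool = False,
) -> np.ndarray:
    """Smoothed random-blob lesion mask inside the brain.

    An axis-aligned ellipsoid with band-limited radial perturbation:
    voxels where the normalized ellipsoidal radius is below
    ``1 + irregularity * n(x)`` (n a smooth unit-variance noise field)
    belong to the lesion.  ``irregularity=0`` gives an exact voxelized
    ellipsoid.  Deterministic for a given seed.
    """
    centroid_mm = np.asarray(centroid_mm, dtype=float)
    radii = np.asarray(principal_radii_mm, dtype=float)
    if np.any(radii <= phantom.voxel_size):
        raise ConfigurationError(
            "lesion radii must exceed the voxel size to be resolvable"
        )
    if phantom.labels_at(centroid_mm)[0] not in brain_labels:
        raise ConfigurationError(
            f"lesion centroid {centroid_mm} mm is not inside brain tissue"
        )

    # Work in a bounding box around the lesion: the radial noise is a
    # lesion-scale perturbation, so its correlation length must track
    # the lesion size, not the phantom size.
    center_vox = phantom.world_to_voxel(centroid_mm)[0]
    extent_mm = radii * (1.0 + 3.0 * max(irregularity, 0.0)) + 2 * phantom.voxel_size
    lo = np.maximum(np.floor(center_vox - extent_mm / phantom.voxel_size), 0).astype(int)
    hi = np.minimum(
        np.ceil(center_vox + extent_mm / phantom.voxel_size) + 1,
        phantom.shape,
    ).astype(int)
    box_shape = tuple(hi - lo)
    grids = (np.indices(box_shape, dtype=float)
             + lo[:, None, None, None]).reshape(3, -1).T
    world = phantom.voxel_to_world(grids)
    rho = np.sqrt(
        (((world - centroid_mm) / radii) ** 2).sum(axis=1)
    ).reshape(box_shape)

    if irregularity > 0:
        rng = np.random.default_rng(seed)
        coarse = rng.standard_normal((5, 5, 5))
        noise = ndimage.zoom(
            coarse, [max(s, 5) / 5 for s in box_shape], order=3, mode="nearest"
        )
        noise = noise[: box_shape[0], : box_shape[1], : box_shape[2]]
        noise = (noise - noise.mean()) / max(noise.std(), 1e-12)
        threshold = 1.0 + irregularity * noise
    else:
        threshold = 1.0

    blob = np.zeros(phantom.shape, dtype=bool)
    blob[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = rho <= threshold
    brain = np.isin(phantom.labels, brain_labels)
    mask = blob & brain
    clipped = int(blob.sum() - mask.sum())
    if clipped:
        frac = clipped / max(int(blob.sum()), 1)
        message = (
            f"lesion clipped to brain tissue: {clipped} voxels "
            f"({100 * frac:.1f}%) removed"
        )
        if strict:
            raise PemfDoseError(message)
        warnings.warn(message, stacklevel=2)
    if not np.any(mask):
        raise PemfDoseError("generated lesion is empty")
    return mask


def evolve_lesion(
    pre_mask,
    field_magnitude_mT,
    m_true: float = 79.38,
    a_true: float = -0.1,
    exposure_floor_mT: float = 0.5,
    growth_rate_untreated: float = 0.3,
    seed: int = 0,
    brain_mask=None,
    apply_closing: bool = False,
) -> LesionPair:
    """Evolve a lesion under a known exponential dose-response law.

    Voxels exposed above ``exposure_floor_mT`` are retained
    independently with probability ``min(1, (m_true/100) *
    exp(a_true * B_mT))`` - the same law form the analysis fits, so
    recovery of (m_true, a_true) closes the validation loop.  Voxels
    below the floor are considered untreated: they persist and the
    lesion grows into neighbouring sub-floor brain tissue at the
    expected rate ``growth_rate_untreated`` (fraction of the untreated
    volume).  Optional morphological closing reconnects the post mask
    at the price of distorting the exact Bernoulli expectation, so it
    is off by default.
    """
    pre = np.asarray(pre_mask, dtype=bool)
    B = np.asarray(field_magnitude_mT, dtype=float)
    if B.shape != pre.shape:
        raise ConfigurationError("field volume is not congruent with the mask")
    if m_true <= 0:
        raise ConfigurationError("m_true must be positive")
    if growth_rate_untreated < 0 or exposure_floor_mT < 0:
        raise ConfigurationError("rates and floors must be non-negative")

    rng = np.random.default_rng(seed)
    treated = pre & (B >= exposure_floor_mT)
    untreated = pre & ~treated

    retention = np.minimum(1.0, (m_true / 100.0) * np.exp(a_true * B[treated]))
    kept = np.zeros_like(pre)
    kept[treated] = rng.random(retention.shape) < retention
    kept[untreated] = True

    n_untreated = int(untreated.sum())
    if n_untreated and growth_rate_untreated > 0:
        candidates = (
            ndimage.binary_dilation(pre)
            & ~pre
            & (B < exposure_floor_mT)
        )
        if brain_mask is not None:
            candidates &= np.asarray(brain_mask, dtype=bool)
        n_candidates = int(candidates.sum())
        if n_candidates:
            p_grow = min(1.0, growth_rate_untreated * n_untreated / n_candidates)
            grow = np.zeros_like(pre)
            grow[candidates] = rng.random(n_candidates) < p_grow
            kept |= grow

    if apply_closing:
        kept = ndimage.binary_closing(kept)

    metadata = {
        "m_true": m_true,
        "a_true": a_true,
        "exposure_floor_mT": exposure_floor_mT,
        "growth_rate_untreated": growth_rate_untreated,
        "seed": seed,
        "apply_closing": apply_closing,
    }
    return LesionPair(pre, kept, metadata)


DEFAULT_INTENSITIES = {
    AIR: 5.0,
    NAME_LABELS["skin"]: 45.0,
    NAME_LABELS["skull"]: 25.0,
    NAME_LABELS["csf"]: 35.0,
    GREY: 60.0,
    WHITE: 50.0,
    LESION: 90.0,
}


def lesion_cnr(intensity_table: dict, noise_sd: float,
               grey_label: int = GREY, lesion_label: int = LESION) -> float:
    """Lesion-to-grey-matter contrast-to-noise ratio of a rendering."""
    if noise_sd <= 0:
        raise ConfigurationError("CNR undefined for non-positive noise_sd")
    return (intensity_table[lesion_label] - intensity_table[grey_label]) / noise_sd


def render_mri_like(
    phantom: VoxelPhantom,
    lesion_mask=None,
    intensity_table: dict | None = None,
    noise_sd: float = 4.0,
    seed: int = 0,
) -> np.ndarray:
    """Grey-scale MRI-like volume with a strongly hyperintense lesion.

    Per-voxel Gaussian noise around the label mean intensity;
    ``noise_sd = 0`` gives the piecewise-constant volume.  The lesion
    mean must be strictly the highest so that the lesion is the
    hyperintense structure.
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be non-negative")
    table = dict(DEFAULT_INTENSITIES if intensity_table is None else intensity_table)
    labels = phantom.labels.copy()
    if lesion_mask is not None:
        phantom._check_congruent(lesion_mask)
        labels[np.asarray(lesion_mask, dtype=bool)] = LESION
    present = np.unique(labels)
    missing = set(present) - set(table)
    if missing:
        raise ConfigurationError(f"no intensity assigned for labels {sorted(missing)}")
    if LESION in present:
        others = [table[l] for l in present if l != LESION]
        if table[LESION] <= max(others):
            raise ConfigurationError("lesion intensity must be strictly highest")
    volume = np.zeros(phantom.shape, dtype=float)
    for label in present:
        volume[labels == label] = table[label]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        volume = volume + rng.normal(0.0, noise_sd, size=phantom.shape)
    return volume.astype(np.float32)
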