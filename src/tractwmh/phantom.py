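"""Synthetic phantom geometry: a co-registered stand-in for tract atlas + parcellation.

The phantom replaces the registered probabilistic fiber-tract atlas and the
cortical parcellation of a real study with simple parametric solids laid out
in a single voxel grid:

* a central white-matter (WM) slab,
* four rectangular tract "tubes" inside the WM, one per default-mode-network
  (DMN) pathway (SLF, IFOF, cingulum, cingulum-hippocampus),
* four gray-matter (GM) cortical blocks, each sharing a face with the WM slab
  right where its paired tract ends (SLF-IPL, IFOF-MPFC, CING-PCC,
  CING_Hippo-MTL),
* a cerebellum block below the WM used as the PET reference region.

Because every mask lives on the same grid, co-registration holds by
construction and the downstream stages (segmentation, intersection, SUVr)
can be validated voxel-exactly against known ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, PlacementError

__all__ = [
    "TRACT_NAMES",
    "REGION_NAMES",
    "REGION_FOR_TRACT",
    "TRACT_FOR_REGION",
    "DEFAULT_COMPOSITION",
    "PhantomSpace",
    "LesionSet",
    "build_phantom_space",
    "simulate_lesions",
    "render_flair",
    "render_pet",
    "DegenerateSigmaWarning",
]

TRACT_NAMES = ("CING", "CING_Hippo", "SLF", "IFOF")
REGION_NAMES = ("PCC", "MTL", "IPL", "MPFC")

#: tract -> connected DMN cortical region
REGION_FOR_TRACT = {
    "CING": "PCC",
    "CING_Hippo": "MTL",
    "SLF": "IPL",
    "IFOF": "MPFC",
}
TRACT_FOR_REGION = {r: t for t, r in REGION_FOR_TRACT.items()}

#: cortical-parcellation label composition of each composite DMN region
DEFAULT_COMPOSITION = {
    "MTL": ["entorhinal", "parahippocampal"],
    "MPFC": ["rostral_anterior_cingulate", "caudal_anterior_cingulate", "medial_orbitofrontal"],
    "PCC": ["posterior_cingulate"],
    "IPL": ["inferior_parietal"],
}

# fractional [lo, hi) bounds per axis for each solid; tracts occupy disjoint
# z-bands inside the WM slab, and each GM block shares the WM face where its
# tract terminates.
_WM = ((0.20, 0.80), (0.20, 0.80), (0.30, 0.70))
_TRACT_BOUNDS = {
    "IFOF": ((0.20, 0.80), (0.28, 0.46), (0.32, 0.41)),
    "CING": ((0.20, 0.80), (0.54, 0.72), (0.41, 0.50)),
    "SLF": ((0.28, 0.46), (0.20, 0.80), (0.50, 0.59)),
    "CING_Hippo": ((0.54, 0.72), (0.20, 0.80), (0.59, 0.68)),
}
_REGION_BOUNDS = {
    "MPFC": ((0.08, 0.20), (0.28, 0.46), (0.32, 0.41)),
    "PCC": ((0.80, 0.92), (0.54, 0.72), (0.41, 0.50)),
    "IPL": ((0.28, 0.46), (0.08, 0.20), (0.50, 0.59)),
    "MTL": ((0.54, 0.72), (0.80, 0.92), (0.59, 0.68)),
}
_CEREBELLUM = ((0.30, 0.70), (0.30, 0.70), (0.08, 0.22))


class DegenerateSigmaWarning(UserWarning):
    """Zero intensity noise makes the lesion contrast offset k*sigma collapse to 0."""


@dataclass
class PhantomSpace:
    """Co-registered masks and parcellation for one phantom geometry."""

    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    wm_mask: np.ndarray
    gm_region_masks: dict[str, np.ndarray]
    tract_masks: dict[str, np.ndarray]
    cerebellum_mask: np.ndarray
    parcellation: np.ndarray
    label_names: dict[int, str]

    @property
    def voxel_volume_ml(self) -> float:
        vx, vy, vz = self.voxel_size
        return vx * vy * vz / 1000.0

    def tract_volume_ml(self, tract: str) -> float:
        return float(self.tract_masks[tract].sum()) * self.voxel_volume_ml


def _box(shape: tuple[int, int, int], bounds) -> np.ndarray:
    """Binary mask for a fractional-coordinate axis-aligned box (lo incl, hi excl)."""
    mask = np.zeros(shape, dtype=bool)
    sl = tuple(
        slice(int(np.floor(lo * n)), int(np.floor(hi * n)))
        for (lo, hi), n in zip(bounds, shape)
    )
    mask[sl] = True
    return mask


def build_phantom_space(
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.2),
    seed: int = 0,
) -> PhantomSpace:
    """Build the deterministic phantom geometry.

    ``seed`` is accepted for interface symmetry with the stochastic
    generators; the geometry itself is a deterministic function of
    ``grid_shape``, so identical inputs give bit-identical masks.

    Raises
    ------
    ConfigurationError
        If any grid axis is below 32 voxels (solids would collapse/overlap).
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    if len(grid_shape) != 3 or any(n < 32 for n in grid_shape):
        raise ConfigurationError(
            f"grid_shape must have three axes of at least 32 voxels, got {grid_shape}"
        )
    voxel_size = tuple(float(v) for v in voxel_size)
    if any(v <= 0 for v in voxel_size):
        raise ConfigurationError(f"voxel_size must be positive, got {voxel_size}")

    wm = _box(grid_shape, _WM)
    tracts = {name: _box(grid_shape, b) for name, b in _TRACT_BOUNDS.items()}
    regions = {name: _box(grid_shape, b) for name, b in _REGION_BOUNDS.items()}
    cerebellum = _box(grid_shape, _CEREBELLUM)

    # parcellation: split each composite region's block into one slab per label
    parcellation = np.zeros(grid_shape, dtype=np.int32)
    label_names: dict[int, str] = {}
    next_label = 1
    for region in REGION_NAMES:
        labels = DEFAULT_COMPOSITION[region]
        idx = np.argwhere(regions[region])
        if idx.size == 0:
            raise ConfigurationError(f"region {region} is empty at grid {grid_shape}")
        # slab along the longest in-block axis so every label is nonempty
        spans = idx.max(axis=0) - idx.min(axis=0) + 1
        axis = int(np.argmax(spans))
        lo = idx[:, axis].min()
        width = spans[axis]
        if width < len(labels):
            raise ConfigurationError(
                f"grid {grid_shape} too small to split region {region} into {len(labels)} labels"
            )
        edges = lo + np.round(np.linspace(0, width, len(labels) + 1)).astype(int)
        coord = np.arange(grid_shape[axis]).reshape(
            [-1 if a == axis else 1 for a in range(3)]
        )
        for i, label in enumerate(labels):
            sub = regions[region] & (coord >= edges[i]) & (coord < edges[i + 1])
            parcellation[sub] = next_label
            label_names[next_label] = label
            next_label += 1
    parcellation[cerebellum] = next_label
    label_names[next_label] = "cerebellum"

    space = PhantomSpace(
        grid_shape=grid_shape,
        voxel_size=voxel_size,
        wm_mask=wm,
        gm_region_masks=regions,
        tract_masks=tracts,
        cerebellum_mask=cerebellum,
        parcellation=parcellation,
        label_names=label_names,
    )
    _check_invariants(space)
    return space


def _check_invariants(space: PhantomSpace) -> None:
    for name, tract in space.tract_masks.items():
        if not tract.any():
            raise ConfigurationError(f"tract mask {name} is empty")
        if (tract & ~space.wm_mask).any():
            raise ConfigurationError(f"tract mask {name} leaves the WM mask")
    all_gm = np.zeros(space.grid_shape, dtype=int)
    for name, gm in space.gm_region_masks.items():
        if not gm.any():
            raise ConfigurationError(f"GM region mask {name} is empty")
        all_gm += gm.astype(int)
    overlap = all_gm + space.wm_mask.astype(int) + space.cerebellum_mask.astype(int)
    if (overlap > 1).any():
        raise ConfigurationError("GM regions, WM and cerebellum masks overlap")
    if not space.cerebellum_mask.any():
        raise ConfigurationError("cerebellum mask is empty")


@dataclass
class LesionSet:
    """Per-tract lesion voxels for one subject, plus achieved (quantized) volumes."""

    per_tract: dict[str, np.ndarray]
    achieved_ml: dict[str, float] = field(default_factory=dict)

    def combined(self) -> np.ndarray:
        masks = list(self.per_tract.values())
        out = np.zeros_like(masks[0], dtype=bool)
        for m in masks:
            out |= m
        return out


def simulate_lesions(
    space: PhantomSpace,
    target_volumes_ml: dict[str, float],
    seed: int = 0,
) -> LesionSet:
    """Place one connected hyperintense blob per tract with a target volume.

    The blob is the set of tract voxels nearest (in mm) to an interior anchor
    point, so it is connected and wholly contained in the tract. The achieved
    volume is voxel-quantized: ``round(target / voxel_volume)`` voxels, which
    is always within half a voxel volume of the target.

    Raises
    ------
    PlacementError
        If a target is negative or exceeds half the tract's volume.
    """
    rng = np.random.default_rng(seed)
    vox_ml = space.voxel_volume_ml
    per_tract: dict[str, np.ndarray] = {}
    achieved: dict[str, float] = {}
    for tract in TRACT_NAMES:
        target = float(target_volumes_ml.get(tract, 0.0))
        mask = np.zeros(space.grid_shape, dtype=bool)
        if target < 0:
            raise PlacementError(f"negative lesion target for {tract}: {target}")
        n_vox = int(round(target / vox_ml))
        capacity = int(space.tract_masks[tract].sum())
        if target > 0.5 * capacity * vox_ml:
            raise PlacementError(
                f"lesion target {target:.3f} mL exceeds half of tract {tract} "
                f"volume ({capacity * vox_ml:.3f} mL)"
            )
        if n_vox > 0:
            coords = np.argwhere(space.tract_masks[tract])
            mm = coords * np.asarray(space.voxel_size)
            # anchor jittered around the tract centroid; jitter keeps repeated
            # subjects from sharing one exact blob while staying deterministic
            centroid = mm.mean(axis=0)
            jitter = rng.normal(0.0, 1.5, size=3)
            d2 = ((mm - (centroid + jitter)) ** 2).sum(axis=1)
            order = np.argsort(d2, kind="stable")
            chosen = coords[order[:n_vox]]
            mask[tuple(chosen.T)] = True
        per_tract[tract] = mask
        achieved[tract] = n_vox * vox_ml
    return LesionSet(per_tract=per_tract, achieved_ml=achieved)


# cosmetic mean intensities for tissue outside the WM mask (arbitrary units);
# downstream stages only ever look inside the WM mask
_FLAIR_BACKGROUND_MU = 30.0
_FLAIR_GM_MU = 60.0
_FLAIR_CEREBELLUM_MU = 55.0


def render_flair(
    space: PhantomSpace,
    lesions: LesionSet,
    nawm_mu: float = 100.0,
    nawm_sigma: float = 10.0,
    lesion_contrast_k: float = 6.0,
    lesion_sd_frac: float = 1.0,
    noise_scale: float = 1.0,
    seed: int = 0,
):
    """Render a FLAIR-like intensity volume.

    Normal-appearing WM voxels are drawn from Normal(nawm_mu,
    nawm_sigma*noise_scale); lesion voxels from
    Normal(nawm_mu + k*nawm_sigma, nawm_sigma*lesion_sd_frac*noise_scale).
    ``nawm_sigma`` is the nominal intensity-model width that sets the lesion
    contrast offset ``k*sigma``; ``noise_scale=0`` renders a noise-free
    phantom whose lesions keep that positive contrast. Non-WM tissue gets
    distinct cosmetic means with the same noise level.
    """
    from .image import VolumetricImage

    if nawm_sigma < 0:
        raise ConfigurationError(f"nawm_sigma must be >= 0, got {nawm_sigma}")
    if noise_scale < 0:
        raise ConfigurationError(f"noise_scale must be >= 0, got {noise_scale}")
    if nawm_sigma == 0:
        warnings.warn(
            "nawm_sigma=0: lesion contrast k*sigma collapses to 0 and lesions "
            "are indistinguishable from NAWM",
            DegenerateSigmaWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    mu_map = np.full(space.grid_shape, _FLAIR_BACKGROUND_MU)
    sd_map = np.full(space.grid_shape, nawm_sigma * noise_scale)
    for gm in space.gm_region_masks.values():
        mu_map[gm] = _FLAIR_GM_MU
    mu_map[space.cerebellum_mask] = _FLAIR_CEREBELLUM_MU
    mu_map[space.wm_mask] = nawm_mu
    lesion = lesions.combined()
    mu_map[lesion] = nawm_mu + lesion_contrast_k * nawm_sigma
    sd_map[lesion] = nawm_sigma * lesion_sd_frac * noise_scale
    data = mu_map + sd_map * rng.standard_normal(space.grid_shape)
    return VolumetricImage(data=data, voxel_size=space.voxel_size)


@dataclass
class CouplingConfig:
    """Generative coupling between tract lesion burden and regional PET uptake.

    Regional uptake follows ``b0 + b1*log10(V_tract) + bX.covariates + noise``
    where ``V_tract`` is the true lesion volume (mL) in the region's paired
    tract. The cerebellum renders at ``reference_value``, so with the default
    reference of 1 the rendered uptake is already on the SUVr scale.

    The default ``noise_sd`` is the closed-form calibration
    ``|b1| * sd(log10 V) * sqrt((1-t)/t)`` for an expected adjusted R^2 of
    t=.2 at the phantom cohort's log-volume SD of 0.2 — i.e. effect sizes on
    the scale the analysis is designed around. Pass 0 for noiseless cohorts.
    """

    b0: float = 1.5
    b1: float = 0.3
    covariate_effects: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    noise_sd: float = 0.12
    lesion_contrast_k: float = 6.0
    reference_value: float = 1.0
    zero_volume_floor_ml: float | None = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")

    def linear_predictor(self, volume_ml: float, covariates) -> float:
        if volume_ml <= 0:
            if self.zero_volume_floor_ml is None:
                raise ConfigurationError(
                    "zero lesion volume encountered but zero_volume_floor_ml is None; "
                    "set a floor or exclude zero-volume subjects"
                )
            volume_ml = self.zero_volume_floor_ml
        cov = np.asarray(covariates, dtype=float)
        bx = np.asarray(self.covariate_effects, dtype=float)
        return float(self.b0 + self.b1 * np.log10(volume_ml) + bx @ cov)


# cosmetic uptake outside regions of interest (arbitrary units)
_PET_BACKGROUND = 0.5
_PET_WM = 0.8


def render_pet(
    space: PhantomSpace,
    true_volumes_ml: dict[str, float],
    coupling: CouplingConfig,
    covariates,
    seed: int = 0,
):
    """Render a PET-like uptake volume for one subject.

    Each DMN region is constant at its linear predictor plus one regional
    noise draw; the cerebellum is constant at the reference value, so the
    region SUVr equals (predictor + noise) / reference exactly up to float
    rounding.

    ``covariates`` is the (age, sex, apoe_e4_count, icv) vector entering the
    generative model through ``coupling.covariate_effects``.

    Returns the image and the per-region noiseless+noise uptake means actually
    rendered (the generative ground truth for SUVr checks).
    """
    from .image import VolumetricImage

    rng = np.random.default_rng(seed)
    data = np.full(space.grid_shape, _PET_BACKGROUND)
    data[space.wm_mask] = _PET_WM
    region_uptake: dict[str, float] = {}
    for region in REGION_NAMES:
        tract = TRACT_FOR_REGION[region]
        mean = coupling.linear_predictor(true_volumes_ml.get(tract, 0.0), covariates)
        noise = rng.normal(0.0, coupling.noise_sd) if coupling.noise_sd > 0 else 0.0
        value = mean + noise
        data[space.gm_region_masks[region]] = value
        region_uptake[region] = value
    data[space.cerebellum_mask] = coupling.reference_value
    img = VolumetricImage(data=data, voxel_size=space.voxel_size)
    return img, region_uptake
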