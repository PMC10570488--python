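"""Synthetic cohort generation: covariates, ground-truth lesion burden, images.

Two levels of simulation are provided:

``simulate_association_table``
    Tabular-only draws of (covariates, per-tract log lesion volume, regional
    SUVr) straight from the generative coupling model. Used for statistical
    calibration studies (parameter recovery, type-I error) where rendering
    voxel images for hundreds of replicate cohorts would add nothing.

``generate_cohort``
    Full image-level cohorts on the phantom grid: lesion blobs placed in
    tracts, FLAIR-like and PET-like volumes rendered per subject. Used to
    exercise the segmentation, volumetrics and SUVr stages end to end.

Default covariate marginals reproduce the reference cohort of 72
cognitively unimpaired older adults: age ~ Normal(74.96, 8.13) years,
intracranial volume ~ Normal(1455.26, 132.46) mL, 49.3% male, and ApoE e4
allele-count probabilities P(1 copy)=.099, P(2 copies)=.366.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .image import VolumetricImage, write_volume
from .phantom import (
    REGION_FOR_TRACT,
    TRACT_NAMES,
    CouplingConfig,
    LesionSet,
    PhantomSpace,
    build_phantom_space,
    render_flair,
    render_pet,
    simulate_lesions,
)

__all__ = [
    "CovariateMarginals",
    "LOG_VOLUME_MARGINALS",
    "sample_covariates",
    "calibrate_noise_sd",
    "simulate_association_table",
    "PhantomCohortConfig",
    "Cohort",
    "generate_cohort",
    "write_cohort",
]

COVARIATE_COLUMNS = ("age", "sex", "apoe_e4_count", "icv")


@dataclass(frozen=True)
class CovariateMarginals:
    """Marginal distributions for the four regression covariates."""

    age_mean: float = 74.96
    age_sd: float = 8.13
    icv_mean: float = 1455.26  # mL
    icv_sd: float = 132.46
    p_male: float = 0.493
    p_e4_one_copy: float = 0.099
    p_e4_two_copies: float = 0.366


#: per-tract (mean, sd) of log10 lesion volume in mL, as observed in the
#: reference cohort; used by the tabular simulator
LOG_VOLUME_MARGINALS = {
    "SLF": (1.12, 0.66),
    "IFOF": (1.14, 0.65),
    "CING": (0.92, 0.94),
    "CING_Hippo": (0.95, 0.74),
}


def sample_covariates(
    n: int,
    seed: int = 0,
    marginals: CovariateMarginals | None = None,
) -> pd.DataFrame:
    """Sample a covariate table with the reference-cohort marginals.

    Columns: subject_id, age (years), sex (1=male), apoe_e4_count (0/1/2),
    icv (mL).
    """
    if n < 1:
        raise InputError(f"n must be >= 1, got {n}")
    m = marginals or CovariateMarginals()
    rng = np.random.default_rng(seed)
    age = rng.normal(m.age_mean, m.age_sd, size=n)
    icv = rng.normal(m.icv_mean, m.icv_sd, size=n)
    sex = (rng.random(n) < m.p_male).astype(int)
    p0 = 1.0 - m.p_e4_one_copy - m.p_e4_two_copies
    apoe = rng.choice([0, 1, 2], size=n, p=[p0, m.p_e4_one_copy, m.p_e4_two_copies])
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "apoe_e4_count": apoe,
            "icv": icv,
        }
    )


def calibrate_noise_sd(
    b1: float,
    sd_log_volume: float,
    target_adj_r2: float,
) -> float:
    """Regional-uptake noise SD giving an expected model adjusted R-squared.

    With covariate effects set to zero the population variance explained by
    the model is b1^2 * Var(log10 V) / (b1^2 * Var(log10 V) + noise_sd^2);
    the adjustment for the fitted-but-null covariates cancels the overfitting
    bias in expectation, so the population ratio is matched to the target
    adjusted R-squared directly.
    """
    if not 0 < target_adj_r2 < 1:
        raise InputError(f"target_adj_r2 must be in (0,1), got {target_adj_r2}")
    signal_var = (b1 * sd_log_volume) ** 2
    noise_var = signal_var * (1.0 - target_adj_r2) / target_adj_r2
    return float(np.sqrt(noise_var))


def simulate_association_table(
    n: int,
    coupling: CouplingConfig,
    seed: int = 0,
    marginals: CovariateMarginals | None = None,
    log_volume_marginals: dict[str, tuple[float, float]] | None = None,
    b1_per_tract: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Draw a tabular cohort directly from the generative coupling model.

    For each tract, log10 lesion volume is Normal with the reference-cohort
    per-tract marginals, and the paired region's SUVr is
    ``(b0 + b1*log10 V + bX.cov + eps) / reference`` with
    eps ~ Normal(0, noise_sd). ``b1_per_tract`` overrides the common slope
    for selected tracts (e.g. coupling only through SLF).

    Returns a wide DataFrame with covariates, ``log_wmh_<tract>`` and
    ``suvr_<region>`` columns.
    """
    rng = np.random.default_rng(seed)
    cov = sample_covariates(n, seed=int(rng.integers(2**31)), marginals=marginals)
    lv_marg = log_volume_marginals or LOG_VOLUME_MARGINALS
    bx = np.asarray(coupling.covariate_effects, dtype=float)
    cov_mat = cov[list(COVARIATE_COLUMNS)].to_numpy(dtype=float)
    out = cov.copy()
    for tract in TRACT_NAMES:
        mu, sd = lv_marg[tract]
        logv = rng.normal(mu, sd, size=n)
        b1 = coupling.b1 if b1_per_tract is None else b1_per_tract.get(tract, coupling.b1)
        eps = rng.normal(0.0, coupling.noise_sd, size=n) if coupling.noise_sd > 0 else 0.0
        uptake = coupling.b0 + b1 * logv + cov_mat @ bx + eps
        region = REGION_FOR_TRACT[tract]
        out[f"log_wmh_{tract}"] = logv
        out[f"suvr_{region}"] = uptake / coupling.reference_value
    return out


@dataclass
class PhantomCohortConfig:
    """Configuration of an image-level phantom cohort.

    Lesion log10-volumes are drawn per tract from ``log_volume_marginals``.
    The defaults are scaled to the phantom's tract capacity (a 64^3 grid
    holds a few mL of tract, not the tens of mL the reference-cohort
    marginals imply), preserving the log-linear coupling structure at a
    volume scale the phantom can realize. ``p_zero_lesion`` subjects get an
    empty tract to exercise the zero-volume exclusion policy downstream.
    """

    n_subjects: int = 40
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.2)
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    log_volume_marginals: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {t: (-0.45, 0.20) for t in TRACT_NAMES}
    )
    p_zero_lesion: float = 0.0
    nawm_mu: float = 100.0
    nawm_sigma: float = 10.0
    lesion_sd_frac: float = 1.0
    noise_scale: float = 1.0
    seed: int = 0


@dataclass
class Cohort:
    """An in-memory image-level cohort: space, per-subject images and truth."""

    space: PhantomSpace
    covariates: pd.DataFrame
    truth: pd.DataFrame  # long: subject_id, tract_name, true_volume_ml, region_name, true_uptake
    flair: dict[str, VolumetricImage]
    pet: dict[str, VolumetricImage]
    lesions: dict[str, LesionSet]
    config: PhantomCohortConfig


def generate_cohort(config: PhantomCohortConfig) -> Cohort:
    """Generate a full phantom cohort (masks + FLAIR + PET + truth tables)."""
    root = np.random.SeedSequence(config.seed)
    space = build_phantom_space(config.grid_shape, config.voxel_size, seed=config.seed)
    cov_seed, *subject_seeds = root.spawn(config.n_subjects + 1)
    covariates = sample_covariates(
        config.n_subjects, seed=int(cov_seed.generate_state(1)[0] % 2**31)
    )
    vox_ml = space.voxel_volume_ml
    truth_rows = []
    flair: dict[str, VolumetricImage] = {}
    pet: dict[str, VolumetricImage] = {}
    lesions: dict[str, LesionSet] = {}
    for i, row in covariates.iterrows():
        sid = row["subject_id"]
        s_rng = np.random.default_rng(subject_seeds[i])
        targets: dict[str, float] = {}
        for tract in TRACT_NAMES:
            if config.p_zero_lesion > 0 and s_rng.random() < config.p_zero_lesion:
                targets[tract] = 0.0
                continue
            mu, sd = config.log_volume_marginals[tract]
            v = 10.0 ** s_rng.normal(mu, sd)
            # clip to placement capacity, leaving one voxel of headroom
            cap = 0.5 * space.tract_volume_ml(tract) - vox_ml
            targets[tract] = float(min(v, cap))
        ls = simulate_lesions(space, targets, seed=int(s_rng.integers(2**31)))
        f_img = render_flair(
            space,
            ls,
            nawm_mu=config.nawm_mu,
            nawm_sigma=config.nawm_sigma,
            lesion_contrast_k=config.coupling.lesion_contrast_k,
            lesion_sd_frac=config.lesion_sd_frac,
            noise_scale=config.noise_scale,
            seed=int(s_rng.integers(2**31)),
        )
        cov_vec = [row["age"], row["sex"], row["apoe_e4_count"], row["icv"]]
        p_img, region_uptake = render_pet(
            space,
            ls.achieved_ml,
            config.coupling,
            cov_vec,
            seed=int(s_rng.integers(2**31)),
        )
        flair[sid] = f_img
        pet[sid] = p_img
        lesions[sid] = ls
        for tract in TRACT_NAMES:
            region = REGION_FOR_TRACT[tract]
            truth_rows.append(
                {
                    "subject_id": sid,
                    "tract_name": tract,
                    "true_volume_ml": ls.achieved_ml[tract],
                    "region_name": region,
                    "true_uptake": region_uptake[region],
                }
            )
    truth = pd.DataFrame(truth_rows)
    return Cohort(
        space=space,
        covariates=covariates,
        truth=truth,
        flair=flair,
        pet=pet,
        lesions=lesions,
        config=config,
    )


def write_cohort(cohort: Cohort, out_dir: str | os.PathLike) -> dict:
    """Write a cohort to disk: NIfTI volumes, masks, truth/covariate CSVs.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    masks_dir = os.path.join(out_dir, "masks")
    os.makedirs(masks_dir, exist_ok=True)
    space = cohort.space
    vs = space.voxel_size

    def _w(arr, name):
        path = os.path.join(masks_dir, name)
        write_volume(VolumetricImage(arr.astype(np.uint8), vs), path)
        return os.path.relpath(path, out_dir)

    manifest: dict = {
        "n_subjects": len(cohort.covariates),
        "grid_shape": list(space.grid_shape),
        "voxel_size": list(vs),
        "masks": {
            "wm": _w(space.wm_mask, "wm_mask.nii.gz"),
            "cerebellum": _w(space.cerebellum_mask, "cerebellum_mask.nii.gz"),
            "tracts": {t: _w(m, f"tract_{t}.nii.gz") for t, m in space.tract_masks.items()},
        },
        "subjects": {},
    }
    parc_path = os.path.join(masks_dir, "parcellation.nii.gz")
    write_volume(VolumetricImage(space.parcellation, vs), parc_path)
    manifest["masks"]["parcellation"] = os.path.relpath(parc_path, out_dir)
    labels_path = os.path.join(out_dir, "labels.json")
    with open(labels_path, "w") as fh:
        json.dump({str(k): v for k, v in space.label_names.items()}, fh, indent=2)

    for sid in cohort.covariates["subject_id"]:
        sdir = os.path.join(out_dir, sid)
        os.makedirs(sdir, exist_ok=True)
        fpath = os.path.join(sdir, "flair.nii.gz")
        ppath = os.path.join(sdir, "pet.nii.gz")
        write_volume(cohort.flair[sid], fpath)
        write_volume(cohort.pet[sid], ppath)
        manifest["subjects"][sid] = {
            "flair": os.path.relpath(fpath, out_dir),
            "pet": os.path.relpath(ppath, out_dir),
        }
    cohort.covariates.to_csv(os.path.join(out_dir, "covariates.csv"), index=False)
    cohort.truth.to_csv(os.path.join(out_dir, "truth.csv"), index=False)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
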