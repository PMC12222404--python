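"""Synthetic liver-SIRT digital phantoms with paired NC/AC/ASC states.

Patient Y-90 bremsstrahlung SPECT data cannot be redistributed, so the
pipeline is exercised on generated phantoms: piecewise-constant activity in
an ellipsoidal body (liver background, hot spherical tumour, faint body
background, optional lung shunt), degraded by two physics stand-ins,

* *attenuation*: per-voxel multiplication by the mean, over a fan of
  in-plane projection directions spanning 180 degrees, of
  ``exp(-integral of mu along the ray to the body surface)`` — deeper voxels
  lose more signal, which is what CT-based attenuation correction restores;
* *scatter*: count-conserving redistribution
  ``(1-f) * primary + f * Gaussian(primary)`` with a kernel much broader
  than the reconstruction resolution — clinically, scattered photons make up
  30-40% of photopeak-window counts, hence the default fraction 0.35.

The three correction states are then ASC = true activity (optionally Poisson
sampled), AC = scatter-degraded only (attenuation already corrected), and
NC = attenuation applied on top of scatter.  Downstream patient-relative
calibration forces identical whole-liver energy for all three dose maps, so
the states differ purely by spatial redistribution: the tumour (interior,
hot) is underdosed and the normal liver overdosed without scatter
correction, and surface regions are relatively overdosed without attenuation
correction — the qualitative bias pattern the learned corrections remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage

from .image import SegmentationSet, VolumetricImage
from .ldm import DoseMap, RadionuclideParams, dose_from_counts

__all__ = [
    "PhantomRecipe",
    "DegradationModel",
    "TaskTriplet",
    "build_phantom",
    "apply_attenuation",
    "apply_scatter",
    "generate_task_triplet",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class RecipeError(ValueError):
    """Geometry in a phantom recipe is inconsistent (e.g. tumour outside liver)."""


@dataclass(frozen=True)
class PhantomRecipe:
    """Geometry and uptake of one synthetic patient.

    Organ centres and semi-axes are fractions of the physical grid extent so
    one recipe scales from desk-size grids to the clinical 128^3 at 4.795 mm.
    The tumour is specified in mm (clinical lesions do not scale with the
    field of view).  ``uptake_ratio`` is the tumour:liver activity
    concentration ratio (> 1: glass-microsphere SIRT is tumour-avid).
    ``jitter`` scales the seeded random perturbation of geometry and uptake
    that makes every phantom in a cohort distinct.
    """

    shape: Tuple[int, int, int] = (128, 128, 128)
    spacing_mm: float = 4.795
    body_centre: Tuple[float, float, float] = (0.50, 0.50, 0.50)
    body_semiaxes: Tuple[float, float, float] = (0.40, 0.34, 0.46)
    liver_centre: Tuple[float, float, float] = (0.60, 0.46, 0.46)
    liver_semiaxes: Tuple[float, float, float] = (0.145, 0.115, 0.135)
    tumour_centre: Tuple[float, float, float] = (0.57, 0.47, 0.46)
    tumour_radius_mm: float = 30.0
    uptake_ratio: float = 5.0
    background_uptake: float = 0.02
    lung_uptake: float = 0.03
    injected_activity_gbq: float = 2.82
    jitter: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.uptake_ratio <= 1:
            raise RecipeError("tumour:liver uptake ratio must exceed 1")
        if self.tumour_radius_mm < 0:
            raise RecipeError("tumour radius must be non-negative")
        if self.spacing_mm <= 0:
            raise RecipeError("spacing must be positive")


@dataclass(frozen=True)
class DegradationModel:
    """Attenuation/scatter stand-in parameters.

    ``mu_*`` are effective broad-spectrum bremsstrahlung attenuation
    coefficients in mm^-1 (documented stand-in constants, overridable);
    ``n_projection_dirs`` in-plane ray directions span 180 degrees, mirroring
    a 180-degree SPECT acquisition arc; ``scatter_fraction`` defaults to 0.35
    (clinical photopeak scatter is 30-40%); the scatter kernel FWHM is far
    broader than a ~9 mm reconstruction filter so scatter and resolution
    effects stay distinguishable.  Poisson noise enters on the count maps,
    where counting noise physically arises.
    """

    mu_soft: float = 0.011
    mu_lung: float = 0.003
    mu_bone: float = 0.017
    n_projection_dirs: int = 16
    scatter_fraction: float = 0.35
    scatter_kernel_fwhm_mm: float = 30.0
    poisson_noise: bool = True
    total_counts: float = 2.0e6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.scatter_fraction < 1:
            raise ValueError("scatter_fraction must lie in [0, 1)")
        if min(self.mu_soft, self.mu_lung, self.mu_bone) < 0:
            raise ValueError("attenuation coefficients must be >= 0")
        if self.n_projection_dirs < 1:
            raise ValueError("need at least one projection direction")


def _ellipsoid(shape: Tuple[int, int, int], centre_frac, semiaxes_frac
               ) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    extent = np.asarray(shape, dtype=float) - 1.0
    c = np.asarray(centre_frac) * extent
    a = np.maximum(np.asarray(semiaxes_frac) * extent, 1e-9)
    r2 = sum(((idx[d] - c[d]) / a[d]) ** 2 for d in range(3))
    return r2 <= 1.0


def _sphere_mm(shape, spacing, centre_frac, radius_mm) -> np.ndarray:
    if radius_mm <= 0:
        return np.zeros(shape, dtype=bool)
    idx = np.indices(shape, dtype=float)
    extent = np.asarray(shape, dtype=float) - 1.0
    c = np.asarray(centre_frac) * extent
    r2 = sum(((idx[d] - c[d]) * spacing) ** 2 for d in range(3))
    return r2 <= radius_mm ** 2


def build_phantom(recipe: PhantomRecipe
                  ) -> Tuple[VolumetricImage, SegmentationSet, VolumetricImage,
                             DegradationModel]:
    """Generate (true activity, masks, mu map) for one phantom.

    Deterministic under ``recipe.seed``; the seed drives a bounded jitter of
    organ positions, sizes and uptake so cohorts are heterogeneous.  Returns
    the model-independent pieces only; combine with :func:`apply_attenuation`
    / :func:`apply_scatter` or :func:`generate_task_triplet` for degraded
    states.
    """
    rng = np.random.default_rng(recipe.seed)
    j = recipe.jitter

    def wobble(x, rel=0.08):
        x = np.asarray(x, dtype=float)
        return x * (1.0 + j * rel * rng.uniform(-1, 1, size=x.shape))

    shape, sp = recipe.shape, recipe.spacing_mm
    body = _ellipsoid(shape, recipe.body_centre, wobble(recipe.body_semiaxes, 0.04))
    liver_c = np.asarray(recipe.liver_centre) + j * rng.uniform(-0.015, 0.015, 3)
    liver_a = wobble(recipe.liver_semiaxes)
    liver = _ellipsoid(shape, liver_c, liver_a) & body
    tum_c = liver_c + (np.asarray(recipe.tumour_centre)
                       - np.asarray(recipe.liver_centre)) \
        + j * rng.uniform(-0.01, 0.01, 3)
    tum_r = float(recipe.tumour_radius_mm * (1 + j * 0.15 * rng.uniform(-1, 1)))
    tumour = _sphere_mm(shape, sp, tum_c, tum_r)
    if tumour.any() and not (tumour <= liver).all():
        tumour &= liver  # clip protrusions; require the bulk inside
        if recipe.tumour_radius_mm > 0 and not tumour.any():
            raise RecipeError("tumour lies outside the liver")
    lung_l = _ellipsoid(shape, (0.38, 0.46, 0.80), wobble((0.10, 0.10, 0.12)))
    lung_r = _ellipsoid(shape, (0.62, 0.46, 0.82), wobble((0.10, 0.10, 0.11)))
    lungs = (lung_l | lung_r) & body & ~liver
    kid_l = _ellipsoid(shape, (0.38, 0.60, 0.26), wobble((0.05, 0.045, 0.07)))
    kid_r = _ellipsoid(shape, (0.62, 0.62, 0.26), wobble((0.05, 0.045, 0.07)))
    kidneys = (kid_l | kid_r) & body & ~liver & ~lungs
    stomach = _ellipsoid(shape, (0.34, 0.44, 0.52), wobble((0.07, 0.06, 0.09))) \
        & body & ~liver & ~lungs
    if not liver.any():
        raise RecipeError("liver ended up empty; check geometry")

    wnl = liver & ~tumour
    ratio = float(recipe.uptake_ratio * (1 + j * 0.2 * rng.uniform(-1, 1)))
    activity = np.zeros(shape, dtype=float)
    activity[body] = recipe.background_uptake
    activity[wnl] = 1.0
    activity[tumour] = max(ratio, 1.0 + 1e-6)
    activity[lungs] = recipe.lung_uptake

    mu = np.zeros(shape, dtype=float)
    grid = VolumetricImage(activity, (sp, sp, sp))
    masks = SegmentationSet.from_masks(grid, {
        "body": body, "WNL": wnl, "tumour": tumour,
        "lungs": lungs, "kidneys": kidneys, "stomach": stomach,
    })
    model = DegradationModel()
    mu[body] = model.mu_soft
    mu[lungs] = model.mu_lung
    mu_map = VolumetricImage(mu, (sp, sp, sp))
    return grid, masks, mu_map, model


def _path_integral(mu: np.ndarray, spacing: float, angle_deg: float
                   ) -> np.ndarray:
    """Line integral of mu from each voxel to the grid edge along the
    in-plane direction at ``angle_deg`` (0 = +x), half-voxel centred."""
    if angle_deg % 360 == 0:
        rot = mu
    else:
        rot = ndimage.rotate(mu, angle_deg, axes=(0, 1), reshape=False,
                             order=1, mode="constant", cval=0.0)
    csum = np.cumsum(rot[::-1], axis=0)[::-1]  # sum over i' >= i
    integral = spacing * (csum - 0.5 * rot)
    if angle_deg % 360 == 0:
        return integral
    back = ndimage.rotate(integral, -angle_deg, axes=(0, 1), reshape=False,
                          order=1, mode="constant", cval=0.0)
    return np.maximum(back, 0.0)


def apply_attenuation(true_activity: VolumetricImage,
                      mu_map: VolumetricImage,
                      model: DegradationModel) -> VolumetricImage:
    """Depth-dependent signal loss: mean Beer-Lambert survival over the
    direction fan.  Never increases any voxel; identity when mu == 0."""
    true_activity.require_same_grid(mu_map)
    mu = np.asarray(mu_map.values, dtype=float)
    if np.any(mu < 0):
        raise ValueError("attenuation coefficients must be non-negative")
    sp = true_activity.spacing[0]
    n = model.n_projection_dirs
    factor = np.zeros(true_activity.shape, dtype=float)
    for k in range(n):
        angle = 180.0 * k / n
        factor += np.exp(-_path_integral(mu, sp, angle))
    factor /= n
    np.clip(factor, 0.0, 1.0, out=factor)
    return true_activity.with_values(true_activity.values * factor)


def apply_scatter(primary: VolumetricImage,
                  model: DegradationModel) -> VolumetricImage:
    """Count-conserving scatter: blend a fraction f into a broad Gaussian.

    The kernel is normalised and applied with symmetric boundary handling,
    so the global sum is preserved to floating-point precision (photopeak
    scatter redistributes counts, it does not remove them).
    """
    f = model.scatter_fraction
    if f == 0:
        return primary
    sigma_vox = [model.scatter_kernel_fwhm_mm * FWHM_TO_SIGMA / s
                 for s in primary.spacing]
    blurred = ndimage.gaussian_filter(np.asarray(primary.values, float),
                                      sigma_vox, mode="reflect")
    return primary.with_values((1.0 - f) * primary.values + f * blurred)


@dataclass(frozen=True)
class TaskTriplet:
    """One phantom in all three correction states, as counts and as dose."""

    counts: Dict[str, VolumetricImage]
    doses: Dict[str, DoseMap]
    masks: SegmentationSet
    true_activity: VolumetricImage
    mu_map: VolumetricImage
    recipe: PhantomRecipe
    model: DegradationModel


def generate_task_triplet(recipe: PhantomRecipe,
                          model: Optional[DegradationModel] = None,
                          params: RadionuclideParams = RadionuclideParams(),
                          ) -> TaskTriplet:
    """Build one phantom and its NC / AC / ASC count and dose maps.

    ASC counts are the true activity pattern, AC adds scatter degradation
    (its attenuation is 'already corrected'), NC applies attenuation on top.
    All three count maps are scaled to the same expected total before
    optional Poisson sampling, and all three dose maps share the recipe's
    injected activity via whole-liver patient-relative calibration.
    """
    activity, masks, mu_map, default_model = build_phantom(recipe)
    model = model if model is not None else default_model
    asc = activity
    ac = apply_scatter(asc, model)
    nc = apply_attenuation(ac, mu_map, model)

    total = float(np.asarray(asc.values).sum())
    scale = model.total_counts / total if total > 0 else 1.0
    counts: Dict[str, VolumetricImage] = {}
    rng = np.random.default_rng(np.random.SeedSequence([model.seed, recipe.seed]))
    for state, img in (("NC", nc), ("AC", ac), ("ASC", asc)):
        expected = np.asarray(img.values, float) * scale
        if model.poisson_noise:
            sampled = rng.poisson(expected).astype(float)
        else:
            sampled = expected
        counts[state] = img.with_values(sampled)

    wl = masks.mask("WL")
    doses = {
        state: dose_from_counts(counts[state], wl, recipe.injected_activity_gbq,
                                params, correction_state=state)  # type: ignore[arg-type]
        for state in ("NC", "AC", "ASC")
    }
    return TaskTriplet(counts, doses, masks, activity, mu_map, recipe, model)
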