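"""Voxel-level agreement metrics between predicted and reference dose maps.

The battery mirrors standard quantitative-imaging practice: SSIM (reported
x100 as %), PSNR, ME, MAE, MSE, RMSE and the relative errors RE/RAE, plus a
joint-histogram linear fit and 1D line profiles.  Conventions that the
literature frequently leaves implicit are pinned down here and recorded in
every report:

* RE/RAE use the *global* sum-ratio form, RE = 100 * (sum p - sum r)/sum r
  and RAE = 100 * sum|p - r| / sum r over the mask — the per-voxel form
  explodes at near-zero reference voxels (a per-voxel variant with a 0.1 Gy
  reference floor is available via ``per_voxel_relative=True``);
* PSNR uses the in-mask reference maximum as its data range;
* SSIM uses a 7^3 uniform window with k1 = 0.01, k2 = 0.03 on the
  per-volume range, computed over the mask bounding box, with sample
  (n-1) covariance normalisation.

Sign/symmetry: ME is antisymmetric in (pred, ref); MAE/MSE/RMSE are
symmetric; PSNR, SSIM's range convention and RE/RAE are tied to the
reference role.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .image import VolumetricImage
from .ldm import DoseMap

__all__ = ["VoxelMetricReport", "JointHistogramFit", "voxel_report",
           "joint_histogram_fit", "line_profile", "ssim_volume"]


def _values(x) -> np.ndarray:
    return np.asarray(x.values if isinstance(x, (DoseMap, VolumetricImage))
                      else x, dtype=float)


def ssim_volume(pred: np.ndarray, ref: np.ndarray, data_range: float,
                win_size: int = 7, k1: float = 0.01, k2: float = 0.03
                ) -> float:
    """Mean structural similarity over a volume, uniform window.

    Matches the standard windowed SSIM with sample covariance normalisation;
    the mean is taken over the interior (windows fully inside the volume).
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("shapes differ")
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    if any(s < win_size for s in pred.shape):
        win_size = min(min(pred.shape), win_size)
        if win_size % 2 == 0:
            win_size -= 1
        if win_size < 3:
            raise ValueError("volume too small for SSIM window")
    n = win_size ** pred.ndim
    cov_norm = n / (n - 1)
    filt = lambda a: ndimage.uniform_filter(a, win_size, mode="reflect")
    ux, uy = filt(pred), filt(ref)
    uxx, uyy, uxy = filt(pred * pred), filt(ref * ref), filt(pred * ref)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)
    c1, c2 = (k1 * data_range) ** 2, (k2 * data_range) ** 2
    ssim_map = ((2 * ux * uy + c1) * (2 * vxy + c2)) / (
        (ux ** 2 + uy ** 2 + c1) * (vx + vy + c2))
    pad = (win_size - 1) // 2
    interior = tuple(slice(pad, s - pad) for s in pred.shape)
    return float(ssim_map[interior].mean())


@dataclass(frozen=True)
class VoxelMetricReport:
    """One pred-vs-ref voxel comparison.  SSIM is the raw index in [-1, 1]
    (``ssim_pct`` reports it x100); PSNR is +inf for identical inputs."""

    ssim: float
    psnr_db: float
    me_gy: float
    mae_gy: float
    mse_gy2: float
    rmse_gy: float
    re_pct: float
    rae_pct: float
    n_voxels: int
    mask_name: str = "body"
    ssim_window: int = 7
    psnr_range_gy: float = 0.0
    relative_form: str = "global-sum"

    @property
    def ssim_pct(self) -> float:
        return 100.0 * self.ssim

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ssim_pct"] = self.ssim_pct
        return d


def voxel_report(pred: DoseMap | VolumetricImage,
                 ref: DoseMap | VolumetricImage,
                 mask: Optional[np.ndarray] = None,
                 mask_name: str = "body",
                 ssim_window: int = 7,
                 per_voxel_relative: bool = False,
                 relative_floor_gy: float = 0.1) -> VoxelMetricReport:
    """Compute the full voxel metric battery of pred vs ref over a mask."""
    p_full, r_full = _values(pred), _values(ref)
    if p_full.shape != r_full.shape:
        raise ValueError("pred and ref must share a grid")
    if mask is None:
        mask = np.ones(p_full.shape, dtype=bool)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty evaluation mask")
    p, r = p_full[mask], r_full[mask]
    diff = p - r
    me = float(diff.mean())
    mae = float(np.abs(diff).mean())
    mse = float((diff ** 2).mean())
    rmse = math.sqrt(mse)
    ref_sum = float(r.sum())
    if per_voxel_relative:
        denom = np.maximum(r, relative_floor_gy)
        re = float(100.0 * np.mean(diff / denom))
        rae = float(100.0 * np.mean(np.abs(diff) / denom))
        form = f"per-voxel(floor={relative_floor_gy}Gy)"
    else:
        if ref_sum == 0:
            raise ValueError("reference sums to zero: relative metrics undefined")
        re = 100.0 * (float(p.sum()) - ref_sum) / ref_sum
        rae = 100.0 * float(np.abs(diff).sum()) / ref_sum
        form = "global-sum"
    rng = float(r.max())
    psnr = math.inf if mse == 0 else 10.0 * math.log10(rng ** 2 / mse) \
        if rng > 0 else -math.inf
    # SSIM over the mask bounding box
    idx = np.nonzero(mask)
    bbox = tuple(slice(int(i.min()), int(i.max()) + 1) for i in idx)
    pb, rb = p_full[bbox], r_full[bbox]
    drange = float(rb.max() - rb.min())
    ssim = 1.0 if np.array_equal(pb, rb) else ssim_volume(
        pb, rb, drange if drange > 0 else 1.0, ssim_window)
    return VoxelMetricReport(ssim, psnr, me, mae, mse, rmse, re, rae,
                             int(mask.sum()), mask_name, ssim_window, rng, form)


@dataclass(frozen=True)
class JointHistogramFit:
    """OLS fit of predicted on reference voxel doses, plus the 2D histogram
    (for display; the fit uses the raw voxel pairs)."""

    slope: float
    intercept: float
    r_squared: float
    histogram: np.ndarray
    ref_edges: np.ndarray
    pred_edges: np.ndarray
    scope: str = "whole_image"


def joint_histogram_fit(pred: DoseMap | VolumetricImage,
                        ref: DoseMap | VolumetricImage,
                        mask: Optional[np.ndarray] = None,
                        n_bins: int = 100,
                        scope: str = "whole_image") -> JointHistogramFit:
    p, r = _values(pred), _values(ref)
    if p.shape != r.shape:
        raise ValueError("pred and ref must share a grid")
    if mask is not None:
        sel = np.asarray(mask, bool)
        p, r = p[sel], r[sel]
    else:
        p, r = p.ravel(), r.ravel()
    if p.size == 0:
        raise ValueError("empty mask")
    if np.ptp(r) == 0:
        raise ValueError("constant reference: fit degenerate")
    slope, intercept = np.polyfit(r, p, 1)
    fitted = slope * r + intercept
    ss_res = float(((p - fitted) ** 2).sum())
    ss_tot = float(((p - p.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    hist, re_, pe_ = np.histogram2d(r, p, bins=n_bins)
    return JointHistogramFit(float(slope), float(intercept), float(r2),
                             hist, re_, pe_, scope)


def line_profile(dose: DoseMap | VolumetricImage, axis: str,
                 through_point_mm: Tuple[float, float, float]
                 ) -> Tuple[np.ndarray, np.ndarray]:
    """Dose values along the grid line (nearest to a world point) parallel
    to ``axis``; returns (positions mm, values)."""
    img = dose.image if isinstance(dose, DoseMap) else dose
    ax = {"x": 0, "y": 1, "z": 2}[axis.lower()]
    idx = np.rint(img.world_to_index(through_point_mm)).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(img.shape)):
        raise ValueError(f"point {through_point_mm} lies outside the volume")
    sl = [idx[0], idx[1], idx[2]]
    sl[ax] = slice(None)  # type: ignore[call-overload]
    values = np.asarray(img.values)[tuple(sl)]
    positions = img.origin[ax] + np.arange(img.shape[ax]) * img.spacing[ax]
    return positions, np.asarray(values, dtype=float)
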