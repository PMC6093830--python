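"""Volumes of interest: TAC extraction, CP delineation, hippocampal erosion.

The hippocampal VOI comes in two flavours: the *complete* anatomical mask
and an *eroded* mask from which every voxel lying within a configurable
Euclidean distance (mm, voxel centre to voxel centre) of the choroid plexus
has been removed.  The CP itself is delineated automatically on a
partial-volume-corrected image as the largest connected component of
voxels whose late-frame average exceeds a multiple of the background's
late mean — a reproducible surrogate for manual drawing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import EmptyRegionError, ParameterError
from .image import DynamicImage

__all__ = ["TAC", "VOISet", "extract_tac", "delineate_cp", "erode_hippocampus"]


@dataclass
class TAC:
    """Regional time-activity curve (frame means, Bq/mL)."""

    frame_mid_min: np.ndarray
    values: np.ndarray
    region: str
    n_voxels: int

    def __post_init__(self) -> None:
        self.frame_mid_min = np.asarray(self.frame_mid_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.frame_mid_min.shape != self.values.shape:
            raise ParameterError("TAC times and values must have equal length")
        if self.n_voxels < 1:
            raise EmptyRegionError(f"TAC for region '{self.region}' has no voxels")


@dataclass
class VOISet:
    """Named binary masks on one PET grid, plus the erosion bookkeeping."""

    label_volume: np.ndarray
    label_table: dict
    erosion_record: dict = field(default_factory=dict)

    def mask(self, name: str) -> np.ndarray:
        return self.label_volume == self.label_table[name]


def extract_tac(img: DynamicImage, mask: np.ndarray, region: str = "region") -> TAC:
    """Mean in-mask activity per frame."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ParameterError(
            f"mask grid {mask.shape} does not match image grid {img.shape}"
        )
    n = int(mask.sum())
    if n == 0:
        raise EmptyRegionError(f"empty mask for region '{region}'")
    values = img.voxel_data[mask, :].mean(axis=0)
    return TAC(frame_mid_min=img.frames.mid_min, values=values, region=region, n_voxels=n)


def late_frame_average(img: DynamicImage, window_min: float = 25.0) -> np.ndarray:
    """Duration-weighted voxel mean over frames whose mid-time falls in the
    last ``window_min`` minutes of the acquisition."""
    mid = img.frames.mid_min
    t_end = float(img.frames.end_s.max()) / 60.0
    sel = mid >= t_end - window_min
    if not sel.any():
        sel = np.zeros_like(sel)
        sel[-1] = True
    w = img.frames.duration_s[sel]
    return np.tensordot(img.voxel_data[..., sel], w / w.sum(), axes=([3], [0]))


def delineate_cp(
    img_pvc: DynamicImage,
    background_mask: np.ndarray,
    search_mask: np.ndarray | None = None,
    threshold_factor: float = 2.0,
    rel_max_fraction: float | None = 0.5,
    cap_fraction: float = 0.8,
    late_window_min: float = 25.0,
    smoothing_fwhm_mm: float = 3.0,
) -> tuple[np.ndarray, dict]:
    """Automatic choroid-plexus mask on a PVC image.

    Thresholds the late-frame average, restricted to ``search_mask`` (whole
    volume if None), and keeps the largest connected component.  The late
    image is lightly smoothed first (``smoothing_fwhm_mm``) so isolated
    deconvolution spikes do not dominate.  The threshold is
    ``threshold_factor`` times the background label's late mean; if
    ``rel_max_fraction`` is given, it is raised to that fraction of the
    late 99th percentile inside the search region when that is higher,
    which keeps the mask compact when structures brighter than the CP floor
    (e.g. the blurred hippocampal rim) enter the search region while
    staying robust to isolated deconvolution overshoots.  The combined
    threshold is capped at ``cap_fraction`` of the search-region maximum so
    the hottest structure is never thresholded away when the background
    floor runs high (only active together with ``rel_max_fraction``).
    Returns (mask, record) where the record holds the threshold and the
    number of supra-threshold components.
    """
    late = late_frame_average(img_pvc, late_window_min)
    if smoothing_fwhm_mm > 0:
        sigma = (smoothing_fwhm_mm / 2.3548200450309493) / img_pvc.voxel_size
        late = ndimage.gaussian_filter(late, sigma, mode="reflect")
    bg = np.asarray(background_mask, dtype=bool)
    if bg.shape != img_pvc.shape or not bg.any():
        raise ParameterError("background mask must be non-empty and on the image grid")
    threshold = threshold_factor * float(late[bg].mean())
    region = late if search_mask is None else late[np.asarray(search_mask, dtype=bool)]
    if rel_max_fraction is not None and region.size:
        threshold = max(threshold, rel_max_fraction * float(np.percentile(region, 99)))
        threshold = min(threshold, cap_fraction * float(region.max()))
    supra = late > threshold
    if search_mask is not None:
        supra &= np.asarray(search_mask, dtype=bool)
    if not supra.any():
        raise EmptyRegionError("no voxel exceeds the CP threshold (empty CP)")
    comp, n_comp = ndimage.label(supra)
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n_comp + 1))
    largest = int(np.argmax(sizes)) + 1
    mask = comp == largest
    record = {
        "threshold": threshold,
        "threshold_factor": threshold_factor,
        "n_components": int(n_comp),
        "n_voxels": int(mask.sum()),
    }
    return mask, record


def erode_hippocampus(
    hippo_mask: np.ndarray,
    cp_mask: np.ndarray,
    radius_mm: float,
    voxel_size_mm: np.ndarray,
) -> tuple[np.ndarray, dict]:
    """Remove hippocampal voxels within ``radius_mm`` of any CP voxel.

    Distance is Euclidean between voxel centres, in mm, computed with a
    distance transform of the CP mask.  Returns (eroded mask, record with
    removed count and fraction).
    """
    hippo = np.asarray(hippo_mask, dtype=bool)
    cp = np.asarray(cp_mask, dtype=bool)
    if hippo.shape != cp.shape:
        raise ParameterError("hippocampus and CP masks must share one grid")
    if radius_mm < 0:
        raise ParameterError("erosion radius must be non-negative")
    if not hippo.any():
        raise EmptyRegionError("empty hippocampus mask")
    if not cp.any():
        raise EmptyRegionError("empty CP mask")
    dist = ndimage.distance_transform_edt(~cp, sampling=np.asarray(voxel_size_mm, float))
    removed = hippo & (dist <= radius_mm)
    eroded = hippo & ~removed
    n_total = int(hippo.sum())
    n_removed = int(removed.sum())
    if not eroded.any():
        raise EmptyRegionError(
            "erosion removed every hippocampal voxel (complete overlap with CP)"
        )
    record = {
        "radius_mm": float(radius_mm),
        "n_hippocampus": n_total,
        "n_removed": n_removed,
        "removed_fraction": n_removed / n_total,
    }
    return eroded, record


#: default erosion radius (mm), calibrated so the default phantom geometry
#: loses ~40% of its hippocampal voxels (see docs/methods.md)
DEFAULT_ERODE_RADIUS_MM = 4.0
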