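"""Thresholding and component classification.

The ridge response (or raw grayscale) is thresholded to a biofilm
("vessel") mask, and connected components of the union of thresholded
structures are separated into hyphae, bacteria and residual EPS/biofilm.
Classification is width/shape based and resolution independent: bounds
are expressed in microns and converted through the image's calibration.
EPS is defined residually — ridge-detected material that is neither
fungal nor bacterial — mirroring a segmentation chain in which biofilm
is what remains after removing the large structures.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops

from .io import Micrograph
from .ridge import RidgeResponse

logger = logging.getLogger(__name__)

__all__ = [
    "BiofilmMask",
    "MorphClassBounds",
    "ComponentLabels",
    "otsu_threshold",
    "threshold_biofilm",
    "classify_components",
]

_EIGHT = np.ones((3, 3), dtype=bool)

CLASS_NAMES = ("hypha", "bacterium", "eps", "excluded")


@dataclass
class BiofilmMask:
    """Binary mask of retained biofilm ("vessel") pixels."""

    mask: np.ndarray
    source: str = "response"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def vessel_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class MorphClassBounds:
    """Micron-unit class bounds for component classification.

    Defaults span the observed morphometry with margin: bacteria
    0.53-2.6 um long and 0.25-0.85 um wide, hyphae a few microns wide.
    """

    hypha_min_width: float = 1.5          # um; minimum local tube width
    bact_min_len: float = 0.25            # um
    bact_max_len: float = 3.0             # um
    bact_min_width: float = 0.2           # um
    bact_max_width: float = 1.0           # um
    elongation_min: float = 3.0           # major/minor axis ratio for tubes
    solidity_min: float = 0.8             # rod convexity requirement
    min_object_px: int = 4                # smaller foreground specks -> noise


@dataclass
class ComponentLabels:
    """Labeled foreground components with one class per label."""

    labels: np.ndarray
    classes: dict[int, str] = field(default_factory=dict)

    def class_mask(self, cls: str) -> np.ndarray:
        wanted = [lbl for lbl, c in self.classes.items() if c == cls]
        return np.isin(self.labels, wanted) if wanted else np.zeros(self.labels.shape, bool)


def otsu_threshold(values: np.ndarray) -> float:
    """Otsu's threshold over a 256-bin histogram.

    Returns the threshold maximizing between-class variance; a constant
    array is a degenerate input and raises.
    """
    values = np.asarray(values)
    if values.min() == values.max():
        raise ValueError("cannot threshold a constant array")
    return float(threshold_otsu(values, nbins=256))


def threshold_biofilm(
    response: RidgeResponse | np.ndarray,
    method: str = "otsu",
    manual_value: float | None = None,
    source: str = "response",
    image: "Micrograph | np.ndarray | None" = None,
) -> BiofilmMask:
    """Threshold a response (or intensity) map to a biofilm mask.

    Pixels with zero ridge response are never in the mask.  An all-zero
    response yields an empty mask with a warning rather than an error.

    A ridge response spreads roughly one smoothing scale beyond each
    structure's edges, so the raw thresholded support overstates areal
    coverage.  When the source *image* is supplied, each detected
    component is re-cut at half its intensity plateau (FWHM footprint),
    which restores an unbiased area while keeping the ridge detection in
    charge of what counts as a structure.
    """
    values = response.R if isinstance(response, RidgeResponse) else np.asarray(response)
    if manual_value is not None or method == "manual":
        if manual_value is None:
            raise ValueError("manual thresholding requires manual_value")
        thr = float(manual_value)
    elif method == "otsu":
        # a ridge response is overwhelmingly zero; Otsu over the positive
        # support separates weak (noise) from strong (structure) ridges
        # instead of merely separating zero from nonzero
        positive = values[values > 0]
        if positive.size == 0 or values.min() == values.max():
            warnings.warn("all-constant response; biofilm mask is empty", stacklevel=2)
            return BiofilmMask(mask=np.zeros(values.shape, bool), source=source)
        if positive.min() == positive.max():
            thr = 0.5 * float(positive.min())
        else:
            thr = otsu_threshold(positive)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    if manual_value is None and method == "otsu":
        # hysteresis growth: faint ridge pixels count when connected to a
        # confidently detected ridge, so a thin strand is kept end to end
        from skimage.filters import apply_hysteresis_threshold

        mask = apply_hysteresis_threshold(values, 0.5 * thr, thr) & (values > 0)
    else:
        mask = (values > thr) & (values > 0)
    if not mask.any():
        warnings.warn("biofilm mask is empty", stacklevel=2)
    if image is not None and mask.any():
        img = image if isinstance(image, Micrograph) else Micrograph(np.asarray(image))
        refined = np.zeros_like(mask)
        lbl, n = ndimage.label(mask, structure=_EIGHT)
        for sl_idx, sl in enumerate(ndimage.find_objects(lbl), start=1):
            if sl is None:
                continue
            comp = np.zeros_like(mask)
            comp[sl] = lbl[sl] == sl_idx
            refined |= refine_halfmax(img, comp)
        mask = refined
    logger.info("threshold_biofilm: method=%s threshold=%.6g vessels=%d",
                method if manual_value is None else "manual", thr, int(mask.sum()))
    return BiofilmMask(mask=mask, source=source)


def binary_opening_disk(mask: np.ndarray, radius: float) -> np.ndarray:
    """Morphological opening with an exact Euclidean disk, via two EDTs.

    Erosion keeps pixels farther than *radius* from the background; the
    dilation step then restores the retained structures.  Equivalent to
    opening with a true disk footprint but O(N) in image size.
    """
    mask = np.asarray(mask, dtype=bool)
    if radius <= 0:
        return mask.copy()
    eroded = ndimage.distance_transform_edt(mask) > radius
    if not eroded.any():
        return np.zeros_like(mask)
    return ndimage.distance_transform_edt(~eroded) <= radius


def refine_halfmax(
    img: Micrograph, mask: np.ndarray, background: float | None = None, pad: int = 4
) -> np.ndarray:
    """Re-threshold an object at half its peak contrast (FWHM boundary).

    Blurred bright objects segmented with a global threshold carry a
    sub-pixel boundary bias; the full-width-half-maximum boundary is the
    unbiased edge estimate for a plateau object under symmetric blur.
    The refinement is local: it operates on the object's padded bounding
    box, stays within a 1-px dilation of the seed mask, and keeps only
    pixels connected to the seed, so neighboring structures cannot leak in.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    sl = (slice(max(rows[0] - pad, 0), min(rows[-1] + pad + 1, mask.shape[0])),
          slice(max(cols[0] - pad, 0), min(cols[-1] + pad + 1, mask.shape[1])))
    seed = mask[sl]
    # light smoothing suppresses noise raggedness at the re-thresholded
    # contour; a symmetric kernel does not move the half-max boundary
    local = ndimage.gaussian_filter(img.pixels[sl], 1.0)
    outside = local[~seed]
    if background is None:
        # low percentile: the local surroundings may contain other bright
        # structures, the dark field is their lower envelope
        background = float(np.percentile(outside, 10)) if outside.size else 0.0
    peak = float(np.percentile(local[seed], 95))
    if peak <= background:
        return mask
    thr = 0.5 * (peak + background)
    refined = (local > thr) & ndimage.binary_dilation(seed, structure=_EIGHT)
    lbl, _ = ndimage.label(refined, structure=_EIGHT)
    keep = np.unique(lbl[seed & refined])
    keep = keep[keep > 0]
    if keep.size == 0:
        return mask
    out = np.zeros_like(mask)
    out[sl] = np.isin(lbl, keep)
    return out


def _tube_width_px(mask: np.ndarray) -> float:
    """Local tube width in pixels (see morphometry.measure_tube_width)."""
    from .morphometry import measure_tube_width

    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    crop = mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return measure_tube_width(crop, scale=1.0)


def _intensity_levels(pixels: np.ndarray) -> tuple[float, float]:
    """Faint/bright foreground thresholds (t_fg, t_cell).

    A three-class Otsu split separates the dark field, the faint EPS
    film and the bright cellular plateaus (hyphae, bacteria).  When the
    middle class is essentially empty the histogram is bimodal and a
    single Otsu threshold serves as both levels.
    """
    from skimage.filters import threshold_multiotsu

    t_single = threshold_otsu(pixels, nbins=256)
    try:
        t_fg, t_cell = threshold_multiotsu(pixels, classes=3, nbins=256)
    except ValueError:
        return float(t_single), float(t_single)
    middle = float(((pixels > t_fg) & (pixels <= t_cell)).mean())
    # guard against the three-class split latching onto the background
    # noise tail: the faint threshold must clear the dark field by a few
    # robust standard deviations, else there is no faint class
    below = pixels[pixels <= t_single]
    bg_med = float(np.median(below)) if below.size else 0.0
    bg_sd = 1.4826 * float(np.median(np.abs(below - bg_med))) if below.size else 0.0
    if middle < 0.005 or t_fg < bg_med + 3.0 * bg_sd:
        return float(t_single), float(t_single)
    return float(t_fg), float(t_cell)


def classify_components(
    img: Micrograph,
    biofilm: BiofilmMask,
    bounds: MorphClassBounds | None = None,
) -> ComponentLabels:
    """Separate hyphae, bacteria and residual EPS in a calibrated image.

    The foreground is the union of an intensity threshold (bright
    structures including the faint EPS film, via a three-class Otsu
    split) and the supplied biofilm/ridge mask (thin ridge-detected
    structures).  Wide structures are isolated by a disk opening at half
    the minimum hyphal width and classed as hyphae when elongated; among
    the remainder, a small opening removes sub-bacterial filaments and
    the surviving components are classed as bacteria when their ellipse
    axes fall inside the rod bounds, they are approximately convex, and
    they sit at the bright cellular intensity level.  Everything else in
    the foreground is residual EPS/biofilm.
    """
    bounds = bounds or MorphClassBounds()
    scale = img.require_scale()
    ppm = 1.0 / scale

    try:
        t_fg, t_cell = _intensity_levels(img.pixels)
        fg = img.pixels > t_fg
    except ValueError:
        fg = np.zeros(img.shape, bool)
        t_cell = np.inf
    union = fg | biofilm.mask
    if not union.any():
        return ComponentLabels(labels=np.zeros(img.shape, np.int32), classes={})

    # --- wide structures: hyphae (or non-elongated large debris) ---
    r_hypha = 0.5 * bounds.hypha_min_width * ppm
    wide = binary_opening_disk(fg, r_hypha)
    hyphae = np.zeros(img.shape, bool)
    excluded = np.zeros(img.shape, bool)
    wide_lbl, n_wide = ndimage.label(wide, structure=_EIGHT)
    for region in regionprops(wide_lbl):
        comp = wide_lbl == region.label
        width_px = _tube_width_px(comp)
        # curvilinear elongation (centerline length / width); robust to
        # bending, which deflates the ellipse-axis ratio of sinuous tubes
        elong = region.area / width_px**2 if width_px > 0 else np.inf
        if elong >= bounds.elongation_min and width_px >= bounds.hypha_min_width * ppm - 1:
            hyphae |= comp
        else:
            excluded |= comp

    # --- mid-size structures: candidate bacteria ---
    remaining = fg & ~hyphae & ~excluded
    r_bact = max(1.0, 0.5 * bounds.bact_min_width * ppm)
    cand = binary_opening_disk(remaining, r_bact)
    bacteria = np.zeros(img.shape, bool)
    cand_lbl, _ = ndimage.label(cand, structure=_EIGHT)
    for region in regionprops(cand_lbl):
        comp = cand_lbl == region.label
        # classify on the half-max footprint: the faint-threshold blob can
        # annex the glow between a cell and a neighboring structure, which
        # would distort the shape test and swallow EPS material
        refined = refine_halfmax(img, comp)
        ref_lbl, n_ref = ndimage.label(refined, structure=_EIGHT)
        rprops = regionprops(ref_lbl)
        if not rprops:
            continue
        region_r = max(rprops, key=lambda rg: rg.area)
        refined = ref_lbl == region_r.label
        length = region_r.axis_major_length * scale
        width = region_r.axis_minor_length * scale
        if (
            bounds.bact_min_len <= length <= bounds.bact_max_len
            and bounds.bact_min_width <= width <= bounds.bact_max_width
            and region_r.solidity >= bounds.solidity_min
            and float(np.median(img.pixels[refined])) >= t_cell
        ):
            bacteria |= refined

    # --- residual thin ridge-like material: EPS/biofilm ---
    eps = union & ~hyphae & ~bacteria & ~excluded
    # drop sub-resolution specks (noise)
    eps_lbl, n_eps = ndimage.label(eps, structure=_EIGHT)
    if n_eps:
        sizes = np.bincount(eps_lbl.ravel())
        small = sizes < bounds.min_object_px
        small[0] = False
        eps[small[eps_lbl]] = False

    labels = np.zeros(img.shape, dtype=np.int32)
    classes: dict[int, str] = {}
    next_label = 1
    for cls, cmask in (("hypha", hyphae), ("bacterium", bacteria),
                       ("eps", eps), ("excluded", excluded)):
        cls_lbl, n = ndimage.label(cmask, structure=_EIGHT)
        for i in range(1, n + 1):
            labels[cls_lbl == i] = next_label
            classes[next_label] = cls
            next_label += 1
    logger.info(
        "classify_components: %d hyphae px, %d bacteria px, %d eps px",
        int(hyphae.sum()), int(bacteria.sum()), int(eps.sum()),
    )
    return ComponentLabels(labels=labels, classes=classes)
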