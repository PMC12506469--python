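"""End-to-end analysis chain: grayscale -> ridge response -> threshold ->
classification -> morphometry, with a serializable configuration.

This mirrors the processing chain applied to the coculture micrographs:
the multi-scale ridge response (sigma swept over [1, 50] px) is
thresholded to the biofilm mask, large fungal and bacterial structures
are separated out, and the residual EPS supplies the area/coverage
figures while per-object measures are taken on the classified bacteria
and hyphae.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import regionprops

from .io import Micrograph
from .morphometry import (
    AreaReport,
    Attachment,
    ObjectMeasure,
    area_report,
    exclusion_filter,
    measure_attachments,
    measure_rod,
    measure_tube_width,
)
from .ridge import RidgeParams, RidgeResponse, multiscale_response
from .segmentation import (
    BiofilmMask,
    ComponentLabels,
    MorphClassBounds,
    binary_opening_disk,
    classify_components,
    refine_halfmax,
    threshold_biofilm,
)

__all__ = [
    "AnalysisConfig",
    "ImageAnalysis",
    "analyze_micrograph",
    "match_attachments_to_truth",
]


@dataclass
class AnalysisConfig:
    """Full parameterization of one analysis run; JSON round-trippable."""

    sigma_min: float = 1.0
    sigma_max: float = 50.0
    n_scales: int = 10
    alpha: float = 0.25
    tau: float = 0.0
    polarity: str = "bright"
    normalized: bool = True
    threshold_method: str = "otsu"
    manual_threshold: float | None = None
    bounds: MorphClassBounds = field(default_factory=MorphClassBounds)
    sd_ddof: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        data = dict(data)
        if isinstance(data.get("bounds"), dict):
            data["bounds"] = MorphClassBounds(**data["bounds"])
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisConfig":
        return cls.from_dict(json.loads(text))

    def ridge_params(self) -> RidgeParams:
        return RidgeParams(alpha=self.alpha, tau=self.tau, polarity=self.polarity)


@dataclass
class ImageAnalysis:
    """All per-image products of the analysis chain."""

    image: Micrograph
    config: AnalysisConfig
    response: "RidgeResponse"
    biofilm: BiofilmMask
    labels: ComponentLabels
    hyphae_mask: np.ndarray
    bacteria_mask: np.ndarray
    eps_mask: np.ndarray
    #: EPS footprint re-cut at half its plateau contrast; the mask behind
    #: the area report (the class mask is blur-fattened for thin strands)
    eps_refined: np.ndarray
    area: AreaReport
    measures: list[ObjectMeasure]
    attachments: list[Attachment]

    @property
    def included_measures(self) -> list[ObjectMeasure]:
        return [m for m in self.measures if not m.excluded]


def _touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0, :].any() or mask[-1, :].any()
                or mask[:, 0].any() or mask[:, -1].any())


def _component_masks(labels: ComponentLabels, cls: str):
    wanted = sorted(lbl for lbl, c in labels.classes.items() if c == cls)
    for lbl in wanted:
        yield lbl, labels.labels == lbl


def analyze_micrograph(
    img: Micrograph, config: AnalysisConfig | None = None, sample_id: str | None = None
) -> ImageAnalysis:
    """Run the full chain on one calibrated micrograph.

    The biofilm area report is computed on the residual EPS class (the
    biofilm mask after fungal and bacterial structures are removed);
    bacteria and hyphae are measured per object on half-maximum-refined
    masks so that the blur-dependent boundary of the global threshold does
    not bias lengths and widths.  The exclusion rule flags border-touching
    and deformed objects.
    """
    config = config or AnalysisConfig()
    sample_id = sample_id if sample_id is not None else img.name
    scale = img.require_scale()

    response = multiscale_response(
        img,
        sigma_min=config.sigma_min,
        sigma_max=config.sigma_max,
        n_scales=config.n_scales,
        params=config.ridge_params(),
        normalized=config.normalized,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        biofilm = threshold_biofilm(
            response, method=config.threshold_method,
            manual_value=config.manual_threshold,
        )
    labels = classify_components(img, biofilm, config.bounds)
    hyphae_mask = labels.class_mask("hypha")
    bacteria_mask = labels.class_mask("bacterium")
    eps_mask = labels.class_mask("eps")

    # the global foreground threshold sits well below the EPS plateau, so
    # the raw class footprint of thin strands is blur-fattened; re-cut the
    # EPS film at half its plateau contrast for unbiased areal coverage
    eps_refined = eps_mask
    if eps_mask.any():
        smoothed = ndimage.gaussian_filter(img.pixels, 1.0)
        bg_px = ~(eps_mask | hyphae_mask | bacteria_mask)
        background = float(np.median(img.pixels[bg_px])) if bg_px.any() else 0.0
        plateau = float(np.percentile(img.pixels[eps_mask], 75))
        if plateau > background:
            thr = 0.5 * (plateau + background)
            eps_refined = (
                (smoothed > thr)
                & ndimage.binary_dilation(eps_mask, np.ones((3, 3), bool))
                & ~hyphae_mask & ~bacteria_mask
            )
    area = area_report(eps_refined, img)

    measures: list[ObjectMeasure] = []
    refined_bact = np.zeros(img.shape, bool)
    refined_hyph = np.zeros(img.shape, bool)
    for lbl, comp in _component_masks(labels, "bacterium"):
        refined = refine_halfmax(img, comp)
        refined_bact |= refined
        region = regionprops(refined.astype(np.uint8))[0]
        length, width = measure_rod(refined, scale)
        measures.append(ObjectMeasure(
            label=lbl, cls="bacterium", length_um=length, width_um=width,
            touches_border=_touches_border(comp), solidity=float(region.solidity),
            sample_id=sample_id,
        ))
    for lbl, comp in _component_masks(labels, "hypha"):
        refined_hyph |= refine_halfmax(img, comp)
        # width is measured on the disk-opened class mask: its boundary is
        # morphologically smoothed, whereas re-thresholding would re-import
        # noise raggedness that bites notches into the distance transform
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            width = measure_tube_width(comp, scale)
        coords = np.argwhere(comp)
        length = float(np.ptp(coords, axis=0).max() + 1) * scale
        measures.append(ObjectMeasure(
            label=lbl, cls="hypha", length_um=max(length, width), width_um=width,
            touches_border=_touches_border(comp), solidity=1.0,
            sample_id=sample_id,
        ))
    measures = exclusion_filter(
        measures, img.shape, solidity_min=config.bounds.solidity_min
    )

    # attachment lengths run between the half-maximum object boundaries:
    # the blur shoulder between the global-threshold and half-max contours
    # is handed to the EPS path so geodesics start at the true cell edge.
    # A small opening shaves the "nose" that additive blur overlap grows
    # on an anchor where a filament or EPS strand abuts it, which would
    # otherwise bite into the measured gap; the hyphal anchor uses a
    # larger radius (a quarter of the minimum hyphal width) because
    # resolvable EPS strands crossing its edge grow wider noses.
    ppm = 1.0 / scale
    refined_bact = binary_opening_disk(
        refined_bact, max(0.5 * config.bounds.bact_min_width * ppm, 1.0)
    )
    refined_hyph = binary_opening_disk(
        refined_hyph, max(0.25 * config.bounds.hypha_min_width * ppm, 1.0)
    ) & ~refined_bact
    # the corridor is ridge-supported EPS: a genuine filament is a bright
    # ridge, while diffuse blur glow between two nearby cells is a smooth
    # saddle with no ridge response and must not offer shortcut routes.
    # Shoulder pixels and glow within 2 px of a ridge core join as end
    # caps so the path can reach the anchors.
    core = eps_mask & biofilm.mask
    shoulder = (bacteria_mask & ~refined_bact) | (hyphae_mask & ~refined_hyph)
    near_core = ndimage.binary_dilation(core, np.ones((3, 3), bool), iterations=2)
    eps_for_attach = (
        (core | ((eps_mask | shoulder) & near_core))
        & ~refined_bact & ~refined_hyph
    )
    # seal one-pixel breaks so a noise dropout cannot sever a filament
    eps_for_attach = ndimage.binary_closing(
        eps_for_attach, np.ones((3, 3), bool)
    ) & ~refined_bact & ~refined_hyph
    attachments = measure_attachments(
        eps_for_attach, refined_bact, refined_hyph, scale,
        response=response.R,
        intensity=ndimage.gaussian_filter(img.pixels, 1.0),
    )
    # one anchoring structure per bacterium: reliably localized (sub-pixel)
    # candidates first; among those of plausible attachment scale the
    # strongest continuous ridge wins (a faint glow shortcut measures
    # weaker, a wandering detour through the EPS network measures longer)
    def _rank(att: Attachment) -> tuple:
        plausible = att.length_um <= 1.0
        return (att.subpixel, plausible, att.ridge_strength)

    best_per_rod: dict[int, Attachment] = {}
    for att in attachments:
        cur = best_per_rod.get(att.bacterium_label)
        if cur is None or _rank(att) > _rank(cur):
            best_per_rod[att.bacterium_label] = att
    attachments = [best_per_rod[k] for k in sorted(best_per_rod)]

    return ImageAnalysis(
        image=img, config=config, response=response, biofilm=biofilm, labels=labels,
        hyphae_mask=hyphae_mask, bacteria_mask=bacteria_mask, eps_mask=eps_mask,
        eps_refined=eps_refined, area=area, measures=measures,
        attachments=attachments,
    )


def match_attachments_to_truth(scene, analysis: ImageAnalysis):
    """Pair each truth filament with the recovered attachment of its rod.

    The i-th filament of a synthetic scene anchors the i-th rod; the
    recovered attachment whose path starts nearest that rod's center is
    its measurement.  Returns ``[(truth_um, recovered_um | None), ...]``
    with None for undetected filaments.
    """
    scale = scene.image.require_scale()
    pairs: list[tuple[float, float | None]] = []
    for fil, rod in zip(scene.filaments, scene.rods):
        center = np.asarray(rod.center)
        best = None
        best_d = np.inf
        for att in analysis.attachments:
            d = float(np.linalg.norm(att.path[0] - center))
            if d < best_d:
                best_d, best = d, att
        max_d = 0.5 * rod.length_um / scale + 6.0
        pairs.append((fil.length_um, best.length_um if best is not None and best_d <= max_d else None))
    return pairs
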