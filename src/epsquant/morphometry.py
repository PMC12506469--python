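"""Area/coverage quantities and object morphometry.

Implements the area bookkeeping used for biofilm quantification,

    A_v = vessel_pixels * scale**2        (biofilm area, um^2)
    A_t = M * N * scale**2                (field area, um^2)
    P_v = 100 * vessel_pixels / (M * N)   (percent coverage)

plus per-object measurements: rod (bacterium) length/width from the
second-moment ellipse, tube (hypha) width from the skeleton-sampled
distance transform, and attachment-structure length as the geodesic path
along an EPS component between its bacterium-adjacent and hypha-adjacent
pixels.  An exclusion rule flags partially visible (border-touching) and
deformed (low-solidity) objects so they can be omitted from summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import graph as skgraph
from skimage.measure import regionprops
from skimage.morphology import skeletonize

from .io import Micrograph

__all__ = [
    "AreaReport",
    "ObjectMeasure",
    "Attachment",
    "MetricStat",
    "SampleSummary",
    "area_report",
    "measure_rod",
    "measure_tube_width",
    "measure_attachments",
    "exclusion_filter",
    "summarize",
]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class AreaReport:
    """Biofilm area A_v, field area A_t and percent coverage P_v."""

    A_v: float
    A_t: float
    P_v: float
    vessel_pixels: int
    scale: float


@dataclass
class ObjectMeasure:
    """One measured object (bacterium, hypha or EPS structure)."""

    label: int
    cls: str
    length_um: float
    width_um: float
    touches_border: bool = False
    solidity: float = 1.0
    excluded: bool = False
    reason: str = ""
    sample_id: str = ""


@dataclass
class Attachment:
    """A bacterium-to-hypha EPS attachment structure."""

    label: int
    length_um: float
    #: (row, col) pixel coordinates of the measured path.
    path: np.ndarray | None = None
    #: connected-component id of the anchoring bacterium.
    bacterium_label: int = 0
    #: median ridge response along the path (when a response map was given).
    ridge_strength: float = 0.0
    #: whether the length came from sub-pixel interface localization.
    subpixel: bool = False


@dataclass
class MetricStat:
    mean: float
    sd: float
    n: int


@dataclass
class SampleSummary:
    """Per-metric mean and SD for one sample (or the pooled set)."""

    sample_id: str
    metrics: dict[str, MetricStat] = field(default_factory=dict)


def area_report(mask, img: Micrograph) -> AreaReport:
    """Compute A_v, A_t and P_v for a biofilm mask over a calibrated image.

    *mask* may be a :class:`~epsquant.segmentation.BiofilmMask` or a plain
    boolean array of the image's shape.
    """
    arr = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    scale = img.require_scale()
    if arr.shape != img.shape:
        raise ValueError(f"mask shape {arr.shape} != image shape {img.shape}")
    m, n = img.shape
    vessel_pixels = int(arr.sum())
    a_v = vessel_pixels * scale**2
    a_t = m * n * scale**2
    p_v = vessel_pixels / (m * n) * 100.0
    return AreaReport(A_v=a_v, A_t=a_t, P_v=p_v, vessel_pixels=vessel_pixels, scale=scale)


def _single_region(label_mask: np.ndarray):
    label_mask = np.asarray(label_mask, dtype=bool)
    if not label_mask.any():
        raise ValueError("empty region")
    return regionprops(label_mask.astype(np.uint8))[0]


def measure_rod(label_mask: np.ndarray, scale: float) -> tuple[float, float]:
    """Length and width (um) of a rod region via second-moment ellipse axes.

    Length >= width is enforced by swapping; robust to rotation and to
    boundary pixelation, unlike Feret diameters.
    """
    region = _single_region(label_mask)
    a = region.axis_major_length * scale
    b = region.axis_minor_length * scale
    return (a, b) if a >= b else (b, a)


def _prune_skeleton(skel: np.ndarray, n_iter: int) -> np.ndarray:
    """Remove spur branches by iteratively deleting skeleton endpoints.

    Boundary roughness grows short side branches on the skeleton whose
    distance-transform samples would drag the width median down; spurs
    shorter than *n_iter* pixels disappear while the main path only loses
    its two open ends.
    """
    skel = skel.copy()
    kernel = np.ones((3, 3))
    for _ in range(n_iter):
        neighbors = ndimage.convolve(skel.astype(np.uint8), kernel, mode="constant")
        endpoints = skel & (neighbors <= 2)  # self + at most one neighbor
        if not endpoints.any():
            break
        skel &= ~endpoints
        if not skel.any():
            break
    return skel


def measure_tube_width(label_mask: np.ndarray, scale: float) -> float:
    """Width (um) of a tubular region.

    The Euclidean distance transform is sampled along the region's
    morphological skeleton (pruned of spur branches); width =
    2 * median(distance) - 0.5 pixel, the half-pixel correcting for the
    grid distance to the nearest *background* pixel center (for a band of
    n pixel columns, 2 * centerline distance is n for even n and n + 1
    for odd n, so it overshoots the continuous width by 0.5 px on
    average).  Regions thinner than 2 px are quantization dominated and
    return the integer pixel-count width (a one-pixel line reports one
    pixel) with a warning.
    """
    label_mask = np.asarray(label_mask, dtype=bool)
    if not label_mask.any():
        raise ValueError("empty region")
    edt = ndimage.distance_transform_edt(label_mask)
    skel = skeletonize(label_mask)
    pruned = _prune_skeleton(skel, int(np.ceil(edt.max())) + 2)
    if pruned.any():
        skel = pruned
    samples = edt[skel] if skel.any() else edt[label_mask]
    width_px = 2.0 * float(np.median(samples)) - 0.5
    if width_px < 2.0:
        warnings.warn(
            "region thinner than 2 px; width estimate is pixel-limited",
            stacklevel=2,
        )
        width_px = max(1.0, 2.0 * float(np.median(samples)) - 1.0)
    return width_px * scale


def _smoothed_path_length(path: np.ndarray, window: int = 3) -> float:
    """Arc length of a pixel-chain path after light smoothing.

    Moving-average smoothing removes digitization staircase overshoot so a
    straight chain measures close to its Euclidean length while curved
    chains keep their geodesic length.
    """
    pts = np.asarray(path, dtype=float)
    if len(pts) < 2:
        return 0.0
    if len(pts) > window:
        kernel = np.ones(window) / window
        sm = np.column_stack(
            [np.convolve(np.pad(c, window // 2, mode="edge"), kernel, mode="valid")
             for c in pts.T]
        )
        # pin the endpoints so smoothing does not shorten the path ends
        sm[0], sm[-1] = pts[0], pts[-1]
        pts = sm
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def _halfmax_interface_length(
    path: np.ndarray,
    intensity: np.ndarray,
    rod_thr: float,
    tube_thr: float,
    bg: float,
    extend_px: float = 5.0,
    step: float = 0.25,
) -> float | None:
    """Sub-pixel attachment length between anchor half-max crossings.

    The route (bacterium end first) is extended straight into both
    anchors, the intensity is sampled along it, and the length runs from
    where the signal falls below the bacterial half-max to where it rises
    above the hyphal half-max.  Because the filament's own plateau adds
    to the anchor's edge profile at the junction, each crossing level is
    raised by the filament excess estimated mid-path; the crossing then
    sits where the anchor's own contribution passes half its contrast.
    Returns None when either crossing cannot be localized.
    """
    pts = np.asarray(path, dtype=float)
    if len(pts) < 2:
        return None
    if len(pts) > 3:
        kernel = np.ones(3) / 3.0
        sm = np.column_stack(
            [np.convolve(np.pad(c, 1, mode="edge"), kernel, mode="valid")
             for c in pts.T]
        )
        sm[0], sm[-1] = pts[0], pts[-1]
        pts = sm
    k = min(3, len(pts) - 1)
    d0 = pts[0] - pts[k]
    d1 = pts[-1] - pts[-1 - k]
    n0, n1 = np.linalg.norm(d0), np.linalg.norm(d1)
    if n0 == 0 or n1 == 0:
        return None
    d0, d1 = d0 / n0, d1 / n1
    ext = np.arange(step, extend_px + step, step)
    head = pts[0] + np.outer(ext[::-1], d0)     # deepest-in-rod first
    tail = pts[-1] + np.outer(ext, d1)
    verts = np.vstack([head, pts, tail])
    seg = np.linalg.norm(np.diff(verts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    f = ndimage.map_coordinates(intensity, verts.T, order=1, mode="nearest")

    # filament plateau excess over background, estimated mid-path
    n_head = len(ext)
    core = f[n_head : n_head + len(pts)]
    third = max(len(core) // 3, 1)
    plateau = float(np.median(core[third : len(core) - third])) if len(core) > 2 else float(np.median(core))
    excess = max(plateau - bg, 0.0)
    # at the anchor boundary only the outward half of the filament band
    # contributes, so the level shift is half the mid-path excess
    rod_thr = rod_thr + 0.5 * excess
    tube_thr = tube_thr + 0.5 * excess

    def _cross(idx_order, thr):
        # scanning starts deep inside the anchor plateau, so the first
        # drop below the level is the boundary; later dips or bumps from
        # other structures in the gap are irrelevant
        idx = list(idx_order)
        if not idx or f[idx[0]] < thr:
            return None  # never inside the anchor plateau
        for j in range(1, len(idx)):
            a, b = f[idx[j - 1]], f[idx[j]]
            if a >= thr > b:
                t = (thr - a) / (b - a)
                return s[idx[j - 1]] + t * (s[idx[j]] - s[idx[j - 1]])
        return None

    s0 = _cross(range(len(f)), rod_thr)
    s1 = _cross(range(len(f) - 1, -1, -1), tube_thr)
    if s0 is None or s1 is None or s1 <= s0:
        return None
    return float(s1 - s0)


def measure_attachments(
    eps_mask: np.ndarray,
    bacteria_mask: np.ndarray,
    hyphae_mask: np.ndarray,
    scale: float,
    max_length_um: float = 2.0,
    response: np.ndarray | None = None,
    intensity: np.ndarray | None = None,
) -> list[Attachment]:
    """Lengths (um) of EPS attachment structures bridging bacteria to hyphae.

    For every EPS connected component whose 1-px dilation touches both a
    bacterium and a hypha, and for every bacterium it touches, the length
    is the geodesic path along the component from that bacterium's
    adjacency pixels to the nearest hypha-adjacent pixel, plus one pixel
    for the two half-pixel interfaces at the anchoring boundaries.
    Components touching only bacteria or only hyphae contribute nothing.

    Measuring per (component, bacterium) pair rather than once per
    component keeps each bacterium's anchoring structure individually
    measurable even when EPS strands merge into larger networks; the
    search is windowed to *max_length_um* around each bacterium, so an
    anchoring structure longer than that is not reported.

    When a ridge *response* map is given, the route is found on costs
    inversely weighted by the response so that it follows the filament's
    intensity crest instead of cutting through faint blur glow between
    nearby structures.  When an *intensity* image is also given, the
    anchoring interfaces are localized at sub-pixel precision: the route
    is extended into both anchors, the intensity is sampled along it, and
    the length runs between the half-maximum crossings of the bacterial
    and hyphal plateaus; otherwise the pixel-chain length plus a one-pixel
    interface allowance is reported.
    """
    eps_mask = np.asarray(eps_mask, dtype=bool)
    bacteria_mask = np.asarray(bacteria_mask, dtype=bool)
    hyphae_mask = np.asarray(hyphae_mask, dtype=bool)
    if not (eps_mask.shape == bacteria_mask.shape == hyphae_mask.shape):
        raise ValueError("masks must share one shape")
    if (eps_mask & bacteria_mask).any() or (eps_mask & hyphae_mask).any() or (
        bacteria_mask & hyphae_mask
    ).any():
        raise ValueError("masks must be pairwise disjoint")

    eps_labels, n_eps = ndimage.label(eps_mask, structure=_EIGHT)
    if n_eps == 0:
        return []
    bact_labels, n_bact = ndimage.label(bacteria_mask, structure=_EIGHT)
    if n_bact == 0 or not hyphae_mask.any():
        return []
    bact_adj = ndimage.grey_dilation(bact_labels, footprint=_EIGHT)
    bact_adj[bacteria_mask] = 0  # adjacency ring only
    hyph_adj = ndimage.binary_dilation(hyphae_mask, structure=_EIGHT) & ~hyphae_mask

    reach = int(np.ceil(max_length_um / scale)) + 2
    shape = eps_mask.shape
    levels: tuple[float, float, float] | None = None
    nearest_hyph = None
    if intensity is not None and hyphae_mask.any():
        # nearest hyphal pixel lookup, for the measurement chord of
        # corridors whose own chain direction is too quantized
        _, nearest_hyph = ndimage.distance_transform_edt(
            ~hyphae_mask, return_indices=True
        )
    if intensity is not None:
        intensity = np.asarray(intensity, dtype=float)
        outside = ~(eps_mask | bacteria_mask | hyphae_mask)
        bg = float(np.median(intensity[outside])) if outside.any() else 0.0
        lvl_b = float(np.median(intensity[bacteria_mask]))
        lvl_h = float(np.median(intensity[hyphae_mask]))
        levels = (0.5 * (lvl_b + bg), 0.5 * (lvl_h + bg), bg)
    if response is not None:
        response = np.asarray(response, dtype=float)
        floor = 0.05 * np.median(response[eps_mask]) if eps_mask.any() else 0.0
        ridge_cost = 1.0 / (response + max(float(floor), 1e-12)) ** 2
    out: list[Attachment] = []
    for bid, bact_sl in enumerate(ndimage.find_objects(bact_labels), start=1):
        if bact_sl is None:
            continue
        sl = tuple(
            slice(max(s.start - reach, 0), min(s.stop + reach, dim))
            for s, dim in zip(bact_sl, shape)
        )
        ring = (bact_adj[sl] == bid) & (eps_labels[sl] > 0)
        if not ring.any():
            continue
        # one geodesic search per EPS component anchored to this bacterium
        for comp_id in np.unique(eps_labels[sl][ring]):
            comp = eps_labels[sl] == comp_id
            ends = comp & hyph_adj[sl]
            if not ends.any():
                continue
            starts = np.argwhere(ring & comp)
            end_coords = np.argwhere(ends)
            if response is None:
                costs = np.where(comp, 1.0, np.inf)
            else:
                costs = np.where(comp, ridge_cost[sl], np.inf)
            mcp = skgraph.MCP_Geometric(costs)
            cum, _ = mcp.find_costs(starts=starts, ends=end_coords)
            end_costs = cum[ends]
            if not np.isfinite(end_costs).any():
                continue
            best = end_coords[int(np.argmin(end_costs))]
            path = np.asarray(mcp.traceback(tuple(best)), dtype=float)
            offset = np.array([s.start for s in sl])
            path_global = path + offset
            length_px = None
            subpixel = False
            if levels is not None:
                meas_path = path_global
                # a near-straight structure is best measured along its
                # chord toward the hypha: the raster chain's zigzag both
                # inflates arclength and destabilizes the end directions
                if nearest_hyph is not None:
                    p0 = path_global[0]
                    pe = path_global[-1]
                    # anchor point on the hypha: nearest hyphal pixel to the
                    # route's tube-side end, so the chord spans the full gap
                    # toward the structure's own anchor
                    q = np.array([nearest_hyph[0][int(pe[0]), int(pe[1])],
                                  nearest_hyph[1][int(pe[0]), int(pe[1])]], dtype=float)
                    chord = float(np.linalg.norm(q - p0))
                    chain = _smoothed_path_length(path_global)
                    if chord >= 1.0 and (len(path_global) < 6 or chord >= 0.75 * chain):
                        n_samp = max(int(np.ceil(chord * 2)), 8)
                        t_par = np.linspace(0.0, 1.0, n_samp + 1)[:, None]
                        meas_path = p0 + t_par * (q - p0)
                length_px = _halfmax_interface_length(
                    meas_path, intensity, levels[0], levels[1], levels[2]
                )
                subpixel = length_px is not None
            if length_px is None:
                length_px = _smoothed_path_length(path) + 1.0
            if length_px * scale > max_length_um:
                continue
            strength = 0.0
            if response is not None:
                rr, cc = path_global.astype(int).T
                strength = float(np.median(response[rr, cc]))
            out.append(
                Attachment(
                    label=int(comp_id),
                    length_um=length_px * scale,
                    path=path_global,
                    bacterium_label=int(bid),
                    ridge_strength=strength,
                    subpixel=subpixel,
                )
            )
    return out


def exclusion_filter(
    measures: list[ObjectMeasure],
    image_shape: tuple[int, int] | None = None,
    solidity_min: float = 0.8,
) -> list[ObjectMeasure]:
    """Flag partially visible and deformed objects.

    Border-touching objects are excluded with reason ``"partial"``
    (occlusion cannot be detected automatically and is approximated by the
    border rule); bacteria with solidity below *solidity_min* are excluded
    with reason ``"deformed"``.  Hyphae routinely span the whole field, and
    their transverse width stays measurable when they do, so a hypha is
    only "partial" when little more than a stub is visible (length under
    twice its width).  Flagged objects stay in the output but are omitted
    from summaries.
    """
    out = []
    for m in measures:
        if m.cls == "hypha":
            partial = m.length_um < 2.0 * m.width_um
        else:
            partial = m.touches_border
        if partial:
            out.append(replace(m, excluded=True, reason="partial"))
        elif m.cls == "bacterium" and m.solidity < solidity_min:
            out.append(replace(m, excluded=True, reason="deformed"))
        else:
            out.append(replace(m, excluded=False, reason=""))
    return out


def _metric_records(items) -> list[tuple[str, str, float]]:
    """Flatten measures/area reports to (sample_id, metric, value) records."""
    records: list[tuple[str, str, float]] = []
    for item in items:
        if isinstance(item, ObjectMeasure):
            if item.excluded:
                continue
            records.append((item.sample_id, f"{item.cls}_length_um", item.length_um))
            records.append((item.sample_id, f"{item.cls}_width_um", item.width_um))
        elif isinstance(item, AreaReport):
            records.append(("", "biofilm_area_um2", item.A_v))
            records.append(("", "coverage_pct", item.P_v))
        elif isinstance(item, tuple) and len(item) == 3:
            records.append((str(item[0]), str(item[1]), float(item[2])))
        else:
            raise TypeError(f"cannot summarize {type(item).__name__}")
    return records


def summarize(items, ddof: int = 0) -> tuple[list[SampleSummary], SampleSummary]:
    """Per-sample and pooled mean +- SD per metric.

    Accepts ObjectMeasure lists (sample id and metric names are derived
    from the object class; excluded objects are ignored), AreaReport
    lists, or raw ``(sample_id, metric, value)`` tuples.  The SD is the
    population SD (ddof=0) by default and is reported as 0 when n = 1;
    a metric with zero usable values is flagged with n = 0 and NaN mean.
    """
    records = _metric_records(items)
    samples = sorted({sid for sid, _, _ in records})
    metrics = sorted({met for _, met, _ in records})

    def _stat(values: list[float]) -> MetricStat:
        n = len(values)
        if n == 0:
            return MetricStat(mean=float("nan"), sd=float("nan"), n=0)
        arr = np.asarray(values, dtype=float)
        sd = 0.0 if n <= max(1, ddof) else float(arr.std(ddof=ddof))
        return MetricStat(mean=float(arr.mean()), sd=sd, n=n)

    per_sample = []
    for sid in samples:
        summary = SampleSummary(sample_id=sid)
        for met in metrics:
            vals = [v for s, m, v in records if s == sid and m == met]
            if vals:
                summary.metrics[met] = _stat(vals)
        per_sample.append(summary)
    pooled = SampleSummary(sample_id="pooled")
    for met in metrics:
        pooled.metrics[met] = _stat([v for _, m, v in records if m == met])
    return per_sample, pooled
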