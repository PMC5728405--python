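"""Image analysis: nuclear segmentation, ring masks, N/C ratios, foci, reporters.

The measurement geometry mirrors a widely used high-content convention for
nuclear/cytoplasmic partitioning of a fluorescent signal: nuclei are
segmented from the DAPI channel; the nuclear measurement region is the
nucleus eroded by ``erosion_px`` (default 2, Chebyshev / 3x3-square
structuring element, so a 2-px shell is subtracted from the mask
perimeter); the cytoplasmic region is a ring of ``ring_width_px`` (default
30) starting ``ring_gap_px`` (default 2) outside the nucleus boundary.
Ring pixels exclude every nucleus and, where rings of neighbouring cells
would overlap, each pixel is assigned to the nearest nucleus (Euclidean
distance to the nucleus pixel set; ties go to the lowest label).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk, white_tophat
from skimage.segmentation import watershed

from .exceptions import EmptyResultError, ParameterError

__all__ = [
    "RegionPair",
    "segment_nuclei",
    "build_region_pairs",
    "measure_nc_ratio",
    "score_foci",
    "reporter_ratio",
    "mean_nuclear_signal",
]

_CHEBYSHEV = np.ones((3, 3), dtype=bool)


@dataclass
class RegionPair:
    """Measurement regions for one nucleus: eroded core and cytoplasmic ring."""

    label: int
    nuclear: np.ndarray  # boolean mask, full image shape
    ring: np.ndarray  # boolean mask, full image shape
    eroded_away: bool = False  # nucleus vanished under erosion
    border: bool = False  # ideal ring band would leave the image
    meta: dict = field(default_factory=dict)


def _check_2d(image: np.ndarray, name: str = "image") -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2:
        raise ParameterError(f"{name} must be 2-D, got shape {image.shape}")
    return image


def segment_nuclei(
    dapi: np.ndarray,
    min_area_px: int = 50,
    split_touching: bool = False,
    smoothing_sigma: float = 1.0,
) -> np.ndarray:
    """Label nuclei in a DAPI channel.

    Gaussian smoothing, global Otsu threshold, hole filling, minimum-area
    filter, and (optionally) a distance-transform watershed to split
    touching nuclei.  Returns an int32 label image with contiguous labels
    1..K (0 = background); an all-background image yields all zeros.
    """
    dapi = _check_2d(dapi, "dapi")
    if min_area_px < 1:
        raise ParameterError("min_area_px must be >= 1")
    smoothed = gaussian(dapi.astype(float), sigma=smoothing_sigma, preserve_range=True)
    if smoothed.max() == smoothed.min():
        return np.zeros(dapi.shape, dtype=np.int32)
    binary = smoothed > threshold_otsu(smoothed)
    binary = ndimage.binary_fill_holes(binary)

    if split_touching:
        dist = ndimage.distance_transform_edt(binary)
        # seed one marker per local distance maximum (suppress plateaus/noise
        # with a smoothed distance map)
        dist_s = ndimage.gaussian_filter(dist, sigma=2.0)
        maxima = (dist_s == ndimage.maximum_filter(dist_s, size=9)) & binary & (dist_s > 1)
        markers = cc_label(maxima)
        labels = watershed(-dist_s, markers=markers, mask=binary).astype(np.int32)
    else:
        labels = cc_label(binary).astype(np.int32)

    # drop components under the area floor, then relabel contiguously
    counts = np.bincount(labels.ravel())
    too_small = np.flatnonzero(counts < min_area_px)
    labels[np.isin(labels, too_small)] = 0
    keep = np.unique(labels)
    keep = keep[keep > 0]
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    return remap[labels]


def _padded_bbox(
    mask: np.ndarray, pad: int, shape: tuple[int, int]
) -> tuple[slice, slice]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = max(0, rows[0] - pad), min(shape[0], rows[-1] + pad + 1)
    c0, c1 = max(0, cols[0] - pad), min(shape[1], cols[-1] + pad + 1)
    return slice(r0, r1), slice(c0, c1)


def build_region_pairs(
    mask: np.ndarray,
    erosion_px: int = 2,
    ring_gap_px: int = 2,
    ring_width_px: int = 30,
) -> list[RegionPair]:
    """Eroded nuclear mask + cytoplasmic ring for every label in ``mask``.

    The nuclear region is the nucleus eroded ``erosion_px`` times with the
    3x3 square (Chebyshev) element.  The ring is the set of non-nuclear
    pixels whose Euclidean distance to the nucleus pixel set lies in
    ``(ring_gap_px, ring_gap_px + ring_width_px]`` and for which this
    nucleus is the nearest one (ties to the lowest label).  Nuclei that
    vanish under erosion are returned flagged (``eroded_away``) and should
    be excluded from measurement; nuclei whose ideal ring band would leave
    the image are flagged ``border``.
    """
    mask = _check_2d(mask, "mask").astype(np.int32)
    if erosion_px < 0 or ring_gap_px < 0 or ring_width_px < 0:
        raise ParameterError("erosion/gap/width must be >= 0")
    labels = np.unique(mask)
    labels = labels[labels > 0]
    shape = mask.shape
    any_nucleus = mask > 0
    band_outer = ring_gap_px + ring_width_px
    pad = max(erosion_px, band_outer) + 1

    # global nearest-nucleus assignment with a deterministic lowest-label
    # tie-break: per-label distances are compared within each label's band
    best_dist = np.full(shape, np.inf)
    best_label = np.zeros(shape, dtype=np.int32)
    per_label: dict[int, dict] = {}

    for k in labels:
        nucleus = mask == k
        sl = _padded_bbox(nucleus, pad, shape)
        crop = nucleus[sl]
        eroded = (
            ndimage.binary_erosion(crop, structure=_CHEBYSHEV, iterations=erosion_px, border_value=0)
            if erosion_px > 0
            else crop
        )
        dist = ndimage.distance_transform_edt(~crop)
        band = (dist > ring_gap_px) & (dist <= band_outer)
        per_label[int(k)] = {"slice": sl, "eroded": eroded, "band": band, "dist": dist}

        if ring_width_px > 0:
            # assignment competes over the whole neighbourhood (including the
            # gap zone), so a pixel hugging nucleus j is never claimed by a
            # farther nucleus k's ring
            near = (dist > 0) & (dist <= band_outer)
            gd = best_dist[sl]
            gl = best_label[sl]
            better = near & (
                (dist < gd) | ((dist == gd) & ((gl == 0) | (k < gl)))
            )
            gd[better] = dist[better]
            gl[better] = k
            best_dist[sl] = gd
            best_label[sl] = gl

        # border flag: would the ideal band leave the image?
        rows = np.flatnonzero(nucleus.any(axis=1))
        cols = np.flatnonzero(nucleus.any(axis=0))
        per_label[int(k)]["border"] = (
            rows[0] - band_outer < 0
            or rows[-1] + band_outer >= shape[0]
            or cols[0] - band_outer < 0
            or cols[-1] + band_outer >= shape[1]
        )

    pairs: list[RegionPair] = []
    for k in labels:
        k = int(k)
        info = per_label[k]
        sl = info["slice"]
        nuclear = np.zeros(shape, dtype=bool)
        nuclear[sl] = info["eroded"]
        ring = np.zeros(shape, dtype=bool)
        if ring_width_px > 0:
            ring[sl] = info["band"] & (best_label[sl] == k) & ~any_nucleus[sl]
        pairs.append(
            RegionPair(
                label=k,
                nuclear=nuclear,
                ring=ring,
                eroded_away=not nuclear.any(),
                border=bool(info["border"]),
            )
        )
    return pairs


def measure_nc_ratio(
    signal: np.ndarray,
    regions: list[RegionPair],
    exclude_border: bool = True,
) -> pd.DataFrame:
    """Per-cell nuclear mean, cytoplasmic-ring mean and their ratio.

    Cells with an empty ring or a non-positive ring mean are flagged
    (``qc_empty_ring`` / ``qc_zero_denominator``) and get ``nc_ratio`` NaN;
    border-touching cells are flagged and, by default, marked excluded.
    The ``included`` column marks cells that enter condition summaries.
    """
    signal = _check_2d(signal, "signal")
    rows = []
    for rp in regions:
        if signal.shape != rp.nuclear.shape:
            raise ParameterError("signal image shape does not match mask shape")
        nuc_n = int(rp.nuclear.sum())
        ring_n = int(rp.ring.sum())
        nuclear_mean = float(signal[rp.nuclear].mean()) if nuc_n else np.nan
        cyto_mean = float(signal[rp.ring].mean()) if ring_n else np.nan
        empty_ring = ring_n == 0
        zero_den = (not empty_ring) and not (cyto_mean > 0)
        ratio = (
            nuclear_mean / cyto_mean
            if nuc_n and not empty_ring and cyto_mean > 0
            else np.nan
        )
        excluded = rp.eroded_away or empty_ring or zero_den or (exclude_border and rp.border)
        rows.append(
            {
                "label": rp.label,
                "nuclear_mean": nuclear_mean,
                "cyto_mean": cyto_mean,
                "nc_ratio": ratio,
                "nuclear_area_px": nuc_n,
                "ring_area_px": ring_n,
                "qc_border": rp.border,
                "qc_empty_ring": empty_ring,
                "qc_zero_denominator": zero_den,
                "qc_eroded_away": rp.eroded_away,
                "included": not excluded,
            }
        )
    return pd.DataFrame(rows)


def score_foci(
    foci: np.ndarray,
    mask: np.ndarray,
    min_foci: int = 5,
    focus_radius_px: int = 2,
    mad_k: float = 5.0,
    min_spot_area_px: int = 2,
) -> tuple[pd.DataFrame, float]:
    """Count repair foci per nucleus and the fraction of nuclei at/over threshold.

    Spots are isolated with a white top-hat (disk footprint of twice the
    expected focus radius), thresholded per nucleus at median + ``mad_k`` x
    MAD of the top-hat values inside the nucleus interior (the nucleus
    eroded by the top-hat radius, so mask-edge artefacts of the opening are
    ignored), and counted as connected components of at least
    ``min_spot_area_px`` pixels.  Returns the per-nucleus table and the
    fraction of nuclei with count >= ``min_foci`` (inclusive, the figure
    convention for scoring gamma-H2AX/53BP1-positive cells).
    """
    foci = _check_2d(foci, "foci")
    mask = _check_2d(mask, "mask").astype(np.int32)
    if foci.shape != mask.shape:
        raise ParameterError("foci channel shape does not match mask shape")
    if min_foci < 1:
        raise ParameterError("min_foci must be >= 1")

    tophat_radius = 2 * focus_radius_px
    enhanced = white_tophat(foci.astype(float), footprint=disk(tophat_radius))

    labels = np.unique(mask)
    labels = labels[labels > 0]
    rows = []
    for k in labels:
        nucleus = mask == k
        interior = ndimage.binary_erosion(
            nucleus, structure=disk(tophat_radius).astype(bool), border_value=0
        )
        region = interior if interior.any() else nucleus
        vals = enhanced[region]
        med = float(np.median(vals))
        mad = float(np.median(np.abs(vals - med)))
        thr = med + mad_k * mad
        spots = region & (enhanced > thr)
        comp, n_comp = ndimage.label(spots)
        if n_comp and min_spot_area_px > 1:
            areas = np.bincount(comp.ravel())[1:]
            n_comp = int((areas >= min_spot_area_px).sum())
        rows.append({"label": int(k), "foci_count": int(n_comp)})
    table = pd.DataFrame(rows, columns=["label", "foci_count"])
    fraction = float((table["foci_count"] >= min_foci).mean()) if len(table) else 0.0
    return table, fraction


def reporter_ratio(
    numerator: np.ndarray,
    denominator: np.ndarray,
    mask: np.ndarray,
    min_denominator: float = 0.0,
) -> tuple[pd.DataFrame, float]:
    """Per-cell ratio of channel means, excluding untransfected cells.

    Cells whose denominator mean falls below ``min_denominator`` are dropped
    from the output (they carry no reporter).  Returns the per-cell table
    and the mean ratio over retained cells.
    """
    numerator = _check_2d(numerator, "numerator")
    denominator = _check_2d(denominator, "denominator")
    mask = _check_2d(mask, "mask").astype(np.int32)
    if numerator.shape != mask.shape or denominator.shape != mask.shape:
        raise ParameterError("channel shapes must match the mask")
    labels = np.unique(mask)
    labels = labels[labels > 0]
    rows = []
    for k in labels:
        cell = mask == k
        den = float(denominator[cell].mean())
        num = float(numerator[cell].mean())
        if den < min_denominator:
            continue
        rows.append(
            {
                "label": int(k),
                "numerator_mean": num,
                "denominator_mean": den,
                "reporter_ratio": num / den if den > 0 else np.nan,
            }
        )
    if not rows:
        raise EmptyResultError("every cell was excluded by the denominator threshold")
    table = pd.DataFrame(rows)
    return table, float(table["reporter_ratio"].mean())


def mean_nuclear_signal(signal: np.ndarray, mask: np.ndarray) -> tuple[float, float, pd.DataFrame]:
    """Condition mean +/- SEM of per-nucleus mean intensities.

    Returns (mean, sem, per-cell table); SEM is NaN for a single nucleus.
    """
    signal = _check_2d(signal, "signal")
    mask = _check_2d(mask, "mask").astype(np.int32)
    if signal.shape != mask.shape:
        raise ParameterError("signal image shape does not match mask shape")
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise EmptyResultError("no nuclei in mask")
    means = np.array([float(signal[mask == k].mean()) for k in labels])
    table = pd.DataFrame({"label": labels.astype(int), "nuclear_mean": means})
    mean = float(means.mean())
    sem = float(means.std(ddof=1) / np.sqrt(means.size)) if means.size > 1 else float("nan")
    return mean, sem, table
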