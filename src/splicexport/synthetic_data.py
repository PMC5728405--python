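"""Synthetic ground-truth data generators for every pipeline input.

Each generator renders an input the quantification stages consume (FISH
images, repair-foci images, two-channel reporter images, replicate
expression tables, 3'-UTR sequence sets, qPCR Cq tables) together with a
ground-truth record of the planted parameters, so every downstream
measurement can be checked against a known answer.

Conventions shared by the image generators:

* nuclei are filled ellipses with per-cell jittered radii; the DAPI
  channel carries Gaussian-smoothed edges (as stained chromatin does),
  while quantified signal channels use hard-edged region values so that
  mean intensities over the ground-truth masks reproduce the planted
  parameters exactly at zero noise;
* noise is additive Gaussian on a constant background (shot noise is
  deliberately not modelled);
* identical spec + seed gives bit-identical output.

Pixel coordinates are 0-based ``(row, col)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import ndimage

from .exceptions import ParameterError, PlacementError, SchemaError

__all__ = [
    "ImageFrame",
    "FishImageSpec",
    "FociImageSpec",
    "ReporterImageSpec",
    "ExpressionSpec",
    "UtrSpec",
    "CqSpec",
    "FishGroundTruth",
    "FociGroundTruth",
    "ReporterGroundTruth",
    "ExpressionGroundTruth",
    "UtrGroundTruth",
    "CqGroundTruth",
    "NO_AMPLIFICATION",
    "generate_fish_image",
    "generate_foci_image",
    "generate_reporter_image",
    "generate_expression_table",
    "generate_utr_set",
    "generate_cq_table",
]

#: Sentinel Cq for wells with no amplification (RT-minus controls).
NO_AMPLIFICATION = float("nan")

DEFAULT_CONDITIONS = ("siCtrl", "siTHRAP3", "siBCLAF1", "siTHRAP3+siBCLAF1")


@dataclass
class ImageFrame:
    """One field of view: named single-channel images sharing a pixel grid."""

    channels: dict[str, np.ndarray]

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.channels.values()))
        return first.shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class FishImageSpec:
    """Geometry and intensity model for a synthetic RNA-FISH field.

    ``true_nc_ratio`` is the planted per-cell ratio of mean nuclear to mean
    cytoplasmic signal; at ``noise_sd = 0`` the rendered signal channel
    reproduces it exactly over the ground-truth masks.
    """

    image_shape: tuple[int, int] = (768, 768)
    n_cells: int = 50
    nucleus_radius_px: float = 15.0
    radius_jitter: float = 0.2
    true_nc_ratio: float = 2.0
    cytoplasm_extent_px: float = 40.0
    cyto_level: float = 400.0
    dapi_level: float = 3000.0
    background_level: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 0:
            raise ParameterError("n_cells must be >= 0")
        if self.nucleus_radius_px <= 0:
            raise ParameterError("nucleus_radius_px must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.true_nc_ratio < 0:
            raise ParameterError("true_nc_ratio must be >= 0")
        if not (0 <= self.radius_jitter < 1):
            raise ParameterError("radius_jitter must be in [0, 1)")


@dataclass
class FociImageSpec:
    """Synthetic repair-foci field: per-nucleus planted focus counts.

    The number of nuclei equals ``len(foci_counts)``.  Foci are rendered as
    disjoint hard disks of ``focus_radius_px`` at ``focus_amplitude`` above
    the pan-nuclear base level, kept well inside the nucleus so detection
    margins never clip them.
    """

    foci_counts: Sequence[int] = (0, 3, 5, 8)
    image_shape: tuple[int, int] = (512, 512)
    nucleus_radius_px: float = 20.0
    radius_jitter: float = 0.1
    focus_radius_px: int = 2
    focus_amplitude: float = 2000.0
    nuclear_level: float = 300.0
    dapi_level: float = 3000.0
    background_level: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if any(c < 0 for c in self.foci_counts):
            raise ParameterError("planted focus counts must be >= 0")
        if self.focus_radius_px < 1:
            raise ParameterError("focus_radius_px must be >= 1")
        if self.nucleus_radius_px <= 0:
            raise ParameterError("nucleus_radius_px must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


@dataclass
class ReporterImageSpec:
    """Two-channel splicing-reporter field with planted per-cell ratios.

    Cells are rendered as whole-cell disks; the denominator channel (RFP)
    carries ``denominator_level`` inside each cell, the numerator channel
    (GFP) carries ``denominator_level * ratio`` for that cell's planted
    ratio.
    """

    true_ratios: Sequence[float] = (0.3, 1.0, 2.0)
    image_shape: tuple[int, int] = (512, 512)
    cell_radius_px: float = 18.0
    radius_jitter: float = 0.1
    denominator_level: float = 500.0
    background_level: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if any(r < 0 for r in self.true_ratios):
            raise ParameterError("true ratios must be >= 0")
        if self.cell_radius_px <= 0:
            raise ParameterError("cell_radius_px must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


@dataclass
class ExpressionSpec:
    """Replicate expression matrices with planted cytoplasmic down-regulation.

    ``planted_down`` maps a condition label to ``{gene_index: fold_change}``;
    planted genes are multiplied by their fold-change (< 1 for
    down-regulation) in the cytoplasmic fraction of that condition only.
    Replicate noise is log-normal with ``noise_sd_log2`` standard deviation
    on the log2 scale.
    """

    n_genes: int = 5000
    n_replicates: int = 3
    conditions: Sequence[str] = DEFAULT_CONDITIONS
    control: str = "siCtrl"
    planted_down: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    noise_sd_log2: float = 0.05
    base_log2_mean: float = 7.0
    base_log2_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_replicates < 2:
            raise SchemaError("need >= 2 replicates per condition for downstream t-tests")
        if self.control not in self.conditions:
            raise SchemaError(f"control condition {self.control!r} not in conditions")
        for cond, planted in self.planted_down.items():
            if cond not in self.conditions:
                raise SchemaError(f"planted condition {cond!r} not in conditions")
            for idx, fc in planted.items():
                if not (0 <= idx < self.n_genes):
                    raise SchemaError(f"planted gene index {idx} outside universe")
                if fc <= 0:
                    raise ParameterError("fold-changes must be > 0")
        if self.noise_sd_log2 < 0:
            raise ParameterError("noise sd must be >= 0")


@dataclass
class UtrSpec:
    """3'-UTR sequence set with a consensus motif planted in a known fraction."""

    n_sequences: int = 200
    length: int = 300
    background_probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25)
    planted_motif: str = "GGAGGCTGGGGC"
    planted_fraction: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.planted_fraction <= 1):
            raise ParameterError("planted_fraction must be in [0, 1]")
        if set(self.planted_motif) - set("ACGT"):
            raise ParameterError("planted motif must contain only A/C/G/T")
        if len(self.planted_motif) > self.length:
            raise ParameterError("motif longer than sequence length")
        probs = np.asarray(self.background_probs, dtype=float)
        if probs.shape != (4,) or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise ParameterError("background_probs must be 4 values summing to 1")


@dataclass
class CqSpec:
    """qPCR run layout: per-primer efficiencies, true concentrations, standards.

    ``true_concentrations`` rows carry (primer, sample, condition,
    compartment, concentration).  Cq values follow the log-linear standard
    curve  Cq = intercept - log10(conc) / log10(efficiency)  plus Gaussian
    cycle noise.  Each primer's in-run standard series and one RT-minus well
    are emitted alongside the unknowns.
    """

    efficiencies: Mapping[str, float] = field(default_factory=lambda: {"ACTB": 2.0})
    true_concentrations: Sequence[Mapping] = field(default_factory=list)
    standard_dilutions: Sequence[float] = (1.0, 0.1, 0.01, 0.001, 1e-4)
    intercept: float = 25.0
    n_technical_reps: int = 1
    cq_noise_sd: float = 0.0
    contaminated_primers: Sequence[str] = ()
    contamination_cq: float = 35.0
    seed: int = 0

    def validate(self) -> None:
        for primer, eff in self.efficiencies.items():
            if not (1.0 < eff <= 2.0):
                raise ParameterError(f"efficiency of {primer!r} must be in (1, 2]")
        for row in self.true_concentrations:
            if row["primer"] not in self.efficiencies:
                raise SchemaError(f"unknown primer {row['primer']!r}")
            if row["concentration"] <= 0:
                raise ParameterError("concentrations must be > 0")
        if any(d <= 0 for d in self.standard_dilutions):
            raise ParameterError("standard dilutions must be > 0")
        if self.cq_noise_sd < 0:
            raise ParameterError("cq_noise_sd must be >= 0")
        for primer in self.contaminated_primers:
            if primer not in self.efficiencies:
                raise SchemaError(f"contaminated primer {primer!r} not in efficiencies")


# ---------------------------------------------------------------------------
# ground-truth records
# ---------------------------------------------------------------------------


@dataclass
class FishGroundTruth:
    nuclear_labels: np.ndarray
    cyto_labels: np.ndarray
    true_nc_ratios: dict[int, float]
    cells: pd.DataFrame  # label, row, col, semi_a, semi_b, theta, true_nc_ratio


@dataclass
class FociGroundTruth:
    nuclear_labels: np.ndarray
    foci_counts: dict[int, int]
    foci_centers: dict[int, list[tuple[int, int]]]
    cells: pd.DataFrame


@dataclass
class ReporterGroundTruth:
    cell_labels: np.ndarray
    true_ratios: dict[int, float]
    cells: pd.DataFrame


@dataclass
class ExpressionGroundTruth:
    planted_down: dict[str, dict[str, float]]  # condition -> gene id -> fold change
    gene_ids: list[str]


@dataclass
class UtrGroundTruth:
    motif: str
    planted_positions: dict[str, int]  # record id -> 0-based start of the planted copy


@dataclass
class CqGroundTruth:
    efficiencies: dict[str, float]
    intercept: float
    true_concentrations: pd.DataFrame
    contaminated_primers: list[str]


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _ellipse_pixels(
    shape: tuple[int, int], center: tuple[float, float], a: float, b: float, theta: float
) -> tuple[np.ndarray, np.ndarray]:
    """Integer pixel coordinates inside a rotated ellipse, clipped to the image."""
    cr, cc = center
    ext = int(math.ceil(max(a, b))) + 1
    r0, r1 = max(0, int(cr) - ext), min(shape[0], int(cr) + ext + 1)
    c0, c1 = max(0, int(cc) - ext), min(shape[1], int(cc) + ext + 1)
    rr, cc_grid = np.mgrid[r0:r1, c0:c1]
    dr = rr - cr
    dc = cc_grid - cc
    ct, st = math.cos(theta), math.sin(theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return rr[inside], cc_grid[inside]


def _place_centers(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n: int,
    margin: float,
    min_separation: float,
    max_tries_per_cell: int = 400,
) -> list[tuple[float, float]]:
    """Random sequential placement with a minimum pairwise center distance."""
    lo_r, hi_r = margin, shape[0] - margin
    lo_c, hi_c = margin, shape[1] - margin
    if n > 0 and (hi_r <= lo_r or hi_c <= lo_c):
        raise PlacementError("image too small for the requested geometry margins")
    centers: list[tuple[float, float]] = []
    for _ in range(n):
        for _try in range(max_tries_per_cell):
            r = rng.uniform(lo_r, hi_r)
            c = rng.uniform(lo_c, hi_c)
            if all((r - pr) ** 2 + (c - pc) ** 2 >= min_separation**2 for pr, pc in centers):
                centers.append((r, c))
                break
        else:
            raise PlacementError(
                f"could not place cell {len(centers) + 1}/{n} without overlap "
                f"after {max_tries_per_cell} tries"
            )
    return centers


def _render_nuclei(
    rng: np.random.Generator,
    shape: tuple[int, int],
    centers: Sequence[tuple[float, float]],
    radius: float,
    jitter: float,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Label image of jittered ellipses plus their parameter table."""
    labels = np.zeros(shape, dtype=np.int32)
    rows = []
    for k, (cr, cc) in enumerate(centers, start=1):
        a = radius * (1 + rng.uniform(-jitter, jitter))
        b = radius * (1 + rng.uniform(-jitter, jitter))
        theta = rng.uniform(0, math.pi)
        rr, cc_px = _ellipse_pixels(shape, (cr, cc), a, b, theta)
        labels[rr, cc_px] = k
        rows.append({"label": k, "row": cr, "col": cc, "semi_a": a, "semi_b": b, "theta": theta})
    return labels, pd.DataFrame(rows, columns=["label", "row", "col", "semi_a", "semi_b", "theta"])


def _smooth_dapi(
    nuclear_mask: np.ndarray, dapi_level: float, background: float, sigma: float = 1.0
) -> np.ndarray:
    dapi = np.full(nuclear_mask.shape, background, dtype=float)
    dapi += ndimage.gaussian_filter(nuclear_mask.astype(float), sigma) * (dapi_level - background)
    return dapi


def _add_noise(rng: np.random.Generator, image: np.ndarray, sd: float) -> np.ndarray:
    if sd == 0:
        return image
    return image + rng.normal(0.0, sd, size=image.shape)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_fish_image(spec: FishImageSpec) -> tuple[ImageFrame, FishGroundTruth]:
    """Render a DAPI + FISH-signal field with a known per-cell N/C ratio.

    The signal channel carries ``cyto_level * true_nc_ratio`` on nuclear
    pixels, ``cyto_level`` on the cytoplasmic annulus (within
    ``cytoplasm_extent_px`` of a nucleus) and ``background_level`` elsewhere,
    so at zero noise the mean over the ground-truth nuclear mask divided by
    the mean over the cytoplasmic mask equals ``true_nc_ratio`` exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_shape)
    r_max = spec.nucleus_radius_px * (1 + spec.radius_jitter)
    margin = r_max + spec.cytoplasm_extent_px + 2
    # nuclei must stay disjoint with a clear gap; annuli may overlap freely
    centers = _place_centers(rng, shape, spec.n_cells, margin, 2 * r_max + 6)
    nuclear_labels, cells = _render_nuclei(
        rng, shape, centers, spec.nucleus_radius_px, spec.radius_jitter
    )

    any_nucleus = nuclear_labels > 0
    cyto_labels = np.zeros(shape, dtype=np.int32)
    if spec.n_cells > 0:
        dist, (ir, ic) = ndimage.distance_transform_edt(~any_nucleus, return_indices=True)
        nearest = nuclear_labels[ir, ic]
        annulus = (dist > 0) & (dist <= spec.cytoplasm_extent_px)
        cyto_labels[annulus] = nearest[annulus]

    signal = np.full(shape, spec.background_level, dtype=float)
    signal[cyto_labels > 0] = spec.cyto_level
    signal[any_nucleus] = spec.cyto_level * spec.true_nc_ratio
    dapi = _smooth_dapi(any_nucleus, spec.dapi_level, spec.background_level)

    frame = ImageFrame(
        {
            "dapi": _add_noise(rng, dapi, spec.noise_sd),
            "signal": _add_noise(rng, signal, spec.noise_sd),
        }
    )
    cells = cells.assign(true_nc_ratio=spec.true_nc_ratio)
    truth = FishGroundTruth(
        nuclear_labels=nuclear_labels,
        cyto_labels=cyto_labels,
        true_nc_ratios={int(k): spec.true_nc_ratio for k in cells["label"]},
        cells=cells,
    )
    return frame, truth


def generate_foci_image(spec: FociImageSpec) -> tuple[ImageFrame, FociGroundTruth]:
    """Render a DAPI + foci field with exactly the planted spot count per nucleus."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_shape)
    n_cells = len(spec.foci_counts)
    r_max = spec.nucleus_radius_px * (1 + spec.radius_jitter)
    centers = _place_centers(rng, shape, n_cells, r_max + 4, 2 * r_max + 6)
    nuclear_labels, cells = _render_nuclei(
        rng, shape, centers, spec.nucleus_radius_px, spec.radius_jitter
    )
    any_nucleus = nuclear_labels > 0

    foci = np.full(shape, spec.background_level, dtype=float)
    foci[any_nucleus] = spec.nuclear_level

    # candidate focus centers sit deep inside the nucleus: clear of the
    # boundary by focus radius + top-hat detection margin
    inner_margin = spec.focus_radius_px + 5
    interior_dist = ndimage.distance_transform_edt(any_nucleus)
    min_sep = 2 * spec.focus_radius_px + 3

    foci_centers: dict[int, list[tuple[int, int]]] = {}
    for k, count in zip(cells["label"], spec.foci_counts):
        k = int(k)
        candidates = np.argwhere((nuclear_labels == k) & (interior_dist > inner_margin))
        placed: list[tuple[int, int]] = []
        tries = 0
        while len(placed) < count:
            tries += 1
            if tries > 400 * max(count, 1) or len(candidates) == 0:
                raise PlacementError(
                    f"cannot fit {count} disjoint foci inside nucleus {k}"
                )
            r, c = candidates[rng.integers(len(candidates))]
            if all((r - pr) ** 2 + (c - pc) ** 2 >= min_sep**2 for pr, pc in placed):
                placed.append((int(r), int(c)))
        foci_centers[k] = placed
        for r, c in placed:
            rr, cc = _ellipse_pixels(
                shape, (r, c), spec.focus_radius_px, spec.focus_radius_px, 0.0
            )
            foci[rr, cc] = spec.nuclear_level + spec.focus_amplitude

    dapi = _smooth_dapi(any_nucleus, spec.dapi_level, spec.background_level)
    frame = ImageFrame(
        {
            "dapi": _add_noise(rng, dapi, spec.noise_sd),
            "foci": _add_noise(rng, foci, spec.noise_sd),
        }
    )
    counts = {int(k): int(n) for k, n in zip(cells["label"], spec.foci_counts)}
    cells = cells.assign(foci_count=[counts[int(k)] for k in cells["label"]])
    return frame, FociGroundTruth(nuclear_labels, counts, foci_centers, cells)


def generate_reporter_image(spec: ReporterImageSpec) -> tuple[ImageFrame, ReporterGroundTruth]:
    """Render a two-channel reporter field with planted per-cell channel ratios."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_shape)
    n_cells = len(spec.true_ratios)
    r_max = spec.cell_radius_px * (1 + spec.radius_jitter)
    centers = _place_centers(rng, shape, n_cells, r_max + 4, 2 * r_max + 6)
    cell_labels, cells = _render_nuclei(
        rng, shape, centers, spec.cell_radius_px, spec.radius_jitter
    )

    denominator = np.full(shape, spec.background_level, dtype=float)
    numerator = np.full(shape, spec.background_level, dtype=float)
    ratios: dict[int, float] = {}
    for k, ratio in zip(cells["label"], spec.true_ratios):
        k = int(k)
        cell_px = cell_labels == k
        denominator[cell_px] = spec.denominator_level
        numerator[cell_px] = spec.denominator_level * ratio
        ratios[k] = float(ratio)

    frame = ImageFrame(
        {
            "numerator": _add_noise(rng, numerator, spec.noise_sd),
            "denominator": _add_noise(rng, denominator, spec.noise_sd),
        }
    )
    cells = cells.assign(true_ratio=[ratios[int(k)] for k in cells["label"]])
    return frame, ReporterGroundTruth(cell_labels, ratios, cells)


def generate_expression_table(
    spec: ExpressionSpec,
) -> tuple[pd.DataFrame, ExpressionGroundTruth]:
    """Tidy replicate expression table with planted cytoplasmic down-regulation.

    Returns a DataFrame with columns (gene, condition, replicate,
    compartment, value).  At ``noise_sd_log2 = 0`` the cytoplasmic
    condition/control mean ratio of a planted gene equals its fold-change
    exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    width = max(4, len(str(spec.n_genes)))
    gene_ids = [f"G{i:0{width}d}" for i in range(spec.n_genes)]
    base = 2.0 ** rng.normal(spec.base_log2_mean, spec.base_log2_sd, size=spec.n_genes)

    fold = {}  # (condition, compartment) -> per-gene multiplier vector
    for cond in spec.conditions:
        for compartment in ("nuclear", "cytoplasmic"):
            mult = np.ones(spec.n_genes)
            planted = spec.planted_down.get(cond, {})
            if compartment == "cytoplasmic":
                for idx, fc in planted.items():
                    mult[idx] = fc
            fold[(cond, compartment)] = mult

    frames = []
    for cond in spec.conditions:
        for compartment in ("nuclear", "cytoplasmic"):
            for rep in range(1, spec.n_replicates + 1):
                noise = (
                    2.0 ** rng.normal(0.0, spec.noise_sd_log2, size=spec.n_genes)
                    if spec.noise_sd_log2 > 0
                    else 1.0
                )
                values = base * fold[(cond, compartment)] * noise
                frames.append(
                    pd.DataFrame(
                        {
                            "gene": gene_ids,
                            "condition": cond,
                            "replicate": rep,
                            "compartment": compartment,
                            "value": values,
                        }
                    )
                )
    table = pd.concat(frames, ignore_index=True)
    truth = ExpressionGroundTruth(
        planted_down={
            cond: {gene_ids[i]: fc for i, fc in planted.items()}
            for cond, planted in spec.planted_down.items()
        },
        gene_ids=gene_ids,
    )
    return table, truth


def generate_utr_set(spec: UtrSpec) -> tuple[list[SeqRecord], UtrGroundTruth]:
    """Random 3'-UTR-like sequences, a known fraction carrying one motif copy."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    bases = np.array(list("ACGT"))
    probs = np.asarray(spec.background_probs, dtype=float)
    probs = probs / probs.sum()
    n_planted = int(round(spec.planted_fraction * spec.n_sequences))
    planted_idx = set(rng.choice(spec.n_sequences, size=n_planted, replace=False).tolist())

    k = len(spec.planted_motif)
    records: list[SeqRecord] = []
    positions: dict[str, int] = {}
    for i in range(spec.n_sequences):
        seq = rng.choice(bases, size=spec.length, p=probs)
        rec_id = f"utr_{i:04d}"
        if i in planted_idx:
            pos = int(rng.integers(0, spec.length - k + 1))
            seq[pos : pos + k] = list(spec.planted_motif)
            positions[rec_id] = pos
        records.append(SeqRecord(Seq("".join(seq)), id=rec_id, description=""))
    return records, UtrGroundTruth(motif=spec.planted_motif, planted_positions=positions)


def _cq_from_concentration(conc: float, efficiency: float, intercept: float) -> float:
    return intercept - math.log10(conc) / math.log10(efficiency)


def generate_cq_table(spec: CqSpec) -> tuple[pd.DataFrame, CqGroundTruth]:
    """Cq table with in-run standards and RT-minus wells per primer.

    Columns: primer, sample, condition, compartment, replicate, rt_flag,
    standard_conc (NaN for unknowns), cq.  RT-minus wells carry the
    no-amplification sentinel (NaN) unless the primer is planted as
    contaminated.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []

    def noise() -> float:
        return float(rng.normal(0.0, spec.cq_noise_sd)) if spec.cq_noise_sd > 0 else 0.0

    for primer, eff in spec.efficiencies.items():
        for j, dilution in enumerate(spec.standard_dilutions, start=1):
            for rep in range(1, spec.n_technical_reps + 1):
                rows.append(
                    {
                        "primer": primer,
                        "sample": f"std_{j}",
                        "condition": "standard",
                        "compartment": "standard",
                        "replicate": rep,
                        "rt_flag": "+",
                        "standard_conc": dilution,
                        "cq": _cq_from_concentration(dilution, eff, spec.intercept) + noise(),
                    }
                )
        rows.append(
            {
                "primer": primer,
                "sample": "RT_minus",
                "condition": "control",
                "compartment": "none",
                "replicate": 1,
                "rt_flag": "-",
                "standard_conc": np.nan,
                "cq": spec.contamination_cq + noise()
                if primer in set(spec.contaminated_primers)
                else NO_AMPLIFICATION,
            }
        )

    for entry in spec.true_concentrations:
        eff = spec.efficiencies[entry["primer"]]
        for rep in range(1, spec.n_technical_reps + 1):
            rows.append(
                {
                    "primer": entry["primer"],
                    "sample": entry["sample"],
                    "condition": entry.get("condition", ""),
                    "compartment": entry.get("compartment", ""),
                    "replicate": rep,
                    "rt_flag": "+",
                    "standard_conc": np.nan,
                    "cq": _cq_from_concentration(entry["concentration"], eff, spec.intercept)
                    + noise(),
                }
            )

    table = pd.DataFrame(rows)
    truth = CqGroundTruth(
        efficiencies=dict(spec.efficiencies),
        intercept=spec.intercept,
        true_concentrations=pd.DataFrame(list(spec.true_concentrations)),
        contaminated_primers=list(spec.contaminated_primers),
    )
    return table, truth
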