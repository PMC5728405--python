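"""Standard-curve qPCR quantification and derived splicing/export indices.

Relative quantification follows the textbook in-run standard-curve method:
a least-squares line of Cq against log10 concentration per primer set,
amplification efficiency 10^(-1/slope), and unknowns read off the curve as
concentration = 10^((Cq - intercept)/slope).  Derived indices mirror the
assay designs this pipeline serves: reference-gene (ACTB) normalization,
pre-/post-spliced transcript levels from exon-intron vs exon-exon primer
pairs, nuclear/cytoplasmic transcript ratios, a MALAT1 fractionation
purity check, and an RT-minus genomic-contamination check.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import FitError, ParameterError, SchemaError

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "fit_curves_from_table",
    "quantify",
    "quantify_table",
    "normalize_to_reference",
    "purity_check",
    "rt_minus_check",
    "splicing_export_indices",
]


@dataclass
class StandardCurve:
    primer: str
    slope: float  # Cq per log10 concentration (negative)
    intercept: float  # Cq at concentration 1
    efficiency: float  # fold per cycle = 10^(-1/slope)
    r_squared: float


def fit_standard_curve(dilution_log10, cq, primer: str = "") -> StandardCurve:
    """Least-squares Cq ~ log10(concentration) line for one primer set."""
    x = np.asarray(dilution_log10, dtype=float)
    y = np.asarray(cq, dtype=float)
    if x.size < 3:
        raise FitError("standard curve needs >= 3 points")
    if np.unique(x).size < 2:
        raise FitError("standard dilutions must span more than one concentration")
    res = stats.linregress(x, y)
    if not (res.slope < 0):
        raise FitError(f"standard curve slope must be negative, got {res.slope}")
    efficiency = 10.0 ** (-1.0 / res.slope)
    if not (1.0 < efficiency <= 2.2):
        raise FitError(f"fitted efficiency {efficiency:.3f} outside sanity band (1, 2.2]")
    return StandardCurve(
        primer=primer,
        slope=float(res.slope),
        intercept=float(res.intercept),
        efficiency=float(efficiency),
        r_squared=float(res.rvalue**2),
    )


def fit_curves_from_table(table: pd.DataFrame) -> dict[str, StandardCurve]:
    """Fit every primer's in-run standard curve from a Cq table."""
    needed = {"primer", "standard_conc", "cq"}
    if needed - set(table.columns):
        raise SchemaError(f"Cq table missing columns: {sorted(needed - set(table.columns))}")
    standards = table.dropna(subset=["standard_conc"])
    curves = {}
    for primer, grp in standards.groupby("primer"):
        curves[str(primer)] = fit_standard_curve(
            np.log10(grp["standard_conc"].to_numpy(dtype=float)),
            grp["cq"].to_numpy(dtype=float),
            primer=str(primer),
        )
    return curves


def quantify(cq, curve: StandardCurve):
    """Relative concentration(s) from Cq via the fitted curve."""
    cq = np.asarray(cq, dtype=float)
    conc = 10.0 ** ((cq - curve.intercept) / curve.slope)
    return float(conc) if conc.ndim == 0 else conc


def quantify_table(
    table: pd.DataFrame,
    curves: dict[str, StandardCurve] | None = None,
) -> pd.DataFrame:
    """Quantify every RT-plus unknown well; technical replicates averaged
    on the concentration scale.

    Returns one row per (primer, sample, condition, compartment) with the
    mean relative concentration.
    """
    if curves is None:
        curves = fit_curves_from_table(table)
    unknowns = table[
        (table["rt_flag"] == "+") & table["standard_conc"].isna() & table["cq"].notna()
    ].copy()
    unknowns["concentration"] = [
        quantify(cq, curves[primer])
        for cq, primer in zip(unknowns["cq"], unknowns["primer"])
    ]
    out = (
        unknowns.groupby(["primer", "sample", "condition", "compartment"], as_index=False)[
            "concentration"
        ]
        .mean()
        .sort_values(["primer", "sample"])
        .reset_index(drop=True)
    )
    return out


def normalize_to_reference(target, reference):
    """Elementwise target / reference; non-positive references flagged as NaN."""
    target = np.asarray(target, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if target.shape != reference.shape:
        raise SchemaError("target and reference must be matched samples")
    out = np.full_like(target, np.nan)
    ok = reference > 0
    out[ok] = target[ok] / reference[ok]
    return float(out) if out.ndim == 0 else out


def purity_check(malat1_cyto: float, malat1_nuc: float, max_ratio: float = 0.1) -> str:
    """Fractionation purity from the nuclear-retained MALAT1 transcript.

    Returns 'pass', 'fail' (cytoplasmic leakage above ``max_ratio``) or
    'indeterminate' (no nuclear signal to compare against).
    """
    if malat1_cyto < 0 or malat1_nuc < 0:
        raise ParameterError("MALAT1 levels must be >= 0")
    if malat1_nuc == 0:
        return "indeterminate"
    return "fail" if malat1_cyto / malat1_nuc > max_ratio else "pass"


def rt_minus_check(table: pd.DataFrame) -> pd.DataFrame:
    """Per-primer genomic-contamination check on RT-minus wells.

    A primer fails when any of its RT-minus wells amplified (finite Cq
    instead of the no-amplification sentinel NaN).
    """
    minus = table[table["rt_flag"] == "-"]
    if minus.empty:
        raise SchemaError("no RT-minus wells in table")
    out = minus.groupby("primer")["cq"].apply(lambda c: bool(c.notna().any())).reset_index()
    out.columns = ["primer", "amplified"]
    out["status"] = np.where(out["amplified"], "fail", "pass")
    return out


def splicing_export_indices(
    quantified: pd.DataFrame,
    reference_primer: str = "ACTB",
    pre_suffix: str = "_pre",
    post_suffix: str = "_post",
) -> pd.DataFrame:
    """Per-transcript normalized pre-/post-spliced levels and N/C ratios.

    ``quantified`` is the output of :func:`quantify_table`.  Primer naming
    convention: ``<transcript>_pre`` spans an exon-intron junction
    (pre-spliced), ``<transcript>_post`` an exon-exon junction
    (post-spliced); a primer with neither suffix measures the mature
    transcript.  Every value is normalized to the reference primer within
    the same (sample, condition, compartment); the N/C ratio divides the
    nuclear by the cytoplasmic normalized value of the same transcript,
    condition and primer kind, and is NaN (flagged) when a compartment is
    missing or the cytoplasmic value is zero.
    """
    needed = {"primer", "sample", "condition", "compartment", "concentration"}
    if needed - set(quantified.columns):
        raise SchemaError(
            f"quantified table missing columns: {sorted(needed - set(quantified.columns))}"
        )
    ref = quantified[quantified["primer"] == reference_primer]
    if ref.empty:
        raise SchemaError(f"reference primer {reference_primer!r} absent")
    ref_map = {
        (r["sample"], r["condition"], r["compartment"]): r["concentration"]
        for _, r in ref.iterrows()
    }

    rows = []
    targets = quantified[quantified["primer"] != reference_primer]
    for _, r in targets.iterrows():
        key = (r["sample"], r["condition"], r["compartment"])
        if key not in ref_map:
            raise SchemaError(f"no reference measurement for sample group {key}")
        primer = str(r["primer"])
        if primer.endswith(pre_suffix):
            transcript, kind = primer[: -len(pre_suffix)], "pre_spliced"
        elif primer.endswith(post_suffix):
            transcript, kind = primer[: -len(post_suffix)], "post_spliced"
        else:
            transcript, kind = primer, "mature"
        rows.append(
            {
                "transcript": transcript,
                "kind": kind,
                "sample": r["sample"],
                "condition": r["condition"],
                "compartment": r["compartment"],
                "normalized": normalize_to_reference(r["concentration"], ref_map[key]),
            }
        )
    norm = pd.DataFrame(rows)

    out_rows = []
    for (transcript, kind, condition), grp in norm.groupby(["transcript", "kind", "condition"]):
        comp = {c: v for c, v in zip(grp["compartment"], grp["normalized"])}
        nuc = comp.get("nuclear", math.nan)
        cyto = comp.get("cytoplasmic", math.nan)
        nc = nuc / cyto if (not math.isnan(nuc) and not math.isnan(cyto) and cyto > 0) else math.nan
        out_rows.append(
            {
                "transcript": transcript,
                "kind": kind,
                "condition": condition,
                "nuclear": nuc,
                "cytoplasmic": cyto,
                "nc_ratio": nc,
                "nc_ratio_flag": "" if not math.isnan(nc) else "missing_compartment",
            }
        )
    return pd.DataFrame(out_rows).sort_values(["transcript", "kind", "condition"]).reset_index(
        drop=True
    )
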