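"""Quantify the synthetic microscopy fields and compare against ground truth.

Segments nuclei from DAPI, measures per-cell nuclear/cytoplasmic signal
ratios (2-px eroded nuclear mask, 30-px ring with a 2-px gap), scores
repair foci per nucleus with the >= 5-focus convention, and computes
per-cell reporter channel ratios.  Writes per-cell tables and summaries
under results/imaging/.
"""

from pathlib import Path

import numpy as np

from splicexport import cli_io, image_quant as iq, stats_report as sr

ROOT = Path(__file__).resolve().parents[1] / "results"
IN = ROOT / "inputs"
OUT = ROOT / "imaging"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = cli_io.PipelineConfig()

    frame = cli_io.read_image_frame(IN / "fish.tif")
    truth_cells = cli_io.read_table(IN / "fish_truth.csv")
    labels = iq.segment_nuclei(frame["dapi"], min_area_px=cfg.min_area_px)
    pairs = iq.build_region_pairs(labels, cfg.erosion_px, cfg.ring_gap_px, cfg.ring_width_px)
    cells = iq.measure_nc_ratio(frame["signal"], pairs, cfg.exclude_border)
    cli_io.write_table(cells, OUT / "fish_cells.csv")
    kept = cells.loc[cells["included"], "nc_ratio"].to_numpy()
    mean, sem = sr.mean_sem(kept)
    true_ratio = float(truth_cells["true_nc_ratio"].iloc[0])
    cli_io.write_json({"n_cells": int(kept.size), "mean_nc_ratio": mean, "sem": sem,
                       "true_nc_ratio": true_ratio}, OUT / "fish_summary.json")
    print(f"N/C ratio: {mean:.4f} +/- {sem:.4f} over {kept.size} cells "
          f"(planted {true_ratio}; relative error "
          f"{abs(mean - true_ratio) / true_ratio:.2%})")

    foci_frame = cli_io.read_image_frame(IN / "foci.tif")
    foci_labels = iq.segment_nuclei(foci_frame["dapi"], min_area_px=cfg.min_area_px)
    foci_table, fraction = iq.score_foci(
        foci_frame["foci"], foci_labels, cfg.min_foci, cfg.focus_radius_px
    )
    cli_io.write_table(foci_table, OUT / "foci_counts.csv")
    truth = cli_io.read_table(IN / "foci_truth.csv")
    planted_fraction = float((truth["foci_count"] >= cfg.min_foci).mean())
    cli_io.write_json({"fraction_ge_5": fraction, "planted_fraction": planted_fraction},
                      OUT / "foci_summary.json")
    print(f"Foci: detected counts {sorted(foci_table['foci_count'])}, "
          f"fraction >= {cfg.min_foci} foci: {fraction:.3f} (planted {planted_fraction:.3f})")

    rep_frame = cli_io.read_image_frame(IN / "reporter.tif")
    rep_labels = cli_io.read_label_mask(IN / "reporter_truth_labels.tif")
    rep_table, rep_mean = iq.reporter_ratio(
        rep_frame["numerator"], rep_frame["denominator"], rep_labels,
        cfg.min_denominator,
    )
    cli_io.write_table(rep_table, OUT / "reporter_cells.csv")
    rep_truth = cli_io.read_table(IN / "reporter_truth.csv")
    true_mean = float(rep_truth["true_ratio"].mean())
    cli_io.write_json({"mean_reporter_ratio": rep_mean, "true_mean": true_mean},
                      OUT / "reporter_summary.json")
    print(f"Reporter GFP/RFP: mean {rep_mean:.4f} (planted mean {true_mean:.4f})")


if __name__ == "__main__":
    main()
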