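"""Generate every synthetic input the downstream analyses consume.

Writes FISH/foci/reporter image stacks with ground-truth masks, a replicate
expression table with planted cytoplasmic down-regulation, a 3'-UTR set
carrying the consensus motif, and a qPCR Cq table with in-run standards —
all under results/inputs/, fully determined by SEED.
"""

from pathlib import Path

import numpy as np

from splicexport import cli_io
from splicexport import synthetic_data as sd

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    fish_spec = sd.FishImageSpec(true_nc_ratio=2.0, noise_sd=20.0, seed=SEED)
    frame, truth = sd.generate_fish_image(fish_spec)
    cli_io.write_image_frame(frame, OUT / "fish.tif")
    cli_io.write_label_mask(truth.nuclear_labels, OUT / "fish_truth_labels.tif")
    cli_io.write_table(truth.cells, OUT / "fish_truth.csv")
    print(f"FISH field: {len(truth.cells)} cells, true N/C ratio "
          f"{fish_spec.true_nc_ratio}, noise sd {fish_spec.noise_sd}")

    rng = np.random.default_rng(SEED)
    counts = tuple(int(c) for c in rng.integers(0, 9, size=8))
    foci_frame, foci_truth = sd.generate_foci_image(
        sd.FociImageSpec(foci_counts=counts, image_shape=(640, 640), seed=SEED)
    )
    cli_io.write_image_frame(foci_frame, OUT / "foci.tif")
    cli_io.write_label_mask(foci_truth.nuclear_labels, OUT / "foci_truth_labels.tif")
    cli_io.write_table(foci_truth.cells, OUT / "foci_truth.csv")
    print(f"Foci field: planted counts {counts}")

    rep_frame, rep_truth = sd.generate_reporter_image(
        sd.ReporterImageSpec(true_ratios=(0.3, 1.0, 2.0, 1.5, 0.8), seed=SEED)
    )
    cli_io.write_image_frame(rep_frame, OUT / "reporter.tif")
    cli_io.write_label_mask(rep_truth.cell_labels, OUT / "reporter_truth_labels.tif")
    cli_io.write_table(rep_truth.cells, OUT / "reporter_truth.csv")
    print(f"Reporter field: true GFP/RFP ratios {sorted(rep_truth.true_ratios.values())}")

    planted = {
        "siTHRAP3": {int(i): 0.4 for i in rng.choice(2000, 120, replace=False)},
        "siBCLAF1": {int(i): 0.4 for i in rng.choice(2000, 110, replace=False)},
        "siTHRAP3+siBCLAF1": {int(i): 0.4 for i in rng.choice(2000, 300, replace=False)},
    }
    table, expr_truth = sd.generate_expression_table(
        sd.ExpressionSpec(n_genes=2000, planted_down=planted, seed=SEED)
    )
    cli_io.write_table(table, OUT / "expression.csv")
    cli_io.write_json(expr_truth.planted_down, OUT / "expression_truth.json")
    print(f"Expression table: 2000 genes, planted down-sets "
          f"{ {k: len(v) for k, v in planted.items()} }")

    records, utr_truth = sd.generate_utr_set(sd.UtrSpec(planted_fraction=1.0, seed=SEED))
    cli_io.write_fasta(records, OUT / "utrs.fasta")
    cli_io.write_json({"motif": utr_truth.motif,
                       "positions": utr_truth.planted_positions}, OUT / "utrs_truth.json")
    null_records, _ = sd.generate_utr_set(sd.UtrSpec(planted_fraction=0.0, seed=SEED))
    cli_io.write_fasta(null_records, OUT / "utrs_null.fasta")
    print(f"UTR sets: 200 sequences with planted {utr_truth.motif}, plus a null set")

    primers = {"ACTB": 2.0, "ATM_pre": 1.87, "ATM_post": 1.94, "MALAT1": 2.0}
    conc = []
    for cond, export in (("siCtrl", 1.0), ("siTHRAP3+siBCLAF1", 0.35)):
        for compartment in ("nuclear", "cytoplasmic"):
            sample = f"{cond}_{compartment}"
            conc += [
                {"primer": "ACTB", "sample": sample, "condition": cond,
                 "compartment": compartment, "concentration": 0.8},
                {"primer": "ATM_pre", "sample": sample, "condition": cond,
                 "compartment": compartment,
                 "concentration": 0.07 * (2.0 if cond != "siCtrl" else 1.0)},
                {"primer": "ATM_post", "sample": sample, "condition": cond,
                 "compartment": compartment,
                 "concentration": 0.6 * (export if compartment == "cytoplasmic" else 1.0)},
                {"primer": "MALAT1", "sample": sample, "condition": cond,
                 "compartment": compartment,
                 "concentration": 1.0 if compartment == "nuclear" else 0.02},
            ]
    cq_table, cq_truth = sd.generate_cq_table(
        sd.CqSpec(efficiencies=primers, true_concentrations=conc,
                  cq_noise_sd=0.05, n_technical_reps=3, seed=SEED)
    )
    cli_io.write_table(cq_table, OUT / "cq_table.csv")
    cli_io.write_json({"efficiencies": cq_truth.efficiencies,
                       "intercept": cq_truth.intercept}, OUT / "cq_truth.json")
    print(f"Cq table: {len(cq_table)} wells over primers {list(primers)}")
    print(f"all inputs written to {OUT}")


if __name__ == "__main__":
    main()
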