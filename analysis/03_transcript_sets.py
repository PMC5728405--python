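"""Differential filtering and set-overlap arithmetic on the expression table.

For each knockdown: per-gene cytoplasmic fold-change and t-test, BH
adjustment, and the "down > 1.5-fold at FDR < 0.01" filter; then the
overlap report between the single-knockdown target lists.  Also reproduces
the two printed arithmetic identities these reports rest on: 191 shared
genes out of an 849 + 749 union = 13.6%, and 2538 of 26,501 = 9.6%.
"""

import dataclasses
from pathlib import Path

from splicexport import cli_io, transcript_sets as ts

ROOT = Path(__file__).resolve().parents[1] / "results"
IN = ROOT / "inputs"
OUT = ROOT / "transcript_sets"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = cli_io.PipelineConfig()
    table = cli_io.read_table(IN / "expression.csv")
    truth = cli_io.read_json(IN / "expression_truth.json")

    down = {}
    for cond in ("siTHRAP3", "siBCLAF1", "siTHRAP3+siBCLAF1"):
        diff = ts.differential_cytoplasmic(table, "siCtrl", cond)
        cli_io.write_table(diff.reset_index(), OUT / f"diff_{cond}.csv")
        down[cond] = ts.filter_down(diff, cfg.fc_threshold, cfg.fdr_alpha)
        cli_io.write_gene_set(down[cond], OUT / f"down_{cond}.txt")
        planted = set(truth[cond])
        sens = len(down[cond] & planted) / len(planted)
        fdp = len(down[cond] - planted) / max(len(down[cond]), 1)
        print(f"{cond}: {len(down[cond])} genes down >1.5-fold at FDR<{cfg.fdr_alpha} "
              f"(sensitivity {sens:.3f}, FDP {fdp:.3f} vs planted truth)")

    rep = ts.overlap_stats(down["siTHRAP3"], down["siBCLAF1"])
    cli_io.write_json(dataclasses.asdict(rep), OUT / "overlap.json")
    print(f"overlap: |A|={rep.n_a}, |B|={rep.n_b}, shared {rep.n_intersection} "
          f"= {rep.pct_of_union}% of the union")

    frac = ts.fraction_of_universe(down["siTHRAP3+siBCLAF1"], 2000)
    print(f"double knockdown: {len(down['siTHRAP3+siBCLAF1'])} of 2000 genes = {frac}%")

    # the printed-count arithmetic these reports implement
    a = {f"g{i}" for i in range(849)}
    b = {f"g{i}" for i in range(849 - 191, 849 - 191 + 749)}
    printed = ts.overlap_stats(a, b)
    frac_printed = ts.fraction_of_universe({f"g{i}" for i in range(2538)}, 26501)
    cli_io.write_json(
        {"overlap_849_749_shared_191_pct_of_union": printed.pct_of_union,
         "fraction_2538_of_26501_pct": frac_printed},
        OUT / "printed_arithmetic.json",
    )
    print(f"printed arithmetic: 191/(849+749-191) = {printed.pct_of_union}%; "
          f"2538/26501 = {frac_printed}%")


if __name__ == "__main__":
    main()
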