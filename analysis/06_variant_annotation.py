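"""Codon arithmetic and consequence calls for the recurrent truncating variants.

Maps the two cancer-associated THRAP3 substitutions (C301>T, C2509>T) to
their codons and, on a synthetic stand-in CDS carrying CGA (arginine)
codons at those positions, verifies both call as nonsense (R -> *).
"""

import dataclasses
from pathlib import Path

from splicexport import cds_annot as ca
from splicexport import cli_io

OUT = Path(__file__).resolve().parents[1] / "results" / "variants"

# Synthetic stand-in CDS (the real 955-codon sequence is not bundled):
# 955 codons of GCT (Ala) with ATG start, TAA stop, and CGA arginine codons
# placed at codons 101 and 837 so the C>T substitutions recreate the
# R101*/R837* truncations.
N_CODONS = 955


def synthetic_cds() -> str:
    codons = ["GCT"] * N_CODONS
    codons[0] = "ATG"
    codons[100] = "CGA"  # codon 101
    codons[836] = "CGA"  # codon 837
    codons[-1] = "TAA"
    return "".join(codons)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cds = synthetic_cds()
    rows = []
    for pos in (301, 2509):
        variant = ca.annotate_substitution(cds, pos, ref="C", alt="T")
        rows.append(dataclasses.asdict(variant))
        print(f"C{pos}>T: codon {variant.codon_index} position "
              f"{variant.position_in_codon}, {variant.ref_codon}->{variant.alt_codon} "
              f"({variant.ref_aa}{variant.codon_index}{variant.alt_aa}, "
              f"{variant.consequence}); {variant.truncated_length} residues retained "
              f"of the {N_CODONS}-aa protein")
    cli_io.write_json(rows, OUT / "variant_annotations.json")


if __name__ == "__main__":
    main()
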