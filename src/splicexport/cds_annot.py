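"""Coding-coordinate arithmetic for point substitutions.

Maps 1-based CDS nucleotide positions (A of the ATG = position 1) to codon
indices and, given the CDS sequence, calls the consequence of a
substitution (silent / missense / nonsense) via the standard genetic code.
Houses the truncating-variant arithmetic used for nonsense mutations such
as C301>T (codon 101, R -> *) and C2509>T (codon 837, R -> *).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .exceptions import ParameterError

__all__ = ["CdsVariant", "codon_of", "annotate_substitution"]

_STOPS = set(standard_dna_table.stop_codons)


@dataclass
class CdsVariant:
    cds_position: int
    ref: str
    alt: str
    codon_index: int
    position_in_codon: int  # 1, 2 or 3
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    consequence: str  # silent | missense | nonsense | stop_lost
    truncated_length: int | None  # residues retained before a new stop, else None


def codon_of(cds_position: int) -> tuple[int, int]:
    """(codon index, position within codon), both 1-based.

    Codon c covers CDS nucleotides 3c-2 .. 3c, so position 301 falls in
    codon 101 (first base) and position 2509 in codon 837.
    """
    if cds_position < 1:
        raise ParameterError("CDS positions are 1-based; got < 1")
    return (cds_position - 1) // 3 + 1, (cds_position - 1) % 3 + 1


def annotate_substitution(cds_sequence: str, position: int, ref: str, alt: str) -> CdsVariant:
    """Consequence of a single-nucleotide substitution in a CDS.

    ``truncated_length`` for a nonsense variant is codon_index - 1: the
    stop codon replaces the affected residue, so a stop at codon 101
    retains 100 residues.
    """
    seq = str(cds_sequence).upper()
    ref, alt = ref.upper(), alt.upper()
    if len(seq) % 3 != 0:
        raise ParameterError("CDS length must be divisible by 3")
    if not (1 <= position <= len(seq)):
        raise ParameterError("position outside the CDS")
    if seq[position - 1] != ref:
        raise ParameterError(
            f"reference mismatch at CDS position {position}: sequence has "
            f"{seq[position - 1]}, variant says {ref}"
        )
    if alt not in "ACGT" or ref not in "ACGT":
        raise ParameterError("ref/alt must be single A/C/G/T bases")

    codon_index, pos_in_codon = codon_of(position)
    start = (codon_index - 1) * 3
    ref_codon = seq[start : start + 3]
    alt_codon = ref_codon[: pos_in_codon - 1] + alt + ref_codon[pos_in_codon:]
    ref_aa = "*" if ref_codon in _STOPS else str(Seq(ref_codon).translate())
    alt_aa = "*" if alt_codon in _STOPS else str(Seq(alt_codon).translate())

    if alt_aa == ref_aa:
        consequence = "silent"
    elif alt_aa == "*":
        consequence = "nonsense"
    elif ref_aa == "*":
        consequence = "stop_lost"
    else:
        consequence = "missense"

    return CdsVariant(
        cds_position=position,
        ref=ref,
        alt=alt,
        codon_index=codon_index,
        position_in_codon=pos_in_codon,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        consequence=consequence,
        truncated_length=codon_index - 1 if alt_aa == "*" else None,
    )
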