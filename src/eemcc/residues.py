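"""Sequence-level charge bookkeeping for protein species.

Integer titration at a given pH with textbook side-chain pKa values: a
basic group is counted protonated (+1) when pH < pKa and an acidic
group deprotonated (-1) when pH > pKa.  Cysteines are assumed
disulfide-bonded (non-titratable) by default, appropriate for
disulfide-rich proteins such as lysozyme.
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO

#: side-chain pKa (basic groups protonate below, acidic deprotonate above)
PKA_BASIC = {"R": 12.48, "K": 10.53, "H": 6.00}
PKA_ACIDIC = {"D": 3.65, "E": 4.25, "Y": 10.07, "C": 8.30}
PKA_NTERM = 9.60
PKA_CTERM = 2.34


def read_sequence(path: str | Path) -> str:
    """First sequence of a FASTA file as a one-letter string."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def count_basic_residues(seq: str, pH: float = 9.0) -> int:
    """Residues with a protonated (positive) basic side chain at this pH."""
    return sum(1 for aa in seq if aa in PKA_BASIC and pH < PKA_BASIC[aa])


def net_charge(
    seq: str,
    pH: float = 9.0,
    disulfides: bool = True,
    termini: bool = True,
) -> int:
    """Integer net charge of one chain at the given pH."""
    q = 0
    for aa in seq:
        if aa in PKA_BASIC and pH < PKA_BASIC[aa]:
            q += 1
        elif aa in PKA_ACIDIC and pH > PKA_ACIDIC[aa]:
            if aa == "C" and disulfides:
                continue
            q -= 1
    if termini:
        if pH < PKA_NTERM:
            q += 1
        if pH > PKA_CTERM:
            q -= 1
    return q
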