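"""Genetic-code tables and small sequence helpers shared across modules.

Everything here derives from NCBI translation table 11 (bacterial/archaeal/
plant plastid), the standard code for chloroplast protein-coding genes.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]

#: codon (DNA, upper case) -> one-letter amino acid, sense codons only
AA_OF: dict[str, str] = dict(_TABLE11.forward_table)

#: the three stop codons under table 11
STOP_CODONS: frozenset[str] = frozenset(_TABLE11.stop_codons)

#: the 61 sense codons
SENSE_CODONS: tuple[str, ...] = tuple(sorted(AA_OF))

#: amino acid -> sorted tuple of its synonymous codons
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in AA_OF.items():
    FAMILIES.setdefault(_aa, [])
for _codon, _aa in sorted(AA_OF.items()):
    FAMILIES[_aa].append(_codon)  # type: ignore[attr-defined]
FAMILIES = {aa: tuple(codons) for aa, codons in FAMILIES.items()}

#: degeneracy (family size) -> amino acids in that class
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {}
for _aa, _codons in sorted(FAMILIES.items()):
    DEGENERACY_CLASSES.setdefault(len(_codons), [])
    DEGENERACY_CLASSES[len(_codons)].append(_aa)  # type: ignore[attr-defined]
DEGENERACY_CLASSES = {k: tuple(v) for k, v in DEGENERACY_CLASSES.items()}

#: codons counted for synonymous third-position statistics (GC3s, A3s ...):
#: all sense codons of amino acids with >= 2 synonymous codons, i.e. the 61
#: sense codons minus ATG (Met) and TGG (Trp); stop codons are never included.
SYNONYMOUS_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if len(FAMILIES[AA_OF[c]]) >= 2
)

ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt: str) -> str:
    """Translate an in-frame DNA string under table 11; stops become ``*``."""
    aas = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i : i + 3]
        if codon in STOP_CODONS:
            aas.append("*")
        else:
            aas.append(AA_OF.get(codon, "X"))
    return "".join(aas)


def codons_of(nt: str) -> list[str]:
    """Split an in-frame DNA string into its codon triplets."""
    if len(nt) % 3:
        raise ValueError(f"sequence length {len(nt)} is not a multiple of 3")
    return [nt[i : i + 3] for i in range(0, len(nt), 3)]


def is_gc(base: str) -> bool:
    return base in "GC"
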