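"""Standard nuclear genetic code and its synonymous-family structure.

The degeneracy-class layout of the standard code drives every codon-bias
statistic in this package: 61 sense codons partition into 2 one-fold
families (Met, Trp), 9 two-fold, 1 three-fold (Ile), 5 four-fold and
3 six-fold (Leu, Ser, Arg) families.  Six-fold families are kept whole
(no 2+4 split), matching the class coefficients of Wright's effective
number of codons.
"""

from __future__ import annotations

import itertools
from types import MappingProxyType

BASES = "ACGT"

#: all 64 codons in lexicographic (A<C<G<T) order
CODONS: tuple[str, ...] = tuple("".join(p) for p in itertools.product(BASES, repeat=3))
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

_TCAG = "TCAG"
_AA_BY_TCAG = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_TABLE = {
    a + b + c: aa
    for (a, b, c), aa in zip(itertools.product(_TCAG, _TCAG, _TCAG), _AA_BY_TCAG)
}

#: codon -> one-letter amino acid ('*' for stop)
CODON_TO_AA: MappingProxyType = MappingProxyType({c: _TABLE[c] for c in CODONS})

STOP_CODONS: frozenset[str] = frozenset(c for c, aa in CODON_TO_AA.items() if aa == "*")
SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS if c not in STOP_CODONS)

#: one-letter aa -> tuple of synonymous codons, lexicographic
FAMILIES: MappingProxyType = MappingProxyType(
    {
        aa: tuple(c for c in CODONS if CODON_TO_AA[c] == aa)
        for aa in sorted(set(CODON_TO_AA.values()) - {"*"})
    }
)

#: aa -> degeneracy class k (family size)
DEGENERACY: MappingProxyType = MappingProxyType({aa: len(f) for aa, f in FAMILIES.items()})

#: the 18 families with k >= 2 (the ones RSCU and Nc are defined on)
MULTI_FAMILIES: tuple[str, ...] = tuple(aa for aa in FAMILIES if DEGENERACY[aa] >= 2)

#: the 59 sense codons in families of size >= 2
INFORMATIVE_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if DEGENERACY[CODON_TO_AA[c]] >= 2
)

#: amino acids grouped by degeneracy class; class counts are (2, 9, 1, 5, 3)
CLASSES: MappingProxyType = MappingProxyType(
    {
        k: tuple(aa for aa in FAMILIES if DEGENERACY[aa] == k)
        for k in (1, 2, 3, 4, 6)
    }
)

AA_3TO1: MappingProxyType = MappingProxyType(
    {
        "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
        "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
        "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
        "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    }
)
AA_1TO3: MappingProxyType = MappingProxyType({v: k for k, v in AA_3TO1.items()})


def normalize_aa(aa: str) -> str:
    """Return the one-letter code for a one- or three-letter amino acid name.

    Raises ``ValueError`` for anything that is not one of the 20 standard
    amino acids.
    """
    s = aa.strip()
    if len(s) == 1 and s.upper() in AA_1TO3:
        return s.upper()
    if s.capitalize() in AA_3TO1:
        return AA_3TO1[s.capitalize()]
    raise ValueError(f"unknown amino acid name: {aa!r}")
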