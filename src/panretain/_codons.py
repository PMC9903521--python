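"""Standard genetic code tables shared by the Ka/Ks and codon-model machinery.

The 61 sense codons are kept in a fixed lexicographic order (TCAG-free:
plain A<C<G<T sort) so that rate matrices, frequency vectors and simulators
all agree on state indexing.
"""

from __future__ import annotations

import itertools

NUCLEOTIDES = "ACGT"

#: amino-acid translation for all 64 codons, "*" = stop (standard code)
GENETIC_CODE: dict[str, str] = {}
_bases = {
    "T": "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG",
}
for _i, (_n1, _n2, _n3) in enumerate(
    itertools.product("TCAG", "TCAG", "TCAG")
):
    GENETIC_CODE[_n1 + _n2 + _n3] = _bases["T"][_i]

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")

#: the 61 sense codons, sorted lexicographically over A<C<G<T
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in GENETIC_CODE if c not in STOP_CODONS)
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

_PURINES = frozenset("AG")


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a->b is a transition."""
    return a != b and ((a in _PURINES) == (b in _PURINES))


def translate(cds: str) -> str:
    """Translate an ungapped CDS under the standard code ('*' for stops)."""
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    return "".join(GENETIC_CODE[cds[i : i + 3]] for i in range(0, len(cds), 3))


def codon_diffs(c1: str, c2: str) -> list[int]:
    """Positions (0..2) at which two codons differ."""
    return [i for i in range(3) if c1[i] != c2[i]]
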