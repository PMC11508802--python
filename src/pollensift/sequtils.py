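"""Small nucleotide-sequence helpers shared across the pipeline.

IUPAC-aware primer matching is set-intersection based: a primer base matches
a template base when their IUPAC degeneracy sets share at least one
unambiguous nucleotide (so primer ``R`` matches template ``A``, ``G``, or any
ambiguity code containing either).
"""

from __future__ import annotations

from .errors import InvalidSequenceError

#: IUPAC nucleotide codes mapped to the set of unambiguous bases they denote.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def validate_iupac(seq: str, *, context: str = "sequence") -> str:
    """Return ``seq`` unchanged, or raise :class:`InvalidSequenceError`."""
    bad = set(seq) - IUPAC_SETS.keys()
    if bad:
        raise InvalidSequenceError(
            f"{context} contains non-IUPAC characters: {sorted(bad)!r}"
        )
    return seq


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(a: str, b: str) -> bool:
    """True when the IUPAC sets of two bases intersect."""
    return not IUPAC_SETS[a].isdisjoint(IUPAC_SETS[b])


def count_mismatches(primer: str, window: str) -> int:
    """Number of positions where the primer and an equal-length window are
    IUPAC-incompatible."""
    return sum(1 for p, w in zip(primer, window) if not iupac_match(p, w))


def find_primer_matches(
    seq: str, primer: str, max_mismatch: int
) -> list[tuple[int, int]]:
    """All ungapped matches of ``primer`` in ``seq`` within tolerance.

    Returns ``(start, n_mismatches)`` pairs in left-to-right order.  Naive
    scan: primers are short (~20-25 nt) and templates are amplicon-sized, so
    O(len(seq) * len(primer)) is adequate.
    """
    L, p = len(seq), len(primer)
    out = []
    for i in range(L - p + 1):
        mm = 0
        for a, b in zip(primer, seq[i : i + p]):
            if not iupac_match(a, b):
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            out.append((i, mm))
    return out


def longest_homopolymer(seq: str) -> int:
    """Length of the longest single-base run (0 for the empty string)."""
    best = run = 0
    prev = None
    for ch in seq:
        run = run + 1 if ch == prev else 1
        prev = ch
        if run > best:
            best = run
    return best
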