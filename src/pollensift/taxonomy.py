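"""Ranked taxonomic lineages and the string dialect used throughout.

A lineage is an ordered path over the seven standard ranks
kingdom > phylum > class > order > family > genus > species.  Unknown ranks
are representable as absent, and a lineage truncated at rank *r* contains
exactly the ranks at or above *r* — the property the majority-rule LCA
ascent relies on.

The canonical string dialect is the 7-field, semicolon-delimited
``k__...;p__...;c__...;o__...;f__...;g__...;s__...`` form with empty values
for unknown ranks, which makes truncation unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

RANKS: tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)
RANK_PREFIXES: tuple[str, ...] = ("k", "p", "c", "o", "f", "g", "s")
_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}


@dataclass(frozen=True)
class TaxonLineage:
    """An ordered ranked taxonomy path from kingdom down to species.

    ``names`` always has exactly seven entries, one per rank in
    :data:`RANKS`; ``None`` marks an unknown rank.
    """

    names: tuple[str | None, ...] = field(default=(None,) * 7)

    def __post_init__(self):
        if len(self.names) != len(RANKS):
            raise ValueError(
                f"lineage must have {len(RANKS)} ranks, got {len(self.names)}"
            )
        cleaned = tuple(n if n else None for n in self.names)
        object.__setattr__(self, "names", cleaned)

    # -- constructors -------------------------------------------------

    @classmethod
    def from_names(cls, **kwargs: str | None) -> "TaxonLineage":
        """Build from rank keywords, e.g. ``from_names(genus="Vicia")``."""
        unknown = set(kwargs) - set(RANKS)
        if unknown:
            raise ValueError(f"unknown ranks: {sorted(unknown)}")
        return cls(tuple(kwargs.get(r) for r in RANKS))

    @classmethod
    def from_string(cls, s: str) -> "TaxonLineage":
        """Parse the ``k__;p__;...;s__`` dialect.

        Trailing ranks may be omitted; ``k__`` prefixes are required so that
        field order cannot be silently mistaken.
        """
        parts = [p.strip() for p in s.split(";")] if s.strip() else []
        if len(parts) > len(RANKS):
            raise ValueError(f"too many ranked fields in lineage string: {s!r}")
        names: list[str | None] = [None] * len(RANKS)
        for i, part in enumerate(parts):
            prefix = RANK_PREFIXES[i] + "__"
            if not part.startswith(prefix):
                raise ValueError(
                    f"field {i} of {s!r} should start with {prefix!r}"
                )
            value = part[len(prefix):].strip()
            names[i] = value or None
        return cls(tuple(names))

    # -- accessors ----------------------------------------------------

    def name_at(self, rank: str) -> str | None:
        return self.names[_RANK_INDEX[rank]]

    @property
    def deepest_rank(self) -> str | None:
        """Lowest rank with a known name, or None for an empty lineage."""
        for i in range(len(RANKS) - 1, -1, -1):
            if self.names[i] is not None:
                return RANKS[i]
        return None

    @property
    def display_name(self) -> str:
        """The name at the deepest known rank (empty string if none)."""
        r = self.deepest_rank
        return self.name_at(r) if r else ""

    def truncate(self, rank: str) -> "TaxonLineage":
        """Keep ranks at or above ``rank``; lower ranks become unknown."""
        k = _RANK_INDEX[rank]
        return TaxonLineage(self.names[: k + 1] + (None,) * (len(RANKS) - k - 1))

    def prefix_through(self, rank: str) -> tuple[str | None, ...]:
        """The name path from kingdom down to ``rank`` inclusive."""
        return self.names[: _RANK_INDEX[rank] + 1]

    def to_string(self) -> str:
        return ";".join(
            f"{p}__{n or ''}" for p, n in zip(RANK_PREFIXES, self.names)
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def lineages_compatible(a: TaxonLineage, b: TaxonLineage) -> bool:
    """Rank-aware ancestor/descendant match.

    True when one lineage is an ancestor of (or equal to) the other: the two
    agree at every rank where both are known, down to the deepest rank of the
    shallower lineage.  This is how a dietary taxon recorded at genus level
    ("Vicia") matches a species-level detection ("Vicia faba").
    """
    da, db = a.deepest_rank, b.deepest_rank
    if da is None or db is None:
        return False
    depth = min(_RANK_INDEX[da], _RANK_INDEX[db])
    for i in range(depth + 1):
        x, y = a.names[i], b.names[i]
        if x is not None and y is not None and x != y:
            return False
    return True


def rank_index(rank: str) -> int:
    return _RANK_INDEX[rank]
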