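"""Per-sample taxon profiles: tallying, taxon selection, genus collapsing,
and low-depth sample exclusion.

Counts are keyed by lineage strings at the assigned rank.  Selection keeps
the most-abundant taxon plus every taxon with at least 1% of its count;
samples with fewer than 50 assigned units (3000 for ASV-unit data) are
dropped outright.  Both thresholds are inclusive/exclusive exactly as the
field convention reads them: a taxon at exactly 1% is selected, a sample
with exactly the minimum unit count is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

from .classify import ASSIGNED, Assignment
from .taxonomy import TaxonLineage, rank_index

_EPS = 1e-9

SUPRA_GENUS = "supra-genus"


@dataclass
class SampleProfile:
    """Taxon -> unit-count table for one sample, with selection flags."""

    sample_id: str
    counts: dict[str, int] = field(default_factory=dict)
    selected: set[str] = field(default_factory=set)
    flags: dict[str, str] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        stray = self.selected - self.counts.keys()
        if stray:
            raise ValueError(f"selected labels not in counts: {sorted(stray)}")

    @property
    def total_units(self) -> int:
        return sum(self.counts.values())


def tally(assignments: list[Assignment], sample_id: str) -> SampleProfile:
    """Count Assigned reads per lineage label; Unassigned and Unresolved
    reads contribute nothing, not even to the total."""
    counts: dict[str, int] = {}
    for a in assignments:
        if a.status == ASSIGNED:
            label = a.lineage.to_string()
            counts[label] = counts.get(label, 0) + 1
    return SampleProfile(sample_id=sample_id, counts=counts)


def select_taxa(
    profile: SampleProfile, rel_threshold: float = 0.01
) -> SampleProfile:
    """Select the top taxon and every taxon at >= ``rel_threshold`` of it.

    The comparison is inclusive (a count of exactly 1% of the maximum is
    selected).  Ties for the maximum all anchor the same threshold.  Counts
    for non-selected taxa are retained, only flagged out of ``selected``.
    """
    if not profile.counts:
        return replace(profile, selected=set())
    top = max(profile.counts.values())
    cut = rel_threshold * top
    selected = {t for t, c in profile.counts.items() if c >= cut - _EPS}
    return replace(profile, selected=selected)


def drop_small_samples(
    profiles: list[SampleProfile], min_sample_units: int = 50
) -> tuple[list[SampleProfile], list[SampleProfile]]:
    """Partition into (kept, dropped) on total units.

    Strict "fewer than": a sample with exactly ``min_sample_units`` is kept.
    """
    kept = [p for p in profiles if p.total_units >= min_sample_units]
    dropped = [p for p in profiles if p.total_units < min_sample_units]
    return kept, dropped


def collapse_to_genus(profile: SampleProfile) -> SampleProfile:
    """Merge species-level labels into their genus; flag supra-genus labels.

    Species-level entries are truncated to genus and counts summed with any
    existing genus entry.  Labels already at genus pass through.  Labels
    above genus (family or higher) cannot be expanded downward without
    external information, so they are retained as-is and flagged
    ``supra-genus``.  Total units are conserved.
    """
    genus_idx = rank_index("genus")
    counts: dict[str, int] = {}
    flags: dict[str, str] = {}
    relabel: dict[str, str] = {}
    for label, n in profile.counts.items():
        lin = TaxonLineage.from_string(label)
        deepest = lin.deepest_rank
        if deepest is not None and rank_index(deepest) >= genus_idx:
            new_label = lin.truncate("genus").to_string()
        else:
            new_label = label
            flags[new_label] = SUPRA_GENUS
        relabel[label] = new_label
        counts[new_label] = counts.get(new_label, 0) + n
    selected = {relabel[t] for t in profile.selected}
    return SampleProfile(
        sample_id=profile.sample_id,
        counts=counts,
        selected=selected,
        flags=flags,
        metadata=dict(profile.metadata),
    )


def consensus_read_sets(
    profile: SampleProfile, assignments: list[Assignment]
) -> dict[str, list[str]]:
    """Read ids backing each *selected* taxon, for external consensus
    polishing.  Assignment order is preserved within each taxon."""
    out: dict[str, list[str]] = {t: [] for t in sorted(profile.selected)}
    for a in assignments:
        if a.status != ASSIGNED:
            continue
        label = a.lineage.to_string()
        if label in out:
            out[label].append(a.read_id)
    return out


# -- profile TSV -------------------------------------------------------


def write_profiles(profiles: list[SampleProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\ttaxon\tcount\tselected\tflag\n")
        for p in profiles:
            for taxon in sorted(p.counts):
                fh.write(
                    f"{p.sample_id}\t{taxon}\t{p.counts[taxon]}\t"
                    f"{int(taxon in p.selected)}\t{p.flags.get(taxon, '')}\n"
                )


def read_profiles(path: str | Path) -> list[SampleProfile]:
    rows: dict[str, SampleProfile] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sample_id\t"):
            raise ValueError("not a profile table (missing header)")
        for line in fh:
            sample_id, taxon, count, selected, flag = line.rstrip("\n").split("\t")
            prof = rows.setdefault(sample_id, SampleProfile(sample_id=sample_id))
            prof.counts[taxon] = int(count)
            if selected == "1":
                prof.selected.add(taxon)
            if flag:
                prof.flags[taxon] = flag
    return list(rows.values())
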