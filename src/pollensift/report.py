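"""Contamination accounting and abundance reporting.

Answers the questions a surface-sterilisation experiment asks of its
profiles: what fraction of each sample's assigned units is *not* explained
by the known diet (contamination), in how many replicates of each treatment
group a target (spiked) taxon is detected, and what the absolute and
proportional levels of that target are per group.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import EmptyInputError
from .profile import SampleProfile
from .taxonomy import TaxonLineage, lineages_compatible

GroupKey = tuple[str, str]  # (sample-type, treatment)


@dataclass(frozen=True)
class ContaminationReport:
    sample_id: str
    diet_taxa: frozenset[str]
    pct_contaminant: float
    flag_over_threshold: bool
    threshold: float = 5.0

    def __post_init__(self):
        if not 0.0 <= self.pct_contaminant <= 100.0:
            raise ValueError("pct_contaminant outside [0, 100]")


@dataclass(frozen=True)
class DetectionMatrix:
    """Replicate-detection counts per (sample-type, treatment) group."""

    target_taxon: str
    cells: dict[GroupKey, tuple[int, int]]  # (n_detected, n_replicates)

    def __post_init__(self):
        for key, (d, n) in self.cells.items():
            if not 0 <= d <= n:
                raise ValueError(f"group {key}: detected {d} of {n}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_type": k[0],
                "treatment": k[1],
                "n_detected": d,
                "n_replicates": n,
            }
            for k, (d, n) in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows)


def _parse_label(label: str) -> TaxonLineage:
    """Lenient label parse: full lineage strings preferred, a bare name is
    taken as a genus-level label."""
    try:
        return TaxonLineage.from_string(label)
    except ValueError:
        return TaxonLineage.from_names(genus=label)


def _matches_any(label: str, diet_lineages: list[TaxonLineage]) -> bool:
    lin = _parse_label(label)
    return any(lineages_compatible(lin, d) for d in diet_lineages)


def _target_count(profile: SampleProfile, target: TaxonLineage) -> int:
    return sum(
        n
        for label, n in profile.counts.items()
        if lineages_compatible(_parse_label(label), target)
    )


def contamination_fraction(
    profile: SampleProfile,
    diet_taxa: set[str],
    threshold: float = 5.0,
) -> ContaminationReport:
    """Percentage of assigned units not attributable to the diet.

    Diet matching is rank-aware: a profile label matches a diet taxon when
    either lineage is an ancestor of the other, so a genus-level diet entry
    claims its species-level detections.  The over-threshold flag is a
    *strict* inequality — a sample at exactly the threshold is not flagged.
    """
    if profile.total_units == 0:
        raise EmptyInputError(
            f"sample {profile.sample_id!r} has no assigned units"
        )
    diet_lineages = [_parse_label(t) for t in diet_taxa]
    contaminant = sum(
        n
        for label, n in profile.counts.items()
        if not _matches_any(label, diet_lineages)
    )
    pct = 100.0 * contaminant / profile.total_units
    return ContaminationReport(
        sample_id=profile.sample_id,
        diet_taxa=frozenset(diet_taxa),
        pct_contaminant=pct,
        flag_over_threshold=pct > threshold,
        threshold=threshold,
    )


def detection_matrix(
    groups: dict[GroupKey, list[SampleProfile]],
    target_taxon: str,
    presence_min_count: int = 1,
) -> DetectionMatrix:
    """Replicates per group in which the target taxon is present.

    Presence means at least ``presence_min_count`` units across all labels
    compatible with the target lineage (default: a single read counts).
    """
    if not groups or any(len(v) == 0 for v in groups.values()):
        raise EmptyInputError("every replicate group must be non-empty")
    target = _parse_label(target_taxon)
    cells = {}
    for key, replicates in groups.items():
        detected = sum(
            1 for p in replicates if _target_count(p, target) >= presence_min_count
        )
        cells[key] = (detected, len(replicates))
    return DetectionMatrix(target_taxon=target_taxon, cells=cells)


def group_target_summary(
    groups: dict[GroupKey, list[SampleProfile]],
    target_taxon: str,
) -> dict[GroupKey, dict[str, float]]:
    """Mean absolute target count and min-max proportion range per group.

    Proportions are 100 * target units / total units per replicate; a
    replicate with no assigned units contributes a 0% proportion.
    """
    if not groups or any(len(v) == 0 for v in groups.values()):
        raise EmptyInputError("every replicate group must be non-empty")
    target = _parse_label(target_taxon)
    out = {}
    for key, replicates in groups.items():
        counts = [_target_count(p, target) for p in replicates]
        pcts = [
            (100.0 * c / p.total_units) if p.total_units else 0.0
            for c, p in zip(counts, replicates)
        ]
        out[key] = {
            "mean_count": sum(counts) / len(counts),
            "pct_min": min(pcts),
            "pct_max": max(pcts),
        }
    return out


def abundance_matrix(profiles: list[SampleProfile]) -> pd.DataFrame:
    """Taxon x sample count table; absent taxa are 0, orders lexicographic."""
    if not profiles:
        return pd.DataFrame()
    taxa = sorted({t for p in profiles for t in p.counts})
    samples = sorted(p.sample_id for p in profiles)
    by_id = {p.sample_id: p for p in profiles}
    data = {
        s: [by_id[s].counts.get(t, 0) for t in taxa] for s in samples
    }
    return pd.DataFrame(data, index=taxa, columns=samples)


def plot_relative_abundance(profiles: list[SampleProfile], ax=None):
    """Stacked-bar relative abundance of taxa per sample (fractions of the
    per-sample total)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.0 + 0.6 * len(profiles), 4.0))
    matrix = abundance_matrix(profiles)
    rel = matrix / matrix.sum(axis=0).replace(0, 1)
    bottom = None
    for taxon, row in rel.iterrows():
        short = _parse_label(taxon).display_name or taxon
        ax.bar(rel.columns, row.values, bottom=bottom, label=short)
        bottom = row.values if bottom is None else bottom + row.values
    ax.set_ylabel("relative abundance")
    ax.set_ylim(0, 1)
    ax.legend(fontsize="small", bbox_to_anchor=(1.02, 1), loc="upper left")
    return ax
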