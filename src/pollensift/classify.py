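"""Hit filtering and majority-rule lowest-common-ancestor read assignment.

Each read's hits pass a two-step filter — (1) percent identity >= 80 and
alignment coverage >= 80% of the read, (2) bitscore within 5% of the best
surviving hit — and the surviving hits' lineages are put to a 75% majority
vote that starts at species and ascends rank by rank until some taxon at the
rank reaches the majority.  Reads whose hits never agree are *Unresolved*;
reads with no surviving hits at all are *Unassigned* — a distinction kept
because both classes are excluded from downstream profiles for different
reasons.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from .align import AlignmentHit
from .errors import EmptyInputError
from .readqc import Read
from .refdb import ReferenceDB
from .taxonomy import RANKS, TaxonLineage

ASSIGNED = "Assigned"
UNRESOLVED = "Unresolved"
UNASSIGNED = "Unassigned"

# float guard for expressions like count >= fraction * n where the product
# is not exactly representable
_EPS = 1e-9


@dataclass(frozen=True)
class HitFilterConfig:
    min_pct_identity: float = 80.0
    min_coverage: float = 80.0
    bitscore_window: float = 0.05
    coverage_denominator: str = "read"  # "read" | "reference" | "amplicon"
    amplicon_len: int | None = None

    def __post_init__(self):
        if not 0 <= self.min_pct_identity <= 100:
            raise ValueError("min_pct_identity outside [0, 100]")
        if not 0 <= self.min_coverage <= 100:
            raise ValueError("min_coverage outside [0, 100]")
        if not 0 <= self.bitscore_window <= 1:
            raise ValueError("bitscore_window outside [0, 1]")
        if self.coverage_denominator not in ("read", "reference", "amplicon"):
            raise ValueError("coverage_denominator must be read|reference|amplicon")


@dataclass(frozen=True)
class LCAConfig:
    majority_fraction: float = 0.75
    #: vote denominator: all surviving hits (True, conservative default) or
    #: only hits annotated at the rank under consideration (False)
    count_unranked: bool = True

    def __post_init__(self):
        if not 0.5 < self.majority_fraction <= 1.0:
            raise ValueError("majority_fraction must be in (0.5, 1]")


@dataclass(frozen=True)
class Assignment:
    read_id: str
    status: str
    lineage: TaxonLineage | None = None
    n_hits_used: int = 0

    def __post_init__(self):
        if self.status not in (ASSIGNED, UNRESOLVED, UNASSIGNED):
            raise ValueError(f"unknown status {self.status!r}")
        if (self.status == ASSIGNED) != (self.lineage is not None):
            raise ValueError("lineage must be present iff status is Assigned")


def filter_hits(
    hits: list[AlignmentHit],
    read_len: int,
    cfg: HitFilterConfig = HitFilterConfig(),
    ref_lengths: dict[str, int] | None = None,
) -> list[AlignmentHit]:
    """Identity/coverage filter, then the top-bitscore window.

    Strictly two steps in this order: the 5% bitscore window is anchored at
    the best hit *among identity/coverage survivors*, not the overall best.
    Coverage is ``100 * aln_len / denominator`` with the read length as the
    default denominator.
    """
    if read_len <= 0:
        raise ValueError("read_len must be positive")

    def _denominator(hit: AlignmentHit) -> float:
        if cfg.coverage_denominator == "read":
            return float(read_len)
        if cfg.coverage_denominator == "amplicon":
            if cfg.amplicon_len is None:
                raise ValueError("amplicon_len required for amplicon coverage")
            return float(cfg.amplicon_len)
        if ref_lengths is None:
            raise ValueError("ref_lengths required for reference coverage")
        return float(ref_lengths[hit.ref_id])

    step1 = [
        h
        for h in hits
        if h.pct_identity >= cfg.min_pct_identity - _EPS
        and 100.0 * h.aln_len / _denominator(h) >= cfg.min_coverage - _EPS
    ]
    if not step1:
        return []
    best = max(h.bitscore for h in step1)
    cutoff = (1.0 - cfg.bitscore_window) * best
    return [h for h in step1 if h.bitscore >= cutoff - _EPS]


def majority_lca(
    lineages: list[TaxonLineage], cfg: LCAConfig = LCAConfig()
) -> tuple[str, TaxonLineage | None]:
    """Majority vote ascending from species toward kingdom.

    At each rank the candidate taxa are the distinct kingdom->rank name
    paths among lineages annotated at that rank (voting on full paths, not
    bare names, so genus homonyms in different families never pool votes).
    The vote denominator is all ``n`` lineages by default; lineages missing
    the rank simply cannot support any candidate there.
    """
    if not lineages:
        raise EmptyInputError("majority_lca of an empty lineage list")
    n = len(lineages)
    for rank in reversed(RANKS):  # species first, kingdom last
        annotated = [lin for lin in lineages if lin.name_at(rank) is not None]
        if not annotated:
            continue
        denom = n if cfg.count_unranked else len(annotated)
        counts = Counter(lin.prefix_through(rank) for lin in annotated)
        path, count = counts.most_common(1)[0]
        if count >= cfg.majority_fraction * denom - _EPS:
            winner = TaxonLineage(path + (None,) * (len(RANKS) - len(path)))
            return ASSIGNED, winner
    return UNRESOLVED, None


def classify_read(
    read: Read,
    hits: list[AlignmentHit],
    db: ReferenceDB,
    hcfg: HitFilterConfig = HitFilterConfig(),
    lcfg: LCAConfig = LCAConfig(),
) -> Assignment:
    """Filter hits, map survivors to lineages, and vote.

    Each surviving hit contributes one vote, even when several hits point at
    references with identical annotation.  No surviving hits means
    *Unassigned*.
    """
    surviving = filter_hits(hits, len(read), hcfg)
    if not surviving:
        return Assignment(read.id, UNASSIGNED, None, 0)
    lineages = [db.lineage_for(h.ref_id) for h in surviving]
    status, lineage = majority_lca(lineages, lcfg)
    return Assignment(read.id, status, lineage, len(surviving))


def classify_sample(
    reads: list[Read],
    hits_by_read: dict[str, list[AlignmentHit]],
    db: ReferenceDB,
    hcfg: HitFilterConfig = HitFilterConfig(),
    lcfg: LCAConfig = LCAConfig(),
) -> list[Assignment]:
    return [
        classify_read(r, hits_by_read.get(r.id, []), db, hcfg, lcfg)
        for r in reads
    ]


# -- assignment TSV ----------------------------------------------------


def write_assignments(assignments: list[Assignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tstatus\trank\tlineage\tn_hits_used\n")
        for a in assignments:
            rank = a.lineage.deepest_rank if a.lineage else ""
            lineage = a.lineage.to_string() if a.lineage else ""
            fh.write(f"{a.read_id}\t{a.status}\t{rank}\t{lineage}\t{a.n_hits_used}\n")


def read_assignments(path: str | Path) -> list[Assignment]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id\t"):
            raise ValueError("not an assignment table (missing header)")
        for line in fh:
            read_id, status, _rank, lineage, n_used = line.rstrip("\n").split("\t")
            out.append(
                Assignment(
                    read_id,
                    status,
                    TaxonLineage.from_string(lineage) if lineage else None,
                    int(n_used),
                )
            )
    return out
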