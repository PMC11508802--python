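"""Reference database curation for the rbcLa amplicon.

Builds the search target from locally supplied reference FASTA plus a
taxonomy table: each reference is trimmed to the amplicon region between the
PCR primers, screened against degenerate-base / homopolymer / length filters,
and dereplicated so that no two records share both an identical sequence and
an identical taxonomic annotation (records with equal sequence but different
taxonomy are deliberately both retained).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .errors import TaxonomyLookupError
from .sequtils import (
    IUPAC_SETS,
    find_primer_matches,
    longest_homopolymer,
    revcomp,
    validate_iupac,
)
from .taxonomy import TaxonLineage


@dataclass(frozen=True)
class RefCurationConfig:
    """Primer pair and quality thresholds for reference curation.

    The degenerate-base, homopolymer and length thresholds are deliberately
    config-exposed defaults, comparable to what common reference-curation
    tools apply to rbcL: at most 5 non-ACGT bases, no single-base run longer
    than 8, amplicon length within [500, 700].
    """

    fwd_primer: str
    rev_primer: str
    max_primer_mismatch: int = 2
    max_degenerate_bases: int = 5
    max_homopolymer_run: int = 8
    min_len: int = 500
    max_len: int = 700

    def __post_init__(self):
        if not self.fwd_primer or not self.rev_primer:
            raise ValueError("primers must be non-empty")
        validate_iupac(self.fwd_primer, context="fwd_primer")
        validate_iupac(self.rev_primer, context="rev_primer")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        for name in ("max_primer_mismatch", "max_degenerate_bases",
                     "max_homopolymer_run", "min_len", "max_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ReferenceRecord:
    """One curated amplicon sequence with its ranked taxonomy."""

    id: str
    sequence: str
    lineage: TaxonLineage

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        validate_iupac(self.sequence, context=f"record {self.id!r}")


@dataclass
class ReferenceDB:
    """The curated, dereplicated amplicon database searched by the aligner."""

    records: list[ReferenceRecord] = field(default_factory=list)
    curation_config: RefCurationConfig | None = None
    provenance: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self._kmer_cache: dict[int, dict[str, set[str]]] = {}

    def __len__(self) -> int:
        return len(self.records)

    def lineage_for(self, ref_id: str) -> TaxonLineage:
        try:
            return self._by_id()[ref_id].lineage
        except KeyError:
            raise TaxonomyLookupError(
                f"hit references unknown reference id {ref_id!r}"
            ) from None

    def sequence_for(self, ref_id: str) -> str:
        try:
            return self._by_id()[ref_id].sequence
        except KeyError:
            raise TaxonomyLookupError(
                f"unknown reference id {ref_id!r}"
            ) from None

    def _by_id(self) -> dict[str, ReferenceRecord]:
        # ids may legitimately repeat only before dereplication; last wins is
        # never relied upon because build_db output ids are unique
        if not hasattr(self, "_id_map") or len(self._id_map) != len(self.records):
            self._id_map = {r.id: r for r in self.records}
        return self._id_map

    def kmer_index(self, k: int) -> dict[str, set[str]]:
        """Exact k-mer -> reference-id index (cached per k)."""
        if k not in self._kmer_cache:
            index: dict[str, set[str]] = {}
            for rec in self.records:
                s = rec.sequence
                for i in range(len(s) - k + 1):
                    index.setdefault(s[i : i + k], set()).add(rec.id)
            self._kmer_cache[k] = index
        return self._kmer_cache[k]

    # -- persistence --------------------------------------------------

    def write(self, fasta_path: str | Path, tax_path: str | Path) -> None:
        with open(fasta_path, "w") as fh:
            for rec in self.records:
                fh.write(f">{rec.id}\n{rec.sequence}\n")
        with open(tax_path, "w") as fh:
            for rec in self.records:
                fh.write(f"{rec.id}\t{rec.lineage.to_string()}\n")

    @classmethod
    def read(cls, fasta_path: str | Path, tax_path: str | Path) -> "ReferenceDB":
        taxa = _read_tax_table(tax_path)
        records = []
        for sr in SeqIO.parse(str(fasta_path), "fasta"):
            if sr.id not in taxa:
                raise TaxonomyLookupError(
                    f"reference {sr.id!r} has no taxonomy row"
                )
            records.append(
                ReferenceRecord(sr.id, str(sr.seq).upper(), taxa[sr.id])
            )
        return cls(records=records)


def _find_amplicon_on_strand(seq: str, cfg: RefCurationConfig) -> str | None:
    fwd = find_primer_matches(seq, cfg.fwd_primer, cfg.max_primer_mismatch)
    if not fwd:
        return None
    f_start, _ = fwd[0]  # leftmost forward match: maximal amplicon
    f_end = f_start + len(cfg.fwd_primer)
    rc_rev = revcomp(cfg.rev_primer)
    rev = [
        (start, mm)
        for start, mm in find_primer_matches(seq, rc_rev, cfg.max_primer_mismatch)
        if start >= f_end
    ]
    if not rev:
        return None
    r_start, _ = rev[-1]  # rightmost reverse match
    return seq[f_end:r_start]


def trim_to_amplicon(seq: str, cfg: RefCurationConfig) -> str | None:
    """Extract the amplicon strictly between the primer pair.

    Searches both strands, allowing up to ``cfg.max_primer_mismatch``
    IUPAC-aware mismatches per primer, and returns the amplicon in forward
    orientation; ``None`` when either primer is not found within tolerance.
    Among multiple primer matches the leftmost forward and rightmost reverse
    are taken, giving the maximal amplicon deterministically.
    """
    validate_iupac(seq)
    amplicon = _find_amplicon_on_strand(seq, cfg)
    if amplicon is None:
        amplicon = _find_amplicon_on_strand(revcomp(seq), cfg)
    return amplicon


def reference_passes_filters(seq: str, cfg: RefCurationConfig) -> bool:
    """Degenerate-base count, homopolymer run, and length screen."""
    validate_iupac(seq)
    n_degenerate = sum(1 for ch in seq if ch not in "ACGT")
    return (
        n_degenerate <= cfg.max_degenerate_bases
        and longest_homopolymer(seq) <= cfg.max_homopolymer_run
        and cfg.min_len <= len(seq) <= cfg.max_len
    )


def dereplicate(records: list[ReferenceRecord]) -> list[ReferenceRecord]:
    """Drop records identical in both sequence and full taxonomic annotation.

    The first-seen record of each (sequence, lineage) pair survives, in input
    order.  Records sharing a sequence but annotated with different taxonomy
    are both kept — they are distinct taxa that happen to be indistinguishable
    at this marker.
    """
    seen: set[tuple[str, str]] = set()
    out = []
    for rec in records:
        key = (rec.sequence, rec.lineage.to_string())
        if key not in seen:
            seen.add(key)
            out.append(rec)
    return out


def _read_tax_table(tax_path: str | Path) -> dict[str, TaxonLineage]:
    taxa: dict[str, TaxonLineage] = {}
    with open(tax_path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or not row[0].strip():
                continue
            if len(row) < 2:
                raise ValueError(
                    f"taxonomy row for {row[0]!r} lacks a lineage column"
                )
            taxa[row[0].strip()] = TaxonLineage.from_string(row[1])
    return taxa


def build_db(
    ref_fasta: str | Path,
    tax_table: str | Path,
    cfg: RefCurationConfig,
) -> ReferenceDB:
    """Full curation pipeline: parse -> trim -> filter -> dereplicate.

    Every FASTA id must have a taxonomy row (a missing row is an error naming
    the id).  Per-step drop counts are recorded in ``provenance``:
    ``no_amplicon`` (primers not found), ``failed_filter``, ``duplicate``.
    """
    taxa = _read_tax_table(tax_table)
    drops = {"no_amplicon": 0, "failed_filter": 0, "duplicate": 0}
    trimmed: list[ReferenceRecord] = []
    n_input = 0
    for sr in SeqIO.parse(str(ref_fasta), "fasta"):
        n_input += 1
        if sr.id not in taxa:
            raise TaxonomyLookupError(
                f"reference {sr.id!r} has no taxonomy row"
            )
        seq = str(sr.seq).upper()
        bad = set(seq) - IUPAC_SETS.keys()
        if bad:
            drops["failed_filter"] += 1
            continue
        amplicon = trim_to_amplicon(seq, cfg)
        if amplicon is None:
            drops["no_amplicon"] += 1
            continue
        if not reference_passes_filters(amplicon, cfg):
            drops["failed_filter"] += 1
            continue
        trimmed.append(ReferenceRecord(sr.id, amplicon, taxa[sr.id]))
    unique = dereplicate(trimmed)
    drops["duplicate"] = len(trimmed) - len(unique)
    provenance = {"n_input": n_input, "n_output": len(unique), **drops}
    return ReferenceDB(records=unique, curation_config=cfg, provenance=provenance)
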