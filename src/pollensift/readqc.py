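"""ONT amplicon read trimming, filtering, and QC summary statistics.

Reads are primer-trimmed (qualities sliced in lockstep), then filtered on a
length window and a per-read mean quality threshold.  Defaults follow the
amplicon study conditions this package models: keep reads of 450-650 bases
(both bounds inclusive — the discards are reads *longer than* 650 or
*shorter than* 450) with mean Phred >= 7.

The per-read quality statistic defaults to the arithmetic mean of per-base
Phred values; error-space averaging (mean of per-base error probabilities,
re-expressed as a Phred value) is available via ``ReadFilterConfig.q_average``.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .errors import EmptyInputError
from .sequtils import find_primer_matches, revcomp, validate_iupac


@dataclass(frozen=True)
class Read:
    """A quality-scored amplicon read (qualities are integer Phred values)."""

    id: str
    bases: str
    quals: tuple[int, ...]
    sample_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "quals", tuple(self.quals))
        if len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases vs "
                f"{len(self.quals)} quality values"
            )
        if self.quals and not all(0 <= q <= 93 for q in self.quals):
            raise ValueError(f"read {self.id!r}: Phred values outside [0, 93]")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class ReadFilterConfig:
    min_len: int = 450
    max_len: int = 650
    min_mean_q: float = 7.0
    q_average: str = "phred"  # "phred" (mean of Q) or "error" (mean of p)

    def __post_init__(self):
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.min_mean_q < 0:
            raise ValueError("min_mean_q must be >= 0")
        if self.q_average not in ("phred", "error"):
            raise ValueError("q_average must be 'phred' or 'error'")


@dataclass(frozen=True)
class QCReport:
    """Per-sample QC summary.

    ``median_len`` and ``mean_q`` describe the *kept* reads; the counts and
    discard percentage compare input against kept.
    """

    n_input: int
    n_output: int
    median_len: float = 0.0
    mean_q: float = 0.0

    @property
    def pct_discarded(self) -> float:
        if self.n_input == 0:
            return 0.0
        return 100.0 * (self.n_input - self.n_output) / self.n_input

    @property
    def error_rate_pct(self) -> float:
        return phred_to_error_pct(self.mean_q)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_output": self.n_output,
            "pct_discarded": self.pct_discarded,
            "median_len": self.median_len,
            "mean_q": self.mean_q,
            "error_rate_pct": self.error_rate_pct,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def __str__(self) -> str:
        return (
            f"reads in: {self.n_input}  kept: {self.n_output} "
            f"({self.pct_discarded:.1f}% discarded)\n"
            f"kept median length: {self.median_len:.0f} b\n"
            f"kept mean Phred: {self.mean_q:.1f} "
            f"(~{self.error_rate_pct:.1f}% error)"
        )


def mean_phred(quals) -> float:
    """Arithmetic mean of integer Phred values."""
    quals = list(quals)
    if not quals:
        raise EmptyInputError("mean_phred of an empty quality list")
    return sum(quals) / len(quals)


def phred_to_error_pct(q: float) -> float:
    """Phred score -> per-base error percentage, 100 * 10^(-q/10)."""
    if q < 0:
        raise ValueError("Phred score must be >= 0")
    return 100.0 * 10.0 ** (-q / 10.0)


def _read_quality(read: Read, mode: str) -> float:
    if mode == "phred":
        return mean_phred(read.quals)
    p = np.mean([10.0 ** (-q / 10.0) for q in read.quals])
    return float(-10.0 * np.log10(p))


def trim_read(
    read: Read, fwd_primer: str, rev_primer: str, max_mismatch: int = 2
) -> Read:
    """Remove primers and anything outside them from both ends.

    Each end is trimmed independently where its primer is found within
    tolerance.  If no primer is found on the forward strand, the
    reverse-complement orientation is tried, and the read is re-oriented
    forward when found there.  Reads without any primer are returned
    unchanged.
    """
    validate_iupac(fwd_primer, context="fwd_primer")
    validate_iupac(rev_primer, context="rev_primer")

    def _trim_oriented(bases: str, quals: tuple[int, ...]):
        fwd = find_primer_matches(bases, fwd_primer, max_mismatch)
        start = fwd[0][0] + len(fwd_primer) if fwd else 0
        rc_rev = revcomp(rev_primer)
        rev = [
            (s, mm)
            for s, mm in find_primer_matches(bases, rc_rev, max_mismatch)
            if s >= start
        ]
        end = rev[-1][0] if rev else len(bases)
        found = bool(fwd or rev)
        return found, bases[start:end], quals[start:end]

    found, bases, quals = _trim_oriented(read.bases, read.quals)
    if not found:
        rc_bases = revcomp(read.bases)
        rc_quals = read.quals[::-1]
        found, bases, quals = _trim_oriented(rc_bases, rc_quals)
        if not found:
            return read
    return Read(read.id, bases, quals, read.sample_id)


def filter_reads(
    reads: list[Read], cfg: ReadFilterConfig = ReadFilterConfig()
) -> tuple[list[Read], QCReport]:
    """Length-window plus mean-quality filter, with a QC summary.

    Boundary semantics are inclusive: reads of exactly ``min_len`` or exactly
    ``max_len`` bases are kept (only strictly shorter/longer reads are
    discarded).
    """
    kept = [
        r
        for r in reads
        if cfg.min_len <= len(r) <= cfg.max_len
        and _read_quality(r, cfg.q_average) >= cfg.min_mean_q
    ]
    if kept:
        lengths = sorted(len(r) for r in kept)
        median_len = float(lengths[(len(lengths) - 1) // 2])  # lower median
        mean_q = float(np.mean([mean_phred(r.quals) for r in kept]))
    else:
        median_len = 0.0
        mean_q = 0.0
    report = QCReport(
        n_input=len(reads),
        n_output=len(kept),
        median_len=median_len,
        mean_q=mean_q,
    )
    return kept, report


# -- FASTQ IO (Phred+33, gzip-transparent) ----------------------------


def _open_maybe_gzip(path: str | Path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path: str | Path, sample_id: str = "") -> list[Read]:
    with _open_maybe_gzip(path, "r") as fh:
        return [
            Read(
                rec.id,
                str(rec.seq).upper(),
                tuple(rec.letter_annotations["phred_quality"]),
                sample_id,
            )
            for rec in SeqIO.parse(fh, "fastq")
        ]


def write_fastq(reads: list[Read], path: str | Path) -> None:
    with _open_maybe_gzip(path, "w") as fh:
        for r in reads:
            qual_str = "".join(chr(min(q, 93) + 33) for q in r.quals)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{qual_str}\n")
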