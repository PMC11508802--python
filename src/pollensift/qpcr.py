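"""TaqMan CT summarisation: replicate averaging, detection calls, and the
UV time-course trend.

CT (cycle threshold) is the qPCR cycle at which fluorescence crosses the
detection threshold; lower CT means more template.  Runs are capped at 40
cycles, so a CT of 40 is a censored "no detection" value.  Censored 40s are
kept as point values when averaging (not dropped, not imputed), which is the
convention that makes a replicate pair like (40, 40) average to exactly 40
and be called undetected.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import EmptyInputError


@dataclass(frozen=True)
class CTRecord:
    assay: str  # "COX", "NAD", or other assay names
    sample_label: str
    replicate_cts: tuple[float, ...]
    max_cycles: int = 40

    def __post_init__(self):
        object.__setattr__(self, "replicate_cts", tuple(self.replicate_cts))
        if not self.replicate_cts:
            raise EmptyInputError(
                f"CT record {self.sample_label!r} has no replicates"
            )
        for ct in self.replicate_cts:
            if not 0 < ct <= self.max_cycles:
                raise ValueError(
                    f"CT {ct} outside (0, {self.max_cycles}] "
                    f"for {self.sample_label!r}"
                )


def raw_average_ct(rec: CTRecord) -> float:
    """Plain arithmetic mean of replicate CTs (censored 40s included)."""
    return float(np.mean(rec.replicate_cts))


def average_ct(rec: CTRecord) -> float:
    """Replicate mean rounded half-up to 2 decimals for reporting.

    The mean is taken in decimal arithmetic on the replicates' printed form,
    so a pair like (29.81, 30.18) averages to exactly 29.995 and rounds
    half-up to 30.00 rather than falling to 29.99 through binary floating
    point.  The unrounded value is available via :func:`raw_average_ct`.
    """
    total = sum(Decimal(repr(ct)) for ct in rec.replicate_cts)
    mean = total / len(rec.replicate_cts)
    return float(mean.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def format_ct(value: float) -> str:
    """Printed form: 2 decimals, trailing zeros (and bare point) trimmed."""
    s = f"{value:.2f}".rstrip("0").rstrip(".")
    return s if s else "0"


def detection_call(rec: CTRecord) -> bool:
    """Detected iff the (unrounded) replicate average is strictly below the
    cycle cap."""
    return raw_average_ct(rec) < rec.max_cycles


@dataclass(frozen=True)
class UVTrendResult:
    rank_correlation: float  # Spearman rho of CT against exposure time
    monotone_increasing: bool  # strict increase of CT along the series
    pearson_r: float

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.rank_correlation <= 1.0 + 1e-12:
            raise ValueError("rank correlation outside [-1, 1]")


def uv_trend(times: list[float], avg_cts: list[float]) -> UVTrendResult:
    """Dose-response trend of CT against UV exposure time.

    Rising CT with exposure time means falling amounts of intact template —
    i.e. progressive DNA degradation.  Rank (Spearman) correlation is the
    headline statistic because no linearity is assumed; Pearson r is also
    reported.  The monotone flag requires a strict increase at every step.
    """
    if len(times) != len(avg_cts):
        raise EmptyInputError(
            f"length mismatch: {len(times)} times vs {len(avg_cts)} CTs"
        )
    if len(times) < 3:
        raise EmptyInputError("need at least 3 time points")
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("times must be strictly increasing")
    rho = float(stats.spearmanr(times, avg_cts).statistic)
    r = float(stats.pearsonr(times, avg_cts).statistic)
    monotone = all(b > a for a, b in zip(avg_cts, avg_cts[1:]))
    return UVTrendResult(rho, monotone, r)


# -- CSV IO ------------------------------------------------------------


def read_ct_csv(path: str | Path) -> list[CTRecord]:
    """Read ``assay,sample,rep1_ct,rep2_ct,...`` rows (header optional,
    detected by a non-numeric third field; ragged replicate counts fine)."""
    records = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or not row[0].strip():
                continue
            if len(row) < 3:
                raise ValueError(f"CT row too short: {row!r}")
            try:
                cts = tuple(float(x) for x in row[2:] if x.strip())
            except ValueError:
                continue  # header row
            records.append(CTRecord(row[0].strip(), row[1].strip(), cts))
    return records


def summarise_ct(records: list[CTRecord]) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        {
            "assay": [r.assay for r in records],
            "sample": [r.sample_label for r in records],
            "average_ct": [average_ct(r) for r in records],
            "average_ct_printed": [format_ct(average_ct(r)) for r in records],
            "detected": [detection_call(r) for r in records],
        }
    )
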