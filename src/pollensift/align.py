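"""Per-read alignment against the reference database.

Two routes produce :class:`AlignmentHit` lists: a built-in seeded local
aligner (exact k-mer candidate selection followed by affine-gap local
alignment on both strands, backed by biotite's optimal-alignment kernel), and
ingestion of an external 12-column tabular hit file in the classic
``outfmt 6`` dialect, so that hits computed by an external search tool drop
into the same downstream classification.

The built-in aligner is desk-scale plumbing, not a production search engine:
no E-values from database statistics, no heuristic extensions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import biotite.sequence as bseq
import biotite.sequence.align as balign

from .errors import HitTableParseError
from .readqc import Read
from .refdb import ReferenceDB
from .sequtils import revcomp

HIT_TABLE_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch/affine-gap scores plus Karlin-Altschul parameters.

    Defaults mirror common megablast-style scoring (+2/-3, gap open -5,
    extend -2, lambda 0.625, K 0.41) so that the downstream 5% bitscore
    window behaves comparably to an external search.  A gap of length n
    costs ``gap_open + (n - 1) * gap_extend``.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    lam: float = 0.625
    k: float = 0.41

    def __post_init__(self):
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("lambda and K must be positive")

    def bitscore(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.k)) / math.log(2.0)


@dataclass(frozen=True)
class AlignmentHit:
    """One read-vs-reference local alignment (outfmt-6-shaped).

    Coordinates are 1-based inclusive.  A reverse-strand alignment is noted
    by ``read_start > read_end`` (coordinates on the original read).
    ``evalue`` is absent (None) for hits from the internal aligner.
    """

    read_id: str
    ref_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    bitscore: float
    evalue: float | None = None
    raw_score: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity outside [0, 100]")
        if self.aln_len < 1:
            raise ValueError("aln_len must be >= 1")
        if not math.isfinite(self.bitscore):
            raise ValueError("bitscore must be finite")


@lru_cache(maxsize=8)
def _substitution_matrix(match: int, mismatch: int) -> balign.SubstitutionMatrix:
    alph = bseq.NucleotideSequence.alphabet_amb
    n = len(alph)
    mat = np.full((n, n), mismatch, dtype=np.int32)
    np.fill_diagonal(mat, match)
    return balign.SubstitutionMatrix(alph, alph, mat)


def _align_one_strand(read_seq: str, ref_seq: str, scheme: ScoringScheme):
    """Best local alignment of one strand; returns None for score <= 0."""
    s_read = bseq.NucleotideSequence(read_seq, ambiguous=True)
    s_ref = bseq.NucleotideSequence(ref_seq, ambiguous=True)
    matrix = _substitution_matrix(scheme.match, scheme.mismatch)
    alns = balign.align_optimal(
        s_read,
        s_ref,
        matrix,
        gap_penalty=(scheme.gap_open, scheme.gap_extend),
        local=True,
        max_number=1,
    )
    if not alns or alns[0].score <= 0:
        return None
    return alns[0]


def _hit_from_alignment(
    aln, read_seq: str, ref_seq: str, read_id: str, ref_id: str,
    scheme: ScoringScheme, reverse: bool, read_len: int,
) -> AlignmentHit:
    trace = aln.trace  # (columns, 2); -1 marks a gap
    ri, si = trace[:, 0], trace[:, 1]
    both = (ri >= 0) & (si >= 0)
    read_arr = np.frombuffer(read_seq.encode(), dtype="S1")
    ref_arr = np.frombuffer(ref_seq.encode(), dtype="S1")
    matches = int(np.sum(read_arr[ri[both]] == ref_arr[si[both]]))
    aln_len = int(trace.shape[0])
    mism = int(both.sum()) - matches
    gap_opens = 0
    for col in (ri, si):
        gapped = col < 0
        gap_opens += int(np.sum(gapped[1:] & ~gapped[:-1]) + (1 if gapped[0] else 0))
    q0, q1 = int(ri[ri >= 0].min()) + 1, int(ri[ri >= 0].max()) + 1
    s0, s1 = int(si[si >= 0].min()) + 1, int(si[si >= 0].max()) + 1
    if reverse:
        # map back onto the original read; start > end flags the strand
        q0, q1 = read_len - q0 + 1, read_len - q1 + 1
    return AlignmentHit(
        read_id=read_id,
        ref_id=ref_id,
        pct_identity=100.0 * matches / aln_len,
        aln_len=aln_len,
        mismatches=mism,
        gap_opens=gap_opens,
        read_start=q0,
        read_end=q1,
        ref_start=s0,
        ref_end=s1,
        bitscore=scheme.bitscore(aln.score),
        raw_score=int(aln.score),
    )


def local_align(
    read_seq: str,
    ref_seq: str,
    scheme: ScoringScheme = ScoringScheme(),
    read_id: str = "read",
    ref_id: str = "ref",
    strands: str = "both",
) -> AlignmentHit | None:
    """Best affine-gap local alignment of a read against one reference.

    Both strands of the read are tried (unless ``strands`` restricts to
    ``"fwd"`` or ``"rev"``) and the better-scoring one kept; ties favour the
    forward strand.  Percent identity counts exact base matches over all
    alignment columns (gap columns included in the denominator).  Returns
    None when no alignment scores above zero.
    """
    if not read_seq or not ref_seq:
        raise ValueError("sequences must be non-empty")
    candidates = []
    if strands in ("both", "fwd"):
        aln = _align_one_strand(read_seq, ref_seq, scheme)
        if aln is not None:
            candidates.append((aln.score, 0, aln, read_seq, False))
    if strands in ("both", "rev"):
        rc = revcomp(read_seq)
        aln = _align_one_strand(rc, ref_seq, scheme)
        if aln is not None:
            candidates.append((aln.score, 1, aln, rc, True))
    if not candidates:
        return None
    score, _, aln, oriented, reverse = max(
        candidates, key=lambda c: (c[0], -c[1])
    )
    return _hit_from_alignment(
        aln, oriented, ref_seq, read_id, ref_id, scheme, reverse, len(read_seq)
    )


def search(
    read: Read,
    db: ReferenceDB,
    seed_k: int = 11,
    scheme: ScoringScheme = ScoringScheme(),
) -> list[AlignmentHit]:
    """Seeded search: align only references sharing an exact k-mer seed.

    A reference is a candidate on a given strand when it shares at least one
    exact ``seed_k``-mer with that strand of the read; candidates are then
    locally aligned and all hits returned, sorted by bitscore descending with
    ties broken by reference id (deterministic).
    """
    if len(db) == 0:
        raise ValueError("reference database is empty")
    if seed_k < 4:
        raise ValueError("seed_k must be >= 4")
    index = db.kmer_index(seed_k)

    def _candidates(seq: str) -> set[str]:
        found: set[str] = set()
        for i in range(len(seq) - seed_k + 1):
            found |= index.get(seq[i : i + seed_k], set())
        return found

    fwd_cand = _candidates(read.bases)
    rev_cand = _candidates(revcomp(read.bases))
    hits = []
    for ref_id in sorted(fwd_cand | rev_cand):
        strands = (
            "both"
            if ref_id in fwd_cand and ref_id in rev_cand
            else ("fwd" if ref_id in fwd_cand else "rev")
        )
        hit = local_align(
            read.bases,
            db.sequence_for(ref_id),
            scheme,
            read_id=read.id,
            ref_id=ref_id,
            strands=strands,
        )
        if hit is not None:
            hits.append(hit)
    hits.sort(key=lambda h: (-h.bitscore, h.ref_id))
    return hits


def search_all(
    reads: list[Read],
    db: ReferenceDB,
    seed_k: int = 11,
    scheme: ScoringScheme = ScoringScheme(),
) -> dict[str, list[AlignmentHit]]:
    """Seeded search for a batch of reads, keyed by read id."""
    return {r.id: search(r, db, seed_k, scheme) for r in reads}


# -- 12-column tabular hit files --------------------------------------


def read_hit_table(path: str | Path) -> list[AlignmentHit]:
    """Parse an ``outfmt 6`` TSV into hits, preserving row order.

    Raises :class:`HitTableParseError` (with the 1-based line number) on a
    row with the wrong column count or non-numeric numeric fields.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise HitTableParseError(
                    f"line {lineno}: expected 12 columns, got {len(fields)}",
                    line_number=lineno,
                )
            try:
                hits.append(
                    AlignmentHit(
                        read_id=fields[0],
                        ref_id=fields[1],
                        pct_identity=float(fields[2]),
                        aln_len=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        read_start=int(fields[6]),
                        read_end=int(fields[7]),
                        ref_start=int(fields[8]),
                        ref_end=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise HitTableParseError(
                    f"line {lineno}: {exc}", line_number=lineno
                ) from exc
    return hits


def write_hit_table(hits: list[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            evalue = 0.0 if h.evalue is None else h.evalue
            fh.write(
                "\t".join(
                    [
                        h.read_id,
                        h.ref_id,
                        f"{h.pct_identity:.3f}",
                        str(h.aln_len),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.read_start),
                        str(h.read_end),
                        str(h.ref_start),
                        str(h.ref_end),
                        f"{evalue:.3g}",
                        f"{h.bitscore:.3f}",
                    ]
                )
                + "\n"
            )
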