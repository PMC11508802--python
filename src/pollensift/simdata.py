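"""Synthetic amplicon experiments with ground truth.

Generates the data regime the pipeline is built for: caged-insect samples
whose reads are a mixture of diet-plant amplicons and contaminant-pollen
amplicons at configurable proportions, read with an ONT-like error model
(substitutions : insertions : deletions at 2:1:1, scaled so the total
per-base error rate matches the target mean Phred — Q13.4 corresponds to
about 4.6% error).  Reads are emitted primer-flanked and on random strands
so the trimming and strand-handling stages are exercised end-to-end, and a
truth table records every read's source taxon.

Everything is deterministic per seed; replicate seeds are derived from the
experiment seed so each replicate is independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import edlib
import numpy as np
import pandas as pd

from .errors import SimulationError
from .readqc import Read, write_fastq
from .refdb import ReferenceDB, ReferenceRecord
from .sequtils import IUPAC_SETS, revcomp
from .taxonomy import TaxonLineage

#: rbcLa amplification primer pair (target-specific parts, 5'->3').
DEFAULT_FWD_PRIMER = "TGTCACCACAAACAGAGACTAAAGC"
DEFAULT_REV_PRIMER = "GTAAAATCAAGTCCACCRCG"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """One sample's mixture and error model.

    ``composition`` maps genus names present in the reference set to
    fractions summing to 1.  Error rates default to a 2:1:1
    substitution:insertion:deletion split totalling ``10^(-target_mean_q/10)``
    per base; any rate may be overridden explicitly.
    """

    composition: dict[str, float]
    n_reads: int = 1000
    target_mean_q: float = 13.4
    q_sd: float = 3.0
    sub_rate: float | None = None
    ins_rate: float | None = None
    del_rate: float | None = None
    len_jitter_sd: float = 0.0
    seed: int = 0
    add_primers: bool = True
    revcomp_fraction: float = 0.5

    def __post_init__(self):
        total = sum(self.composition.values())
        if self.composition and abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition fractions sum to {total}, not 1")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        for name in ("sub_rate", "ins_rate", "del_rate"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def effective_rates(self) -> tuple[float, float, float]:
        """(sub, ins, del) per-base rates after the 2:1:1 default split."""
        total = 10.0 ** (-self.target_mean_q / 10.0)
        sub = self.sub_rate if self.sub_rate is not None else total / 2.0
        ins = self.ins_rate if self.ins_rate is not None else total / 4.0
        dele = self.del_rate if self.del_rate is not None else total / 4.0
        return sub, ins, dele


@dataclass(frozen=True)
class ExperimentGroup:
    """One treatment group: diet mixture, optional spike, replicate count."""

    label: str
    n_replicates: int
    diet_taxa: dict[str, float]  # proportions within the dietary part
    spike_taxon: str | None = None
    spike_fraction: float = 0.0
    treatment: str = "none"

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 <= self.spike_fraction <= 1.0:
            raise ValueError("spike_fraction outside [0, 1]")
        if self.spike_fraction > 0 and self.spike_taxon is None:
            raise ValueError("spike_fraction > 0 requires a spike_taxon")

    def composition(self) -> dict[str, float]:
        diet_total = sum(self.diet_taxa.values())
        comp = {
            t: (1.0 - self.spike_fraction) * f / diet_total
            for t, f in self.diet_taxa.items()
        }
        if self.spike_taxon is not None and self.spike_fraction > 0:
            comp[self.spike_taxon] = (
                comp.get(self.spike_taxon, 0.0) + self.spike_fraction
            )
        return comp


@dataclass(frozen=True)
class ExperimentDesign:
    groups: tuple[ExperimentGroup, ...]

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple(self.groups))
        labels = [g.label for g in self.groups]
        if len(labels) != len(set(labels)):
            raise ValueError("group labels must be unique")


def caged_insect_design(
    diet_taxon: str = "Vicia",
    spike_taxon: str = "Tulipa",
    spike_fraction: float = 0.95,
    sterilised_spike_fraction: float = 0.5,
    n_replicates: int = 3,
) -> ExperimentDesign:
    """A dusted/non-dusted x sterilisation x sample-part design.

    Mirrors the structure of a pollen-dusting trial: whole insects, dissected
    guts and exoskeletons, each pollen-dusted or clean, with a disinfectant
    ("distel") arm in which residual spike pollen persists at a reduced
    fraction rather than being removed outright.
    """
    diet = {diet_taxon: 1.0}
    g = ExperimentGroup
    return ExperimentDesign(
        groups=(
            g("whole_dusted", n_replicates, diet, spike_taxon, spike_fraction),
            g("whole_dusted_distel", n_replicates, diet, spike_taxon,
              sterilised_spike_fraction, treatment="distel"),
            g("gut_dusted", n_replicates, diet, spike_taxon, spike_fraction),
            g("exo_dusted", n_replicates, diet, spike_taxon, spike_fraction),
            g("whole_clean", n_replicates, diet),
            g("whole_clean_distel", n_replicates, diet, treatment="distel"),
            g("gut_clean", n_replicates, diet),
            g("exo_clean", n_replicates, diet),
        )
    )


def _global_identity(a: str, b: str) -> float:
    """Global-alignment identity: 1 - edit distance / alignment length."""
    res = edlib.align(a, b, task="distance", mode="NW")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


def make_reference_set(
    n_taxa: int,
    amplicon_len: int = 550,
    seed: int = 0,
    genus_names: list[str] | None = None,
    max_pairwise_identity: float = 0.80,
    max_retries_per_taxon: int = 100,
) -> ReferenceDB:
    """Random mutually divergent amplicons, one distinct lineage each.

    Sequences are rejection-sampled until every pair sits below
    ``max_pairwise_identity`` global-alignment identity, so reads simulated
    from one reference cannot produce confusable full-length hits against
    another.  Deterministic per seed.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    if genus_names is not None and len(genus_names) != n_taxa:
        raise ValueError("genus_names must have n_taxa entries")
    rng = np.random.default_rng(seed)
    seqs: list[str] = []
    for i in range(n_taxa):
        for _ in range(max_retries_per_taxon):
            cand = "".join(rng.choice(_BASES, size=amplicon_len))
            if all(
                _global_identity(cand, s) < max_pairwise_identity for s in seqs
            ):
                seqs.append(cand)
                break
        else:
            raise SimulationError(
                f"could not draw taxon {i} below "
                f"{max_pairwise_identity:.0%} pairwise identity"
            )
    records = []
    for i, seq in enumerate(seqs):
        genus = genus_names[i] if genus_names else f"Genus{i:02d}"
        lineage = TaxonLineage((
            "Viridiplantae",
            "Streptophyta",
            "Magnoliopsida",
            f"Order{i:02d}",
            f"Family{i:02d}",
            genus,
            f"{genus} simulata",
        ))
        records.append(ReferenceRecord(f"REF{i:03d}", seq, lineage))
    return ReferenceDB(records=records)


def _mutate(seq: str, rates: tuple[float, float, float], rng) -> str:
    """Apply substitutions, insertions and deletions independently per base."""
    sub, ins, dele = rates
    if sub == ins == dele == 0.0:
        return seq
    out = []
    n = len(seq)
    # one uniform draw per event type per base
    u = rng.random((n, 3))
    for i, ch in enumerate(seq):
        if u[i, 2] < dele:
            continue  # base dropped
        if u[i, 0] < sub:
            choices = [b for b in "ACGT" if b != ch]
            ch = choices[rng.integers(len(choices))]
        out.append(ch)
        if u[i, 1] < ins:
            out.append("ACGT"[rng.integers(4)])
    return "".join(out)


def _resolve_iupac(primer: str, rng) -> str:
    """Replace degenerate codes with a concrete base, as a polymerase would."""
    return "".join(
        ch if ch in "ACGT" else sorted(IUPAC_SETS[ch])[rng.integers(len(IUPAC_SETS[ch]))]
        for ch in primer
    )


def simulate_sample(
    db: ReferenceDB,
    cfg: SimConfig,
    sample_id: str = "sim",
    fwd_primer: str = DEFAULT_FWD_PRIMER,
    rev_primer: str = DEFAULT_REV_PRIMER,
) -> tuple[list[Read], pd.DataFrame]:
    """Draw reads from a taxon mixture under the configured error model.

    Returns the reads plus a truth table (read_id, source_taxon, source_ref)
    with the source genus of every read.  With all error rates zero and
    primers disabled, each read is exactly its source amplicon.
    """
    by_genus: dict[str, list[ReferenceRecord]] = {}
    for rec in db.records:
        genus = rec.lineage.name_at("genus")
        by_genus.setdefault(genus, []).append(rec)
    missing = set(cfg.composition) - set(by_genus)
    if missing:
        raise ValueError(f"composition taxa not in reference set: {sorted(missing)}")

    rng = np.random.default_rng(cfg.seed)
    taxa = sorted(cfg.composition)
    fracs = np.array([cfg.composition[t] for t in taxa])
    rates = cfg.effective_rates

    reads: list[Read] = []
    truth_rows = []
    if cfg.n_reads > 0 and taxa:
        sources = rng.choice(len(taxa), size=cfg.n_reads, p=fracs)
    else:
        sources = np.empty(0, dtype=int)
    for i, src in enumerate(sources):
        genus = taxa[src]
        recs = by_genus[genus]
        rec = recs[rng.integers(len(recs))]
        seq = _mutate(rec.sequence, rates, rng)
        if cfg.len_jitter_sd > 0:
            cut = int(abs(rng.normal(0.0, cfg.len_jitter_sd)))
            if cut and cut < len(seq):
                seq = seq[cut:] if rng.random() < 0.5 else seq[: len(seq) - cut]
        if cfg.add_primers:
            seq = (
                _resolve_iupac(fwd_primer, rng)
                + seq
                + revcomp(_resolve_iupac(rev_primer, rng))
            )
        if rng.random() < cfg.revcomp_fraction:
            seq = revcomp(seq)
        quals = np.clip(
            np.rint(rng.normal(cfg.target_mean_q, cfg.q_sd, size=len(seq))),
            1,
            41,
        ).astype(int)
        read_id = f"{sample_id}_r{i:06d}"
        reads.append(Read(read_id, seq, tuple(quals), sample_id))
        truth_rows.append(
            {"read_id": read_id, "source_taxon": genus, "source_ref": rec.id}
        )
    truth = pd.DataFrame(truth_rows, columns=["read_id", "source_taxon", "source_ref"])
    return reads, truth


@dataclass(frozen=True)
class SimulatedReplicate:
    group: str
    replicate: int
    sample_id: str
    treatment: str
    spiked: bool
    reads: tuple[Read, ...]
    truth: pd.DataFrame = field(compare=False)


def _replicate_seed(base_seed: int, group_idx: int, rep_idx: int) -> int:
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(group_idx, rep_idx))
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_experiment(
    db: ReferenceDB,
    design: ExperimentDesign,
    base_cfg: SimConfig,
    fwd_primer: str = DEFAULT_FWD_PRIMER,
    rev_primer: str = DEFAULT_REV_PRIMER,
) -> list[SimulatedReplicate]:
    """Simulate every replicate of a treatment design.

    Each replicate's composition is the group's diet mixture scaled by
    ``1 - spike_fraction`` plus the spike taxon at ``spike_fraction``;
    replicate seeds derive deterministically from the base seed and the
    (group, replicate) indices, so any replicate can be regenerated alone.
    """
    out = []
    for gi, group in enumerate(design.groups):
        for rep in range(group.n_replicates):
            cfg = replace(
                base_cfg,
                composition=group.composition(),
                seed=_replicate_seed(base_cfg.seed, gi, rep),
            )
            sample_id = f"{group.label}_rep{rep + 1}"
            reads, truth = simulate_sample(
                db, cfg, sample_id, fwd_primer, rev_primer
            )
            truth = truth.assign(group=group.label, replicate=rep + 1)
            out.append(
                SimulatedReplicate(
                    group=group.label,
                    replicate=rep + 1,
                    sample_id=sample_id,
                    treatment=group.treatment,
                    spiked=group.spike_fraction > 0,
                    reads=tuple(reads),
                    truth=truth,
                )
            )
    return out


def write_experiment(
    replicates: list[SimulatedReplicate],
    out_dir: str | Path,
    design: ExperimentDesign | None = None,
) -> None:
    """FASTQ per replicate plus a combined truth TSV (and the design as
    JSON when given)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truths = []
    for rep in replicates:
        write_fastq(list(rep.reads), out_dir / f"{rep.sample_id}.fastq")
        truths.append(rep.truth)
    pd.concat(truths, ignore_index=True).to_csv(
        out_dir / "truth.tsv", sep="\t", index=False
    )
    if design is not None:
        payload = [
            {
                "label": g.label,
                "n_replicates": g.n_replicates,
                "diet_taxa": g.diet_taxa,
                "spike_taxon": g.spike_taxon,
                "spike_fraction": g.spike_fraction,
                "treatment": g.treatment,
            }
            for g in design.groups
        ]
        (out_dir / "design.json").write_text(json.dumps(payload, indent=2))
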