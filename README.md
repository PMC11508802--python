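# pollensift

Plant *rbcL*a metabarcoding classification and surface-contamination
assessment for insect gut-content studies.

## The problem

Dietary analysis of herbivorous insects by DNA metabarcoding amplifies a
plant barcode (here the ~550–600 bp *rbcL*a fragment of the chloroplast
*rbcL* gene) from whole-insect or gut extracts, sequences the amplicons, and
assigns reads to plant taxa against a reference database. The hard part is
not the sequencing but the interpretation: pollen adhering to the insect
surface carries plant DNA that is indistinguishable, read by read, from
ingested material. For a xylem feeder such as the meadow spittlebug
(*Philaenus spumarius*) — a vector of *Xylella fastidiosa*, whose feeding
range one would like to read out of its gut — the ingested signal is
intrinsically tiny, so surface contamination can dominate the result and
masquerade as diet.

`pollensift` packages the complete analysis chain such a study needs, with
every stage testable on synthetic data:

- **refdb** — curate an amplicon reference database: trim references to the
  region between the PCR primers (IUPAC-aware, mismatch-tolerant, both
  strands), screen out references with too many degenerate bases, excessive
  homopolymers or out-of-range lengths, and dereplicate records identical in
  both sequence and taxonomy.
- **readqc** — primer-trim ONT reads (qualities sliced in lockstep,
  reverse-strand reads re-oriented), keep reads of 450–650 bases with mean
  Phred ≥ 7, and summarise counts, median length, mean quality and the
  implied error rate (error % = 100·10^(−Q/10)).
- **align** — per-read local alignment against the database, either with the
  built-in seeded affine-gap aligner or by ingesting a 12-column tabular hit
  file (the classic `outfmt 6` dialect) from an external search tool.
- **classify** — the hit-filtering and assignment rules: keep hits with
  ≥ 80% identity and ≥ 80% alignment coverage of the read, then keep hits
  with a bitscore within 5% of the best survivor; vote the surviving hits'
  lineages with a 75% majority rule that starts at species and ascends rank
  by rank (majority-rule lowest common ancestor). Reads with no agreement
  are `Unresolved`; reads with no surviving hits are `Unassigned`.
- **profile** — per-sample taxon tallies; select the top taxon plus every
  taxon with ≥ 1% of its reads; collapse species to genus; drop samples with
  fewer than 50 assigned units (3000 for ASV-unit data).
- **report** — contamination accounting: the fraction of assigned reads not
  explained by the known diet (flagged when strictly > 5%),
  replicate-detection matrices for a spiked taxon per treatment group,
  group-wise absolute and proportional target summaries, and the
  taxon × sample abundance matrix.
- **qpcr** — TaqMan CT summarisation: replicate averaging with the
  censored-40 ("no detection") convention, detection calls, and the UV
  dose–response trend (rank correlation of CT against exposure time).
- **simdata** — ground-truthed synthetic experiments: mutually divergent
  reference amplicons, reads drawn from diet + pollen-contaminant mixtures
  under an ONT-like 2:1:1 substitution:insertion:deletion error model,
  primer-flanked and randomly stranded, including full dusted/non-dusted
  treatment designs.

## Worked example

```python
from pollensift import (
    SimConfig, make_reference_set, simulate_sample,
    trim_read, filter_reads, search_all, classify_sample, tally,
    contamination_fraction,
)
from pollensift.simdata import DEFAULT_FWD_PRIMER, DEFAULT_REV_PRIMER

db = make_reference_set(4, seed=1,
                        genus_names=["Vicia", "Tulipa", "Urtica", "Pinus"])
cfg = SimConfig(composition={"Vicia": 0.9, "Tulipa": 0.1},
                n_reads=200, target_mean_q=13.4, seed=7)
reads, truth = simulate_sample(db, cfg)

trimmed = [trim_read(r, DEFAULT_FWD_PRIMER, DEFAULT_REV_PRIMER) for r in reads]
kept, qc = filter_reads(trimmed)
print(qc)
assignments = classify_sample(kept, search_all(kept, db), db)
profile = tally(assignments, "caged_insect_1")
print({k.split(";")[-2]: v for k, v in profile.counts.items()})
print(contamination_fraction(profile, {"Vicia"}).pct_contaminant, "% contaminant")
```

prints

```
reads in: 200  kept: 200 (0.0% discarded)
kept median length: 550 b
kept mean Phred: 13.4 (~4.6% error)
{'g__Vicia': 179, 'g__Tulipa': 21}
10.5 % contaminant
```

A 200-read sample simulated as 90% broad-bean (diet) and 10% tulip
(contaminant pollen) passes QC intact at its target quality (Q13.4 ≈ 4.6%
error), every read is assigned to its true genus, and the contamination
report recovers the spiked-in 10% tulip share (21/200 reads, within
binomial sampling noise of the true fraction).

The same stages are available as a CLI for file-based work:
`pollensift refdb|qc|align|classify|profile|report|qpcr|simulate --help`.

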