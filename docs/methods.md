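# Methods

This note documents the models, conventions and numerical choices behind
`pollensift`, and what its synthetic-data tests do and do not demonstrate
about real sequencing data.

## The classification model

A read's taxonomic label is decided in three stages.

**Hit filtering.** Every candidate alignment of the read against the
reference database carries a percent identity (exact base matches over all
alignment columns, gaps included in the denominator), an alignment length in
columns, and a bitscore. Two filters are applied strictly in order:

1. keep hits with identity ≥ 80% **and** coverage ≥ 80%, where coverage is
   100·(alignment columns)/(read length);
2. among the survivors, keep hits with bitscore ≥ 0.95 × the best surviving
   bitscore.

The order matters: the 5% window is anchored at the best hit *after* the
identity/coverage screen, so a strong but low-identity alignment cannot set
the bar. A consequence worth knowing: the composed filter is not globally
monotone in its thresholds. Tightening the identity threshold can remove the
anchor hit, lower the window cutoff, and admit hits the wider anchor had
excluded. Each stage is monotone on its own, and the composition is monotone
whenever the anchor survives; the test suite pins exactly these properties.

The coverage denominator is read-relative by default because it is invariant
to reference padding; reference-length and expected-amplicon-length
denominators are available via `HitFilterConfig.coverage_denominator` for
workflows that define coverage differently.

**Majority-rule LCA.** The surviving hits' lineages vote over the rank
ladder kingdom > phylum > class > order > family > genus > species, starting
at species and ascending. At each rank, candidates are the distinct
kingdom→rank *paths* (not bare names, so genus homonyms in different
families never pool votes). If a candidate reaches 75% of **all** surviving
hits, the read is assigned that path truncated at the rank; otherwise the
vote moves one rank up. With a unanimity requirement (fraction = 1.0) this
reduces to the classic strict LCA (deepest common prefix). The vote
denominator deliberately includes hits whose references lack the rank under
consideration: this is the conservative reading, preventing a single
species-annotated reference from winning species when most references are
annotated only to genus. The alternative (denominator = hits annotated at
the rank) is available via `LCAConfig.count_unranked=False`.

Two failure modes are kept distinct because they mean different things:
`Unassigned` (no hits survived filtering — the read matches nothing in the
database well enough) and `Unresolved` (good hits that never agree — the
marker cannot separate the candidates). Both are excluded from profiles.

**Profiles and selection.** Counts are tallied per assigned lineage.
Selection keeps the most-abundant taxon and every taxon with ≥ 1% of its
count (inclusive; ties for the top all anchor the same threshold). Species
are collapsed into their genus where possible; labels above genus cannot be
pushed down without external information and are retained with a
`supra-genus` flag. Samples with fewer than the minimum assigned units
(default 50 for read data, 3000 for ASV-unit data) are dropped; a sample at
exactly the minimum is kept (the rule is "fewer than").

## Boundary conventions

All threshold comparisons follow the natural-language rule they implement,
and the test suite pins each one:

| rule | boundary case | outcome |
|---|---|---|
| reads "shorter than 450 / longer than 650" discarded | exactly 450 or 650 | kept |
| mean Phred "less than 7" discarded | exactly 7 | kept |
| taxa "≥ 1% of the top count" selected | exactly 1% | selected |
| samples "fewer than 50 reads" removed | exactly 50 | kept |
| contamination "> 5%" flagged | exactly 5% | not flagged |
| CT 40 = "no detection" | average exactly 40 | not detected |

## Read QC

The per-read quality statistic is the arithmetic mean of per-base Phred
values, the convention common ONT read filters use; averaging in error space
(mean of per-base error probabilities, re-expressed as Phred) is available
via `ReadFilterConfig.q_average="error"` and is always the stricter of the
two for heterogeneous quality strings. The error-rate display uses
100·10^(−Q/10). Median length uses the lower median for even counts, so the
statistic is always an observed read length. FASTQ is Phred+33 throughout,
gzip-transparent.

## The built-in aligner

The internal search exists so the classification rules can be exercised and
tested without an external alignment tool; it is desk-scale plumbing, not a
production search engine. Candidates are references sharing at least one
exact k-mer (default k = 11) with either strand of the read; candidates are
then aligned with an affine-gap local aligner (biotite's optimal-alignment
kernel) on the strand(s) that seeded. Scoring defaults to +2/−3 with gaps
−5/−2 and Karlin–Altschul parameters λ = 0.625, K = 0.41, mirroring common
megablast-style settings so the 5% bitscore window behaves comparably to an
external search; a gap of length n costs open + (n−1)·extend. Ties in
bitscore order deterministically by reference id. E-values are not computed
(they need database-level statistics); hits ingested from external tabular
files carry them through. The aligner is validated in the tests against an
independent pure-Python Smith–Waterman dynamic program on random sequence
pairs, and the seeded search against unseeded all-pairs alignment at 10%
read error.

## Reference curation

Primer matching is IUPAC-aware (a primer base matches a template base when
their degeneracy sets intersect — the amplification primers contain R/Y/B/K
codes), tolerates a configurable number of mismatches per primer (default 2),
and searches both strands, returning the amplicon in forward orientation.
Among multiple matches the leftmost forward and rightmost reverse are taken:
the maximal amplicon, deterministically. Curation thresholds — at most 5
degenerate bases, no homopolymer longer than 8, length within [500, 700] —
are exposed in `RefCurationConfig` rather than asserted as universal; they
are defaults comparable to what common rbcL curation pipelines apply.
Dereplication removes records identical in both sequence *and* full
taxonomic annotation; records sharing a sequence across different taxa are
all retained, because they are exactly the cases the LCA must adjudicate.

## qPCR CT summarisation

Replicate CTs are averaged with censored 40s included as point values —
not dropped, not imputed — which makes an all-censored pair average to
exactly 40 and call "not detected". Reported averages are rounded half-up to
2 decimals, computed in decimal arithmetic on the replicates' printed form
so that a replicate pair averaging to exactly x.xx5 rounds up rather than
falling through binary floating point (e.g. mean(29.81, 30.18) = 29.995 →
30.00). Detection uses the unrounded mean, strictly below the cycle cap.
The UV dose–response trend reports Spearman rank correlation of CT against
exposure time as the headline statistic — monotone degradation is the claim
of interest, not linearity — alongside Pearson r and a strict-monotonicity
flag.

## The synthetic-data generator

`simdata` emulates the statistical structure of a caged-insect pollen-dusting
experiment: each sample is a mixture of diet-plant amplicons and
contaminant-pollen amplicons at configured proportions; an experiment is a
set of treatment groups (whole insects / dissected guts / exoskeletons,
dusted or clean, with or without a disinfectant arm), three replicates each,
where dusting adds the spike taxon at a dominant fraction (default 0.95,
matching the regime where applied pollen overwhelms all other signal) and
the disinfectant arm reduces but does not remove it (default 0.5).

Reference amplicons are random 550-mers rejection-sampled until all pairs
sit below 80% *global-alignment* identity (edlib edit distance over the
alignment length). Global identity is the right divergence notion here:
best-local-alignment identity between unrelated random sequences is
trivially high (any short perfect seed is a 100%-identity local hit), so a
local-identity criterion would never terminate; what matters downstream is
that no cross-pair can produce a hit passing the 80%-identity,
80%-coverage filter, which the sub-80% global bound guarantees and the
tests verify with the package's own aligner.

The error model applies substitutions, insertions and deletions
independently per base at 2:1:1, scaled so the total per-base error equals
10^(−Q/10) for the target mean quality (Q13.4 ≈ 4.6%, the regime of a
typical ONT amplicon run). Quality values are drawn per base around the
target. Reads are flanked with the PCR primers (degenerate codes resolved
randomly, as a polymerase would) and half are emitted reverse-complemented,
so trimming and strand handling are exercised; errors are applied to the
amplicon core, keeping the primer flanks intact so trimming behaviour is
deterministic. One experiment seed derives per-replicate seeds through
`numpy` seed sequences, so any single replicate can be regenerated alone.

What the generator does **not** model: homopolymer-biased ONT errors,
chimeras, quality–error correlation within a read, PCR amplification bias,
barcode crosstalk, or shared k-mers between related real taxa. Passing
end-to-end tests therefore demonstrate that the *pipeline logic* recovers
known mixtures under calibrated uniform noise — not that real, closely
related plant references are distinguishable at these error rates. Real
rbcL databases contain congeneric sequences well above 80% mutual identity;
on such references the LCA deliberately retreats to genus or family, which
is the designed behaviour, not a failure.

## Problem sizes and determinism

The end-to-end checks run at desk scale, chosen so the full suite stays
fast while keeping binomial noise well inside the asserted bounds: 2,000
reads for composition recovery (3 binomial SDs of the 10% contaminant
fraction ≈ ±2 percentage points) and 150 reads per replicate across the
8-group × 3-replicate dusting design (a 95% spike is then unmissable and a
zero spike cannot false-positive, since cross-taxon hits cannot pass the
filter). Every stochastic step is seeded; hypothesis-based property tests
run derandomised. `scripts/acceptance.py --seed N` threads one seed through
reference generation and both simulated experiments.

## Known limitations

- The aligner is O(read × reference) per candidate pair; it is meant for
  thousands of reads against tens of references, not production search.
- "Manual inspection" steps of real workflows (curating consensus sequences,
  resolving family-level assignments by eye) have no algorithmic
  counterpart beyond genus collapsing and the supra-genus flag.
- Consensus polishing is out of scope: `consensus_read_sets` emits per-taxon
  read bundles for an external polisher.
- E-values are carried through from external hit files but never computed.
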