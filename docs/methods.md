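# Methods

This note records the models, conventions and numerical choices behind
`mirnome`, and what the synthetic benchmark does and does not establish.

## Conventions

All sequences are uppercase DNA; RNA input (U) is converted to T on
ingestion and outputs are always DNA. Coordinates are 0-based, half-open
everywhere, including BED. `N` is a legal read character but never matches —
it always counts as a substitution. Collapsed libraries hold one record per
distinct sequence with a multiplicity; collapsing conserves total read mass.

## Read matching

The matching primitive throughout is *ungapped, end-to-end within the
subject, at most k substitutions* (default k = 2). The choice of
substitutions-only, no-indel matching mirrors the short-read aligners of the
bulk small-RNA era and keeps the operation exactly checkable: the test suite
compares the vectorised implementation against an exhaustive sliding-window
Hamming scan on random fixtures. Among accepted placements the
minimum-mismatch hit wins, with ties broken by record name, then offset.
Class databases are matched in transcript sense only; genomic region
matching is strand-agnostic (exact matches of the read or its reverse
complement).

## Elimination annotation

Reads of length ≥ 14 nt (boundary inclusive) are annotated by sequential
elimination in the fixed priority order miRNA, sn/snoRNA, lincRNA, tRNA,
rRNA, mRNA, misc; assignment to a class removes the read from later stages,
so priority dominates mismatch count by design. The order is configurable.
The miRNA stage matches reads against the pre-miRNA *hairpins* (plus any
matures that could not be located on a hairpin) rather than the mature
sequences: isomiRs are shifted or trimmed relative to the mature and only
the precursor contains them end-to-end; matching matures alone would
misclassify most of the miRNA read mass. The mismatch budget is applied
uniformly to every class.

## Expression profiles

The reference profile counts reads *exactly equal* to each canonical mature
sequence — full-string equality, deterministic and oracle-checkable — and
reports TPM = raw / library_total × 10⁶ at full floating precision
(tabulated at 6 decimals). Mature names are keys: identical sequences under
different names are each credited in full and reported as duplicate-name
groups; same name with different sequences is an error. "Highly expressed"
is strict (raw > 10,000). Sample similarity uses average-linkage
agglomeration on 1 − Spearman correlation of log2(TPM+1) vectors over the
union of miRNA names; the rank correlation and the log transform are both
responses to the profiles' ~5-orders-of-magnitude dynamic range, and both
metric and linkage are configurable. A zero-variance profile has no defined
correlation and raises rather than silently clustering.

## IsomiR families and the YES/NO comparison

Reads align to hairpins with the same ≤ 2-substitution contract; only each
read's best-mismatch stratum is kept, and multi-mapping reads contribute
their full count to every family they enter (a fractional-splitting mode is
available for users who need mass conservation across families). An
alignment joins the mature locus on its hairpin with which it overlaps most,
provided the overlap is ≥ 50% of the shorter of read and mature; alignments
clearing no locus (for example loop-spanning reads) are set aside as
"hairpin-other" and reported. Family members are keyed by read sequence and
carry 5′/3′ offsets relative to the mature locus; a 1-mismatch variant at
offsets (0,0) is therefore a distinct member from the canonical sequence.

The dominant isomiR is the member with the highest count; ties prefer the
smaller |5′ offset|, then |3′ offset|, then the lexicographically smaller
sequence, so the canonical register wins exact ties. A miRNA counts as
expressed in a sample when its dominant count reaches the detection
threshold (default 1, configurable — the detection limit of the original
analysis is not quantified anywhere, so the permissive default is used and
stated). Group status requires unanimity: YES / NO only when every sample of
the group is expressed and agrees; otherwise non-uniform (expressed,
disagreeing) or low-expression, reported together as "not considered".

Because the canonical sequence, when present at its locus, is itself a
family member, the abundant (dominant-count) profile dominates the reference
profile row-wise and its row set is a superset; the row-count excess equals
the number of miRNAs expressed only through non-canonical isomiRs. Both
properties are asserted in the acceptance suite.

## Novel miRNA discovery

Unannotated reads with per-sample count ≥ 5 are placed by exact match (both
strands) within intergenic/intronic intervals, extended by 70 nt on both
sides (clipped at chromosome ends, reverse-complemented on minus placements
so the read stays in sense), folded, filtered structurally, then pooled
across samples, merged by overlapping same-strand loci, deduplicated and
named `jnu-pat-hsa-<n>` in descending total-count order.

### Folding

Two routines coexist deliberately. `nussinov_max_pairs` /
`nussinov_structure` implement the textbook Nussinov DP — maximum nested
base pairs, Watson–Crick plus G·U, minimum loop 3 — and are verified against
exhaustive enumeration of nested structures for short sequences. They are
*not* the default candidate gate: a 160 nt window whose 70 nt flanks are
random sequence always attains its pairing maximum with extra loops in the
flanks, so "is the global optimum a single hairpin" rejects essentially
everything. The default engine instead finds the best *single stem-loop* by
a local DP in which each Watson–Crick pair scores +1 and interior
mismatches/bulges cost 2 per skipped position (window ≤ 4 per side), then
accepts iff the stem carries ≥ 16 pairs at a pairing fraction ≥ 0.6 with a
terminal loop ≥ 3 nt. G·U pairs are excluded from the detector's scoring:
admitting them raises the random per-position pairing probability from 1/4
to 3/8, which erodes the margin between genuine inverted repeats and
background. Measured on random 162 nt windows versus miRNA-like planted
windows, the default thresholds accept ~96% of planted stems and ~4% of
random windows; both error rates are properties of the detector, and all
thresholds are configurable. The engine interface is pluggable so external
precursor predictors can be slotted in, their scores recorded verbatim on
candidates rather than re-implemented.

### Structural filters

The seeding sRNA must lie within one stem arm — ≥ 90% of its positions
in-arm and none in the loop — or the window is discarded as a prediction
error; this is the only hard gate by default. The two corroborating
features, an isomiR (another candidate read starting and ending within ±3 nt
of the seed) and a counterpart (a read lying mostly in the opposite arm),
are recorded as flags, with a strict mode that requires all three. The
rationale for gating only on stem placement is that the corroborating
features are reported attributes of candidates rather than preconditions in
the analysis this package operationalises.

## Synthetic data generator

The generator is the package's study stand-in, not a test fixture: its
defaults *are* the study conditions. Hairpins are built as stem-loops — a
random arm of 20–24 nt (mode 22), an 8–15 nt loop, the arm's reverse
complement with interior substitutions (rate 0.05, at least where planted
novel loci are concerned two forced interior changes so no planted stem is a
perfect palindrome and reads map on one strand only), and a few context
nucleotides of padding. Construction is rejection-sampled so every planted
hairpin is accepted by the default fold engine and every mature locates
uniquely. Class proportions default to miRNA 0.74, sn/sno 0.02, lincRNA
0.02, tRNA 0.03, rRNA 0.01, mRNA 0.04, misc 0.02, unannotated genomic 0.05,
unmatched 0.07. IsomiR 5′/3′ offsets are uniform over [−2, +2]²; family
size grows with expression (2 + 2·log₁₀ weight members), reproducing the
more-isomiRs-for-higher-expression pattern; the dominant member carries a
≥ 2× count margin and equals the canonical sequence with probability 0.32.
Expression weights are log-uniform over ~0.3–3.8 decades.

Read-length structure: intact libraries draw lengths from a table with mode
22 nt. Degraded libraries apply, to a fraction (default 0.7) of reads, a 3′
truncation down to a target length drawn from a mode-17 table — this
reproduces the shifted mode and heavy short tail of degraded material and
makes the 17 nt mode statistically robust at 10⁴ reads, which a
geometric-only trim does not.

Unannotated-genomic background is built in two tiers so it can never
masquerade as a novel locus: a few moderate-count "hub" reads whose
flank-extended windows are rejection-sampled to *not* fold (as are the
explicit decoy loci), and many low-count debris reads whose expected counts
sit well below the novel-candidate frequency gate at any library size.
Unmatched reads are random sequences verified absent from every database and
the genome. Counts are multinomial over planted weights by default; fixture
mode writes the planned integers exactly (guaranteeing the dominant margin)
and is what the margin-sensitive tests use. In multinomial mode the truth
table records *realized* counts and re-derives dominants and YES/NO labels
from them. Cohorts share expression weights and family plans within a group
and plant each miRNA's group status directly, with priors (low 0.63,
non-uniform 0.07, YES 0.10, NO 0.20) matching the composition a
whole-miRnome comparison shows; cohort families always contain the canonical
member so reference profiles are informative for clustering.

Identical spec and seed give byte-identical libraries, and the end-to-end
study (annotation → profiles → comparison → clustering → discovery → TSV
output) is byte-deterministic under a seed.

## What the benchmark does and does not show

Passing the planted-truth suite shows the pipeline's operations implement
their contracts exactly: mass is partitioned, exactness is exact, dominants
with a 2× margin are always recovered, planted group labels are reproduced,
planted hairpins are found and non-folding decoys are not. It does not show
performance on real libraries: real backgrounds contain repeat-derived
multimapping reads, adapter artefacts, non-templated 3′ additions, sequencing
error, and genuine unannotated loci that fold — none of which the generator
models (spontaneously folding background windows are the one simulated
analogue, at the detector's ~4% rate on random sequence). Sizes used
throughout (10⁴–10⁵ reads, tens of hairpins, tens-of-kb genomes) are the
package's own desk-scale choices; every operation scales linearly in reads ×
database size.

## Known limitations

- The mismatch matcher has no indel model, by contract; reads with true
  indels relative to the reference fall through to later classes.
- Multi-mapped reads counted fully in each family make family masses
  non-conservative across families (the fractional mode trades this for
  non-integer counts).
- The default fold engine is a combinatorial detector, not a thermodynamic
  model; it has no stacking energies and its acceptance thresholds are
  calibrated on the generator's hairpin geometry.
- The YES/NO comparison keys on full-sequence identity, so a 1-nt 3′
  variant of the canonical sequence counts as NO even though its locus
  register is canonical — the sequence-keyed convention of isomiR tables.
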