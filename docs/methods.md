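# Methods

## Repeat tracts and read classification

A repeat tract of a 3-nt unit is defined as a maximal substring equal to a
window of the infinite repetition of the unit, starting at any of the
three phases.  This makes tract length nt-denominated rather than
unit-denominated: `GCAGCAGCAG` is a 10-nt CAG tract even though 10 is not
a multiple of 3.  The scanner computes, for each of the three phase
classes, the runs of positions matching the phased unit, and returns the
longest run of ≥ 3 nt, ties broken by smallest start.  `N` never matches,
so it terminates tracts — a conservative choice that cannot inflate tract
lengths.  Sequences are normalized to a single DNA alphabet (U→T) at
ingest and the input dialect is irrelevant thereafter.

Read classification assigns each read exactly once, to the length class of
its longest tract (clamped to `max_len`, default 50 for 50-nt libraries),
or to `unclassified` when below `min_len` (default 10).  Totals are
conserved exactly; this is asserted on every fixture.  Pure-repeat
counting is stricter: a read counts for a rotation only when the whole
read is a phase-0 prefix of that rotation's repetition, so each read
matches at most one of CAG/AGC/GCA.

A deliberately quadratic brute force (test every substring for membership
in the infinite repetition, then check maximality) ships in the package as
the independent oracle; the linear scanner is required to agree with it
exactly on randomized repeat-rich inputs.

## TNR gene-set catalog

Per gene, the longest deposited candidate of each region kind (5'UTR, ORF,
3'UTR) is selected and stitched in that order into an mRNA proxy; ties on
length fall to the lexicographically smallest sequence, logged, so the
build is deterministic.  A gene joins the set "≥ n nt" when the stitched
mRNA carries a tract of at least n nt under the same any-phase definition
used for reads — in particular a tract spanning a region junction counts.
The thresholds 10…19 nt produce nested sets by construction; nesting is
still verified as an invariant.  Input is a generic region table (TSV or
FASTA with `gene|kind` headers), never a live annotation query, so
catalogs are reproducible offline; CUG sets are matched against the mRNA
sense strand.

## Enrichment statistic

Genes are ranked by log fold change, descending, ties broken by gene id.
For a set with k members present in a ranking of N genes, the running sum
gains |score|^p / Σ_members |score|^p at member positions and loses
1/(N−k) elsewhere; ES is the extreme deviation, with weight p = 1 (the
standard "weighted" setting).  When the positive and negative extremes are
mathematically tied the positive one is returned; the tie window is 1e-12
so the choice is stable against summation order.  Member sets with all
scores exactly zero fall back to unweighted 1/k steps.

The null distribution comes from random member sets of size k drawn
without replacement (gene-label permutation — the only permutation scheme
available to a preranked analysis).  NES divides ES by the mean |null ES|
of the same sign; the nominal p is (1 + #{same-sign nulls ≥ |ES|}) /
(1 + #same-sign), so it is never zero and is floored at 1/(n_perm+1).
When no null shares the sign of ES, NES is reported undefined with the
floor p and a flag.  Null ES values are computed vectorized (one matrix of
permuted membership masks per set), which keeps 1000 permutations on a
2000-gene ranking under 0.1 s.  The default 1000 permutations match
standard practice for this analysis.

The family runner derives one permutation stream per threshold from the
caller's seed, drops thresholds with empty intersection, and reports set
sizes alongside ES/NES/p.

## RISC-bound read grouping

Group 1 is defined by the three 19-mers `CAGCAGCAGCAGCAGCAGC`,
`AGCAGCAGCAGCAGCAGCA`, `GCAGCAGCAGCAGCAGCAG`; group 2 by the three CCG
rotations; group 3 is everything else.  A read matching both families
(possible for CAG/CCG junction fragments) goes to group 1 — a precedence
choice, made auditable by a separate ambiguity tally.  Normalization is
reads-per-million of the library total, which preserves between-group
ratios exactly.  Length histograms and species (distinct-sequence) tables
are kept per group.

## Hairpin structures

Folding is a narrow contract to an external Turner-1999 nearest-neighbor
engine (ViennaRNA bindings): sequence and options in, dot-bracket and ΔG
out, engine identity recorded in every structure.  Options are minimum
free energy, no isolated pairs, and dangling energies on both sides of a
helix in any case (`dangles=2`).  SHAPE slope 1.9 / intercept 0.7 are
carried in the settings object for fidelity but never applied — no
reactivity data exists in this workflow.  Degenerate co-optimal MFE
resolves to the engine's canonical structure, recorded verbatim.

Stems are maximal runs of base pairs in which consecutive pairs (i,j),
(i',j') satisfy i'−i ≤ 2 and j−j' ≤ 2: only 1×1 interior loops are
tolerated inside a stem, because that is how the periodic A·A mismatch of
CAG self-pairing appears in MFE output; any bulge or larger loop starts a
new segment.  Within a segment, CAG units are counted on the 5' arm by a
left-to-right scan: a triplet `CAG` counts when both its C and its G are
paired inside the segment, and the scan then jumps past it so units never
overlap; half-paired triplets never count.  The reported "longest
uninterrupted CAG stem" is the maximum unit count over segments.  How the
original structure figures counted double-stranded repeats across small
bulges was not specified; the 1×1 rule is this package's declared
convention, and `check_printed_stem_counts` compares against the reported
flanked-construct counts (15/25) without reconciling discrepancies.  The
15-nt genomic flanks of the full-length constructs are a user input; the
flankless 153-nt formula constructs reproduce the orderings (stem 14 vs
23 units, ΔG −53.5 vs −58.8 kcal/mol for Ref vs LOI).

## Synthetic data

The generators produce exactly the statistical structure the analyses
assume, with exact truth tables:

- **Read libraries**: fixed-length (default 50 nt) reads with planted
  tracts of exact lengths.  Every planting is re-scanned by the
  production scanner before emission and regenerated on collision, so
  "planted length" is the true longest-tract length, not an expectation.
  Background reads are guaranteed free of tracts at or above the lowest
  classification threshold (10 nt by default, configurable down to the
  listing threshold when needed).  The optional error model is
  substitution-only at a per-base rate, applied after verification with
  pre-noise truth recorded; indels and ligation/adapter biases of real
  repeat sequencing are deliberately not modeled.
- **Transcriptomes**: per-gene region records with planted tracts, a
  configurable fraction split across the ORF/3'UTR junction; the stitched
  mRNA is re-scanned before emission.
- **Ranked lists**: target genes Normal(effect, σ), others Normal(0, σ);
  defaults effect −2, σ = 1, N = 2000, |set| = 100.
- **RISC libraries**: per construct, a seeded multinomial over group 1
  (base fraction 0.08 scaled by construct abundance, LOI:Ref = 4:1 by
  default), group 2 (fixed 0.01) and background; group-1 products start
  with the fixed 5' phase AGC at lengths 21/22 (equal mass), group-2
  products start CCG.

Every generator is a deterministic function of (spec, seed).  Passing
tests on these fixtures demonstrates correctness of the computations under
the assumed structure; it does not demonstrate robustness to the known
pathologies of real repeat sequencing (low fidelity on repetitive inserts,
length-dependent ligation efficiency), which the error model only
caricatures.

## Validation studies and problem sizes

The studies in `tnrkit.validation` (shared by the tests, the analysis
drivers and the acceptance script) use: 1000 random sequences per oracle
comparison; 2000-read conservation fixtures; a catalog of 42 planted plus
60 background genes; 200 random instances for ES brute-force equivalence
(agreement required within 1e-12); 500 null simulations of a 200-gene
ranking with 999 permutations each for type-I calibration (expected
rejection ≈ 5% at α = 0.05); 100 replicates of the planted-shift power
study at the default ranked-list conditions with 1000 permutations; the
repeat-length trend at 30 genes per tract length 10–19 plus 1200
background, with the −2.5 shift (σ = 0.15) restricted to tract ≥ 19 genes
so each deeper threshold is strictly purer in shifted genes; and 50,000
reads per RISC library.  These sizes put every study's sampling error
well inside its decision band while keeping the whole validation run
around half a minute.

## Known limitations

- Reads are classified by sequence content only; attributing reads to
  genes (alignment) is out of scope.
- The catalog uses one stitched proxy per gene, not isoform-aware
  transcript models.
- Nominal permutation p-values only; no FDR across collections and no
  leading-edge extraction.
- Group-1/group-2 precedence is a convention; the ambiguity tally is the
  audit trail.
- Structural results are MFE-only (no partition-function ensembles, no
  pseudoknots) and inherit the engine's parameter set and tie-breaking.
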