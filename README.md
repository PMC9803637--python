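# tnrkit

Expanded CAG trinucleotide repeats (TNRs) in *HTT* and *AR* cause
Huntington's disease and spinal and bulbar muscular atrophy.  The repeat
RNA folds into hairpins whose CAG-containing stems are Dicer substrates;
the resulting 21–22-nt short CAG RNAs (sCAGs) load into the RISC and
silence genes carrying complementary CUG repeats.  Disease onset tracks
the length of the *uninterrupted* CAG run: the loss-of-inhibition (LOI)
*HTT* allele differs from the reference allele by two A→G substitutions,
extends the uninterrupted run from 40 to 42 units, and folds into one long
stem instead of an interrupted one.

`tnrkit` is the computational side of that story as a tested, reusable
pipeline for anyone analysing repeat-derived small RNAs:

- **`repeat_scan`** — detect maximal perfect repeat tracts (any phase of
  the unit, so a 10-nt tract like `GCAGCAGCAG` counts) and classify reads
  once each by their longest tract length.
- **`tnr_catalog`** — stitch per-gene 5'UTR/ORF/3'UTR candidates (longest
  of each) into mRNA proxies and build the nested gene-set family
  "contains a (CUG)ₙ/(CAG)ₙ tract ≥ n nt" for n = 10…19.
- **`enrichment`** — preranked gene-set enrichment with the weighted
  Kolmogorov–Smirnov running-sum statistic: genes ordered by log fold
  change, P_hit steps of |s|ᵖ/Σ|s|ᵖ at member ranks, P_miss steps of
  1/(N−k) elsewhere, ES = signed maximum of P_hit − P_miss, with a
  gene-label permutation null, sign-restricted NES and a +1-corrected
  nominal p.
- **`risc_profile`** — partition Ago-pulldown libraries into CAG-phase
  (group 1), CCG-phase (group 2) and other (group 3) reads by six fixed
  19-mers, with per-million normalization, length histograms and species
  tables.
- **`hairpin_struct`** — build HTT/AR repeat-variant RNAs, fold them at
  minimum free energy (ViennaRNA, Turner-1999 parameters, no isolated
  pairs, dangles on both sides), segment the pair table into stems that
  tolerate only 1×1 interior loops (the A·A mismatches of CAG
  self-pairing), and count double-stranded CAG units per stem.
- **`synthetic_data`** — seeded generators for all of the above, each with
  an exact planted truth table verified by the production scanner.

## Worked example

```python
from tnrkit import fold, longest_uninterrupted_cag_stem
from tnrkit.hairpin_struct import REF_HP, LOI_HP

ref, loi = fold(REF_HP), fold(LOI_HP)
print(ref.delta_g, longest_uninterrupted_cag_stem(ref))
print(loi.delta_g, longest_uninterrupted_cag_stem(loi))
```

prints (ΔG in kcal/mol, then stem length in CAG units):

```
-31.200000762939453 6
-36.5 13
```

The LOI hairpin mimetic folds more stably than the reference (−36.5 vs
−31.2 kcal/mol) and carries a more than twice longer uninterrupted
double-stranded CAG stem (13 vs 6 units) — the structural difference that
makes it the better Dicer substrate.

The numbered scripts under `analysis/` run the full pipeline on synthetic
data: `01_simulate_data.py` plants the truth, `02`–`05` classify reads,
build the CUG catalog, run the enrichment (recovering the planted
downregulation of long-CUG genes with |ES| rising from 0.69 to 1.00 across
thresholds 10→19 nt), and profile the RISC libraries (recovering the
planted 4:1 LOI:Ref sCAG ratio as 3.98), and `06_fold_hairpins.py`
tabulates all hairpin constructs.

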