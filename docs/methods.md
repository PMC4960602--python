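# Methods

## Problem and model

`varprio` prioritizes rare coding variants in multi-case pedigrees under a
highly penetrant, dominant-acting model: if a family's clustering of an
otherwise complex phenotype (the motivating case is nonsyndromic cleft
lip/palate) is driven by a single coding mutation, that mutation should be
(i) carried by every affected family member who was sequenced, (ii) absent
from population variant catalogues, (iii) located in a gene plausibly related
to the phenotype, and (iv) predicted deleterious.  None of these conditions
is individually decisive, so the pipeline is a conjunction of independent
filters followed by a rank aggregation, not a statistical test.  There is no
segregation likelihood, penetrance model or kinship verification; the output
is a short ordered candidate table for human follow-up.

## The filter cascade

Ten stages, applied in a fixed order with per-stage attrition recorded in a
trace.  All stages are independent predicates on a (variant, family) pair,
so the order changes only the trace, never the surviving set (a tested
property).

1. **Consequence class** — keep nonsynonymous SNVs, stopgain/stoploss,
   splicing and frameshift/non-frameshift indels.  Classes are consumed from
   annotation input against a closed vocabulary; the package never calls
   consequences from transcript models.
2. **Gene panel** — keep variants in a user-supplied phenotype gene panel
   (case-normalized symbols).  The motivating study used an 865-gene
   clefting panel; the synthetic generator reproduces that panel size.
3. **Read depth** — remove a variant if *any* sequenced affected carrier is
   covered below `min_depth` (default 10).  The published rule states only
   "depth < 10"; the per-carrier, fail-closed reading is a package decision:
   one under-covered carrier genotype makes the sharing evidence for the
   whole family unreliable.  Missing depth counts as 0.
4. **Homopolymer context** — remove variants overlapped by a single-base
   reference run of length >= 6 (configurable), given a reference window
   centred on the variant.  The published analysis excluded
   homopolymer/repeat artifacts without stating a criterion; run-length >= 6
   is the package's operational definition.  Records without context pass
   with a warning (the filter cannot fail closed without data).
5. **Mutable-gene blacklist** — remove variants in genes from a
   user-supplied "highly mutable" list (the study cites such a list by
   reference; no symbols are printed, so it is an input, not a constant).
6. **Novelty / rarity** — preset `novel` (default): remove variants present
   in dbSNP135, 1000 Genomes, the Exome Variant Server or an in-house
   database; presence at low frequency in ExAC alone never removes a
   variant (ExAC aggregates disease cohorts and is consulted for frequency
   annotation, not for novelty).  Preset `rare_1pct`: keep variants with
   1000 Genomes MAF < 1%.
7. **Splice differential** — splicing-class variants are kept iff
   |ΔMaxEnt| >= 3, where ΔMaxEnt is the change in the maximum-entropy
   splice-model score consumed as an annotation column (the splice model
   itself is out of scope).  The absolute value is used because loss and
   gain of a splice signal are both of interest.  Splicing records without
   a score are dropped (fail-closed) and logged.
8. **Family sharing** — a variant becomes a candidate in a family iff every
   sequenced affected member carries the alternate allele (het or hom-alt).
   A missing genotype excludes: sharing evidence must be positive.  Members
   with unknown affection are treated as unaffected, i.e. they never
   constrain sharing.
9. **Cross-family exclusion** — any variant that is a candidate in two or
   more families is removed from all of them, as a proxy for regional
   variation missing from the population catalogues.
10. **Damaging-by-at-least-one-metric** — missense candidates must be called
    deleterious by at least one of SIFT, PolyPhen-2 HumVar, MutationTaster,
    LRT, PhyloP or GERP++.  Truncating, splicing and indel candidates bypass
    this gate (their mechanism is not score-predicted) and are reported in a
    separate table.

## Deleteriousness thresholds

Applied with their exact inequality senses: SIFT < 0.05 (strict);
PolyPhen-2 possibly damaging > 0.447 (strict), probably damaging >= 0.909;
MutationTaster > 0.95 (strict); Grantham > 100 "radical" (strict, and
computed on the unrounded value).  PhyloP and GERP++ cutoffs are **not**
published for this pipeline; the defaults (> 2.0 each) are package choices,
configurable in `Thresholds`.  LRT contributes through its categorical call.
The Grantham score is reported for every missense candidate but deliberately
excluded from the "at least one metric" gate: the published gate lists six
predictive metrics and Grantham is a physicochemical description, not a
predictor.  The gate's metric set is configurable because published
candidate tables include rows (e.g. a G696E substitution with SIFT 0.05,
PolyPhen 0.09, MutationTaster 0.37) that only pass via categorical calls not
shown in print.

## Grantham distance

Two routes, which deliberately coexist:

* `grantham_distance` returns the canonical integer from the published 1974
  matrix.  This is the value annotation databases print and the value all
  thresholds were calibrated against, so it is what the pipeline reports.
* `grantham_distance_formula` recomputes
  `D = rho * sqrt(alpha*dc^2 + beta*dp^2 + gamma*dv^2)` from the residue
  composition (c), polarity (p) and side-chain volume (v) values, with
  alpha = 1.833, beta = 0.1018, gamma = 0.000399 and rho normalised so the
  mean over the 190 heterogeneous residue pairs is exactly 100
  (rho = 50.7899).

The published matrix is *not* the formula rounded: no single rho reproduces
it (S–G = 56 needs rho >= 50.94 while V–M = 21 needs rho < 50.67).  The test
suite pins the relationship instead: the formula agrees with the matrix to
within one unit on 188/190 cells, with two historical quirks asserted
explicitly — D–W printed 181 against a formula value of 190.6 (consistent
with a transposed digit, 191 -> 181, propagated through the literature) and
N–E printed 42 against 40.9.  The mean of both routes is 100 ± 0.5.

## Composite summed rank

For candidates carrying all four of PhyloP, GERP++, CADD and Logit: each
column is ranked with the largest value at rank 1 (ties take the average of
tied positions), the four ranks are summed, and candidates are ordered by
ascending sum; rank 1 is predicted most deleterious.  Candidates missing any
of the four scores are reported unranked at the foot of the table.  Rank-sum
ties are broken by ascending SIFT, then descending CADD, then genomic
position — a deterministic package convention (the source study prints
unique ranks without a tie rule); every tie-break application is logged.
Ranking is computed within the final candidate table.  On the packaged
28-row published candidate table this ordering reproduces the four anchor
positions the study's text highlights (WNT7A 9th, MSX1 10th, CLPTM1 11th,
EVC2 23rd), leaves the score-incomplete COL6A2 row unranked, and agrees with
the printed rank column at 17 of 27 positions; the five transposed adjacent
pairs cannot be produced by any within-table rank-sum (one inverted pair
differs by 7 rank-sum units), indicating the original ranks were computed
over a larger, undeposited variant universe.  `analysis/03` prints this
agreement; the acceptance suite asserts the full column and therefore
documents the discrepancy as a failure rather than hiding it.

## Synthetic cohorts

The generator emulates the motivating study design, not population genetics:

* **Pedigrees** — seven families: two sequenced singleton probands, two
  sequenced parent–offspring pairs, two sequenced sib pairs, one sequenced
  avuncular pair; each family carries 2–6 affected members, not all
  sequenced; one family includes a sequenced member of unknown affection to
  exercise the affection-coding rules.
* **Planted variants** — one per family, heterozygous in all sequenced
  affecteds, depth in [20, 80], panel gene outside the blacklist, absent
  from all novelty databases, scores passing every default threshold.  Five
  are missense, one stopgain and one splicing (ΔMaxEnt >= 5), so both
  candidate tables are exercised.
* **Decoys** — 200 per family by default, spread over nine failure modes
  (off-panel, database-known, low depth, homopolymer, synonymous,
  non-shared, cross-family, low splice differential, blacklisted gene) by
  largest-remainder apportionment.  Every decoy is *single-fault*: it
  violates exactly its assigned rule and passes all others, so the filter
  trace attributes each removal unambiguously, and disabling exactly that
  stage (a `disabled_stages` diagnostic in `FilterConfig`) makes exactly
  that stage's decoys survive.  In singleton-proband families a non-shared
  decoy is realised as a missing (uncalled) genotype in the sole sequenced
  affected — a joint-calling artifact pattern — because a one-member sharing
  quantifier cannot fail on hom-ref alone.
* **Scores** — drawn uniformly inside pass/fail bands around the published
  thresholds, including values at the boundaries themselves (SIFT 0.05,
  PolyPhen-2 0.447, MutationTaster 0.95) to exercise strict-versus-non-strict
  semantics.  They are *not* sampled from realistic genome-wide score
  distributions, and positions live on one artificial contig with generated
  reference contexts: passing tests demonstrate rule correctness and
  recovery under the assumed inheritance model, not performance on real
  exomes (no empirical site-frequency spectrum, no LD, no alignment error
  model, no incomplete penetrance).
* **Determinism** — a fixed seed yields byte-identical output files.

## Numerical and degenerate-input conventions

Coordinates are 1-based fully closed (VCF convention) everywhere.
Multi-allelic sites are decomposed into one record per ALT allele.  Missing
annotation values (`.`/`-`) map to absent; absent scores contribute "not
damaging" to every verdict.  A record with no annotation row is treated as
absent from all databases (kept by novelty, logged), but a missense record
with no scores fails the damaging gate — both fail-closed in the direction
that protects the final table's interpretability.  Empty cohorts produce
empty traces; duplicate variant keys in one input are a hard error.

## Problem sizes used in the checks

The recovery benchmark runs 20 independent seeds at the default design
(7 families x ~201 variants, ~1 400 decoys per cohort).  Oracle-equivalence
checks run 100 random cohorts of up to 200 variants against an independent
rule-conjunction oracle and 100 random score tables of up to 12 rows against
an exhaustive ranking oracle.  These sizes give full coverage of every rule
boundary while keeping the whole suite interactive; the cascade itself is
linear in variants x families and handles exome-scale inputs without any
special handling.
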