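# varprio

Family-based rare-variant prioritization for multi-case pedigrees.

When a complex phenotype clusters in families, a subset of those families
may segregate a single highly penetrant coding mutation.  `varprio`
implements the exome-analysis strategy used to find such candidates: a
filter cascade over multi-sample variant calls from several pedigrees
(consequence class → gene panel → read depth → homopolymer context →
mutable-gene blacklist → database novelty → splice-model differential →
within-family sharing → cross-family exclusion → damaging-by-≥1-metric),
Grantham substitution scoring, and a composite summed-rank that orders the
surviving missense candidates from most to least deleterious.

The composite rank aggregates PhyloP, GERP++, CADD and Logit: each score
column is ranked separately (largest value = rank 1, ties averaged), the
four per-variant ranks are summed, and candidates are ordered by ascending
sum, so rank 1 is predicted most deleterious.  Grantham distances come from
the canonical published matrix, with a first-principles implementation
(`D = ρ·[α(Δc)² + β(Δp)² + γ(Δv)²]^½`, normalised to mean 100) alongside.
Deleteriousness calls use the conventional cutoffs: SIFT < 0.05,
PolyPhen-2 > 0.447 / ≥ 0.909, MutationTaster > 0.95, Grantham > 100.

Because studies of this design rarely deposit raw exomes, the package ships
a synthetic cohort generator that emulates the study structure — seven
multi-case families with planted causal variants shared by all sequenced
affecteds, plus single-fault decoys covering every filter failure mode — so
the whole pipeline is testable end to end against a known truth manifest.

## Worked example

```sh
varprio simulate --seed 9 --n-background 27 --out sim
varprio run --vcf sim/CL1.vcf --vcf sim/CL2.vcf --vcf sim/CL3.vcf \
    --vcf sim/CL4.vcf --vcf sim/CL5.vcf --vcf sim/CL6.vcf --vcf sim/CL7.vcf \
    --ped sim/cohort.ped --sequenced sim/sequenced.txt \
    --annotations sim/annotations.tsv --panel sim/panel.txt \
    --blacklist sim/blacklist.txt --contexts sim/contexts.json --out run
```

prints the attrition trace and candidate counts:

```
effect_class        196 -> 175
panel               175 -> 154
depth               154 -> 133
homopolymer         133 -> 112
mutable_gene        112 -> 91
novelty              91 -> 70
splicing             70 -> 49
family_sharing       49 -> 28
cross_family         28 -> 7
damaging              7 -> 7
2 truncating/splicing/indel and 5 ranked missense candidates
```

Each stage removed exactly its share of the 189 single-fault decoys, and the
7 survivors are the 7 planted causal variants: 5 missense (ranked 1–5 in
`run/missense_candidates.tsv`) and 2 truncating/splicing
(`run/truncating_candidates.tsv`).  `varprio rank table.tsv` ranks an external
candidate table on its own; `varprio trace run/report.json` re-prints a
stored trace.

The same steps are available as a scripted narrative under `analysis/`
(`01_simulate_cohort.py`, `02_run_cascade.py`,
`03_rank_published_candidates.py`, `04_recovery_benchmark.py`), writing
their tables under `results/`.  Step 03 ranks the packaged 28-row published
candidate table and prints

```
WNT7A   S340N   rank  9  (rank sum 41.5)
MSX1    P260T   rank 10  (rank sum 42.5)
CLPTM1  N353S   rank 11  (rank sum 45.0)
EVC2    E846K   rank 23  (rank sum 80.0)
unranked (incomplete scores): COL6A2
```

— the four previously phenotype-associated genes land at the positions the
source study highlights, and the row with incomplete scores is emitted
unranked.  Step 04 confirms sensitivity 1.000 with zero surviving decoys
over 20 independent cohorts.

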