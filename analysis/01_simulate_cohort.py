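#!/usr/bin/env python
"""Generate the default synthetic pedigree cohort used by the later steps.

Seven multi-case families (two sequenced singletons, two parent-offspring
pairs, two sib pairs, one avuncular pair), one planted heterozygous causal
variant per family, 200 single-fault background decoys per family.  Writes
per-family VCFs, PED + sequenced sidecar, annotation TSV, panel, blacklist,
reference contexts and the truth manifest under scratch/cohort/
(regenerable intermediate data, deliberately outside results/).
"""
import sys
from pathlib import Path

from varprio.simulate import SimulationConfig, generate_cohort

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
out = Path(__file__).resolve().parents[1] / "scratch" / "cohort"
cohort = generate_cohort(SimulationConfig(seed=seed), out)

print(f"seed {seed}: wrote cohort to {out}")
print(f"  families: {len(cohort.pedigree.families)}")
print(f"  planted causal variants: {len(cohort.manifest.planted_keys())}")
print(f"  background decoys: {len(cohort.manifest.decoys)}")
print(f"  panel genes: {len(cohort.panel_genes)}; blacklist: {len(cohort.blacklist_genes)}")
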