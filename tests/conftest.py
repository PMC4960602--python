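"""Shared fixtures and independent oracles for the test suite.

The brute-force helpers here deliberately re-derive every filtering and
ranking rule from scratch (set comprehensions over independent predicates,
positional rank counting) so they can serve as oracles for the pipeline
implementations without sharing code with them.
"""
from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pytest

from varprio import FilterConfig, GenePanel
from varprio.model import (
    Call,
    Family,
    Genotype,
    Member,
    PedigreeCohort,
    ScoreSet,
    VariantRecord,
)
from varprio.simulate import SimulationConfig, generate_cohort

# ---------------------------------------------------------------------------
# cohort fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def small_cohort():
    """In-memory synthetic cohort, 45 background variants per family."""
    return generate_cohort(SimulationConfig(seed=11, n_background_per_family=45))


@pytest.fixture(scope="session")
def small_cohort_config(small_cohort):
    return FilterConfig(
        panel=GenePanel(frozenset(small_cohort.panel_genes)),
        mutable_blacklist=frozenset(small_cohort.blacklist_genes),
    )


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory) -> Path:
    """A small cohort written to disk in every pipeline input format."""
    out = tmp_path_factory.mktemp("cohort")
    generate_cohort(SimulationConfig(seed=7, n_background_per_family=30), out)
    return out


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------


def _max_run_overlapping(context: str, lo: int, hi: int) -> int:
    best = 0
    for m in re.finditer(r"(.)\1*", context):
        if m.start() <= hi and m.end() - 1 >= lo:
            best = max(best, m.end() - m.start())
    return best


def _damaging_any(ss: ScoreSet, t) -> bool:
    checks = {
        "sift": ss.sift is not None and ss.sift < t.sift_max,
        "polyphen": ss.polyphen2_humvar is not None
        and (ss.polyphen2_humvar > t.polyphen_possibly
             or ss.polyphen2_humvar >= t.polyphen_probably),
        "mutation_taster": ss.mutation_taster is not None
        and ss.mutation_taster > t.mutation_taster_min,
        "lrt": ss.lrt_call == "deleterious",
        "phylop": ss.phylop is not None and ss.phylop > t.phylop_min,
        "gerp": ss.gerp is not None and ss.gerp > t.gerp_min,
        "grantham": ss.grantham is not None and ss.grantham > t.grantham_radical,
    }
    return any(checks[m] for m in t.gate_metrics)


def brute_force_survivors(records, scores, pedigree, config, contexts):
    """Conjunction-of-independent-rules oracle for the whole cascade.

    Returns {(family_id, variant_key)} for surviving per-family candidates.
    """
    def per_variant_ok(rec: VariantRecord) -> bool:
        ss = scores.get(rec.key)
        if rec.effect_class not in config.effect_classes_kept:
            return False
        if rec.gene.upper() not in {g.upper() for g in config.panel.genes}:
            return False
        if rec.gene.upper() in config.mutable_blacklist:
            return False
        for fam in pedigree.families:
            for m in fam.sequenced_affected():
                g = rec.genotypes.get(m.sample_id)
                if g and g.call in (Call.het, Call.hom_alt) and g.depth < config.min_depth:
                    return False
        ctx = None if contexts is None else contexts.get(rec.key)
        if ctx is not None:
            centre = len(ctx) // 2
            if _max_run_overlapping(ctx, centre, centre + len(rec.ref) - 1) >= config.homopolymer_min_run:
                return False
        if ss is not None:
            if config.rarity_preset == "novel":
                if ss.known_in & config.novelty_databases:
                    return False
            elif ss.kg_maf is not None and ss.kg_maf >= 0.01:
                return False
        if rec.effect_class == "splicing":
            dme = None if ss is None else ss.delta_maxent
            if dme is None or abs(dme) < config.delta_maxent_min:
                return False
        if rec.effect_class == "nonsynonymous_SNV":
            if not _damaging_any(ss if ss is not None else ScoreSet(), config.thresholds):
                return False
        return True

    def shared(rec: VariantRecord, fam: Family) -> bool:
        members = fam.sequenced_affected()
        return bool(members) and all(
            (g := rec.genotypes.get(m.sample_id)) is not None
            and g.call in (Call.het, Call.hom_alt)
            for m in members
        )

    n_sharing = {rec.key: sum(shared(rec, f) for f in pedigree.families) for rec in records}
    return {
        (fam.family_id, rec.key)
        for rec in records
        for fam in pedigree.families
        if per_variant_ok(rec) and shared(rec, fam) and n_sharing[rec.key] == 1
    }


def brute_force_rank_order(table: list[dict]) -> list[int]:
    """Exhaustive summed-rank ordering oracle for small score tables.

    ``table`` rows carry phylop/gerp/cadd/logit (+ optional sift, position).
    Returns row indices from most to least deleterious using positional
    average-rank counting and the same deterministic tie-break contract as
    the implementation (ascending SIFT, descending CADD, position).
    """
    def column_rank(values, x):
        greater = sum(1 for v in values if v > x)
        equal = sum(1 for v in values if v == x)
        return greater + (equal + 1) / 2

    sums = []
    for i, row in enumerate(table):
        total = 0.0
        for col in ("phylop", "gerp", "cadd", "logit"):
            values = [r[col] for r in table]
            total += column_rank(values, row[col])
        sums.append((total, row.get("sift", float("inf")), -row["cadd"], row.get("pos", i), i))
    return [i for *_, i in sorted(sums)]


# ---------------------------------------------------------------------------
# random (non-single-fault) cohort construction for oracle equivalence
# ---------------------------------------------------------------------------


def make_random_cohort(rng: np.random.Generator):
    """A fully random small cohort: faults may combine arbitrarily."""
    n_fam = int(rng.integers(2, 5))
    families = []
    for i in range(n_fam):
        fid = f"F{i}"
        n_seq = int(rng.integers(1, 4))
        members = [Member(f"{fid}_A{j}", affected=True, sequenced=True) for j in range(n_seq)]
        members.append(Member(f"{fid}_U", affected=False, sequenced=bool(rng.integers(0, 2))))
        families.append(Family(fid, members))
    pedigree = PedigreeCohort(families=families)
    panel_genes = [f"G{i}" for i in range(8)]
    config = FilterConfig(
        panel=GenePanel(frozenset(panel_genes)),
        mutable_blacklist=frozenset(panel_genes[:2]),
        rarity_preset=str(rng.choice(["novel", "rare_1pct"])),
    )
    effects = ["nonsynonymous_SNV", "stopgain", "splicing", "synonymous",
               "frameshift_deletion", "other"]
    records, scores, contexts = [], {}, {}
    n_var = int(rng.integers(5, 60))
    for i in range(n_var):
        genotypes = {}
        for fam in families:
            if rng.random() < 0.8:  # family genotyped at the site
                for m in fam.members:
                    if not m.sequenced:
                        continue
                    call = Call(str(rng.choice(["hom_ref", "het", "hom_alt", "missing"],
                                               p=[0.25, 0.5, 0.15, 0.1])))
                    genotypes[m.sample_id] = Genotype(call, int(rng.integers(0, 40)))
        rec = VariantRecord(
            chrom="1", pos=1000 + i, ref="A", alt="G",
            gene=str(rng.choice(panel_genes + ["OFF1", "OFF2"])),
            effect_class=str(rng.choice(effects)),
            genotypes=genotypes,
        )
        records.append(rec)
        if rng.random() < 0.9:
            scores[rec.key] = ScoreSet(
                sift=float(rng.choice([0.0, 0.049, 0.05, 0.3, 1.0])),
                mutation_taster=float(rng.choice([0.0, 0.95, 0.951, 1.0])),
                phylop=float(rng.uniform(-2, 8)) if rng.random() < 0.7 else None,
                gerp=float(rng.uniform(-2, 6)) if rng.random() < 0.7 else None,
                kg_maf=float(rng.choice([0.0, 0.005, 0.01, 0.02])),
                delta_maxent=float(rng.uniform(-5, 25)) if rng.random() < 0.7 else None,
                known_in=frozenset(rng.choice(["dbSNP135", "1000G", "EVS", "inhouse"],
                                              size=rng.integers(0, 3), replace=False)),
            )
        if rng.random() < 0.8:
            base = str(rng.choice(list("ACGT")))
            run = int(rng.integers(1, 9))
            ctx = (base * run).center(13, "T" if base != "T" else "C")
            contexts[rec.key] = "A" + ctx[:6] + rec.ref + ctx[7:12]  # centre = ref
    return records, scores, pedigree, config, contexts
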