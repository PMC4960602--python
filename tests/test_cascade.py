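"""Filter cascade: per-stage semantics, trace invariants, oracle equivalence."""
from __future__ import annotations

import dataclasses
import random

import numpy as np
import pytest

from conftest import brute_force_survivors, make_random_cohort
from varprio.cascade import (
    FilterConfig,
    filter_depth,
    filter_effect_class,
    filter_homopolymer,
    filter_mutable_genes,
    filter_novelty,
    filter_panel,
    filter_splicing,
    run_cascade,
)
from varprio.errors import ConfigError, JoinError
from varprio.model import (
    Call,
    Family,
    GenePanel,
    Genotype,
    Member,
    PedigreeCohort,
    ScoreSet,
    VariantRecord,
)

PANEL = GenePanel(frozenset({"MSX1", "IRF6", "WNT7A"}))


def rec(pos=100, gene="MSX1", effect="nonsynonymous_SNV", ref="C", alt="A",
        genotypes=None) -> VariantRecord:
    return VariantRecord(chrom="1", pos=pos, ref=ref, alt=alt, gene=gene,
                         effect_class=effect, genotypes=genotypes or {})


def cfg(**kwargs) -> FilterConfig:
    return FilterConfig(panel=PANEL, **kwargs)


def sib_pair(fid="F1"):
    return Family(fid, [Member(f"{fid}_A", affected=True, sequenced=True),
                        Member(f"{fid}_B", affected=True, sequenced=True)])


# -- individual stage semantics --------------------------------------------

def test_effect_class_filter():
    records = [rec(1, effect="synonymous"), rec(2, effect="stopgain"),
               rec(3, effect="nonsynonymous_SNV"), rec(4, effect="other")]
    kept, removed = filter_effect_class(records, cfg())
    assert [r.pos for r in kept] == [2, 3]
    assert len(removed) == 2
    assert filter_effect_class([], cfg()) == ([], [])


def test_panel_filter_case_normalised():
    records = [rec(1, gene="msx1"), rec(2, gene="NOTONPANEL")]
    kept, _ = filter_panel(records, cfg())
    assert [r.pos for r in kept] == [1]
    everything = FilterConfig(panel=GenePanel(frozenset({"MSX1", "NOTONPANEL"})))
    assert filter_panel(records, everything)[0] == records


@pytest.mark.parametrize("depths,removed", [((10,), False), ((9,), True), ((50, 8), True), ((50, 10), False)])
def test_depth_filter_fail_closed_over_carriers(depths, removed):
    fam = Family("F1", [Member(f"S{i}", affected=True, sequenced=True) for i in range(len(depths))])
    pedigree = PedigreeCohort(families=[fam])
    r = rec(genotypes={f"S{i}": Genotype(Call.het, d) for i, d in enumerate(depths)})
    kept, _ = filter_depth([r], pedigree, cfg())
    assert (not kept) is removed


def test_depth_ignores_noncarriers_and_unaffected():
    fam = Family("F1", [Member("A", affected=True, sequenced=True),
                        Member("U", affected=False, sequenced=True)])
    pedigree = PedigreeCohort(families=[fam])
    r = rec(genotypes={"A": Genotype(Call.het, 30), "U": Genotype(Call.het, 2)})
    assert filter_depth([r], pedigree, cfg())[0] == [r]
    r2 = rec(genotypes={"A": Genotype(Call.hom_ref, 3), "U": Genotype(Call.het, 30)})
    assert filter_depth([r2], pedigree, cfg())[0] == [r2]


def test_mutable_gene_blacklist_wins_over_panel():
    records = [rec(1, gene="MSX1"), rec(2, gene="IRF6")]
    config = cfg(mutable_blacklist=frozenset({"MSX1"}))
    kept, _ = filter_mutable_genes(records, config)
    assert [r.gene for r in kept] == ["IRF6"]
    assert filter_mutable_genes(records, cfg())[0] == records  # empty blacklist


@pytest.mark.parametrize(
    "context,removed",
    [
        ("AAAAAAAAAAAAA", True),   # run 13 >= 6
        ("ACGTACAACGTAC", False),  # max run 2
        ("GGGAAAAAAGGGG", True),   # run exactly 6 overlapping centre
        ("AAAAATACGTACG", False),  # run 5 touching centre, below threshold
        ("TTTTTTACGCGCG", False),  # run 6 but not overlapping the centre base
    ],
)
def test_homopolymer_overlap_rule(context, removed):
    r = rec(ref="A", alt="G")
    kept, _ = filter_homopolymer([r], {r.key: context}, cfg())
    assert (not kept) is removed


def test_homopolymer_without_context_passes():
    r = rec()
    kept, _ = filter_homopolymer([r], None, cfg())
    assert kept == [r]


def test_novelty_presets():
    known = rec(1)
    exac_only = rec(2)
    common_kg = rec(3)
    scores = {
        known.key: ScoreSet(known_in=frozenset({"dbSNP135"})),
        exac_only.key: ScoreSet(exac_maf=1.3e-4, kg_maf=0.0),
        common_kg.key: ScoreSet(kg_maf=0.02),
    }
    records = [known, exac_only, common_kg]
    kept, _ = filter_novelty(records, scores, cfg())
    assert [r.pos for r in kept] == [2, 3]  # novelty ignores frequencies
    kept, _ = filter_novelty(records, scores, cfg(rarity_preset="rare_1pct"))
    assert [r.pos for r in kept] == [1, 2]  # rarity ignores database presence
    unannotated = rec(4)
    assert filter_novelty([unannotated], {}, cfg())[0] == [unannotated]


@pytest.mark.parametrize("dme,removed", [(22.0, False), (3.0, False), (-8.0, False), (1.5, True), (None, True)])
def test_splice_differential_cutoff(dme, removed):
    r = rec(effect="splicing")
    scores = {} if dme is None else {r.key: ScoreSet(delta_maxent=dme)}
    kept, _ = filter_splicing([r], scores, cfg())
    assert (not kept) is removed


def test_splice_rule_scoped_to_splicing_class():
    r = rec(effect="nonsynonymous_SNV")
    assert filter_splicing([r], {}, cfg())[0] == [r]


# -- configuration ----------------------------------------------------------

@pytest.mark.parametrize(
    "kwargs",
    [dict(min_depth=-1), dict(delta_maxent_min=0), dict(homopolymer_min_run=2),
     dict(rarity_preset="bogus"), dict(effect_classes_kept=frozenset({"nope"})),
     dict(disabled_stages=frozenset({"nonstage"}))],
)
def test_config_invariants(kwargs):
    with pytest.raises(ConfigError):
        cfg(**kwargs)


def test_config_from_yaml(tmp_path):
    doc = tmp_path / "cfg.yaml"
    doc.write_text("min_depth: 15\nrarity_preset: rare_1pct\nthresholds:\n  phylop_min: 1.5\n")
    config = FilterConfig.from_yaml(doc, PANEL, ["MSX1"])
    assert config.min_depth == 15
    assert config.rarity_preset == "rare_1pct"
    assert config.thresholds.phylop_min == 1.5
    assert config.mutable_blacklist == frozenset({"MSX1"})


# -- whole-cascade properties ----------------------------------------------

def test_empty_cohort_gives_empty_trace():
    pedigree = PedigreeCohort(families=[sib_pair()])
    result = run_cascade([], {}, pedigree, cfg(), None)
    assert result.surviving_keys() == set()
    assert all(s.n_in == s.n_out == 0 for s in result.trace.stages)


def test_duplicate_input_keys_rejected():
    pedigree = PedigreeCohort(families=[sib_pair()])
    with pytest.raises(JoinError, match="duplicate"):
        run_cascade([rec(), rec()], {}, pedigree, cfg(), None)


def test_trace_counts_chain_and_decrease(small_cohort, small_cohort_config):
    c = small_cohort
    result = run_cascade(c.records, c.scores, c.pedigree, small_cohort_config, c.contexts)
    stages = result.trace.stages
    assert [s.name for s in stages] == [
        "effect_class", "panel", "depth", "homopolymer", "mutable_gene",
        "novelty", "splicing", "family_sharing", "cross_family", "damaging"]
    for s in stages:
        assert s.n_out <= s.n_in
    for prev, nxt in zip(stages, stages[1:]):
        assert nxt.n_in == prev.n_out
    assert len(result.surviving_keys()) == stages[-1].n_out


def test_survivors_invariant_under_input_order(small_cohort, small_cohort_config):
    c = small_cohort
    shuffled = list(c.records)
    random.Random(13).shuffle(shuffled)
    a = run_cascade(c.records, c.scores, c.pedigree, small_cohort_config, c.contexts)
    b = run_cascade(shuffled, c.scores, c.pedigree, small_cohort_config, c.contexts)
    assert a.surviving_keys() == b.surviving_keys()
    assert {(f, r.key) for f, r in a.missense} == {(f, r.key) for f, r in b.missense}


def test_each_filter_is_idempotent(small_cohort, small_cohort_config):
    c, config = small_cohort, small_cohort_config
    pedigree = c.pedigree
    stages = [
        lambda rs: filter_effect_class(rs, config)[0],
        lambda rs: filter_panel(rs, config)[0],
        lambda rs: filter_depth(rs, pedigree, config)[0],
        lambda rs: filter_homopolymer(rs, c.contexts, config)[0],
        lambda rs: filter_mutable_genes(rs, config)[0],
        lambda rs: filter_novelty(rs, c.scores, config)[0],
        lambda rs: filter_splicing(rs, c.scores, config)[0],
    ]
    for stage in stages:
        once = stage(list(c.records))
        assert stage(list(once)) == once


def test_cascade_equals_brute_force_oracle_on_random_cohorts():
    """Survivor sets match an independent rule-conjunction oracle."""
    for trial in range(100):
        rng = np.random.default_rng(1000 + trial)
        records, scores, pedigree, config, contexts = make_random_cohort(rng)
        result = run_cascade(records, scores, pedigree, config, contexts)
        got = {(fid, r.key) for fid, recs in result.per_family.items() for r in recs}
        expected = brute_force_survivors(records, scores, pedigree, config, contexts)
        assert got == expected, f"trial {trial}"


def test_stage_order_does_not_change_survivors(small_cohort, small_cohort_config):
    """Filters are independent predicates: the trace depends on order, the
    surviving set does not (checked by disabling a mid-cascade stage and
    applying it before the cascade instead)."""
    c, config = small_cohort, small_cohort_config
    pre_filtered, _ = filter_novelty(list(c.records), c.scores, config)
    reordered = run_cascade(pre_filtered, c.scores, c.pedigree,
                            dataclasses.replace(config, disabled_stages=frozenset({"novelty"})),
                            c.contexts)
    normal = run_cascade(c.records, c.scores, c.pedigree, config, c.contexts)
    assert reordered.surviving_keys() == normal.surviving_keys()
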