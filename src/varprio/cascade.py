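"""Ordered variant-attrition cascade for multi-case pedigree cohorts.

Candidate variants must, in order: carry a kept consequence class; fall in
the gene panel; be well covered (read depth >= 10 in every sequenced affected
carrier); lie outside homopolymer runs; avoid the highly-mutable gene
blacklist; be novel (absent from dbSNP135/1000G/EVS/in-house — low-frequency
ExAC presence alone never disqualifies) or, under the ``rare_1pct`` preset,
rare (<1% in 1000 Genomes); pass the splice-model differential for splicing
records; be shared by every sequenced affected member of a family; be private
to a single family; and (missense only) be called damaging by at least one
predictive metric.  Every stage's attrition is recorded in a trace.

All filters are independent per-variant/per-family predicates, so stage
order affects only the trace, never the surviving set.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

import yaml

from .errors import ConfigError, JoinError
from .model import (
    EFFECT_CLASSES,
    KNOWN_DB_TAGS,
    GenePanel,
    PedigreeCohort,
    ScoreSet,
    VariantKey,
    VariantRecord,
)
from .prioritize import exclude_cross_family, shared_in_family
from .scoring import Thresholds, classify_damaging

logger = logging.getLogger(__name__)

DEFAULT_KEPT_CLASSES = frozenset(EFFECT_CLASSES - {"synonymous", "other"})

#: Cascade stage names, in execution order.
STAGES = (
    "effect_class",
    "panel",
    "depth",
    "homopolymer",
    "mutable_gene",
    "novelty",
    "splicing",
    "family_sharing",
    "cross_family",
    "damaging",
)


@dataclass
class FilterConfig:
    """Every threshold and list the cascade consults."""

    panel: GenePanel
    min_depth: int = 10
    mutable_blacklist: frozenset[str] = frozenset()
    novelty_databases: frozenset[str] = frozenset(KNOWN_DB_TAGS)
    rarity_preset: str = "novel"  # or "rare_1pct"
    splice_window_bp: int = 10
    delta_maxent_min: float = 3.0
    homopolymer_min_run: int = 6
    effect_classes_kept: frozenset[str] = DEFAULT_KEPT_CLASSES
    thresholds: Thresholds = field(default_factory=Thresholds)
    #: stages to skip entirely (diagnostic use, e.g. single-fault attribution)
    disabled_stages: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not set(self.disabled_stages) <= set(STAGES):
            raise ConfigError(f"unknown stages: {sorted(set(self.disabled_stages) - set(STAGES))}")
        if self.min_depth < 0:
            raise ConfigError("min_depth must be >= 0")
        if self.delta_maxent_min <= 0:
            raise ConfigError("delta_maxent_min must be > 0")
        if self.homopolymer_min_run < 3:
            raise ConfigError("homopolymer_min_run must be >= 3")
        if self.rarity_preset not in ("novel", "rare_1pct"):
            raise ConfigError(f"unknown rarity preset {self.rarity_preset!r}")
        unknown = set(self.effect_classes_kept) - EFFECT_CLASSES
        if unknown:
            raise ConfigError(f"unknown effect classes kept: {sorted(unknown)}")
        self.mutable_blacklist = frozenset(g.upper() for g in self.mutable_blacklist)

    @classmethod
    def from_yaml(cls, path: str | Path, panel: GenePanel,
                  blacklist: Iterable[str] = ()) -> "FilterConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        thr = Thresholds(**doc.pop("thresholds", {}))
        for key in ("effect_classes_kept", "novelty_databases"):
            if key in doc:
                doc[key] = frozenset(doc[key])
        return cls(panel=panel, mutable_blacklist=frozenset(blacklist), thresholds=thr, **doc)


@dataclass
class Stage:
    name: str
    n_in: int
    n_out: int
    removed_sample: list[VariantKey] = field(default_factory=list)


@dataclass
class FilterTrace:
    stages: list[Stage] = field(default_factory=list)
    #: full removal attribution per stage (the per-stage ``removed_sample``
    #: lists are capped for display; this is the complete bookkeeping)
    removed_by_stage: dict[str, set[VariantKey]] = field(default_factory=dict)

    def record(self, name: str, n_in: int, n_out: int, removed: list[VariantKey]) -> None:
        self.stages.append(Stage(name, n_in, n_out, sorted(removed)[:10]))
        self.removed_by_stage[name] = set(removed)

    def as_rows(self) -> list[dict]:
        return [
            {"stage": s.name, "variants_in": s.n_in, "variants_out": s.n_out}
            for s in self.stages
        ]


@dataclass
class CascadeResult:
    """Survivors partitioned the way the published candidate tables are."""

    per_family: dict[str, list[VariantRecord]]
    truncating: list[tuple[str, VariantRecord]]  # (family_id, record)
    missense: list[tuple[str, VariantRecord]]
    trace: FilterTrace

    def surviving_keys(self) -> set[VariantKey]:
        return {r.key for records in self.per_family.values() for r in records}


# ---------------------------------------------------------------------------
# Individual filters.  Each returns (kept, removed_keys).
# ---------------------------------------------------------------------------

def filter_effect_class(records: list[VariantRecord], config: FilterConfig):
    kept = [r for r in records if r.effect_class in config.effect_classes_kept]
    return kept, [r.key for r in records if r.effect_class not in config.effect_classes_kept]


def filter_panel(records: list[VariantRecord], config: FilterConfig):
    kept = [r for r in records if r.gene in config.panel]
    return kept, [r.key for r in records if r.gene not in config.panel]


def _low_depth(record: VariantRecord, pedigree: PedigreeCohort, min_depth: int) -> bool:
    """True when any sequenced affected carrier is covered below ``min_depth``.

    Fail-closed: a low-depth genotype in any carrier whose sharing evidence
    the pipeline relies on makes that evidence unreliable.
    """
    for fam in pedigree.families:
        for m in fam.sequenced_affected():
            g = record.genotypes.get(m.sample_id)
            if g is not None and g.call.carries_alt() and g.depth < min_depth:
                return True
    return False


def filter_depth(records: list[VariantRecord], pedigree: PedigreeCohort, config: FilterConfig):
    kept, removed = [], []
    for r in records:
        (removed if _low_depth(r, pedigree, config.min_depth) else kept).append(r)
    return kept, [r.key for r in removed]


def filter_mutable_genes(records: list[VariantRecord], config: FilterConfig):
    kept = [r for r in records if r.gene.upper() not in config.mutable_blacklist]
    return kept, [r.key for r in records if r.gene.upper() in config.mutable_blacklist]


def _in_homopolymer(record: VariantRecord, context: str, min_run: int) -> bool:
    """True when a single-base run of length >= min_run overlaps the locus.

    ``context`` is a reference window whose centre base is the variant
    position; the variant footprint spans len(ref) bases from the centre.
    """
    centre = len(context) // 2
    lo, hi = centre, centre + len(record.ref) - 1
    run_start = 0
    for i in range(1, len(context) + 1):
        if i == len(context) or context[i] != context[run_start]:
            if i - run_start >= min_run and run_start <= hi and i - 1 >= lo:
                return True
            run_start = i
    return False


def filter_homopolymer(records: list[VariantRecord],
                       contexts: Optional[Mapping[VariantKey, str]],
                       config: FilterConfig):
    kept, removed = [], []
    for r in records:
        context = None if contexts is None else contexts.get(r.key)
        if context is None:
            logger.warning("no reference context for %s; homopolymer check skipped", r.key)
            kept.append(r)
        elif _in_homopolymer(r, context, config.homopolymer_min_run):
            removed.append(r)
        else:
            kept.append(r)
    return kept, [r.key for r in removed]


def filter_novelty(records: list[VariantRecord],
                   scores: Mapping[VariantKey, ScoreSet],
                   config: FilterConfig):
    kept, removed = [], []
    for r in records:
        ss = scores.get(r.key)
        if ss is None:
            logger.info("no annotation for %s; treated as absent from all databases", r.key)
            kept.append(r)
            continue
        if config.rarity_preset == "novel":
            drop = bool(ss.known_in & config.novelty_databases)
        else:  # rare_1pct
            drop = ss.kg_maf is not None and ss.kg_maf >= 0.01
        (removed if drop else kept).append(r)
    return kept, [r.key for r in removed]


def filter_splicing(records: list[VariantRecord],
                    scores: Mapping[VariantKey, ScoreSet],
                    config: FilterConfig):
    kept, removed = [], []
    for r in records:
        if r.effect_class != "splicing":
            kept.append(r)
            continue
        ss = scores.get(r.key)
        dme = None if ss is None else ss.delta_maxent
        if dme is None:
            logger.warning("splicing record %s lacks a MaxEntScan differential; dropped", r.key)
            removed.append(r)
        elif abs(dme) >= config.delta_maxent_min:
            kept.append(r)
        else:
            removed.append(r)
    return kept, [r.key for r in removed]


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

def run_cascade(records: list[VariantRecord],
                scores: Mapping[VariantKey, ScoreSet],
                pedigree: PedigreeCohort,
                config: FilterConfig,
                contexts: Optional[Mapping[VariantKey, str]] = None) -> CascadeResult:
    """Apply the full attrition cascade and return partitioned survivors."""
    keys = [r.key for r in records]
    if len(keys) != len(set(keys)):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise JoinError(f"duplicate variant keys in input: {dupes[:3]}")

    trace = FilterTrace()
    current = list(records)

    def apply(name: str, kept: list[VariantRecord], removed: list[VariantKey]) -> None:
        trace.record(name, len(kept) + len(removed), len(kept), removed)

    for name, fn in (
        ("effect_class", lambda rs: filter_effect_class(rs, config)),
        ("panel", lambda rs: filter_panel(rs, config)),
        ("depth", lambda rs: filter_depth(rs, pedigree, config)),
        ("homopolymer", lambda rs: filter_homopolymer(rs, contexts, config)),
        ("mutable_gene", lambda rs: filter_mutable_genes(rs, config)),
        ("novelty", lambda rs: filter_novelty(rs, scores, config)),
        ("splicing", lambda rs: filter_splicing(rs, scores, config)),
    ):
        if name in config.disabled_stages:
            continue
        kept, removed = fn(current)
        apply(name, kept, removed)
        current = kept

    # Family sharing: a variant becomes a per-family candidate where every
    # sequenced affected member carries the alternate allele.  With the stage
    # disabled, membership degrades to "any of the family's samples genotyped
    # at the site" so later stages still see per-family candidate sets.
    per_family: dict[str, list[VariantRecord]] = {}
    for fam in pedigree.families:
        if "family_sharing" in config.disabled_stages:
            sample_ids = set(fam.sample_ids())
            per_family[fam.family_id] = [r for r in current if sample_ids & r.genotypes.keys()]
        else:
            per_family[fam.family_id] = shared_in_family(current, fam)
    shared_keys = {r.key for recs in per_family.values() for r in recs}
    if "family_sharing" not in config.disabled_stages:
        trace.record("family_sharing", len(current), len(shared_keys),
                     [r.key for r in current if r.key not in shared_keys])

    # Cross-family exclusion: variants candidate in >= 2 families are
    # regionally recurrent, not family-private; dropped everywhere.
    before = set(shared_keys)
    if "cross_family" not in config.disabled_stages:
        per_family = exclude_cross_family(per_family)
        after = {r.key for recs in per_family.values() for r in recs}
        trace.record("cross_family", len(before), len(after), sorted(before - after))
    else:
        after = before

    # Damaging-by-at-least-one-metric gate, missense records only; truncating,
    # splicing and indel records bypass it into the truncating table.
    n_in = len(after)
    gated: dict[str, list[VariantRecord]] = {}
    removed_gate: list[VariantKey] = []
    if "damaging" in config.disabled_stages:
        gated = per_family
    else:
        for fid, recs in per_family.items():
            kept_recs = []
            for r in recs:
                if r.is_missense:
                    ss = scores.get(r.key, ScoreSet())
                    if not classify_damaging(ss, config.thresholds).any_damaging:
                        removed_gate.append(r.key)
                        continue
                kept_recs.append(r)
            gated[fid] = kept_recs
    final_keys = {r.key for recs in gated.values() for r in recs}
    if "damaging" not in config.disabled_stages:
        trace.record("damaging", n_in, len(final_keys), sorted(set(removed_gate)))

    truncating = [(fid, r) for fid, recs in sorted(gated.items()) for r in recs
                  if not r.is_missense]
    missense = [(fid, r) for fid, recs in sorted(gated.items()) for r in recs
                if r.is_missense]
    return CascadeResult(per_family=gated, truncating=truncating,
                         missense=missense, trace=trace)


def with_stage_disabled(config: FilterConfig, stage: str) -> FilterConfig:
    """A copy of ``config`` with the named stage switched off (diagnostics)."""
    return replace(config, disabled_stages=config.disabled_stages | {stage})
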