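"""Family sharing logic and the composite summed-rank ordering.

The composite rank aggregates PhyloP, GERP++, CADD and Logit: each column is
ranked separately (largest score = rank 1 = most deleterious, ties receiving
the average of tied positions), the four per-variant ranks are summed, and
candidates are ordered by ascending rank sum so the variant with overall
rank 1 is predicted most deleterious.  Candidates missing any of the four
scores are reported unranked at the foot of the table.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import PedigreeError
from .model import Family, ScoreSet, VariantKey, VariantRecord
from .scoring import DamagingVerdict

logger = logging.getLogger(__name__)

COMPOSITE_SCORES = ("phylop", "gerp", "cadd", "logit")


def shared_in_family(records: Sequence[VariantRecord], family: Family) -> list[VariantRecord]:
    """Records carried (het or hom-alt) by every sequenced affected member.

    A missing genotype in any sequenced affected member excludes the record:
    segregation support must be positive, not merely uncontradicted.
    """
    members = family.sequenced_affected()
    if not members:
        raise PedigreeError(f"family {family.family_id} has no sequenced affected members")
    out = []
    for rec in records:
        calls = [rec.genotypes.get(m.sample_id) for m in members]
        if all(g is not None and g.call.carries_alt() for g in calls):
            out.append(rec)
    return out


def exclude_cross_family(per_family: dict[str, list[VariantRecord]]) -> dict[str, list[VariantRecord]]:
    """Drop, from every family, any variant that is a candidate in >= 2 families."""
    counts: dict[VariantKey, int] = {}
    for recs in per_family.values():
        for r in recs:
            counts[r.key] = counts.get(r.key, 0) + 1
    return {
        fid: [r for r in recs if counts[r.key] == 1]
        for fid, recs in per_family.items()
    }


def rank_column(values: Sequence[float], larger_is_worse: bool = True) -> list[float]:
    """Average-tie ranks with rank 1 = most deleterious.

    ``larger_is_worse=True`` means the largest value receives rank 1.
    """
    if len(values) == 0:
        raise ValueError("cannot rank an empty column")
    arr = np.asarray(values, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("rank_column requires complete values; exclude unscored candidates first")
    return list(rankdata(-arr if larger_is_worse else arr, method="average"))


@dataclass
class RankedCandidate:
    """A surviving variant with its per-metric verdicts and composite rank."""

    variant: VariantRecord
    family_id: str
    scores: ScoreSet
    verdict: Optional[DamagingVerdict] = None
    ranks: dict[str, float] = field(default_factory=dict)
    rank_sum: Optional[float] = None
    overall_rank: Optional[int] = None  # None = unranked (incomplete scores)

    @property
    def fully_scored(self) -> bool:
        return all(getattr(self.scores, s) is not None for s in COMPOSITE_SCORES)


def composite_rank(candidates: Sequence[RankedCandidate]) -> list[RankedCandidate]:
    """Assign summed-rank composite ordering in place; return candidates sorted.

    Fully scored candidates receive overall ranks 1..K with no gaps; the rest
    are appended unranked.  Rank-sum ties are broken deterministically by
    ascending SIFT, then descending CADD, then genomic position (a package
    tie-break, logged whenever exercised).
    """
    scored = [c for c in candidates if c.fully_scored]
    unscored = [c for c in candidates if not c.fully_scored]
    for c in unscored:
        c.ranks, c.rank_sum, c.overall_rank = {}, None, None

    if scored:
        for score_name in COMPOSITE_SCORES:
            column = rank_column([getattr(c.scores, score_name) for c in scored])
            for c, r in zip(scored, column):
                c.ranks[f"{score_name}_rank"] = r
        for c in scored:
            c.rank_sum = sum(c.ranks.values())

        def tie_break(c: RankedCandidate):
            sift = c.scores.sift if c.scores.sift is not None else float("inf")
            cadd = c.scores.cadd if c.scores.cadd is not None else float("-inf")
            return (sift, -cadd, c.variant.chrom, c.variant.pos, c.variant.ref, c.variant.alt)

        sums = [c.rank_sum for c in scored]
        if len(set(sums)) != len(sums):
            tied = sorted({s for s in sums if sums.count(s) > 1})
            logger.warning("rank-sum tie(s) at %s broken by SIFT/CADD/position", tied)
        scored.sort(key=lambda c: (c.rank_sum, *tie_break(c)))
        for position, c in enumerate(scored, start=1):
            c.overall_rank = position
    return scored + unscored
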