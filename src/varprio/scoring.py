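"""Per-metric deleteriousness classification and missense-notation parsing.

The published thresholds, applied with their exact inequality senses:
SIFT < 0.05 (affects protein function); PolyPhen-2 HumVar > 0.447 possibly
damaging and >= 0.909 probably damaging; MutationTaster > 0.95 damaging;
Grantham > 100 radical amino-acid change.  PhyloP and GERP++ cutoffs were
not published; the defaults here (> 2.0 each) are package choices and are
configurable.  LRT contributes through its categorical call.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .errors import ConfigError
from .grantham import grantham_distance, grantham_distance_formula  # noqa: F401  (re-export)
from .model import ScoreSet

#: Metrics the damaging-by-at-least-one gate consults by default.  Grantham is
#: reported but deliberately excluded: a radical substitution is descriptive,
#: not one of the six predictive metrics of the published gate.
DEFAULT_GATE_METRICS = frozenset({"sift", "polyphen", "mutation_taster", "lrt", "phylop", "gerp"})


@dataclass(frozen=True)
class Thresholds:
    """Deleteriousness cutoffs.  ``phylop_min``/``gerp_min`` are non-published defaults."""

    sift_max: float = 0.05          # damaging iff score <  sift_max
    polyphen_possibly: float = 0.447  # possibly damaging iff score >  this
    polyphen_probably: float = 0.909  # probably damaging iff score >= this
    mutation_taster_min: float = 0.95  # damaging iff score >  this
    grantham_radical: float = 100.0    # radical iff score >  this
    phylop_min: float = 2.0         # conserved iff score > this (package default)
    gerp_min: float = 2.0           # constrained iff score > this (package default)
    gate_metrics: frozenset[str] = DEFAULT_GATE_METRICS

    def __post_init__(self) -> None:
        unknown = set(self.gate_metrics) - {"sift", "polyphen", "mutation_taster",
                                            "lrt", "phylop", "gerp", "grantham"}
        if unknown:
            raise ConfigError(f"unknown gate metrics: {sorted(unknown)}")


@dataclass
class DamagingVerdict:
    sift_damaging: bool = False
    polyphen_possibly: bool = False
    polyphen_probably: bool = False
    mutation_taster_damaging: bool = False
    grantham_radical: bool = False
    lrt_deleterious: bool = False
    phylop_conserved: bool = False
    gerp_constrained: bool = False
    any_damaging: bool = False


def classify_damaging(scores: ScoreSet, thresholds: Thresholds = Thresholds()) -> DamagingVerdict:
    """Apply every per-metric cutoff; absent scores contribute False throughout."""
    t = thresholds
    v = DamagingVerdict()
    if scores.sift is not None:
        v.sift_damaging = scores.sift < t.sift_max
    if scores.polyphen2_humvar is not None:
        v.polyphen_probably = scores.polyphen2_humvar >= t.polyphen_probably
        # probably damaging implies possibly damaging even though the printed
        # cutoffs (>0.447 vs >=0.909) would otherwise allow a gap at exactly 0.909
        v.polyphen_possibly = scores.polyphen2_humvar > t.polyphen_possibly or v.polyphen_probably
    if scores.mutation_taster is not None:
        v.mutation_taster_damaging = scores.mutation_taster > t.mutation_taster_min
    if scores.grantham is not None:
        v.grantham_radical = scores.grantham > t.grantham_radical
    if scores.lrt_call is not None:
        v.lrt_deleterious = scores.lrt_call == "deleterious"
    if scores.phylop is not None:
        v.phylop_conserved = scores.phylop > t.phylop_min
    if scores.gerp is not None:
        v.gerp_constrained = scores.gerp > t.gerp_min
    by_metric = {
        "sift": v.sift_damaging,
        "polyphen": v.polyphen_possibly,
        "mutation_taster": v.mutation_taster_damaging,
        "lrt": v.lrt_deleterious,
        "phylop": v.phylop_conserved,
        "gerp": v.gerp_constrained,
        "grantham": v.grantham_radical,
    }
    v.any_damaging = any(by_metric[m] for m in t.gate_metrics)
    return v


_MISSENSE_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_NON_MISSENSE_TARGETS = {"X", "*"}  # stopgain notation


def protein_change_residues(protein_change: Optional[str]) -> Optional[tuple[str, str]]:
    """Parse "R721C"-style missense notation into (reference, alternate) residues.

    Anything that is not simple missense notation between two standard
    residues (stopgains like "E2452X", indels like "308_309del", empty or
    absent strings) yields ``None``.
    """
    if not protein_change:
        return None
    m = _MISSENSE_RE.match(protein_change.strip())
    if not m:
        return None
    aa_from, aa_to = m.group(1), m.group(3)
    from .grantham import AMINO_ACID_PROPERTIES

    if aa_from not in AMINO_ACID_PROPERTIES or aa_to not in AMINO_ACID_PROPERTIES:
        return None
    return aa_from, aa_to
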