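"""Run-level report assembly and rendering (candidate tables, trace, JSON)."""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .cascade import CascadeResult, FilterConfig
from .model import ScoreSet, VariantKey
from .prioritize import RankedCandidate, composite_rank
from .scoring import classify_damaging

TABLE_COLUMNS = [
    "gene", "genomic_position", "transcript_id", "exon", "cdna_change",
    "protein_change", "effect_class", "exac_maf", "sift", "polyphen2",
    "mutation_taster", "grantham", "phylop", "gerp", "cadd", "logit",
    "delta_maxent", "rank", "family",
]


@dataclass
class RunReport:
    """Everything one pipeline run produced, ready to serialize."""

    config: dict
    trace_rows: list[dict]
    truncating: pd.DataFrame
    missense: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "config": self.config,
            "trace": self.trace_rows,
            "truncating_candidates": self.truncating.fillna(".").to_dict(orient="records"),
            "missense_candidates": self.missense.fillna(".").to_dict(orient="records"),
            "warnings": self.warnings,
        }

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "report": out / "report.json",
            "truncating": out / "truncating_candidates.tsv",
            "missense": out / "missense_candidates.tsv",
            "trace": out / "trace.tsv",
        }
        paths["report"].write_text(json.dumps(self.to_json_dict(), indent=1, default=str))
        self.truncating.to_csv(paths["truncating"], sep="\t", index=False, na_rep=".")
        self.missense.to_csv(paths["missense"], sep="\t", index=False, na_rep=".")
        pd.DataFrame(self.trace_rows).to_csv(paths["trace"], sep="\t", index=False)
        return paths


def _candidate_row(cand: RankedCandidate) -> dict:
    v, s = cand.variant, cand.scores
    return {
        "gene": v.gene,
        "genomic_position": f"{v.chrom}:{v.pos}",
        "transcript_id": v.transcript_id,
        "exon": v.exon,
        "cdna_change": v.cdna_change,
        "protein_change": v.protein_change,
        "effect_class": v.effect_class,
        "exac_maf": s.exac_maf,
        "sift": s.sift,
        "polyphen2": s.polyphen2_humvar,
        "mutation_taster": s.mutation_taster,
        "grantham": s.grantham,
        "phylop": s.phylop,
        "gerp": s.gerp,
        "cadd": s.cadd,
        "logit": s.logit,
        "delta_maxent": s.delta_maxent,
        "rank": cand.overall_rank if cand.overall_rank is not None else "-",
        "family": cand.family_id,
    }


def build_report(result: CascadeResult,
                 scores: Mapping[VariantKey, ScoreSet],
                 config: FilterConfig,
                 warnings: Optional[list[str]] = None) -> RunReport:
    """Rank the missense survivors and lay both candidate tables out."""
    missense_cands = [
        RankedCandidate(
            variant=rec, family_id=fid, scores=scores.get(rec.key, ScoreSet()),
            verdict=classify_damaging(scores.get(rec.key, ScoreSet()), config.thresholds),
        )
        for fid, rec in result.missense
    ]
    ranked = composite_rank(missense_cands)
    missense_df = pd.DataFrame([_candidate_row(c) for c in ranked], columns=TABLE_COLUMNS)
    truncating_df = pd.DataFrame(
        [_candidate_row(RankedCandidate(variant=rec, family_id=fid,
                                        scores=scores.get(rec.key, ScoreSet())))
         for fid, rec in result.truncating],
        columns=TABLE_COLUMNS,
    )
    config_echo = {
        "min_depth": config.min_depth,
        "panel": f"{config.panel.name} ({len(config.panel)} genes)",
        "blacklist_size": len(config.mutable_blacklist),
        "novelty_databases": sorted(config.novelty_databases),
        "rarity_preset": config.rarity_preset,
        "delta_maxent_min": config.delta_maxent_min,
        "homopolymer_min_run": config.homopolymer_min_run,
        "effect_classes_kept": sorted(config.effect_classes_kept),
        "thresholds": dataclasses.asdict(config.thresholds) | {
            "gate_metrics": sorted(config.thresholds.gate_metrics)},
    }
    return RunReport(config=config_echo, trace_rows=result.trace.as_rows(),
                     truncating=truncating_df, missense=missense_df,
                     warnings=warnings or [])


def rank_table(df: pd.DataFrame) -> pd.DataFrame:
    """Standalone composite ranking of an externally supplied candidate table.

    Requires the four composite score columns (phylop, gerp, cadd, logit);
    rows missing any of them are emitted unranked ('-') at the table's foot.
    """
    from .errors import AnnotationError

    for col in ("phylop", "gerp", "cadd", "logit"):
        if col not in df.columns:
            raise AnnotationError(f"missing required score column {col!r}")
    df = df.reset_index(drop=True)
    from .model import VariantRecord
    from .prioritize import COMPOSITE_SCORES

    cands = []
    for i, row in df.iterrows():
        pos_label = str(row.get("genomic_position", f"row:{i + 1}"))
        chrom, _, pos = pos_label.partition(":")
        scores = ScoreSet(
            **{c: (None if pd.isna(row[c]) else float(row[c])) for c in COMPOSITE_SCORES},
            sift=None if pd.isna(row.get("sift")) else float(row.get("sift")),
        )
        cands.append(RankedCandidate(
            variant=VariantRecord(chrom=chrom or "NA", pos=int(pos) if pos.isdigit() else i + 1,
                                  ref="N", alt="A", gene=str(row.get("gene", ""))),
            family_id=str(row.get("family", "")), scores=scores,
        ))
    order = {id(c): i for i, c in enumerate(cands)}
    ranked = composite_rank(cands)
    out = df.iloc[[order[id(c)] for c in ranked]].copy()
    out["rank"] = [c.overall_rank if c.overall_rank is not None else "-" for c in ranked]
    out["rank_sum"] = [c.rank_sum if c.rank_sum is not None else "-" for c in ranked]
    return out.reset_index(drop=True)
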