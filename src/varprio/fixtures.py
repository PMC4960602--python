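"""Packaged candidate tables from the published seven-family clefting study.

``missense_fixture`` holds the 28 missense variants (ranked 1-27 plus one
row unrankable for missing scores); ``truncating_fixture`` the five
truncating, splicing and indel variants.  These serve as parsing fixtures
and as the reproduction surface for Grantham and composite-rank checks.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .model import ScoreSet, VariantRecord
from .prioritize import RankedCandidate

_NA = [".", "-"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("varprio.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", na_values=_NA, keep_default_na=False,
                           dtype={"rank": "object"})


def missense_fixture() -> pd.DataFrame:
    """The 28 published missense candidate rows, scores at printed precision."""
    df = _load("missense_candidates.tsv")
    for col in ("sift", "polyphen2", "mutation_taster", "grantham", "phylop",
                "gerp", "cadd", "logit", "exac_maf"):
        df[col] = pd.to_numeric(df[col])
    df["rank"] = df["rank"].fillna("-")  # the unranked row prints '-'
    return df


def truncating_fixture() -> pd.DataFrame:
    """The five published truncating/splicing/indel candidate rows."""
    df = _load("truncating_candidates.tsv")
    df["delta_maxent"] = pd.to_numeric(df["delta_maxent"])
    return df


def published_candidates() -> list[RankedCandidate]:
    """The fixture rows as in-memory candidates ready for composite ranking."""
    out = []
    for row in missense_fixture().itertuples(index=False):
        chrom, pos = row.genomic_position.split(":")
        rec = VariantRecord(
            chrom=chrom, pos=int(pos), ref="N", alt="A",  # alleles not printed
            gene=row.gene, transcript_id=row.transcript_id, exon=int(row.exon),
            cdna_change=row.cdna_change, protein_change=row.protein_change,
            effect_class="nonsynonymous_SNV",
        )
        scores = ScoreSet(
            sift=_none(row.sift), polyphen2_humvar=_none(row.polyphen2),
            mutation_taster=_none(row.mutation_taster), grantham=_none(row.grantham),
            phylop=_none(row.phylop), gerp=_none(row.gerp), cadd=_none(row.cadd),
            logit=_none(row.logit), exac_maf=_none(row.exac_maf),
        )
        out.append(RankedCandidate(variant=rec, family_id=row.family, scores=scores))
    return out


def _none(value):
    return None if pd.isna(value) else float(value)
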