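"""Domain types and file readers/writers for variant calls, pedigrees,
annotation tables and gene lists.

Coordinates are 1-based fully closed throughout, following VCF convention.
Effect classes are consumed from annotation input (the pipeline does not call
consequences from transcript models) and constrained to a closed vocabulary.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
import pysam

from .errors import (
    AnnotationError,
    GeneListError,
    PedigreeError,
    VcfParseError,
)

#: Closed vocabulary of variant consequence classes.
EFFECT_CLASSES = frozenset(
    {
        "nonsynonymous_SNV",
        "stopgain",
        "stoploss",
        "splicing",
        "frameshift_insertion",
        "frameshift_deletion",
        "nonframeshift_insertion",
        "nonframeshift_deletion",
        "synonymous",
        "other",
    }
)

#: Effect classes reported in the truncating/splicing/indel candidate table.
TRUNCATING_CLASSES = frozenset(
    {
        "stopgain",
        "stoploss",
        "splicing",
        "frameshift_insertion",
        "frameshift_deletion",
        "nonframeshift_insertion",
        "nonframeshift_deletion",
    }
)

#: Variant-database tags recognised by the novelty filter.
KNOWN_DB_TAGS = frozenset({"dbSNP135", "1000G", "EVS", "inhouse"})

VariantKey = tuple[str, int, str, str]


class Call(str, Enum):
    """Diploid genotype call for one sample at one site."""

    hom_ref = "hom_ref"
    het = "het"
    hom_alt = "hom_alt"
    missing = "missing"

    def carries_alt(self) -> bool:
        return self in (Call.het, Call.hom_alt)


@dataclass
class Genotype:
    call: Call
    depth: int = 0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError(f"negative depth {self.depth}")


@dataclass
class VariantRecord:
    """One called variant (one ALT allele) with per-sample genotypes.

    ``(chrom, pos, ref, alt)`` uniquely identifies the record within a cohort.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    transcript_id: Optional[str] = None
    exon: Optional[int] = None
    cdna_change: Optional[str] = None
    protein_change: Optional[str] = None
    effect_class: str = "other"
    genotypes: dict[str, Genotype] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect_class!r}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_missense(self) -> bool:
        return self.effect_class == "nonsynonymous_SNV"

    @property
    def is_truncating_or_indel(self) -> bool:
        return self.effect_class in TRUNCATING_CLASSES


def _check_unit(name: str, value: Optional[float]) -> Optional[float]:
    if value is not None and not (0.0 <= value <= 1.0):
        raise AnnotationError(f"{name} must lie in [0, 1], got {value}")
    return value


@dataclass
class ScoreSet:
    """Annotation scores and database-membership facts for one variant.

    SIFT, PolyPhen-2 HumVar, MutationTaster and Logit are scaled to [0, 1];
    PhyloP, GERP++, CADD and the MaxEntScan differential are unbounded.
    ``known_in`` holds presence flags for the novelty databases; ``exac_maf``
    is deliberately separate because low-frequency ExAC presence does not
    disqualify a variant.
    """

    sift: Optional[float] = None
    polyphen2_humvar: Optional[float] = None
    mutation_taster: Optional[float] = None
    lrt_call: Optional[str] = None  # "deleterious" | "neutral" | "unknown"
    phylop: Optional[float] = None
    gerp: Optional[float] = None
    cadd: Optional[float] = None
    logit: Optional[float] = None
    grantham: Optional[float] = None
    exac_maf: Optional[float] = None
    kg_maf: Optional[float] = None
    delta_maxent: Optional[float] = None
    known_in: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name in ("sift", "polyphen2_humvar", "mutation_taster", "logit", "exac_maf", "kg_maf"):
            _check_unit(name, getattr(self, name))
        if self.grantham is not None and self.grantham < 0:
            raise AnnotationError(f"grantham must be non-negative, got {self.grantham}")
        if self.lrt_call is not None and self.lrt_call not in ("deleterious", "neutral", "unknown"):
            raise AnnotationError(f"unrecognised LRT call {self.lrt_call!r}")
        bad = set(self.known_in) - KNOWN_DB_TAGS
        if bad:
            raise AnnotationError(f"unrecognised database tags: {sorted(bad)}")
        self.known_in = frozenset(self.known_in)


@dataclass
class Member:
    sample_id: str
    affected: bool = False
    sequenced: bool = False
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    #: unknown affection is treated as unaffected by all sharing logic, but is
    #: preserved so PED round-trips keep the 0/-9 coding
    unknown_affection: bool = False


@dataclass
class Family:
    family_id: str
    members: list[Member] = field(default_factory=list)

    def sequenced_affected(self) -> list[Member]:
        return [m for m in self.members if m.affected and m.sequenced]

    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.members]


@dataclass
class PedigreeCohort:
    families: list[Family] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [f.family_id for f in self.families]
        if len(ids) != len(set(ids)):
            raise PedigreeError("duplicate family ids")
        for fam in self.families:
            present = set(fam.sample_ids())
            for m in fam.members:
                for parent in (m.father_id, m.mother_id):
                    if parent is not None and parent not in present:
                        raise PedigreeError(
                            f"{fam.family_id}/{m.sample_id}: parent {parent} not in family"
                        )

    def family_of(self, sample_id: str) -> Family:
        for fam in self.families:
            if sample_id in fam.sample_ids():
                return fam
        raise PedigreeError(f"sample {sample_id} not in any family")

    def sequenced_sample_ids(self) -> list[str]:
        return [m.sample_id for f in self.families for m in f.members if m.sequenced]


@dataclass
class GenePanel:
    """A case-normalised set of gene symbols (e.g. a clefting gene panel)."""

    genes: frozenset[str]
    name: str = "panel"

    def __post_init__(self) -> None:
        if not self.genes:
            raise GeneListError(f"gene panel {self.name!r} is empty")
        self.genes = frozenset(g.upper() for g in self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_INFO_FIELDS = {
    "GENE": "gene",
    "EFFECT": "effect_class",
    "TRANSCRIPT": "transcript_id",
    "CDNA": "cdna_change",
    "PROT": "protein_change",
}


def _info_get(rec, tag: str):
    # rec.info.get raises on tags absent from the header; membership is safe
    return rec.info[tag] if tag in rec.info else None


def _classify_gt(indices: tuple, alt_index: int) -> Call:
    if any(i is None for i in indices) or not indices:
        return Call.missing
    n = sum(1 for i in indices if i == alt_index)
    if n == 0:
        return Call.hom_ref
    if n == len(indices):
        return Call.hom_alt
    return Call.het


def read_vcf(path: str | Path, pedigree: Optional[PedigreeCohort] = None) -> list[VariantRecord]:
    """Read a multi-sample VCF into :class:`VariantRecord` objects.

    Multi-allelic sites are decomposed into one record per ALT allele.
    Genotype depth is taken from FORMAT/DP (0 when absent).  When a pedigree
    is supplied, every sample it marks as sequenced that is present in the
    VCF header must be genotyped; sequenced pedigree samples missing from the
    header are an error only if no other VCF could carry them — callers
    working with per-family VCFs should pass per-family pedigrees or check
    coverage with :func:`check_sequenced_samples` after merging.
    """
    path = Path(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"{path}: cannot open as VCF: {exc}") from exc
    records: list[VariantRecord] = []
    with vf:
        samples = list(vf.header.samples)
        if pedigree is not None:
            present = set(samples)
            missing: list[str] = []
            for fam in pedigree.families:
                if present & set(fam.sample_ids()):
                    missing.extend(
                        m.sample_id for m in fam.members
                        if m.sequenced and m.sample_id not in present
                    )
            if missing:
                raise VcfParseError(
                    f"{path}: sequenced samples absent from VCF: {', '.join(sorted(missing))}"
                )
        try:
            for rec in vf:
                for alt_index, alt in enumerate(rec.alts or (), start=1):
                    genotypes: dict[str, Genotype] = {}
                    for s in samples:
                        fmt = rec.samples[s]
                        call = _classify_gt(tuple(fmt.get("GT") or ()), alt_index)
                        depth = fmt.get("DP")
                        genotypes[s] = Genotype(call=call, depth=int(depth) if depth is not None else 0)
                    info = {attr: _info_get(rec, tag) for tag, attr in _INFO_FIELDS.items()}
                    effect = info.pop("effect_class") or "other"
                    if effect not in EFFECT_CLASSES:
                        effect = "other"
                    exon = _info_get(rec, "EXON")
                    records.append(
                        VariantRecord(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            gene=info.pop("gene") or "",
                            exon=int(exon) if exon is not None else None,
                            effect_class=effect,
                            genotypes=genotypes,
                            **info,
                        )
                    )
        except (ValueError, OSError) as exc:
            raise VcfParseError(f"{path}: malformed VCF record: {exc}") from exc
    return records


def check_sequenced_samples(records: Iterable[VariantRecord], pedigree: PedigreeCohort) -> None:
    """Hard error when a sequenced pedigree sample has no genotypes at all."""
    seen: set[str] = set()
    for rec in records:
        seen.update(rec.genotypes)
    missing = [s for s in pedigree.sequenced_sample_ids() if s not in seen]
    if missing:
        raise VcfParseError(
            "samples marked sequenced in the pedigree are absent from the VCF(s): "
            + ", ".join(sorted(missing))
        )


def merge_records(per_file: Iterable[list[VariantRecord]]) -> list[VariantRecord]:
    """Merge per-family record lists by variant key, unioning genotype maps."""
    merged: dict[VariantKey, VariantRecord] = {}
    for records in per_file:
        for rec in records:
            existing = merged.get(rec.key)
            if existing is None:
                merged[rec.key] = rec
            else:
                existing.genotypes.update(rec.genotypes)
    return list(merged.values())


def write_vcf(records: Iterable[VariantRecord], path: str | Path, sample_ids: list[str],
              contigs: Optional[Iterable[str]] = None) -> None:
    """Write records (restricted to ``sample_ids``) as an uncompressed VCF."""
    records = sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    header = pysam.VariantHeader()
    if contigs is None:
        contigs = sorted({r.chrom for r in records})
    for c in contigs:
        header.contigs.add(c)
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    header.add_line('##INFO=<ID=EFFECT,Number=1,Type=String,Description="Consequence class">')
    header.add_line('##INFO=<ID=TRANSCRIPT,Number=1,Type=String,Description="Transcript accession">')
    header.add_line('##INFO=<ID=EXON,Number=1,Type=Integer,Description="Exon number">')
    header.add_line('##INFO=<ID=CDNA,Number=1,Type=String,Description="cDNA change">')
    header.add_line('##INFO=<ID=PROT,Number=1,Type=String,Description="Protein change">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    for s in sample_ids:
        header.add_sample(s)
    gt_codes = {Call.hom_ref: (0, 0), Call.het: (0, 1), Call.hom_alt: (1, 1), Call.missing: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            row = out.new_record(contig=rec.chrom, start=rec.pos - 1, alleles=(rec.ref, rec.alt))
            row.info["GENE"] = rec.gene or "."
            row.info["EFFECT"] = rec.effect_class
            if rec.transcript_id:
                row.info["TRANSCRIPT"] = rec.transcript_id
            if rec.exon is not None:
                row.info["EXON"] = rec.exon
            if rec.cdna_change:
                row.info["CDNA"] = rec.cdna_change
            if rec.protein_change:
                row.info["PROT"] = rec.protein_change
            for s in sample_ids:
                g = rec.genotypes.get(s, Genotype(Call.missing, 0))
                row.samples[s]["GT"] = gt_codes[g.call]
                row.samples[s]["DP"] = g.depth
            out.write(row)


#: Annotation-table columns and how they map onto :class:`ScoreSet` fields.
ANNOTATION_COLUMNS = {
    "sift": "sift",
    "polyphen2_humvar": "polyphen2_humvar",
    "mutation_taster": "mutation_taster",
    "lrt_call": "lrt_call",
    "phylop": "phylop",
    "gerp": "gerp",
    "cadd": "cadd",
    "logit": "logit",
    "grantham": "grantham",
    "exac_maf": "exac_maf",
    "kg_maf": "kg_maf",
    "delta_maxent": "delta_maxent",
    "known_in": "known_in",
}
_KEY_COLUMNS = ("chrom", "pos", "ref", "alt")


def read_annotation_table(path: str | Path) -> dict[VariantKey, ScoreSet]:
    """Read a dbNSFP-style per-variant score table (TSV, '.'/'-' = missing)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    missing_keys = [c for c in _KEY_COLUMNS if c not in df.columns]
    if missing_keys:
        raise AnnotationError(f"{path}: missing key column(s) {missing_keys}")
    unknown = [c for c in df.columns if c not in _KEY_COLUMNS and c not in ANNOTATION_COLUMNS]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown column(s) {unknown}", stacklevel=2)

    def _val(raw: Optional[str]) -> Optional[str]:
        if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw in (".", "-", ""):
            return None
        return raw

    out: dict[VariantKey, ScoreSet] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        key = (d["chrom"], int(d["pos"]), d["ref"], d["alt"])
        if key in out:
            raise AnnotationError(f"{path}: duplicate variant key {key}")
        kwargs: dict = {}
        for col, attr in ANNOTATION_COLUMNS.items():
            raw = _val(d.get(col))
            if raw is None:
                continue
            if attr == "known_in":
                kwargs[attr] = frozenset(t for t in raw.split(",") if t)
            elif attr == "lrt_call":
                kwargs[attr] = raw
            else:
                kwargs[attr] = float(raw)
        out[key] = ScoreSet(**kwargs)
    return out


def write_annotation_table(scores: Mapping[VariantKey, ScoreSet], path: str | Path) -> None:
    rows = []
    for key in sorted(scores):
        ss = scores[key]
        row: dict = dict(zip(_KEY_COLUMNS, key))
        for col, attr in ANNOTATION_COLUMNS.items():
            value = getattr(ss, attr)
            if attr == "known_in":
                row[col] = ",".join(sorted(value)) if value else "."
            elif value is None:
                row[col] = "."
            else:
                row[col] = value
        rows.append(row)
    pd.DataFrame(rows, columns=list(_KEY_COLUMNS) + list(ANNOTATION_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def read_pedigree(ped_path: str | Path, sequenced: str | Path | Iterable[str]) -> PedigreeCohort:
    """Read a 6-column PED file plus a sequenced-sample sidecar.

    Affection coding: 2 = affected, 1 = unaffected, 0/-9 = unknown (treated
    as unaffected by the sharing logic).  ``sequenced`` is a path to a
    line-delimited sample-id list, or any iterable of sample ids.
    """
    ped_path = Path(ped_path)
    if isinstance(sequenced, (str, Path)):
        seq_ids = {line.strip() for line in Path(sequenced).read_text().splitlines()
                   if line.strip() and not line.startswith("#")}
    else:
        seq_ids = set(sequenced)
    families: dict[str, Family] = {}
    all_samples: set[str] = set()
    for lineno, line in enumerate(ped_path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise PedigreeError(f"{ped_path}:{lineno}: expected 6 columns, got {len(fields)}")
        fid, iid, pat, mat, _sex, pheno = fields[:6]
        fam = families.setdefault(fid, Family(family_id=fid))
        fam.members.append(
            Member(
                sample_id=iid,
                affected=(pheno == "2"),
                sequenced=(iid in seq_ids),
                father_id=None if pat in ("0", ".") else pat,
                mother_id=None if mat in ("0", ".") else mat,
                unknown_affection=pheno in ("0", "-9"),
            )
        )
        all_samples.add(iid)
    if not families:
        raise PedigreeError(f"{ped_path}: no families")
    orphan = seq_ids - all_samples
    if orphan:
        raise PedigreeError(
            f"{ped_path}: sequenced samples not present in PED: {', '.join(sorted(orphan))}"
        )
    return PedigreeCohort(families=list(families.values()))


def read_gene_list(path: str | Path, name: Optional[str] = None) -> GenePanel:
    """Read a line-delimited gene-symbol list ('#' comments allowed)."""
    path = Path(path)
    genes = {
        line.strip().upper()
        for line in path.read_text().splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    }
    if not genes:
        raise GeneListError(f"{path}: no gene symbols found")
    return GenePanel(genes=frozenset(genes), name=name or path.stem)
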