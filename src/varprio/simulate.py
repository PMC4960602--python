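"""Synthetic multi-case pedigree cohorts with planted causal variants.

The generator emulates the study design this pipeline targets: seven
multi-case families (two sequenced singletons, two sequenced parent-offspring
pairs, two sequenced sib pairs, one sequenced avuncular pair; families carry
two to six affected individuals, not all sequenced), one heterozygous causal
variant planted per family and shared by all its sequenced affected members,
plus background decoy variants.

Every decoy is constructed *single-fault*: it violates exactly one cascade
rule and satisfies all the others, so the filter trace attributes each
removal unambiguously and disabling one stage makes exactly that stage's
decoys survive.  Score profiles are drawn inside pass/fail bands around the
published thresholds (including values at the boundary itself) to exercise
strict-versus-non-strict inequality semantics; they are not sampled from
realistic genome-wide distributions.

Positions live on one artificial contig so no reference genome is required;
homopolymer contexts are emitted in a generated reference sidecar.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ConfigError
from .grantham import AMINO_ACID_PROPERTIES, grantham_distance
from .model import (
    Call,
    Family,
    Genotype,
    Member,
    PedigreeCohort,
    ScoreSet,
    VariantKey,
    VariantRecord,
    write_annotation_table,
    write_vcf,
)

CONTIG = "1"

#: Decoy failure modes and the cascade stage that removes each.
DECOY_STAGE = {
    "off_panel": "panel",
    "known_in_db": "novelty",
    "low_depth": "depth",
    "homopolymer": "homopolymer",
    "synonymous": "effect_class",
    "non_shared": "family_sharing",
    "cross_family": "cross_family",
    "splicing_low_maxent": "splicing",
    "blacklisted_gene": "mutable_gene",
}

DEFAULT_DECOY_MIX = {mode: 1.0 / len(DECOY_STAGE) for mode in DECOY_STAGE}


def default_family_shapes() -> list[Family]:
    """Seven families mirroring the study's sequenced-pedigree structures."""

    def fam(fid: str, members: list[tuple[str, bool, bool, Optional[str], Optional[str]]]) -> Family:
        return Family(fid, [Member(s, a, q, f, m) for s, a, q, f, m in members])

    return [
        # two families with a single sequenced case (one more affected, unsequenced)
        fam("CL1", [("CL1_P1", True, True, "CL1_F1", "CL1_M1"),
                    ("CL1_S1", True, False, "CL1_F1", "CL1_M1"),
                    ("CL1_F1", False, False, None, None),
                    ("CL1_M1", False, False, None, None)]),
        fam("CL2", [("CL2_P1", True, True, "CL2_F1", "CL2_M1"),
                    ("CL2_S1", True, False, "CL2_F1", "CL2_M1"),
                    ("CL2_F1", False, False, None, None),
                    ("CL2_M1", False, False, None, None)]),
        # two sequenced parent-offspring pairs
        fam("CL3", [("CL3_PA", True, True, None, None),
                    ("CL3_P1", True, True, "CL3_PA", "CL3_M1"),
                    ("CL3_S1", True, False, "CL3_PA", "CL3_M1"),
                    ("CL3_M1", False, False, None, None)]),
        fam("CL4", [("CL4_PA", True, True, None, None),
                    ("CL4_P1", True, True, "CL4_PA", "CL4_M1"),
                    ("CL4_M1", False, False, None, None)]),
        # two sequenced sib pairs
        fam("CL5", [("CL5_P1", True, True, "CL5_F1", "CL5_M1"),
                    ("CL5_P2", True, True, "CL5_F1", "CL5_M1"),
                    ("CL5_S1", True, False, "CL5_F1", "CL5_M1"),
                    ("CL5_F1", False, False, None, None),
                    ("CL5_M1", False, False, None, None)]),
        fam("CL6", [("CL6_P1", True, True, "CL6_F1", "CL6_M1"),
                    ("CL6_P2", True, True, "CL6_F1", "CL6_M1"),
                    ("CL6_F1", False, False, None, None),
                    ("CL6_M1", False, False, None, None)]),
        # one sequenced avuncular pair, plus a sequenced member of unknown affection
        Family("CL7", [
            Member("CL7_U1", affected=True, sequenced=True),
            Member("CL7_P1", affected=True, sequenced=True, father_id="CL7_F1"),
            Member("CL7_F1", affected=False, sequenced=False),
            Member("CL7_X1", affected=False, sequenced=True, unknown_affection=True),
        ]),
    ]


@dataclass
class SimulationConfig:
    seed: int = 1
    families: list[Family] = field(default_factory=default_family_shapes)
    n_background_per_family: int = 200
    panel_size: int = 865
    n_blacklist: int = 15
    decoy_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DECOY_MIX))
    #: effect class planted per family; None = five missense, one stopgain,
    #: one splicing so both candidate-table partitions are exercised.
    planted_effects: Optional[dict[str, str]] = None
    min_depth: int = 10
    depth_range: tuple[int, int] = (20, 80)
    homopolymer_min_run: int = 6
    delta_maxent_min: float = 3.0

    def __post_init__(self) -> None:
        total = sum(self.decoy_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"decoy mix proportions sum to {total}, expected 1")
        unknown = set(self.decoy_mix) - set(DECOY_STAGE)
        if unknown:
            raise ConfigError(f"unknown decoy modes: {sorted(unknown)}")
        if self.planted_effects is None:
            fids = [f.family_id for f in self.families]
            effects = dict.fromkeys(fids, "nonsynonymous_SNV")
            if len(fids) >= 2:
                effects[fids[-2]] = "stopgain"
                effects[fids[-1]] = "splicing"
            self.planted_effects = effects


@dataclass
class Decoy:
    key: VariantKey
    families: list[str]
    failure_stage: str


@dataclass
class TruthManifest:
    planted: dict[str, list[VariantKey]]
    decoys: list[Decoy]

    def planted_keys(self) -> set[VariantKey]:
        return {k for keys in self.planted.values() for k in keys}

    def decoy_keys(self) -> set[VariantKey]:
        return {d.key for d in self.decoys}

    def to_json(self, path: str | Path) -> None:
        doc = {
            "planted": {fid: [list(k) for k in keys] for fid, keys in self.planted.items()},
            "decoys": [
                {"key": list(d.key), "families": d.families, "failure_stage": d.failure_stage}
                for d in self.decoys
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        doc = json.loads(Path(path).read_text())
        return cls(
            planted={fid: [tuple(k) for k in keys] for fid, keys in doc["planted"].items()},
            decoys=[Decoy(tuple(d["key"]), d["families"], d["failure_stage"])
                    for d in doc["decoys"]],
        )


@dataclass
class SyntheticCohort:
    """In-memory cohort plus the paths of every file written."""

    records: list[VariantRecord]
    scores: dict[VariantKey, ScoreSet]
    contexts: dict[VariantKey, str]
    pedigree: PedigreeCohort
    panel_genes: list[str]
    blacklist_genes: list[str]
    manifest: TruthManifest
    paths: dict[str, Path] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# construction helpers
# ---------------------------------------------------------------------------

_BASES = "ACGT"
_RESIDUES = sorted(AMINO_ACID_PROPERTIES)


def _apportion(n: int, mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n decoys over the mix."""
    modes = sorted(mix)
    exact = {m: n * mix[m] for m in modes}
    counts = {m: int(exact[m]) for m in modes}
    short = n - sum(counts.values())
    for m in sorted(modes, key=lambda m: (-(exact[m] - counts[m]), m))[:short]:
        counts[m] += 1
    return counts


class _CohortBuilder:
    def __init__(self, config: SimulationConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.next_pos = 10_000
        self.records: list[VariantRecord] = []
        self.scores: dict[VariantKey, ScoreSet] = {}
        self.contexts: dict[VariantKey, str] = {}
        self.panel = [f"GENE{i:04d}" for i in range(config.panel_size)]
        self.off_panel = [f"OFFP{i:04d}" for i in range(200)]
        blk = self.rng.choice(config.panel_size, size=config.n_blacklist, replace=False)
        self.blacklist = sorted(self.panel[i] for i in blk)
        self.manifest = TruthManifest(planted={}, decoys=[])

    # -- primitive draws ---------------------------------------------------

    def _position(self) -> int:
        self.next_pos += int(self.rng.integers(5, 200))
        return self.next_pos

    def _alleles(self) -> tuple[str, str]:
        ref, alt = self.rng.choice(list(_BASES), size=2, replace=False)
        return str(ref), str(alt)

    def _depth(self) -> int:
        lo, hi = self.config.depth_range
        return int(self.rng.integers(lo, hi + 1))

    def _context(self, ref: str, homopolymer: bool) -> str:
        width = 2 * self.config.homopolymer_min_run + 1
        if homopolymer:
            return ref * width
        centre = width // 2
        seq = [""] * width
        seq[centre] = ref
        for i in range(centre - 1, -1, -1):
            seq[i] = str(self.rng.choice([b for b in _BASES if b != seq[i + 1]]))
        for i in range(centre + 1, width):
            seq[i] = str(self.rng.choice([b for b in _BASES if b != seq[i - 1]]))
        return "".join(seq)

    def _protein_change(self) -> tuple[str, float]:
        a, b = (str(x) for x in self.rng.choice(_RESIDUES, size=2, replace=False))
        pos = int(self.rng.integers(2, 900))
        return f"{a}{pos}{b}", float(grantham_distance(a, b))

    def _passing_scores(self, grantham: Optional[float], boundary_fail: bool = True) -> dict:
        """A profile that the damaging gate accepts via one clearly-passing
        metric, with the remaining metrics at fail values that sit on or near
        the published boundaries."""
        rng = self.rng
        passing = {
            # boundary-exact fail values exercise the strict/non-strict senses
            "sift": 0.05 if boundary_fail and rng.random() < 0.5 else float(rng.uniform(0.06, 1.0)),
            "polyphen2_humvar": 0.447 if boundary_fail and rng.random() < 0.5 else float(rng.uniform(0.0, 0.44)),
            "mutation_taster": 0.95 if boundary_fail and rng.random() < 0.5 else float(rng.uniform(0.0, 0.94)),
            "phylop": float(rng.uniform(-1.0, 2.0)),
            "gerp": float(rng.uniform(-1.0, 2.0)),
        }
        winner = str(rng.choice(["sift", "polyphen2_humvar", "mutation_taster", "phylop", "gerp", "lrt"]))
        lrt = None
        if winner == "sift":
            passing["sift"] = float(rng.uniform(0.0, 0.049))
        elif winner == "polyphen2_humvar":
            passing["polyphen2_humvar"] = float(rng.uniform(0.909, 1.0))
        elif winner == "mutation_taster":
            passing["mutation_taster"] = float(rng.uniform(0.951, 1.0))
        elif winner == "phylop":
            passing["phylop"] = float(rng.uniform(2.1, 10.0))
        elif winner == "gerp":
            passing["gerp"] = float(rng.uniform(2.1, 6.0))
        else:
            lrt = "deleterious"
        return dict(
            **passing,
            lrt_call=lrt,
            cadd=float(rng.uniform(5.0, 35.0)),
            logit=float(rng.uniform(0.0, 0.5)),
            grantham=grantham,
            exac_maf=float(rng.uniform(1e-6, 5e-4)) if rng.random() < 0.5 else None,
            kg_maf=float(rng.uniform(0.0, 0.009)) if rng.random() < 0.3 else None,
        )

    # -- record assembly ---------------------------------------------------

    def _genotypes(self, families: list[Family], *, non_carrier: Optional[str] = None,
                   missing: Optional[str] = None, low_depth_sample: Optional[str] = None) -> dict[str, Genotype]:
        out: dict[str, Genotype] = {}
        for fam in families:
            for m in fam.members:
                if not m.sequenced:
                    continue
                if m.sample_id == missing:
                    out[m.sample_id] = Genotype(Call.missing, 0)
                elif m.sample_id == non_carrier:
                    out[m.sample_id] = Genotype(Call.hom_ref, self._depth())
                elif m.affected:
                    depth = (int(self.rng.integers(1, self.config.min_depth))
                             if m.sample_id == low_depth_sample else self._depth())
                    out[m.sample_id] = Genotype(Call.het, depth)
                else:
                    out[m.sample_id] = Genotype(Call.hom_ref, self._depth())
        return out

    def _add_variant(self, gene: str, effect: str, families: list[Family],
                     scores: ScoreSet, *, homopolymer: bool = False,
                     protein_change: Optional[str] = None,
                     **genotype_kwargs) -> VariantRecord:
        ref, alt = self._alleles()
        rec = VariantRecord(
            chrom=CONTIG, pos=self._position(), ref=ref, alt=alt, gene=gene,
            transcript_id=f"NM_{self.rng.integers(1_000, 999_999):06d}",
            exon=int(self.rng.integers(1, 40)),
            protein_change=protein_change, effect_class=effect,
            genotypes=self._genotypes(families, **genotype_kwargs),
        )
        self.records.append(rec)
        self.scores[rec.key] = scores
        self.contexts[rec.key] = self._context(ref, homopolymer)
        return rec

    # -- planted + decoys --------------------------------------------------

    def plant(self, family: Family, gene: str) -> VariantRecord:
        effect = self.config.planted_effects[family.family_id]
        if gene not in self.panel:
            raise ConfigError(f"planted gene {gene} is not in the generated panel")
        if effect == "nonsynonymous_SNV":
            pchange, g = self._protein_change()
            rng = self.rng
            scores = ScoreSet(
                sift=float(rng.uniform(0.0, 0.04)),
                polyphen2_humvar=float(rng.uniform(0.91, 1.0)),
                mutation_taster=float(rng.uniform(0.96, 1.0)),
                phylop=float(rng.uniform(2.5, 10.0)),
                gerp=float(rng.uniform(2.5, 6.0)),
                cadd=float(rng.uniform(20.0, 35.0)),
                logit=float(rng.uniform(0.02, 0.4)),
                grantham=g,
                exac_maf=float(rng.uniform(1e-6, 2e-4)),
            )
            rec = self._add_variant(gene, effect, [family], scores, protein_change=pchange)
        elif effect == "splicing":
            scores = ScoreSet(delta_maxent=float(self.rng.uniform(
                self.config.delta_maxent_min + 2, 25.0)))
            rec = self._add_variant(gene, effect, [family], scores)
        else:  # truncating / indel classes bypass the metric gate
            scores = ScoreSet(exac_maf=float(self.rng.uniform(1e-6, 2e-4)))
            pchange = f"E{int(self.rng.integers(2, 900))}X" if effect == "stopgain" else None
            rec = self._add_variant(gene, effect, [family], scores, protein_change=pchange)
        self.manifest.planted.setdefault(family.family_id, []).append(rec.key)
        return rec

    def _panel_gene(self) -> str:
        candidates = [g for g in self.panel if g not in self.blacklist]
        return str(self.rng.choice(candidates))

    def add_decoy(self, mode: str, family: Family, partner: Optional[Family] = None) -> VariantRecord:
        gene = self._panel_gene()
        effect = "nonsynonymous_SNV"
        pchange, grantham = self._protein_change()
        scores = ScoreSet(**self._passing_scores(grantham))
        families = [family]
        kwargs: dict = {}

        if mode == "off_panel":
            gene = str(self.rng.choice(self.off_panel))
        elif mode == "blacklisted_gene":
            gene = str(self.rng.choice(self.blacklist))
        elif mode == "known_in_db":
            tag = str(self.rng.choice(sorted({"dbSNP135", "1000G", "EVS", "inhouse"})))
            scores = dataclasses.replace(scores, known_in=frozenset({tag}))
        elif mode == "low_depth":
            carriers = family.sequenced_affected()
            kwargs["low_depth_sample"] = str(self.rng.choice([m.sample_id for m in carriers]))
        elif mode == "homopolymer":
            kwargs["homopolymer"] = True
        elif mode == "synonymous":
            effect, pchange = "synonymous", None
            scores = dataclasses.replace(scores, grantham=None)
        elif mode == "non_shared":
            carriers = family.sequenced_affected()
            if len(carriers) >= 2:
                kwargs["non_carrier"] = str(self.rng.choice([m.sample_id for m in carriers]))
            else:
                # a one-member sharing quantifier cannot fail on hom-ref alone;
                # emulate a joint-calling artifact: the sole sequenced affected
                # is uncalled at the site
                kwargs["missing"] = carriers[0].sample_id
        elif mode == "cross_family":
            if partner is None:
                raise ConfigError("cross_family decoys need a partner family")
            families = [family, partner]
        elif mode == "splicing_low_maxent":
            effect, pchange = "splicing", None
            scores = ScoreSet(delta_maxent=float(self.rng.uniform(0.0, self.config.delta_maxent_min - 0.1)))
        else:
            raise ConfigError(f"unknown decoy mode {mode!r}")

        homopolymer = kwargs.pop("homopolymer", False)
        rec = self._add_variant(gene, effect, families, scores,
                                homopolymer=homopolymer, protein_change=pchange, **kwargs)
        self.manifest.decoys.append(
            Decoy(rec.key, [f.family_id for f in families], DECOY_STAGE[mode]))
        return rec

    def build(self) -> tuple[list[VariantRecord], TruthManifest]:
        cfg = self.config
        fams = cfg.families
        planted_genes = self.rng.choice(len(self.panel), size=len(fams), replace=False)
        usable = [i for i in planted_genes if self.panel[i] not in self.blacklist]
        while len(usable) < len(fams):  # redraw collisions with the blacklist
            extra = int(self.rng.integers(0, len(self.panel)))
            if self.panel[extra] not in self.blacklist and extra not in usable:
                usable.append(extra)
        for fam, gi in zip(fams, usable):
            self.plant(fam, self.panel[gi])
        counts = _apportion(cfg.n_background_per_family, cfg.decoy_mix)
        for fi, fam in enumerate(fams):
            partner = fams[(fi + 1) % len(fams)] if len(fams) > 1 else None
            for mode in sorted(counts):
                for _ in range(counts[mode]):
                    if mode == "cross_family" and partner is None:
                        raise ConfigError("cross_family decoys require >= 2 families")
                    self.add_decoy(mode, fam, partner)
        return self.records, self.manifest


def generate_cohort(config: SimulationConfig, out_dir: Optional[str | Path] = None) -> SyntheticCohort:
    """Generate a cohort; optionally write every pipeline input to ``out_dir``.

    Outputs (when ``out_dir`` is given): one VCF per family, a 6-column PED
    plus sequenced-sample sidecar, the annotation TSV, panel and blacklist
    gene lists, the reference-context sidecar and the truth manifest.  Fixed
    seed => byte-identical files.
    """
    builder = _CohortBuilder(config)
    records, manifest = builder.build()
    pedigree = PedigreeCohort(families=config.families)
    cohort = SyntheticCohort(
        records=records,
        scores=builder.scores,
        contexts=builder.contexts,
        pedigree=pedigree,
        panel_genes=builder.panel,
        blacklist_genes=builder.blacklist,
        manifest=manifest,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = cohort.paths
        for fam in config.families:
            samples = [m.sample_id for m in fam.members if m.sequenced]
            fam_records = [r for r in records if any(s in r.genotypes for s in samples)]
            path = out / f"{fam.family_id}.vcf"
            write_vcf(
                [dataclasses.replace(r, genotypes={s: r.genotypes[s] for s in samples
                                                   if s in r.genotypes})
                 for r in fam_records],
                path, samples, contigs=[CONTIG],
            )
            paths[f"vcf:{fam.family_id}"] = path
        ped_lines, seq_lines = [], []
        for fam in config.families:
            for m in fam.members:
                pheno = "2" if m.affected else ("0" if m.unknown_affection else "1")
                ped_lines.append("\t".join([fam.family_id, m.sample_id,
                                            m.father_id or "0", m.mother_id or "0",
                                            "0", pheno]))
                if m.sequenced:
                    seq_lines.append(m.sample_id)
        (out / "cohort.ped").write_text("\n".join(ped_lines) + "\n")
        (out / "sequenced.txt").write_text("\n".join(seq_lines) + "\n")
        (out / "panel.txt").write_text("\n".join(builder.panel) + "\n")
        (out / "blacklist.txt").write_text("\n".join(builder.blacklist) + "\n")
        write_annotation_table(builder.scores, out / "annotations.tsv")
        (out / "contexts.json").write_text(json.dumps(
            {"{}:{}:{}:{}".format(*k): v for k, v in sorted(builder.contexts.items())},
            indent=0, sort_keys=True))
        manifest.to_json(out / "manifest.json")
        paths.update(ped=out / "cohort.ped", sequenced=out / "sequenced.txt",
                     panel=out / "panel.txt", blacklist=out / "blacklist.txt",
                     annotations=out / "annotations.tsv",
                     contexts=out / "contexts.json", manifest=out / "manifest.json")
    return cohort


def load_contexts(path: str | Path) -> dict[VariantKey, str]:
    doc = json.loads(Path(path).read_text())
    out: dict[VariantKey, str] = {}
    for key, ctx in doc.items():
        chrom, pos, ref, alt = key.rsplit(":", 3)
        out[(chrom, int(pos), ref, alt)] = ctx
    return out
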