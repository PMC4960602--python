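"""Domain types, VCF/PED/TSV/gene-list readers and their error handling."""
from __future__ import annotations

import pytest

from varprio.errors import (
    AnnotationError,
    GeneListError,
    PedigreeError,
    VcfParseError,
)
from varprio.model import (
    Call,
    Family,
    GenePanel,
    Genotype,
    Member,
    PedigreeCohort,
    ScoreSet,
    VariantRecord,
    merge_records,
    read_annotation_table,
    read_gene_list,
    read_pedigree,
    read_vcf,
    write_annotation_table,
    write_vcf,
)

MINIMAL_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##INFO=<ID=GENE,Number=1,Type=String,Description="g">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="e">
##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
1\t100\t.\tC\tA\t.\t.\tGENE=MSX1;EFFECT=nonsynonymous_SNV\tGT:DP\t0/1:30\t0/0:25
1\t200\t.\tG\tA,T\t.\t.\tGENE=IRF6;EFFECT=nonsynonymous_SNV\tGT:DP\t1/2:18\t0/1:9
"""


@pytest.fixture()
def vcf_path(tmp_path):
    path = tmp_path / "mini.vcf"
    path.write_text(MINIMAL_VCF)
    return path


def test_read_vcf_minimal_site(vcf_path):
    records = read_vcf(vcf_path)
    first = records[0]
    assert first.key == ("1", 100, "C", "A")
    assert first.gene == "MSX1" and first.effect_class == "nonsynonymous_SNV"
    assert first.genotypes["S1"].call is Call.het
    assert first.genotypes["S2"].call is Call.hom_ref
    assert first.genotypes["S1"].depth == 30


def test_multiallelic_site_decomposed(vcf_path):
    records = read_vcf(vcf_path)
    site = [r for r in records if r.pos == 200]
    assert {r.alt for r in site} == {"A", "T"}
    assert all(r.ref == "G" for r in site)
    # sample S1 is 1/2: het for each decomposed allele
    assert all(r.genotypes["S1"].call is Call.het for r in site)
    assert len({r.key for r in records}) == len(records) == 3


def test_sequenced_sample_missing_from_vcf_is_hard_error(vcf_path):
    pedigree = PedigreeCohort(families=[Family("F1", [
        Member("S1", affected=True, sequenced=True),
        Member("S9", affected=True, sequenced=True),
    ])])
    with pytest.raises(VcfParseError, match="S9"):
        read_vcf(vcf_path, pedigree)


def test_malformed_vcf_names_file(tmp_path):
    bad = tmp_path / "bad.vcf"
    bad.write_text("not a vcf at all\n")
    with pytest.raises(VcfParseError, match="bad.vcf"):
        read_vcf(bad)


def test_vcf_write_read_round_trip(tmp_path, small_cohort):
    """Write-then-read preserves keys, genotypes and depths exactly."""
    records = small_cohort.records[:40]
    samples = sorted({s for r in records for s in r.genotypes})
    path = tmp_path / "rt.vcf"
    write_vcf(records, path, samples, contigs=["1"])
    back = read_vcf(path)
    by_key = {r.key: r for r in back}
    assert set(by_key) == {r.key for r in records}
    for rec in records:
        for sample, g in rec.genotypes.items():
            g2 = by_key[rec.key].genotypes[sample]
            assert (g2.call, g2.depth) == (g.call, g.depth), (rec.key, sample)


def test_merge_records_unions_genotypes():
    a = VariantRecord("1", 5, "A", "G", gene="X", genotypes={"S1": Genotype(Call.het, 20)})
    b = VariantRecord("1", 5, "A", "G", gene="X", genotypes={"S2": Genotype(Call.het, 22)})
    merged = merge_records([[a], [b]])
    assert len(merged) == 1 and set(merged[0].genotypes) == {"S1", "S2"}


@pytest.mark.parametrize(
    "kwargs,match",
    [
        (dict(chrom="1", pos=0, ref="A", alt="G"), "pos"),
        (dict(chrom="1", pos=5, ref="A", alt="A"), "ref == alt"),
        (dict(chrom="1", pos=5, ref="A", alt="G", effect_class="weird"), "effect class"),
    ],
)
def test_variant_record_invariants(kwargs, match):
    with pytest.raises(ValueError, match=match):
        VariantRecord(**kwargs)


# -- pedigree ---------------------------------------------------------------

PED = """\
CL1\tP1\t0\t0\t0\t2
CL1\tM1\t0\t0\t2\t1
CL2\tPA\t0\t0\t0\t2
CL2\tP2\tPA\t0\t0\t2
CL2\tS2\tPA\t0\t0\t0
"""


def test_read_pedigree_two_families(tmp_path):
    ped = tmp_path / "p.ped"
    ped.write_text(PED)
    seq = tmp_path / "seq.txt"
    seq.write_text("P1\nPA\nP2\n")
    cohort = read_pedigree(ped, seq)
    assert [f.family_id for f in cohort.families] == ["CL1", "CL2"]
    cl2 = cohort.families[1]
    assert [m.sample_id for m in cl2.sequenced_affected()] == ["PA", "P2"]
    # affection 0: retained, not affected, flagged unknown
    s2 = next(m for m in cl2.members if m.sample_id == "S2")
    assert not s2.affected and s2.unknown_affection


def test_read_pedigree_errors(tmp_path):
    empty = tmp_path / "e.ped"
    empty.write_text("\n")
    with pytest.raises(PedigreeError, match="no families"):
        read_pedigree(empty, [])
    ped = tmp_path / "p.ped"
    ped.write_text(PED)
    with pytest.raises(PedigreeError, match="GHOST"):
        read_pedigree(ped, ["GHOST"])


def test_parent_reference_must_be_in_family():
    with pytest.raises(PedigreeError, match="parent"):
        PedigreeCohort(families=[Family("F", [Member("A", father_id="NOPE")])])


# -- gene lists -------------------------------------------------------------

def test_gene_list_dedup_and_case(tmp_path):
    path = tmp_path / "panel.txt"
    path.write_text("# clefting panel\nMSX1\nIRF6\nmsx1\n\n")
    panel = read_gene_list(path)
    assert len(panel) == 2 and "Msx1" in panel


def test_gene_list_empty_is_error(tmp_path):
    path = tmp_path / "empty.txt"
    path.write_text("\n# only a comment\n")
    with pytest.raises(GeneListError):
        read_gene_list(path)


def test_panel_type_rejects_empty():
    with pytest.raises(GeneListError):
        GenePanel(frozenset())


# -- annotation table -------------------------------------------------------

HEADER = "chrom\tpos\tref\talt\tsift\tpolyphen2_humvar\tmutation_taster\tgrantham\tphylop\tgerp\tcadd\tlogit\texac_maf\tknown_in\tdelta_maxent"


def _table(tmp_path, *rows):
    path = tmp_path / "ann.tsv"
    path.write_text("\n".join([HEADER, *rows]) + "\n")
    return path


def test_annotation_published_row_values(tmp_path):
    """A candidate-table row at printed precision parses field-for-field."""
    path = _table(tmp_path, "4\t4864736\tC\tA\t0.00\t0.61\t0.99\t38\t5.96\t4.76\t27.60\t0.04\t1.3E-04\t.\t.")
    ss = read_annotation_table(path)[("4", 4864736, "C", "A")]
    assert ss.sift == 0.0 and ss.polyphen2_humvar == 0.61
    assert ss.mutation_taster == 0.99 and ss.grantham == 38
    assert (ss.phylop, ss.gerp, ss.cadd, ss.logit) == (5.96, 4.76, 27.60, 0.04)
    assert ss.exac_maf == pytest.approx(1.3e-4)
    assert ss.known_in == frozenset() and ss.delta_maxent is None


def test_annotation_missing_value_conventions(tmp_path):
    path = _table(tmp_path, "1\t10\tA\tG\t.\t-\t.\t.\t.\t.\t.\t.\t.\tdbSNP135,EVS\t.")
    ss = read_annotation_table(path)[("1", 10, "A", "G")]
    assert ss.sift is None and ss.polyphen2_humvar is None
    assert ss.known_in == frozenset({"dbSNP135", "EVS"})


def test_annotation_out_of_range_rejected(tmp_path):
    path = _table(tmp_path, "1\t10\tA\tG\t1.5\t.\t.\t.\t.\t.\t.\t.\t.\t.\t.")
    with pytest.raises(AnnotationError, match=r"sift.*\[0, 1\]"):
        read_annotation_table(path)


def test_annotation_duplicate_key_rejected(tmp_path):
    row = "1\t10\tA\tG\t0.1\t.\t.\t.\t.\t.\t.\t.\t.\t.\t."
    with pytest.raises(AnnotationError, match="duplicate"):
        read_annotation_table(_table(tmp_path, row, row))


def test_annotation_unknown_column_warns(tmp_path):
    path = tmp_path / "ann.tsv"
    path.write_text("chrom\tpos\tref\talt\tmystery\n1\t10\tA\tG\t5\n")
    with pytest.warns(UserWarning, match="mystery"):
        read_annotation_table(path)


def test_annotation_round_trip(tmp_path, small_cohort):
    path = tmp_path / "rt.tsv"
    write_annotation_table(small_cohort.scores, path)
    assert read_annotation_table(path) == small_cohort.scores


def test_scoreset_rejects_bad_tag():
    with pytest.raises(AnnotationError, match="database tags"):
        ScoreSet(known_in=frozenset({"dbSNP999"}))
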