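import datetime as dt

import pytest

from pgxrank.annotation import EvidenceFlags
from pgxrank.ehr_features import LabMeasurement, MedicationRecord, ParticipantEHR
from pgxrank.variant_store import VariantRecord


def make_variant(**kwargs) -> VariantRecord:
    """A valid missense RYR2 variant, overridable field by field."""
    defaults = dict(
        chrom="1",
        pos=237754201,
        ref="G",
        alt="A",
        alt_freq_pct=0.11,
        gene="RYR2",
        effect="missense",
        impact="high_moderate",
        has_rsid=True,
        evidence=EvidenceFlags(),
        gerp=3.5,
        cadd=14.0,
        mean_depth=400.0,
    )
    defaults.update(kwargs)
    return VariantRecord(**defaults)


def make_participant(pid="P00001", **kwargs) -> ParticipantEHR:
    defaults = dict(sex="female", race="white", hispanic="no")
    defaults.update(kwargs)
    return ParticipantEHR(participant_id=pid, **defaults)


def lab(assay, value, day=0):
    return LabMeasurement(assay=assay, value=value, date=dt.date(2010, 1, 1) + dt.timedelta(days=day))


def med(drug, day=0, kind="dispensing"):
    return MedicationRecord(drug=drug, date=dt.date(2010, 1, 1) + dt.timedelta(days=day), kind=kind)


#: A small handwritten annotated multi-sample VCF exercising the reader:
#: a het/hom/ref/missing SNV, an all-reference site, a tri-allelic site
#: (per-alt annotations), and an indel.
FIXTURE_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=250000000>
##contig=<ID=19,length=60000000>
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=EFFECT,Number=.,Type=String,Description="Effect class">
##INFO=<ID=IMPACT,Number=.,Type=String,Description="Impact class">
##INFO=<ID=RSID_PRESENT,Number=1,Type=Integer,Description="rsID known">
##INFO=<ID=GERP,Number=1,Type=Float,Description="GERP">
##INFO=<ID=CADD,Number=.,Type=Float,Description="CADD">
##INFO=<ID=CLINVAR,Number=1,Type=String,Description="ClinVar class">
##INFO=<ID=HGMD,Number=1,Type=String,Description="HGMD class">
##INFO=<ID=PRIOR_CLIN,Number=0,Type=Flag,Description="Prior clinical association">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4
1\t100\trs1\tA\tG\t.\tPASS\tGENE=RYR2;EFFECT=missense;IMPACT=high_moderate;RSID_PRESENT=1;GERP=3.5;CADD=14.2;CLINVAR=pathogenic\tGT:DP\t0/1:30\t1/1:28\t0/0:31\t./.:0
1\t200\t.\tC\tT\t.\tPASS\tGENE=RYR2;EFFECT=synonymous;IMPACT=other;RSID_PRESENT=0;GERP=-1.0;CADD=2.0\tGT:DP\t0/0:25\t0/0:26\t0/0:27\t0/0:28
19\t300\trs2\tG\tA,C\t.\tPASS\tGENE=RYR1;EFFECT=missense,intron;IMPACT=high_moderate,other;RSID_PRESENT=1;GERP=2.0;CADD=11.0,1.5;HGMD=disease_causing\tGT:DP\t0/1:40\t1/2:41\t2/2:42\t0/0:39
19\t400\t.\tGA\tG\t.\tPASS\tGENE=RYR1;EFFECT=intron;IMPACT=other;RSID_PRESENT=0;GERP=0.5;CADD=1.0\tGT:DP\t0/1:33\t1/1:35\t0/0:36\t0/1:34
"""


@pytest.fixture
def fixture_vcf(tmp_path):
    path = tmp_path / "fixture.vcf"
    path.write_text(FIXTURE_VCF)
    return path
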