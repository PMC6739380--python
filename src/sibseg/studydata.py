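"""Bundled worked-example data: a four-family AATD discordant-sibling exome
cohort with its published-style segregation tables and cohort-level counts.

The genotype tables carry, per variant row: gene symbol, SNP id ("novel"
rows carry None), the wild-type allele and one genotype cell per subject
column, plus an `immune` flag transcribing the tables' bold markup for genes
with recognized immune function. Two transcription caveats, carried verbatim
from the source layout:

* the non-affected table's column headers repeat the affected subjects' ids
  (AWK/AWL/BIR/BIP) although it lists genotypes of non-affected subjects —
  the headers are kept as printed;
* rows showing fewer genotype cells than subject columns do not indicate
  which column is blank; cells are assigned left-to-right (no counted
  quantity depends on column identity).
"""
from __future__ import annotations

from dataclasses import dataclass

from .io_formats import GenotypeTableRow
from .types import Pedigree, PedigreeIndividual, Phenotype

#: Subject columns of the segregation tables: one per family.
TABLE_SUBJECTS = (
    "AWK (family 3)",
    "AWL (family 185)",
    "BIR (family 237)",
    "BIP (family 114)",
)


def _r(gene, snp, wt, cells, immune=False):
    cells = tuple(cells) + ("",) * (len(TABLE_SUBJECTS) - len(cells))
    return GenotypeTableRow(gene=gene, snp_id=snp, wild_type=wt,
                            cells=cells, immune=immune)


# --- subjects table: 9 siblings from 4 families --------------------------

@dataclass(frozen=True)
class Subject:
    family_id: str
    subject_id: str
    sex: str
    age: int
    aat_level: float
    genotype: str
    fev1_pct_pred: int
    smoking: str
    affected: bool


SUBJECTS = (
    Subject("3", "AWI", "F", 67, 18.0, "ZZ", 94, "Non Smoker", False),
    Subject("3", "AWJ", "M", 65, 43.0, "ZZ", 106, "Non Smoker", False),
    Subject("3", "AWK", "M", 60, 22.0, "ZZ", 25, "Ex Smoker", True),
    Subject("185", "AWL", "F", 73, 37.0, "ZZ", 57, "Non Smoker", True),
    Subject("185", "AWM", "F", 71, 36.0, "ZZ", 85, "Non smoker", False),
    Subject("237", "BIR", "F", 53, 28.0, "ZZ", 102, "Non Smoker", True),
    Subject("237", "BQ0", "F", 43, 35.0, "ZZ", 100, "Non Smoker", False),
    Subject("114", "BIP", "M", 50, 23.3, "Z/Q0", 32, "Ex Smoker", True),
    Subject("114", "BIQ", "F", 47, 20.0, "Z/Q0", 99, "Non Smoker", False),
)


def subjects_pedigree() -> Pedigree:
    """The worked-example cohort as a Pedigree (4 families, 9 siblings)."""
    return Pedigree(
        PedigreeIndividual(
            s.subject_id, s.family_id, s.sex,
            Phenotype.AFFECTED if s.affected else Phenotype.NON_AFFECTED,
        )
        for s in SUBJECTS
    )


# --- affected-group segregation table -------------------------------------

AFFECTED_RECESSIVE_ROWS = (
    _r("AKNA", "rs3748176", "G", ("A/A", "A/A", "A/A"), True),
    _r("DNTTIP2", "rs3747965", "C", ("A/A", "A/A", "A/A"), True),
    _r("FRMD1", "rs1548349", "G", ("C/C", "C/C", "C/C")),
    # listed in the source with genotype cells for only two subjects
    _r("HJURP", "rs3806589", "T", ("C/C", "C/C")),
    _r("HJURP", "rs3732215", "G", ("C/C", "C/C", "C/C")),
    _r("IFIH1", "rs3747517", "T", ("C/C", "C/C", "C/C"), True),
    _r("KLHL3", "rs2905608", "T", ("C/C", "C/C", "C/C"), True),
    _r("KNG1", "rs710446", "T", ("C/C", "C/C", "C/C"), True),
    _r("MIB2", "rs7418389", "T", ("C/C", "C/C", "C/C"), True),
    _r("MS4A14", "rs3217518", "ATT", ("A/A", "A/A", "A/A"), True),
    _r("RTP2", "rs11707167", "T", ("C/C", "C/C", "C/C")),
    _r("SLC22A16", "rs714368", "T", ("C/C", "C/C", "C/C")),
    _r("THSD7B", "rs10206850", "A", ("G/G", "G/G", "G/G"), True),
    _r("TMPRSS5", "rs7110736", "A", ("G/G", "G/G", "G/G")),
    _r("TSPAN8", "rs3763978", "C", ("G/G", "G/G", "G/G")),
)

AFFECTED_DOMINANT_ROWS = (
    _r("ACBD3", None, "CTTTTTTTT",
       ("CTTTTTTTT/CTTTTTTT", "CTTTTTTTT/CTTTTTTT", "CTTTTTTTT/CTTTTTTT")),
    _r("ALAD", "rs1800435", "C", ("C/G", "C/G", "C/G"), True),
    _r("APEX1", "rs1130409", "T", ("T/G", "T/G", "T/G"), True),
    _r("EGFL8", "rs3096697", "G", ("G/A", "G/A", "G/A")),
    _r("HSD17B4", "rs25640", "G", ("G/A", "G/A", "G/A")),
    _r("IQCG", "rs9880989", "G", ("G/T", "G/T", "G/T")),
    _r("KLC2", "rs2276036", "C", ("C/T", "C/T", "C/T"), True),
    _r("L3MBTL4", "rs3737353", "C", ("C/T", "C/T", "C/T")),
    _r("LIPK", "rs1214464", "G", ("G/C", "G/C", "G/C")),
    _r("LRCH4", None, "GTC", ("GTC/GC", "GTC/GC", "GTC/GC")),
    _r("MKI67", "rs8473", "T", ("T/C", "T/C", "T/C")),
    _r("MKI67", "rs11106", "G", ("G/C", "G/C", "G/C")),
    _r("MS4A12", "rs2298553", "C", ("C/T", "C/T", "C/T")),
    _r("PCDH12", "rs164515", "C", ("C/T", "C/T", "C/T")),
    _r("PIK3AP1", "rs17112076", "C", ("C/T", "C/T", "C/T"), True),
    _r("PPT2", "rs3096696", "C", ("C/A", "C/A", "C/A"), True),
    _r("PRDM16", "rs2493292", "C", ("C/T", "C/T", "T/T"), True),
    _r("TBC1D26", "rs11650318", "C", ("C/T", "C/T", "C/T")),
    _r("TBC1D26", "rs17855672", "G", ("G/A", "G/A", "G/A")),
    _r("TRIM16", "rs1060903", "C", ("C/A", "C/A", "C/A")),
    _r("TSPYL1", "rs3828743", "G", ("G/A", "G/A", "G/A")),
    _r("VSTM4", "rs13088", "A", ("A/G", "A/G", "A/G")),
    _r("ZNF286A", "rs3760299", "T", ("T/C", "T/C", "T/C")),
)

AFFECTED_TABLE = AFFECTED_RECESSIVE_ROWS + AFFECTED_DOMINANT_ROWS

# --- non-affected-group segregation table ---------------------------------

NON_AFFECTED_RECESSIVE_ROWS = (
    _r("AAK1", "rs66931661", "CTGT", ("C/C", "C/C", "C/C")),
    _r("ABCB11", "rs2287622", "A", ("G/G", "G/G", "G/G")),
    _r("ALG1L", "rs3828357", "T", ("C/C", "C/C", "C/C")),
    _r("C1orf227", "rs10864004", "A", ("G/G", "G/G", "G/G")),
    _r("CD5", "rs2229177", "C", ("T/T", "T/T", "T/T"), True),
    _r("CPB2", "rs1926447", "A", ("G/G", "G/G", "G/G"), True),
    _r("CSNK1A1L", "rs9576175", "G", ("T/T", "T/T", "T/T")),
    _r("HLA-C", "rs79636386", "A", ("C/C", "C/C", "C/C"), True),
    _r("HLA-DQB1", "rs1049130", "A", ("G/G", "G/G", "G/G"), True),
    _r("KRTAP19-4", "rs2298437", "T", ("C/C", "C/C", "C/C")),
    _r("LCE5A", "rs2105117", "G", ("A/A", "A/A", "A/A")),
    _r("MMRN2", "rs3750823", "C", ("T/T", "T/T", "T/T")),
    _r("NFATC4", "rs7149586", "T", ("C/C", "C/C", "C/C"), True),
    _r("PM20D1", "rs1361754", "A", ("G/G", "G/G", "G/G")),
    _r("RTP1", "rs6764714", "C", ("G/G", "G/G", "G/G"), True),
    _r("SIM2", "rs2073601", "C", ("A/A", "A/A", "A/A"), True),
    _r("TINAG", "rs1058768", "T", ("C/C", "C/C", "C/C")),
    _r("TMED5", "rs1060622", "G", ("A/A", "A/A", "A/A")),
    _r("TMEM173", "rs1131769", "T", ("C/C", "C/C", "C/C"), True),
    _r("TPTE", None, "G", ("T/T", "T/T", "T/T")),
    _r("ZC3H13", "rs9534264", "T", ("A/A", "A/A", "A/A"), True),
)

NON_AFFECTED_DOMINANT_ROWS = (
    _r("ACBD3", "rs2306120", "T", ("T/G", "T/G", "T/G")),
    _r("ALPK2", "rs9944810", "C", ("C/A", "C/A", "C/A")),
    _r("ANKK1", "rs1800497", "G", ("G/A", "G/A", "G/A")),
    _r("ART4", "rs11276", "C", ("C/T", "C/T", "C/T")),
    _r("BBS12", "rs309370", "G", ("G/A", "G/A", "G/A")),
    _r("BBS12", "rs13135778", "G", ("G/A", "G/A", "G/A")),
    _r("C12orf60", "rs139293175", "CTA", ("CTA/C", "CTA/C", "CTA/C")),
    _r("C12orf60", "rs7307438", "T", ("T/A", "T/A", "T/A")),
    _r("CCDC144NL", "rs79930314", "G", ("G/T", "G/T", "G/T")),
    _r("CCDC144NL", "rs79843086", "G", ("G/T", "G/T", "G/T")),
    _r("CCHCR1", "rs130068", "G", ("G/A", "G/A", "G/A")),
    _r("CD200", "rs2272022", "C", ("C/A", "C/A", "C/A"), True),
    _r("CWF19L2", "rs659040", "G", ("G/A", "G/A", "G/A")),
    _r("CYP21A2", "rs397515530", "G", ("A/A", "A/A", "G/A")),
    _r("DHRS4", "rs17099455", "G", ("G/A", "G/A", "G/A")),
    _r("DYNC2LI1", "rs9309107", "T", ("T/A", "T/A", "T/A")),
    _r("EDN1", "rs5370", "G", ("G/T", "T/T", "G/T")),
    _r("EFS", "rs2231798", "T", ("T/C", "T/C", "T/C")),
    _r("EPCAM", "rs1126497", "T", ("T/C", "T/C", "T/C")),
    _r("FHAD1", "rs4661330", "A", ("A/G", "A/G", "A/G")),
    _r("HINFP", "rs100803", "C", ("C/T", "C/T", "C/T")),
    _r("HLA-C", "rs79636386", "A", ("A/C", "C/C", "C/C", "C/C"), True),
    _r("HLA-DQB1", "rs1130398", "C", ("C/T", "C/T", "C/T"), True),
    _r("HLA-DQB1", "rs1063323", "C", ("C/T", "C/T", "C/T"), True),
    _r("HLA-DRB1", "rs71547382", "C", ("C/T", "C/T", "C/T"), True),
    _r("KIF20B", "rs1886997", "A", ("A/G", "A/G", "A/G")),
    _r("KIF20B", "rs144593231", "C", ("C/CTAAAAG", "C/CTAAAAG", "C/CTAAAAG")),
    _r("KLHL33", "rs1953225", "T", ("T/C", "T/C", "T/C")),
    _r("KRT40", "rs9908304", "G", ("G/A", "G/A", "G/A")),
    _r("LRRC6", "rs2293979", "G", ("A/A", "G/A", "G/A")),
    _r("MCCD1", "rs2259435", "G", ("G/A", "G/A", "G/A"), True),
    _r("MICB", "rs1065075", "A", ("A/G", "A/G", "A/G"), True),
    _r("MICB", "rs1051788", "G", ("G/A", "G/A", "G/A"), True),
    _r("MMP27", "rs1276286", "T", ("T/A", "T/A", "A/A")),
    _r("NOS2", "rs2297518", "G", ("G/A", "G/A", "G/A"), True),
    _r("NPAS2", "rs9223", "C", ("C/T", "C/T", "C/T", "C/T")),
    _r("NPY4R", "rs79871698", "G", ("G/A", "G/A", "G/A"), True),
    _r("NRG3", "rs1884282", "C", ("C/G", "C/G", "C/G"), True),
    _r("NSUN4", "rs3737744", "A", ("A/G", "A/G", "A/G")),
    _r("NUMBL", "rs749669311", "TTTGCTGTTGCTGCTGCTGC",
       ("TTTGCTGTTGCTGCTGCTGC/T", "TTTGCTGTTGCTGCTGCTGC/T",
        "TTTGCTGTTGCTGCTGCTGC/T"), True),
    _r("OR10G2", "rs41314525", "C", ("C/A", "C/A", "C/A")),
    _r("OR13C2", "rs10156474", "T", ("T/C", "T/C", "T/C")),
    _r("OR13C2", "rs10991326", "A", ("A/T", "A/T", "A/T")),
    _r("OR13C5", "rs4117966", "C", ("C/T", "C/T", "C/T")),
    _r("OR13C5", "rs1523678", "T", ("T/C", "T/C", "T/C")),
    _r("OR13C5", "rs1851725", "A", ("A/G", "A/G", "A/G")),
    _r("OR13C5", "rs6479260", "G", ("G/C", "G/C", "G/C")),
    _r("OR13C5", "rs11314210", "GT", ("GT/G", "GT/G", "GT/G")),
    _r("OR13C9", "rs993658", "T", ("T/A", "T/A", "T/A")),
    _r("OR2T2", "rs67700848", "C", ("C/T", "C/T", "C/T")),
    _r("OR4E2", "rs61732411", "C", ("C/T", "C/T", "C/T", "C/T")),
    _r("PRDM1", "rs811925", "C", ("C/G", "C/G", "C/G"), True),
    _r("PSMD9", "rs14259", "A", ("A/G", "A/G", "A/G"), True),
    _r("RNLS", "rs2296545", "C", ("C/G", "C/G", "C/G")),
    _r("SPATA16", "rs1515441", "C", ("C/T", "C/T", "C/T")),
    _r("SPATA16", "rs16846616", "C", ("C/T", "C/T", "C/T")),
    _r("SVEP1", "rs3739451", "A", ("A/T", "A/T", "A/T")),
    _r("TMEM132C", "rs12424159", "G", ("G/A", "G/A", "G/A")),
    _r("TMEM71", "rs1895807", "A", ("A/G", "A/G", "A/G")),
    _r("WDR66", "rs17852561", "C", ("C/T", "C/T", "C/T")),
    _r("WWC2", "rs11734376", "G", ("G/T", "G/T", "G/T")),
    _r("ZNF626", "rs73002662", "T", ("T/G", "T/G", "T/G")),
)

NON_AFFECTED_TABLE = NON_AFFECTED_RECESSIVE_ROWS + NON_AFFECTED_DOMINANT_ROWS


def curated_immune_genes() -> set:
    """Genes flagged as immune-related (bold markup) in either table."""
    return {r.gene for r in AFFECTED_TABLE + NON_AFFECTED_TABLE if r.immune}


# --- cohort-level sequencing counts ---------------------------------------

#: Variant-class counts of the worked-example cohort (9 exomes).
VARIANT_CLASS_COUNTS = {
    "subjects": 9,
    "all_variants": 77204,
    "not_confirmed_transcript": 20730,
    "utrs": 14597,
    "functionally_annotated": 41877,
    "synonymous": 20748,
    "non_synonymous": 21129,
    "missense": 19751,
    "nonsense": 240,
    "frameshift": 612,
    "inframe": 447,
    "stop_loss": 59,
    "stop_gain": 20,
    "rare": 5914,       # GMAF <= 1%
    "novel": 3345,
    "deletion": 645,
    "insertion": 413,
}

#: Remaining-variant counts after each cascade step (flowchart brackets).
FILTER_STAGE_COUNTS = {
    "total": 77204,
    "functionally_annotated": 41877,
    "high_confidence": 34725,
    "non_synonymous": 17373,
    "drop_minor_in_reference": 16319,
}


def worked_example():
    """Bundle all worked-example fixtures in one namespace-like dict."""
    return {
        "subjects": SUBJECTS,
        "pedigree": subjects_pedigree(),
        "table_subjects": TABLE_SUBJECTS,
        "affected_table": AFFECTED_TABLE,
        "non_affected_table": NON_AFFECTED_TABLE,
        "curated_immune_genes": curated_immune_genes(),
        "variant_class_counts": dict(VARIANT_CLASS_COUNTS),
        "filter_stage_counts": dict(FILTER_STAGE_COUNTS),
    }
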