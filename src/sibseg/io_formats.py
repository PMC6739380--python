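"""Readers and writers for every external format the pipeline touches.

Formats: multi-sample VCF v4.x (read via cyvcf2, written as plain text),
6-column PED, per-variant annotation TSV with a declared header, GMT gene
sets, plain-text curated gene lists, and the worked-example genotype-table
layout (gene, SNP id, wild-type allele, per-subject genotype cells).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from cyvcf2 import VCF

from .types import (
    GeneSet,
    GeneSetCollection,
    GenotypeCall,
    GenotypeState,
    Pedigree,
    PedigreeIndividual,
    Phenotype,
    Variant,
    VariantAnnotation,
)


class FormatError(ValueError):
    """Malformed input file; the message names the file and line."""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "transcript_status", "region",
    "consequence_term", "gmaf", "alt_pop_freq", "known_id",
]
SCORE_COLUMNS = ["CADD", "DANN", "PROVEAN"]


def _prevalidate_vcf(path: str) -> None:
    """Check line shape before handing the file to cyvcf2 so that ragged
    sample columns are reported with a line number."""
    n_fields = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                n_fields = len(line.split("\t"))
                if n_fields < 8:
                    raise FormatError(f"{path}: line {lineno}: truncated #CHROM header")
                continue
            if line.startswith("#"):
                raise FormatError(f"{path}: line {lineno}: unexpected header line")
            if n_fields is None:
                raise FormatError(f"{path}: line {lineno}: data before #CHROM header")
            got = len(line.split("\t"))
            if got != n_fields:
                raise FormatError(
                    f"{path}: line {lineno}: expected {n_fields} columns, got {got}"
                )
    if n_fields is None:
        raise FormatError(f"{path}: missing #CHROM header line")


def _split_state(alleles: Sequence[int], alt_index: int) -> GenotypeState:
    """Genotype state of one sample for one alternate allele of a
    (possibly multiallelic) record."""
    if any(a < 0 for a in alleles):
        return GenotypeState.MISSING
    n = sum(1 for a in alleles if a == alt_index)
    if n == 2:
        return GenotypeState.HOM_ALT
    if n == 1:
        return GenotypeState.HET
    return GenotypeState.HOM_REF


def read_vcf(path: str):
    """Read a VCF v4.x into (variants, genotypes).

    Returns a list of biallelic :class:`Variant` (multiallelic records are
    split, with allele-specific alt depths) and a dict mapping variant key ->
    list of :class:`GenotypeCall` in VCF sample order. Missing FORMAT fields
    become None.
    """
    _prevalidate_vcf(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    variants: list[Variant] = []
    genotypes: dict = {}
    seen = set()
    for rec in vcf:
        gts = rec.genotypes if samples else []
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        try:
            gq = rec.format("GQ")
        except KeyError:
            gq = None
        for ai, alt in enumerate(rec.ALT, start=1):
            var = Variant(rec.CHROM, rec.POS, rec.REF, alt, known_id=rec.ID)
            if var.key in seen:
                raise FormatError(f"{path}: duplicate variant key {var.key}")
            seen.add(var.key)
            calls = []
            for si, sample in enumerate(samples):
                alleles = gts[si][:-1]  # last element is phasing flag
                state = _split_state(alleles, ai)
                depth = None
                if dp is not None and int(dp[si][0]) >= 0:
                    depth = int(dp[si][0])
                alt_depth = None
                if ad is not None and ad.shape[1] > ai and int(ad[si][ai]) >= 0:
                    alt_depth = int(ad[si][ai])
                gqv = None
                if gq is not None and float(gq[si][0]) >= 0:
                    gqv = float(gq[si][0])
                if depth is not None and alt_depth is not None and alt_depth > depth:
                    depth = alt_depth  # tolerate caller AD/DP drift
                calls.append(GenotypeCall(sample, state, depth=depth, alt_depth=alt_depth, gq=gqv))
            variants.append(var)
            genotypes[var.key] = calls
    return variants, genotypes


_STATE_TO_GT = {
    GenotypeState.HOM_REF: "0/0",
    GenotypeState.HET: "0/1",
    GenotypeState.HOM_ALT: "1/1",
    GenotypeState.MISSING: "./.",
}


def write_vcf(path: str, variants: Sequence[Variant], genotypes: dict, samples: Sequence[str]):
    """Write biallelic variants with GT:DP:AD:GQ as an uncompressed VCF."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    ]
    for chrom in sorted({v.chrom for v in variants}):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    by_sample_order = {s: i for i, s in enumerate(samples)}
    for var in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        calls = sorted(genotypes[var.key], key=lambda c: by_sample_order[c.sample_id])
        cells = []
        for c in calls:
            dp = "." if c.depth is None else str(c.depth)
            if c.alt_depth is None:
                adf = "."
            else:
                ref_d = max((c.depth or c.alt_depth) - c.alt_depth, 0)
                adf = f"{ref_d},{c.alt_depth}"
            gqf = "." if c.gq is None else str(int(c.gq))
            cells.append(f"{_STATE_TO_GT[c.state]}:{dp}:{adf}:{gqf}")
        lines.append(
            "\t".join(
                [var.chrom, str(var.pos), var.known_id or ".", var.ref, var.alt,
                 ".", "PASS", ".", "GT:DP:AD:GQ"] + cells
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

_PED_SEX = {"1": "M", "2": "F", "0": "U"}
_PED_PHENO = {"2": Phenotype.AFFECTED, "1": Phenotype.NON_AFFECTED}


def read_pedigree(path: str, strict: bool = True) -> Pedigree:
    """Read a whitespace-delimited 6-column PED file.

    Phenotype coding follows the PED convention: 2 = affected,
    1 = unaffected; any other code is rejected. In strict mode a family
    without both an affected and a non-affected member is a design error
    (the discordant-sibling design requires both); otherwise a warning.
    """
    individuals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise FormatError(f"{path}: line {lineno}: expected 6 PED columns, got {len(fields)}")
            fam, ind, _father, _mother, sex, pheno = fields[:6]
            if pheno not in _PED_PHENO:
                raise FormatError(
                    f"{path}: line {lineno}: unknown phenotype code {pheno!r} "
                    "(expected 2=affected, 1=unaffected)"
                )
            individuals.append(
                PedigreeIndividual(ind, fam, _PED_SEX.get(sex, "U"), _PED_PHENO[pheno])
            )
    ped = Pedigree(individuals)
    bad = ped.validate_discordant_design(strict=strict)
    if bad and not strict:
        warnings.warn(
            "families without both phenotypes: " + ", ".join(sorted(bad)), stacklevel=2
        )
    return ped


def write_pedigree(path: str, pedigree: Pedigree):
    rows = []
    for ind in pedigree.individuals():
        sex = {"M": "1", "F": "2"}.get(ind.sex, "0")
        pheno = "2" if ind.phenotype == Phenotype.AFFECTED else "1"
        rows.append(f"{ind.family_id}\t{ind.individual_id}\t0\t0\t{sex}\t{pheno}")
    with open(path, "w") as fh:
        fh.write("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# Annotation TSV
# ---------------------------------------------------------------------------

def read_annotations(path: str) -> dict:
    """Read the per-variant annotation TSV into a map variant-key -> annotation.

    The header must name the required columns; GMAF and alt_pop_freq may be
    empty (novelty is GMAF absent AND known id absent). Unknown consequence
    vocabulary is preserved verbatim for downstream normalization.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns: {', '.join(missing)}")
    annotations: dict = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        key = (row.chrom, int(row.pos), row.ref, row.alt)
        if key in annotations:
            raise FormatError(f"{path}: line {i}: duplicate variant key {key}")
        scores = {
            c: float(getattr(row, c))
            for c in SCORE_COLUMNS
            if c in df.columns and getattr(row, c) != ""
        }
        annotations[key] = VariantAnnotation(
            key=key,
            gene=row.gene,
            transcript_status=row.transcript_status,
            region=row.region,
            consequence_term=row.consequence_term,
            gmaf=float(row.gmaf) if row.gmaf != "" else None,
            alt_pop_freq=float(row.alt_pop_freq) if row.alt_pop_freq != "" else None,
            known_id=row.known_id if row.known_id != "" else None,
            scores=scores,
        )
    return annotations


def write_annotations(path: str, annotations: dict):
    rows = []
    for key in sorted(annotations):
        a = annotations[key]
        rows.append(
            {
                "chrom": key[0], "pos": key[1], "ref": key[2], "alt": key[3],
                "gene": a.gene, "transcript_status": a.transcript_status,
                "region": a.region, "consequence_term": a.consequence_term,
                "gmaf": "" if a.gmaf is None else a.gmaf,
                "alt_pop_freq": "" if a.alt_pop_freq is None else a.alt_pop_freq,
                "known_id": a.known_id or "",
                **{c: a.scores.get(c, "") for c in SCORE_COLUMNS},
            }
        )
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS + SCORE_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# GMT / curated gene list
# ---------------------------------------------------------------------------

def read_genesets(path: str) -> GeneSetCollection:
    """Read tab-delimited GMT (set id, description, genes...); duplicate genes
    within a line are deduplicated with a warning, empty sets rejected."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT line needs id, description and >=1 gene"
                )
            set_id, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if not genes:
                raise FormatError(f"{path}: line {lineno}: empty gene set {set_id!r}")
            uniq = list(dict.fromkeys(genes))
            if len(uniq) != len(genes):
                warnings.warn(
                    f"{path}: line {lineno}: duplicated genes in set {set_id!r} deduplicated",
                    stacklevel=2,
                )
            sets.append(GeneSet(set_id, desc, tuple(uniq)))
    return GeneSetCollection(sets)


def write_genesets(path: str, collection: GeneSetCollection):
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.set_id, s.description, *s.genes]) + "\n")


def read_gene_list(path: str) -> set:
    """Plain-text curated gene list, one symbol per line; '#' comments allowed.
    Symbols are compared case-sensitively downstream."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return genes


def write_gene_list(path: str, genes) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# Worked-example genotype tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeTableRow:
    """One row of a published-style segregation table: gene symbol, SNP id
    ('novel' rows carry None), the wild-type allele and one genotype cell per
    subject column (blank = not shown)."""

    gene: str
    snp_id: Optional[str]
    wild_type: str
    cells: tuple  # genotype strings like "C/T", "" for blank
    immune: bool = False  # bold markup in the source table


class GenotypeTableError(FormatError):
    pass


def _parse_cell(cell: str, wild_type: str, alt: Optional[str], context: str):
    """Parse one 'A/B' genotype cell against the wild-type allele. Returns
    (state, alt) where alt is the single consistent alternate allele seen so
    far in the row. Genotypes are unordered: 'C/T' == 'T/C'."""
    parts = cell.split("/")
    if len(parts) != 2 or not all(parts):
        raise GenotypeTableError(f"{context}: cannot parse genotype cell {cell!r}")
    n_alt = 0
    for allele in parts:
        if allele == wild_type:
            continue
        if alt is None:
            alt = allele
        if allele != alt:
            raise GenotypeTableError(
                f"{context}: allele {allele!r} is neither wild-type {wild_type!r} "
                f"nor the row's alternate {alt!r}"
            )
        n_alt += 1
    state = (GenotypeState.HOM_REF, GenotypeState.HET, GenotypeState.HOM_ALT)[n_alt]
    return state, alt


def parse_genotype_table(rows: Sequence[GenotypeTableRow], subjects: Sequence[str]):
    """Parse a worked-example genotype table.

    Returns (variants, matrix, wild_type_map): one Variant per row (row-indexed
    position keeps repeated SNP ids distinct), a map key -> {subject: state},
    and key -> wild-type allele. Blank cells become missing genotypes.
    """
    variants = []
    matrix = {}
    wild_types = {}
    for i, row in enumerate(rows):
        if len(row.cells) != len(subjects):
            raise GenotypeTableError(
                f"row {i} ({row.gene}): {len(row.cells)} cells for {len(subjects)} subjects"
            )
        context = f"row {i} ({row.gene} {row.snp_id or 'novel'})"
        alt = None
        states = {}
        for subject, cell in zip(subjects, row.cells):
            if cell == "":
                states[subject] = GenotypeState.MISSING
                continue
            states[subject], alt = _parse_cell(cell, row.wild_type, alt, context)
        if alt is None:
            raise GenotypeTableError(f"{context}: no alternate allele observed in any cell")
        var = Variant("table", i + 1, row.wild_type, alt, known_id=row.snp_id)
        variants.append(var)
        matrix[var.key] = states
        wild_types[var.key] = row.wild_type
    return variants, matrix, wild_types


def read_genotype_table(path: str):
    """Read a genotype-table TSV (gene, snp_id, wild_type, immune, then one
    column per subject) into (rows, subjects)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    fixed = ["gene", "snp_id", "wild_type", "immune"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns: {', '.join(missing)}")
    subjects = [c for c in df.columns if c not in fixed]
    rows = []
    for rec in df.to_dict("records"):
        rows.append(
            GenotypeTableRow(
                gene=rec["gene"],
                snp_id=rec["snp_id"] or None,
                wild_type=rec["wild_type"],
                cells=tuple(rec[c] for c in subjects),
                immune=rec["immune"] in ("1", "True", "true"),
            )
        )
    return rows, subjects


def write_genotype_table(path: str, rows: Sequence[GenotypeTableRow], subjects: Sequence[str]):
    records = []
    for row in rows:
        rec = {
            "gene": row.gene,
            "snp_id": row.snp_id or "",
            "wild_type": row.wild_type,
            "immune": "1" if row.immune else "0",
        }
        rec.update(dict(zip(subjects, row.cells)))
        records.append(rec)
    pd.DataFrame(records, columns=["gene", "snp_id", "wild_type", "immune", *subjects]).to_csv(
        path, sep="\t", index=False
    )
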