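"""Synthetic discordant-sibling cohorts with a ground-truth manifest.

The generator emulates the study design the pipeline targets: four unrelated
families of siblings who share a monogenic background but split into affected
and non-affected phenotype groups (nine subjects by default — the first
family contributes two non-affected siblings). Background variants draw
genotypes independently per individual from Hardy-Weinberg proportions at a
per-variant allele frequency; planted variants are set directly so that they
satisfy a chosen (model, group) in k of the N families and fail in the
opposite group. Annotations are crafted so that a configured fraction of
background variants dies at each cascade stage, and one bundled gene set is
enriched in the planted genes.

Families are unrelated and siblings share no explicit IBD model: genotypes
are independent draws per individual except at planted sites. Depths follow
a negative binomial (mean ~105x, mirroring a deep exome run) to exercise the
alternate-allele coverage filter realistically.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import io_formats
from .types import (
    GeneSet,
    GeneSetCollection,
    GenotypeCall,
    GenotypeState,
    Model,
    Pedigree,
    PedigreeIndividual,
    Phenotype,
    Variant,
    VariantAnnotation,
)

#: Filter-stage fates a background variant can be assigned.
FATES = (
    "low_quality",
    "unconfirmed_transcript",
    "utr",
    "unannotated",
    "low_alt_coverage",
    "synonymous",
    "minor_in_reference",
    "survive",
)


@dataclass
class SimConfig:
    seed: int
    n_families: int = 4
    affected_per_family: tuple = (1, 1, 1, 1)
    non_affected_per_family: tuple = (2, 1, 1, 1)
    n_background_variants: int = 400
    freq_range: tuple = (0.02, 0.20)
    transition_prob: float = 0.7  # SNV transition weight -> Ti/Tv ~ 2.3
    #: planted variants per (model, group)
    n_planted: dict = field(default_factory=lambda: {
        (Model.RECESSIVE, Phenotype.AFFECTED): 2,
        (Model.DOMINANT, Phenotype.AFFECTED): 2,
        (Model.RECESSIVE, Phenotype.NON_AFFECTED): 2,
        (Model.DOMINANT, Phenotype.NON_AFFECTED): 2,
    })
    k_confirm: int = 3
    missingness: float = 0.0
    depth_mean: float = 105.0
    depth_shape: float = 8.0
    normal_gq: int = 60
    low_gq: int = 5
    #: fraction of background variants assigned each non-surviving fate
    fate_fractions: dict = field(default_factory=lambda: {
        "low_quality": 0.05,
        "unconfirmed_transcript": 0.10,
        "utr": 0.10,
        "unannotated": 0.03,
        "low_alt_coverage": 0.07,
        "synonymous": 0.25,
        "minor_in_reference": 0.05,
    })
    novel_fraction: float = 0.05
    n_background_genes: int = 150
    n_decoy_sets: int = 20
    decoy_set_size: int = 12
    planted_set_extra: int = 4
    curated_background_genes: int = 10

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        if self.k_confirm > self.n_families:
            raise ValueError(
                f"infeasible config: k={self.k_confirm} > n_families={self.n_families}"
            )
        if len(self.affected_per_family) != self.n_families or \
                len(self.non_affected_per_family) != self.n_families:
            raise ValueError("per-family sibling counts must match n_families")
        if sum(self.fate_fractions.values()) > 1.0 + 1e-9:
            raise ValueError("fate fractions exceed 1")


@dataclass
class ManifestEntry:
    key: tuple
    gene: str
    kind: str                      # planted | background
    model: Optional[str]           # planted only
    group: Optional[str]           # planted only
    families: tuple                # planted: families forced to satisfy
    allele_freq: Optional[float]   # background only
    expected_stage: str            # cascade stage of removal, or "survive"
    expected_call: bool            # planted, expected to be called post-cascade


@dataclass
class Cohort:
    config: SimConfig
    pedigree: Pedigree
    variants: list
    genotypes: dict        # key -> list[GenotypeCall]
    annotations: dict      # key -> VariantAnnotation
    genesets: GeneSetCollection
    curated_genes: set
    manifest: list         # list[ManifestEntry]
    planted_set_id: str = "SET_PLANTED"

    def states(self) -> dict:
        """key -> {sample: GenotypeState} view used by the segregation caller."""
        return {
            k: {c.sample_id: c.state for c in calls}
            for k, calls in self.genotypes.items()
        }

    def genes(self) -> dict:
        return {k: a.gene for k, a in self.annotations.items()}


def _build_pedigree(config: SimConfig) -> Pedigree:
    inds = []
    for fi in range(config.n_families):
        fam = f"F{fi + 1}"
        for ai in range(config.affected_per_family[fi]):
            inds.append(PedigreeIndividual(f"{fam}_A{ai + 1}", fam, "U", Phenotype.AFFECTED))
        for ni in range(config.non_affected_per_family[fi]):
            inds.append(PedigreeIndividual(f"{fam}_N{ni + 1}", fam, "U", Phenotype.NON_AFFECTED))
    return Pedigree(inds)


_BASES = ("A", "C", "G", "T")
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _draw_alleles(rng, transition_prob: float):
    """Random SNV ref/alt pair, transitions weighted to mimic exome Ti/Tv."""
    ref = _BASES[int(rng.integers(4))]
    if rng.random() < transition_prob:
        return ref, _TRANSITION[ref]
    choices = [b for b in _BASES if b != ref and b != _TRANSITION[ref]]
    return ref, choices[int(rng.integers(2))]


def _draw_hwe_states(rng, p: float, n: int):
    """n independent genotype draws at alternate-allele frequency p."""
    r = rng.random(n)
    hom_ref = (1 - p) ** 2
    het = hom_ref + 2 * p * (1 - p)
    out = []
    for x in r:
        if x < hom_ref:
            out.append(GenotypeState.HOM_REF)
        elif x < het:
            out.append(GenotypeState.HET)
        else:
            out.append(GenotypeState.HOM_ALT)
    return out


def _depth(rng, config: SimConfig) -> int:
    shape = config.depth_shape
    d = rng.negative_binomial(shape, shape / (shape + config.depth_mean))
    return max(int(d), 1)


def _make_call(rng, sample: str, state: GenotypeState, config: SimConfig,
               gq: int, cap_alt: Optional[int] = None,
               floor_depth: Optional[int] = None) -> GenotypeCall:
    depth = _depth(rng, config)
    if floor_depth is not None:
        depth = max(depth, floor_depth)
    if state == GenotypeState.HOM_ALT:
        alt = depth
    elif state == GenotypeState.HET:
        alt = int(rng.binomial(depth, 0.5))
        if floor_depth is not None:
            alt = max(alt, (cap_alt or 0) + 1 if cap_alt else 40)
    else:
        alt = 0
    if cap_alt is not None and alt > cap_alt:
        alt = int(rng.integers(max(cap_alt // 2, 1), cap_alt + 1))
    if state == GenotypeState.MISSING:
        return GenotypeCall(sample, state, depth=None, alt_depth=None, gq=None)
    return GenotypeCall(sample, state, depth=max(depth, alt), alt_depth=alt, gq=float(gq))


def _expected_stage(calls, annotation: Optional[VariantAnnotation],
                    config: SimConfig) -> str:
    """Reference cascade rules applied to the realized data; this is the
    generator's own straightforward account of where a variant must fall."""
    live = [c for c in calls
            if not (c.gq is not None and c.gq < 20) and c.state != GenotypeState.MISSING]
    if not any(c.state.carries_alt for c in live):
        return "drop_low_quality"
    if annotation is not None and annotation.transcript_status != "confirmed":
        return "drop_unconfirmed_transcript"
    if annotation is not None and annotation.region != "coding":
        return "drop_utr"
    if annotation is None:
        return "functionally_annotated"
    alt_depths = [c.alt_depth for c in live if c.state.carries_alt and c.alt_depth is not None]
    if alt_depths and max(alt_depths) <= 30:
        return "high_confidence"
    if annotation.consequence_term in ("synonymous SNV", "synonymous"):
        return "non_synonymous"
    if annotation.alt_pop_freq is not None and annotation.alt_pop_freq > 0.5:
        return "drop_minor_in_reference"
    return "survive"


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate a cohort; identical configs (same seed) give identical output."""
    rng = np.random.default_rng(config.seed)
    pedigree = _build_pedigree(config)
    samples = pedigree.sample_ids()
    fam_ids = pedigree.family_ids()

    planted_specs = []
    for (model, group), n in sorted(
            config.n_planted.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)):
        for _ in range(n):
            planted_specs.append((model, group))
    n_planted = len(planted_specs)

    bg_genes = [f"GENE{i + 1:04d}" for i in range(config.n_background_genes)]
    planted_genes = [f"GENE{9000 + i + 1:04d}" for i in range(n_planted)]

    variants: list[Variant] = []
    genotypes: dict = {}
    annotations: dict = {}
    manifest: list[ManifestEntry] = []

    pos = 10_000
    # --- planted variants ---------------------------------------------------
    for i, (model, group) in enumerate(planted_specs):
        pos += int(rng.integers(50, 500))
        ref, alt = _draw_alleles(rng, config.transition_prob)
        var = Variant("1", pos, ref, alt, known_id=f"rsP{i + 1}")
        chosen = sorted(rng.choice(fam_ids, size=config.k_confirm, replace=False))
        target_state = (GenotypeState.HOM_ALT if model == Model.RECESSIVE
                        else GenotypeState.HET)
        calls = []
        for ind in pedigree.individuals():
            if ind.family_id in chosen and ind.phenotype == group:
                state = target_state
                call = _make_call(rng, ind.individual_id, state, config,
                                  config.normal_gq, floor_depth=80)
            else:
                # opposite group and non-chosen families fail the spec outright
                call = _make_call(rng, ind.individual_id, GenotypeState.HOM_REF,
                                  config, config.normal_gq)
            calls.append(call)
        gene = planted_genes[i]
        ann = VariantAnnotation(
            key=var.key, gene=gene, transcript_status="confirmed", region="coding",
            consequence_term="nonsynonymous SNV",
            gmaf=round(float(rng.uniform(0.05, 0.4)), 4),
            alt_pop_freq=round(float(rng.uniform(0.05, 0.5)), 4),
            known_id=var.known_id,
        )
        variants.append(var)
        genotypes[var.key] = calls
        annotations[var.key] = ann
        manifest.append(ManifestEntry(
            key=var.key, gene=gene, kind="planted", model=model.value,
            group=group.value, families=tuple(chosen), allele_freq=None,
            expected_stage=_expected_stage(calls, ann, config),
            expected_call=True,
        ))

    # --- background variants ------------------------------------------------
    fate_names = list(config.fate_fractions) + ["survive"]
    fate_probs = list(config.fate_fractions.values())
    fate_probs.append(1.0 - sum(fate_probs))
    for i in range(config.n_background_variants):
        pos += int(rng.integers(50, 500))
        ref, alt = _draw_alleles(rng, config.transition_prob)
        fate = fate_names[int(rng.choice(len(fate_names), p=fate_probs))]
        p = float(rng.uniform(*config.freq_range))
        states = _draw_hwe_states(rng, p, len(samples))
        gq = config.low_gq if fate == "low_quality" else config.normal_gq
        cap_alt = 30 if fate == "low_alt_coverage" else None
        calls = [_make_call(rng, s, st, config, gq, cap_alt=cap_alt)
                 for s, st in zip(samples, states)]
        if config.missingness > 0:
            calls = [
                GenotypeCall(c.sample_id, GenotypeState.MISSING)
                if rng.random() < config.missingness else c
                for c in calls
            ]
        novel = rng.random() < config.novel_fraction
        var = Variant("1", pos, ref, alt,
                      known_id=None if novel else f"rsB{i + 1}")
        gene = bg_genes[int(rng.integers(len(bg_genes)))]
        ann = None
        if fate != "unannotated":
            ann = VariantAnnotation(
                key=var.key, gene=gene,
                transcript_status="unconfirmed" if fate == "unconfirmed_transcript" else "confirmed",
                region=("utr3" if rng.random() < 0.5 else "utr5") if fate == "utr" else "coding",
                consequence_term="synonymous SNV" if fate == "synonymous" else "nonsynonymous SNV",
                gmaf=None if novel else round(min(p, 1 - p), 4),
                alt_pop_freq=(round(float(rng.uniform(0.6, 0.95)), 4)
                              if fate == "minor_in_reference" else round(p, 4)),
                known_id=var.known_id,
            )
        variants.append(var)
        genotypes[var.key] = calls
        if ann is not None:
            annotations[var.key] = ann
        manifest.append(ManifestEntry(
            key=var.key, gene=gene, kind="background", model=None, group=None,
            families=(), allele_freq=p,
            expected_stage=_expected_stage(calls, ann, config),
            expected_call=False,
        ))

    # --- gene sets and curated list ----------------------------------------
    extras = sorted(rng.choice(bg_genes, size=config.planted_set_extra, replace=False))
    planted_set = GeneSet("SET_PLANTED", "planted enriched set",
                          tuple(planted_genes + list(extras)))
    decoys = []
    for i in range(config.n_decoy_sets):
        genes = sorted(rng.choice(bg_genes, size=config.decoy_set_size, replace=False))
        decoys.append(GeneSet(f"SET{i + 1:04d}", f"decoy set {i + 1}", tuple(genes)))
    genesets = GeneSetCollection([planted_set] + decoys)

    curated = set(planted_genes[: max(1, n_planted // 2)])
    curated |= set(rng.choice(bg_genes, size=config.curated_background_genes,
                              replace=False).tolist())

    return Cohort(config=config, pedigree=pedigree, variants=variants,
                  genotypes=genotypes, annotations=annotations,
                  genesets=genesets, curated_genes=curated, manifest=manifest)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir) -> dict:
    """Write the cohort in the pipeline's input formats plus the manifest.

    Returns the path map. Output is deterministic for a given config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "ped": outdir / "cohort.ped",
        "annotations": outdir / "annotations.tsv",
        "gmt": outdir / "genesets.gmt",
        "curated": outdir / "curated_genes.txt",
        "manifest": outdir / "truth_manifest.tsv",
        "descriptor": outdir / "run_descriptor.json",
    }
    samples = cohort.pedigree.sample_ids()
    io_formats.write_vcf(str(paths["vcf"]), cohort.variants, cohort.genotypes, samples)
    io_formats.write_pedigree(str(paths["ped"]), cohort.pedigree)
    io_formats.write_annotations(str(paths["annotations"]), cohort.annotations)
    io_formats.write_genesets(str(paths["gmt"]), cohort.genesets)
    io_formats.write_gene_list(str(paths["curated"]), cohort.curated_genes)

    import pandas as pd

    pd.DataFrame([
        {
            "chrom": m.key[0], "pos": m.key[1], "ref": m.key[2], "alt": m.key[3],
            "gene": m.gene, "kind": m.kind, "model": m.model or "",
            "group": m.group or "", "families": ",".join(m.families),
            "allele_freq": "" if m.allele_freq is None else m.allele_freq,
            "expected_stage": m.expected_stage,
            "expected_call": str(m.expected_call),
        }
        for m in cohort.manifest
    ]).to_csv(paths["manifest"], sep="\t", index=False)

    cfg = asdict(cohort.config)
    cfg["n_planted"] = {f"{m.value}|{g.value}": n
                        for (m, g), n in cohort.config.n_planted.items()}
    with open(paths["descriptor"], "w") as fh:
        json.dump({"config": cfg, "planted_set_id": cohort.planted_set_id},
                  fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
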