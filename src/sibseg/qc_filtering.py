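"""Variant filter cascade with auditable per-stage accounting, plus
exome-style QC summaries (depth, 20X coverage, uniformity, Ti/Tv).

The cascade order is fixed: genotype-quality floor (Q20) -> unconfirmed
transcript drop -> UTR drop -> functionally-annotated checkpoint ->
alternate-allele coverage > 30 -> synonymous drop -> reference-minor drop.
Every stage records the number of variants remaining, so the trace can be
rendered like a flowchart with bracketed counts.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from statistics import mean
from typing import Optional, Sequence

from .types import GenotypeCall, GenotypeState, Variant, VariantAnnotation

STAGES = [
    "total",
    "drop_low_quality",
    "drop_unconfirmed_transcript",
    "drop_utr",
    "functionally_annotated",
    "high_confidence",
    "non_synonymous",
    "drop_minor_in_reference",
]


class ConsequenceClass(enum.Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME = "inframe"
    STOP_LOSS = "stop_loss"
    STOP_GAIN = "stop_gain"


class FrequencyClass(enum.Enum):
    COMMON = "common"
    RARE = "rare"
    NOVEL = "novel"


#: Consequence vocabulary -> class. Covers ANNOVAR-style and Sequence
#: Ontology-style tokens; extend via the `synonyms` argument.
CONSEQUENCE_SYNONYMS = {
    "synonymous SNV": ConsequenceClass.SYNONYMOUS,
    "synonymous_variant": ConsequenceClass.SYNONYMOUS,
    "synonymous": ConsequenceClass.SYNONYMOUS,
    "nonsynonymous SNV": ConsequenceClass.MISSENSE,
    "missense_variant": ConsequenceClass.MISSENSE,
    "missense": ConsequenceClass.MISSENSE,
    "nonsense": ConsequenceClass.NONSENSE,
    "nonsense_variant": ConsequenceClass.NONSENSE,
    "frameshift deletion": ConsequenceClass.FRAMESHIFT,
    "frameshift insertion": ConsequenceClass.FRAMESHIFT,
    "frameshift_variant": ConsequenceClass.FRAMESHIFT,
    "frameshift": ConsequenceClass.FRAMESHIFT,
    "nonframeshift deletion": ConsequenceClass.INFRAME,
    "nonframeshift insertion": ConsequenceClass.INFRAME,
    "inframe_deletion": ConsequenceClass.INFRAME,
    "inframe_insertion": ConsequenceClass.INFRAME,
    "inframe": ConsequenceClass.INFRAME,
    "stoploss": ConsequenceClass.STOP_LOSS,
    "stop_lost": ConsequenceClass.STOP_LOSS,
    "stop_loss": ConsequenceClass.STOP_LOSS,
    "stopgain": ConsequenceClass.STOP_GAIN,
    "stop_gained": ConsequenceClass.STOP_GAIN,
    "stop_gain": ConsequenceClass.STOP_GAIN,
}


class UnknownConsequenceError(ValueError):
    pass


def normalize_consequence(term: str, synonyms: Optional[dict] = None,
                          strict: bool = True) -> Optional[ConsequenceClass]:
    """Map a free-text consequence token to its class.

    Unknown terms raise in strict mode and return None otherwise — never
    silently synonymous.
    """
    table = CONSEQUENCE_SYNONYMS if synonyms is None else synonyms
    if term in table:
        return table[term]
    if strict:
        raise UnknownConsequenceError(f"unclassified consequence term: {term!r}")
    return None


def frequency_class(annotation: VariantAnnotation) -> FrequencyClass:
    """Partition an annotated variant into common / rare / novel.

    novel = no GMAF and no known id; rare = GMAF <= 1% (boundary inclusive);
    else common. A known variant without a GMAF is treated as rare (it is in
    a catalogue, but with no recorded population frequency).
    """
    if annotation.is_novel:
        return FrequencyClass.NOVEL
    if annotation.gmaf is None or annotation.gmaf <= 0.01:
        return FrequencyClass.RARE
    return FrequencyClass.COMMON


def high_confidence(genotypes: Sequence[GenotypeCall], threshold: int = 30,
                    carrier_agg: str = "max", on_missing: str = "keep") -> bool:
    """High-confidence test: alternate-allele coverage > threshold (strict)
    aggregated over carrier samples (max by default; min/sum configurable).

    When no carrier has an alt depth, `on_missing` decides: "keep" (fail-open)
    or "drop" (fail-closed).
    """
    depths = [g.alt_depth for g in genotypes if g.state.carries_alt and g.alt_depth is not None]
    if not depths:
        return on_missing == "keep"
    agg = {"max": max, "min": min, "sum": sum}[carrier_agg]
    return agg(depths) > threshold


def minor_in_reference(annotation: VariantAnnotation) -> bool:
    """True (exclude) when the reference allele is the population minor
    allele, i.e. the alternate allele's population frequency exceeds 0.5.
    Ties (exactly 0.5) and absent frequencies are kept."""
    return annotation.alt_pop_freq is not None and annotation.alt_pop_freq > 0.5


@dataclass
class FilterTrace:
    """Ordered (stage, variants remaining) ledger of the cascade."""

    stages: list = field(default_factory=list)  # [(stage_name, remaining)]

    def add(self, stage: str, remaining: int):
        if self.stages and remaining > self.stages[-1][1]:
            raise ValueError(
                f"filter trace must be non-increasing: {stage} has {remaining} "
                f"after {self.stages[-1]}"
            )
        self.stages.append((stage, remaining))

    def remaining(self, stage: str) -> int:
        for name, n in self.stages:
            if name == stage:
                return n
        raise KeyError(stage)

    def removed(self, stage: str) -> int:
        for i, (name, n) in enumerate(self.stages):
            if name == stage:
                return (self.stages[i - 1][1] - n) if i else 0
        raise KeyError(stage)

    def to_rows(self):
        rows = []
        prev = None
        for name, n in self.stages:
            rows.append({"stage": name, "remaining": n,
                         "removed": 0 if prev is None else prev - n})
            prev = n
        return rows

    def render(self) -> str:
        return "\n".join(f"{r['stage']} [{r['remaining']}] (-{r['removed']})"
                         for r in self.to_rows())


@dataclass
class CascadeConfig:
    gq_floor: float = 20.0           # Q20: calls below become missing
    alt_cov_threshold: int = 30      # strict > threshold
    carrier_agg: str = "max"
    missing_alt_cov: str = "keep"    # fail-open when no carrier depth
    strict_consequences: bool = True
    exclude_sex_chroms: bool = False


@dataclass
class CascadeResult:
    surviving: list                   # variant keys, input order
    trace: FilterTrace
    removed_at: dict                  # stage -> list of removed keys
    masked_genotypes: dict            # key -> list[GenotypeCall] after Q20 mask


def _mask_low_gq(calls: Sequence[GenotypeCall], floor: float):
    out = []
    for c in calls:
        if c.gq is not None and c.gq < floor and c.state != GenotypeState.MISSING:
            out.append(GenotypeCall(c.sample_id, GenotypeState.MISSING,
                                    depth=c.depth, alt_depth=c.alt_depth, gq=c.gq))
        else:
            out.append(c)
    return out


def run_filter_cascade(variants: Sequence[Variant], genotypes: dict,
                       annotations: dict, config: Optional[CascadeConfig] = None
                       ) -> CascadeResult:
    """Run the full filter cascade, returning survivors and the stage trace.

    Q20 masks low-quality calls to missing; a variant with no carrier call
    left is dropped there. Variants lacking any annotation are counted and
    dropped at the functionally_annotated checkpoint. Empty input yields a
    trace of zeros.
    """
    config = config or CascadeConfig()
    trace = FilterTrace()
    removed_at: dict = {}
    by_key = {v.key: v for v in variants}
    current = [v.key for v in variants]
    if config.exclude_sex_chroms:
        sex = {"X", "Y", "chrX", "chrY"}
        dropped = [k for k in current if k[0] in sex]
        current = [k for k in current if k[0] not in sex]
        removed_at["sex_chromosomes"] = dropped
    trace.add("total", len(current))

    masked = {k: _mask_low_gq(genotypes[k], config.gq_floor) for k in current}

    def stage(name, keep_fn):
        nonlocal current
        kept, dropped = [], []
        for k in current:
            (kept if keep_fn(k) else dropped).append(k)
        removed_at[name] = dropped
        current = kept
        trace.add(name, len(current))

    stage("drop_low_quality",
          lambda k: any(c.state.carries_alt for c in masked[k]))
    stage("drop_unconfirmed_transcript",
          lambda k: k not in annotations or annotations[k].transcript_status == "confirmed")
    stage("drop_utr",
          lambda k: k not in annotations or annotations[k].region == "coding")
    stage("functionally_annotated", lambda k: k in annotations)
    stage("high_confidence",
          lambda k: high_confidence(masked[k], config.alt_cov_threshold,
                                    config.carrier_agg, config.missing_alt_cov))
    stage("non_synonymous",
          lambda k: normalize_consequence(annotations[k].consequence_term,
                                          strict=config.strict_consequences)
          != ConsequenceClass.SYNONYMOUS)
    stage("drop_minor_in_reference",
          lambda k: not minor_in_reference(annotations[k]))
    return CascadeResult(surviving=current, trace=trace, removed_at=removed_at,
                         masked_genotypes={k: masked[k] for k in by_key if k in masked})


# ---------------------------------------------------------------------------
# QC summaries
# ---------------------------------------------------------------------------

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def titv_ratio(variants: Sequence[Variant]) -> Optional[float]:
    """Transition/transversion ratio over SNVs (indels ignored).

    Transitions are A<->G and C<->T. Returns None (undefined) when there are
    no transversions.
    """
    ti = tv = 0
    for v in variants:
        if not v.is_snv:
            continue
        if (v.ref.upper(), v.alt.upper()) in _TRANSITIONS:
            ti += 1
        else:
            tv += 1
    if tv == 0:
        return None
    return ti / tv


@dataclass
class QCReport:
    """Cohort QC summary. uniformity is declared as the fraction of targets
    with depth >= 0.2 x the sample's mean depth."""

    mean_depth: Optional[dict] = None        # sample -> mean depth
    frac_ge_20x: Optional[dict] = None       # sample -> fraction of targets >= 20X
    uniformity: Optional[dict] = None        # sample -> fraction >= 0.2 * mean
    titv: Optional[float] = None

    UNIFORMITY_DEFINITION = "fraction of targets with depth >= 0.2 x mean sample depth"


def qc_report(genotypes: dict, variants: Optional[Sequence[Variant]] = None) -> QCReport:
    """Per-sample depth summaries over all genotyped sites plus cohort Ti/Tv.

    Sites with absent DP are skipped; a cohort with no depth data yields a
    report with absent fields.
    """
    depths: dict = {}
    for calls in genotypes.values():
        for c in calls:
            if c.depth is not None:
                depths.setdefault(c.sample_id, []).append(c.depth)
    report = QCReport()
    if depths:
        report.mean_depth = {s: mean(d) for s, d in sorted(depths.items())}
        report.frac_ge_20x = {
            s: sum(1 for x in d if x >= 20) / len(d) for s, d in sorted(depths.items())
        }
        report.uniformity = {
            s: sum(1 for x in d if x >= 0.2 * report.mean_depth[s]) / len(d)
            for s, d in sorted(depths.items())
        }
    if variants is not None:
        report.titv = titv_ratio(variants)
    return report
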