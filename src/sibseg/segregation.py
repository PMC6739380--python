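"""Cross-family segregation calling under recessive and dominant models.

A variant segregates with a phenotype group (affected or non-affected) when
the model holds in at least k of the N unrelated families (k=3 of N=4 by
default). The recessive model requires shared homozygosity for the alternate
allele in every same-group member of a family; the dominant model requires
shared carriage (>=1 alternate allele). A missing genotype in a group member
makes the family fail the model (conservative).

Model precedence is recessive-first: a variant whose confirming (carrier)
families are all homozygous-alternate is reported under the recessive model
only; any confirmed variant with at least one heterozygous confirming family
is reported as dominant. A (variant, group) pair therefore never appears
under both models.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .io_formats import GenotypeTableRow, parse_genotype_table
from .types import (
    GenotypeState,
    GroupSummaryRow,
    Model,
    Pedigree,
    Phenotype,
    SegregationCall,
)


@dataclass
class SegregationConfig:
    min_families: int = 3                 # k
    total_families: Optional[int] = None  # N; defaults to the pedigree's family count
    exclusivity_mode: str = "same_model"  # none | same_model | any_model
    member_rule: str = "all"              # model must hold in all|any same-group members

    def resolve_total(self, pedigree: Pedigree) -> int:
        n = self.total_families if self.total_families is not None else pedigree.n_families
        if not (1 <= self.min_families <= n):
            raise ValueError(f"need 1 <= k ({self.min_families}) <= N ({n})")
        return n


def _state_satisfies(state: GenotypeState, model: Model) -> bool:
    if model == Model.RECESSIVE:
        return state == GenotypeState.HOM_ALT
    return state.carries_alt


def family_satisfies(key, family_id: str, group: Phenotype, model: Model,
                     pedigree: Pedigree, states: dict,
                     member_rule: str = "all") -> bool:
    """Does `model` hold for this variant in the family's `group` members?

    `states` maps sample id -> GenotypeState for this variant. Missing
    genotypes fail. Under the default "all" rule every same-group member of
    the family must satisfy the model (strictest reading of "shared");
    "any" accepts a single satisfying member.
    """
    members = pedigree.group_members(family_id, group)
    if not members:
        return False
    oks = [_state_satisfies(states.get(m.individual_id, GenotypeState.MISSING), model)
           for m in members]
    return all(oks) if member_rule == "all" else any(oks)


def satisfying_families(key, group: Phenotype, model: Model, pedigree: Pedigree,
                        states: dict, member_rule: str = "all") -> frozenset:
    return frozenset(
        fam for fam in pedigree.family_ids()
        if family_satisfies(key, fam, group, model, pedigree, states, member_rule)
    )


def confirm_across_families(key, gene: str, group: Phenotype, model: Model,
                            pedigree: Pedigree, states: dict,
                            config: SegregationConfig) -> Optional[SegregationCall]:
    """Emit a call for a single model iff it holds in >= k families."""
    config.resolve_total(pedigree)
    fams = satisfying_families(key, group, model, pedigree, states, config.member_rule)
    if len(fams) < config.min_families:
        return None
    return SegregationCall(key=key, gene=gene, model=model, group=group,
                           confirming_families=fams)


def assign_model(recessive_families: frozenset, dominant_families: frozenset,
                 k: int) -> Optional[Model]:
    """Recessive-first precedence over the carrier (dominant-sense) families.

    The confirming families of a variant are its carrier families. The call
    is recessive when all of them are homozygous-alternate (and there are at
    least k); if any confirming family carries a heterozygote the call is
    dominant. Below k carrier families there is no call.
    """
    if len(dominant_families) < k:
        return None
    if dominant_families == recessive_families:
        return Model.RECESSIVE
    return Model.DOMINANT


def exclusivity(key, model: Model, group: Phenotype, pedigree: Pedigree,
                states: dict, config: SegregationConfig) -> bool:
    """Is the call exclusive to its phenotype group?

    same_model: the opposite group could not itself be confirmed under the
    call's model (it fails in >= N-k+1 families). any_model: the opposite
    group fails both models. none: always True.
    """
    if config.exclusivity_mode == "none":
        return True
    opposite = (Phenotype.NON_AFFECTED if group == Phenotype.AFFECTED
                else Phenotype.AFFECTED)
    k = config.min_families

    def confirmable(m: Model) -> bool:
        fams = satisfying_families(key, opposite, m, pedigree, states, config.member_rule)
        return len(fams) >= k

    if config.exclusivity_mode == "same_model":
        return not confirmable(model)
    if config.exclusivity_mode == "any_model":
        return not (confirmable(Model.RECESSIVE) or confirmable(Model.DOMINANT))
    raise ValueError(f"unknown exclusivity mode {config.exclusivity_mode!r}")


def call_variants(variant_keys: Sequence, states_by_key: dict, genes: dict,
                  pedigree: Pedigree, config: Optional[SegregationConfig] = None
                  ) -> list[SegregationCall]:
    """Call segregating variants for both groups with recessive-first
    precedence and the configured exclusivity mode.

    `states_by_key` maps variant key -> {sample id -> GenotypeState};
    `genes` maps variant key -> gene symbol.
    """
    config = config or SegregationConfig()
    config.resolve_total(pedigree)
    k = config.min_families
    calls = []
    for key in variant_keys:
        states = states_by_key[key]
        for group in (Phenotype.AFFECTED, Phenotype.NON_AFFECTED):
            rec = satisfying_families(key, group, Model.RECESSIVE, pedigree,
                                      states, config.member_rule)
            dom = satisfying_families(key, group, Model.DOMINANT, pedigree,
                                      states, config.member_rule)
            model = assign_model(rec, dom, k)
            if model is None:
                continue
            fams = rec if model == Model.RECESSIVE else dom
            calls.append(SegregationCall(
                key=key, gene=genes.get(key, ""), model=model, group=group,
                confirming_families=fams,
                exclusive=exclusivity(key, model, group, pedigree, states, config),
            ))
    return calls


# ---------------------------------------------------------------------------
# Worked-example genotype tables (one subject column per family)
# ---------------------------------------------------------------------------

def classify_genotype_table(rows: Sequence[GenotypeTableRow], subjects: Sequence[str],
                            group: Phenotype, k: int = 3,
                            rescue_subthreshold: bool = True) -> list[SegregationCall]:
    """Classify a published-style genotype table into model blocks.

    Each subject column stands for one family's group representative; a blank
    cell is a missing genotype and does not confirm. Rows whose carrier
    columns number >= k are called (recessive when every carrier column is
    homozygous-alternate, dominant otherwise). With `rescue_subthreshold`, a
    row below k whose gene already has a confirmed call in the table is kept
    under its own genotype pattern and flagged `subthreshold` — gene-level
    confirmation, as used by gene-centric prioritization tools.
    """
    variants, matrix, _wild = parse_genotype_table(rows, subjects)
    calls: list[SegregationCall] = []
    pending = []
    confirmed_genes = set()
    for var, row in zip(variants, rows):
        states = matrix[var.key]
        rec = frozenset(s for s in subjects if states[s] == GenotypeState.HOM_ALT)
        dom = frozenset(s for s in subjects if states[s].carries_alt)
        model = assign_model(rec, dom, k)
        if model is not None:
            fams = rec if model == Model.RECESSIVE else dom
            calls.append(SegregationCall(var.key, row.gene, model, group, fams))
            confirmed_genes.add(row.gene)
        else:
            pending.append((var, row, rec, dom))
    if rescue_subthreshold:
        for var, row, rec, dom in pending:
            if not dom or row.gene not in confirmed_genes:
                continue
            model = Model.RECESSIVE if rec == dom else Model.DOMINANT
            fams = rec if model == Model.RECESSIVE else dom
            calls.append(SegregationCall(var.key, row.gene, model, group, fams,
                                         subthreshold=True))
    calls.sort(key=lambda c: c.key[1])  # table row order
    return calls


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(x + 0.5)


def summarize(calls: Sequence[SegregationCall], curated_genes,
              ) -> list[GroupSummaryRow]:
    """Per (group, model) gene/variant counts and curated-list (immune)
    percentage, rounded to the nearest integer. Gene symbols are compared
    case-sensitively. Empty call sets yield no rows."""
    curated = set(curated_genes)
    order = [(g, m) for g in (Phenotype.AFFECTED, Phenotype.NON_AFFECTED)
             for m in (Model.RECESSIVE, Model.DOMINANT)]
    rows = []
    for group, model in order:
        block = [c for c in calls if c.group == group and c.model == model]
        if not block:
            continue
        genes = {c.gene for c in block}
        immune = genes & curated
        rows.append(GroupSummaryRow(
            group=group, model=model, n_genes=len(genes), n_variants=len(block),
            n_immune_genes=len(immune),
            immune_pct=_round_half_up(100.0 * len(immune) / len(genes)),
        ))
    return rows


def calls_to_records(calls: Sequence[SegregationCall]) -> list[dict]:
    """Flatten calls for TSV export, shaped like the published tables."""
    recs = []
    for c in calls:
        recs.append({
            "gene": c.gene,
            "chrom": c.key[0], "pos": c.key[1], "ref": c.key[2], "alt": c.key[3],
            "model": c.model.value, "group": c.group.value,
            "confirming_families": ",".join(sorted(map(str, c.confirming_families))),
            "n_confirming": len(c.confirming_families),
            "exclusive": "" if c.exclusive is None else str(c.exclusive),
            "subthreshold": str(c.subthreshold),
        })
    return recs
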