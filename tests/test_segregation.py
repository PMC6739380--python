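import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sibseg import studydata
from sibseg.segregation import (
    SegregationConfig,
    assign_model,
    call_variants,
    classify_genotype_table,
    confirm_across_families,
    exclusivity,
    family_satisfies,
    summarize,
)
from sibseg.types import (
    GenotypeState,
    Model,
    Pedigree,
    PedigreeIndividual,
    Phenotype,
)

HOM_REF, HET, HOM_ALT, MISS = (GenotypeState.HOM_REF, GenotypeState.HET,
                               GenotypeState.HOM_ALT, GenotypeState.MISSING)


def make_pedigree(n_families=4, affected=1, non_affected=1, extra_non_in_f1=0):
    inds = []
    for i in range(1, n_families + 1):
        for a in range(affected):
            inds.append(PedigreeIndividual(f"F{i}_A{a+1}", f"F{i}", "U", Phenotype.AFFECTED))
        n_non = non_affected + (extra_non_in_f1 if i == 1 else 0)
        for n in range(n_non):
            inds.append(PedigreeIndividual(f"F{i}_N{n+1}", f"F{i}", "U", Phenotype.NON_AFFECTED))
    return Pedigree(inds)


PED = make_pedigree()
KEY = ("1", 1, "A", "G")


def states_for(affected=(), non_affected=(), pedigree=PED):
    """Build a sample->state map; tuples are per-family states."""
    out = {}
    for i, s in enumerate(affected, start=1):
        out[f"F{i}_A1"] = s
    for i, s in enumerate(non_affected, start=1):
        out[f"F{i}_N1"] = s
    return out


# --------------------------------------------------------------------------
# Independent brute-force enumerator used as the oracle
# --------------------------------------------------------------------------

def brute_force_calls(states, pedigree, k, exclusivity_mode="same_model"):
    """Plain re-derivation of the calling semantics: for each group compute
    the per-family homozygous and carrier bitmaps explicitly, then apply
    recessive-first precedence and opposite-group confirmability."""
    out = []
    groups = {Phenotype.AFFECTED: {}, Phenotype.NON_AFFECTED: {}}
    for group in groups:
        hom_fams, carrier_fams = set(), set()
        for fam in pedigree.family_ids():
            members = [m.individual_id for m in pedigree.group_members(fam, group)]
            sts = [states.get(m, MISS) for m in members]
            if members and all(s == HOM_ALT for s in sts):
                hom_fams.add(fam)
            if members and all(s in (HET, HOM_ALT) for s in sts):
                carrier_fams.add(fam)
        groups[group] = {"hom": hom_fams, "carrier": carrier_fams}
    for group, maps in groups.items():
        if len(maps["carrier"]) < k:
            continue
        model = Model.RECESSIVE if maps["carrier"] == maps["hom"] else Model.DOMINANT
        fams = maps["hom"] if model == Model.RECESSIVE else maps["carrier"]
        other = (Phenotype.NON_AFFECTED if group == Phenotype.AFFECTED
                 else Phenotype.AFFECTED)
        other_maps = groups[other]
        if exclusivity_mode == "none":
            excl = True
        elif exclusivity_mode == "same_model":
            other_sat = (other_maps["hom"] if model == Model.RECESSIVE
                         else other_maps["carrier"])
            excl = len(other_sat) < k
        else:  # any_model
            excl = len(other_maps["hom"]) < k and len(other_maps["carrier"]) < k
        out.append((group, model, frozenset(fams), excl))
    return sorted(out, key=lambda t: (t[0].value, t[1].value))


def random_states(rng, pedigree, p_miss=0.05):
    choices = [HOM_REF, HET, HOM_ALT]
    out = {}
    for ind in pedigree.individuals():
        if rng.random() < p_miss:
            out[ind.individual_id] = MISS
        else:
            out[ind.individual_id] = choices[rng.integers(3)]
    return out


class TestFamilySatisfies:
    def test_hom_alt_satisfies_both_models(self):
        states = states_for(affected=(HOM_ALT,))
        assert family_satisfies(KEY, "F1", Phenotype.AFFECTED, Model.RECESSIVE, PED, states)
        assert family_satisfies(KEY, "F1", Phenotype.AFFECTED, Model.DOMINANT, PED, states)

    def test_het_satisfies_dominant_only(self):
        states = states_for(affected=(HET,))
        assert not family_satisfies(KEY, "F1", Phenotype.AFFECTED, Model.RECESSIVE, PED, states)
        assert family_satisfies(KEY, "F1", Phenotype.AFFECTED, Model.DOMINANT, PED, states)

    def test_hom_ref_satisfies_neither(self):
        states = states_for(affected=(HOM_REF,))
        for model in Model:
            assert not family_satisfies(KEY, "F1", Phenotype.AFFECTED, model, PED, states)

    def test_missing_genotype_is_conservative(self):
        states = states_for(affected=(MISS,))
        for model in Model:
            assert not family_satisfies(KEY, "F1", Phenotype.AFFECTED, model, PED, states)

    def test_all_vs_any_member_rule(self):
        ped = make_pedigree(extra_non_in_f1=1)
        states = {"F1_N1": HOM_ALT, "F1_N2": HET}
        assert not family_satisfies(KEY, "F1", Phenotype.NON_AFFECTED,
                                    Model.RECESSIVE, ped, states, member_rule="all")
        assert family_satisfies(KEY, "F1", Phenotype.NON_AFFECTED,
                                Model.RECESSIVE, ped, states, member_rule="any")

    def test_absent_family_is_an_error(self):
        with pytest.raises(KeyError):
            family_satisfies(KEY, "F9", Phenotype.AFFECTED, Model.DOMINANT, PED, {})

    @settings(max_examples=200, deadline=None)
    @given(st.sampled_from([HOM_REF, HET, HOM_ALT, MISS]),
           st.sampled_from([HOM_REF, HET, HOM_ALT, MISS]))
    def test_recessive_implies_dominant(self, s1, s2):
        """Shared homozygosity implies shared carriage for every input."""
        ped = make_pedigree(extra_non_in_f1=1)
        states = {"F1_N1": s1, "F1_N2": s2}
        if family_satisfies(KEY, "F1", Phenotype.NON_AFFECTED, Model.RECESSIVE, ped, states):
            assert family_satisfies(KEY, "F1", Phenotype.NON_AFFECTED, Model.DOMINANT, ped, states)


class TestConfirmAcrossFamilies:
    def test_three_of_four_recessive(self):
        states = states_for(non_affected=(HOM_ALT, HOM_ALT, HOM_ALT, HOM_REF))
        call = confirm_across_families(KEY, "CD5", Phenotype.NON_AFFECTED,
                                       Model.RECESSIVE, PED, states, SegregationConfig())
        assert call is not None
        assert call.confirming_families == frozenset({"F1", "F2", "F3"})

    def test_two_families_is_no_call(self):
        states = states_for(affected=(HOM_ALT, HOM_ALT, HOM_REF, HOM_REF))
        assert confirm_across_families(KEY, "G", Phenotype.AFFECTED, Model.RECESSIVE,
                                       PED, states, SegregationConfig()) is None

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            confirm_across_families(KEY, "G", Phenotype.AFFECTED, Model.RECESSIVE,
                                    PED, {}, SegregationConfig(min_families=5))


class TestAssignModel:
    def test_all_hom_alt_is_recessive_only(self):
        fams = frozenset({"F1", "F2", "F3"})
        assert assign_model(fams, fams, k=3) is Model.RECESSIVE

    def test_any_het_confirming_family_makes_dominant(self):
        rec = frozenset({"F1", "F2"})
        dom = frozenset({"F1", "F2", "F3"})
        assert assign_model(rec, dom, k=3) is Model.DOMINANT

    def test_all_het_is_dominant(self):
        dom = frozenset({"F1", "F2", "F3"})
        assert assign_model(frozenset(), dom, k=3) is Model.DOMINANT

    def test_below_k_is_no_call(self):
        assert assign_model(frozenset(), frozenset({"F1", "F2"}), k=3) is None


class TestExclusivityAndCalls:
    def test_planted_variant_exclusive_under_all_modes(self):
        states = states_for(affected=(HOM_ALT,) * 4,
                            non_affected=(HOM_REF,) * 4)
        for mode in ("none", "same_model", "any_model"):
            cfg = SegregationConfig(exclusivity_mode=mode)
            assert exclusivity(KEY, Model.RECESSIVE, Phenotype.AFFECTED, PED, states, cfg)

    def test_confirmed_in_both_groups_not_exclusive(self):
        states = states_for(affected=(HET,) * 4, non_affected=(HET,) * 4)
        cfg = SegregationConfig(exclusivity_mode="same_model")
        assert not exclusivity(KEY, Model.DOMINANT, Phenotype.AFFECTED, PED, states, cfg)

    @pytest.mark.parametrize("mode", ["none", "same_model", "any_model"])
    def test_randomized_matrices_match_brute_force(self, mode):
        rng = np.random.default_rng(5)
        ped = make_pedigree(extra_non_in_f1=1)
        cfg = SegregationConfig(exclusivity_mode=mode)
        for trial in range(300):
            states = random_states(rng, ped)
            calls = call_variants([KEY], {KEY: states}, {KEY: "G"}, ped, cfg)
            got = sorted(((c.group, c.model, c.confirming_families, c.exclusive)
                          for c in calls), key=lambda t: (t[0].value, t[1].value))
            assert got == brute_force_calls(states, ped, 3, mode), f"trial {trial}"

    def test_k_monotonicity(self):
        """The call set at k+1 is a subset of the call set at k."""
        rng = np.random.default_rng(9)
        ped = make_pedigree()
        for _ in range(200):
            states = random_states(rng, ped, p_miss=0.1)
            by_k = {}
            for k in (2, 3, 4):
                cfg = SegregationConfig(min_families=k, exclusivity_mode="none")
                calls = call_variants([KEY], {KEY: states}, {KEY: "G"}, ped, cfg)
                by_k[k] = {(c.group, c.model) for c in calls}
            assert by_k[4] <= by_k[3] <= by_k[2]

    def test_disjoint_model_blocks(self):
        rng = np.random.default_rng(13)
        ped = make_pedigree()
        for _ in range(200):
            states = random_states(rng, ped)
            calls = call_variants([KEY], {KEY: states}, {KEY: "G"}, ped,
                                  SegregationConfig(exclusivity_mode="none"))
            pairs = [(c.key, c.group) for c in calls]
            assert len(pairs) == len(set(pairs))


@pytest.fixture(scope="module")
def worked_example_calls():
    aff = classify_genotype_table(studydata.AFFECTED_TABLE,
                                  studydata.TABLE_SUBJECTS, Phenotype.AFFECTED)
    non = classify_genotype_table(studydata.NON_AFFECTED_TABLE,
                                  studydata.TABLE_SUBJECTS, Phenotype.NON_AFFECTED)
    return list(aff) + list(non)


class TestWorkedExampleTables:
    @pytest.fixture
    def calls(self, worked_example_calls):
        return worked_example_calls

    def test_akna_recessive_prdm16_dominant(self, calls):
        akna = [c for c in calls if c.gene == "AKNA"]
        assert len(akna) == 1 and akna[0].model is Model.RECESSIVE
        prdm16 = [c for c in calls if c.gene == "PRDM16"]
        assert len(prdm16) == 1 and prdm16[0].model is Model.DOMINANT

    def test_cd5_recessive_three_families(self, calls):
        cd5 = [c for c in calls if c.gene == "CD5"]
        assert len(cd5) == 1
        assert cd5[0].model is Model.RECESSIVE
        assert len(cd5[0].confirming_families) == 3

    def test_subthreshold_gene_rescue_is_flagged(self):
        """The two-cell HJURP row is kept only by gene-level rescue and
        carries the subthreshold flag; strict mode drops it."""
        rescued = classify_genotype_table(studydata.AFFECTED_TABLE,
                                          studydata.TABLE_SUBJECTS, Phenotype.AFFECTED)
        flagged = [c for c in rescued if c.subthreshold]
        assert len(flagged) == 1 and flagged[0].gene == "HJURP"
        assert flagged[0].model is Model.RECESSIVE
        strict = classify_genotype_table(studydata.AFFECTED_TABLE,
                                         studydata.TABLE_SUBJECTS, Phenotype.AFFECTED,
                                         rescue_subthreshold=False)
        assert len(strict) == len(rescued) - 1

    def test_hla_c_rows_fall_in_separate_blocks(self, calls):
        """The same SNP id appears as a homozygous row (recessive) and a
        carrier row with one heterozygote (dominant) in the non-affected
        tables; each row keeps its own block."""
        rows = [c for c in calls if c.gene == "HLA-C"]
        assert sorted(c.model.value for c in rows) == ["dominant", "recessive"]

    def test_model_blocks_match_table_layout(self, calls):
        aff = [c for c in calls if c.group is Phenotype.AFFECTED]
        rec = [c for c in aff if c.model is Model.RECESSIVE]
        dom = [c for c in aff if c.model is Model.DOMINANT]
        assert len(rec) == len(studydata.AFFECTED_RECESSIVE_ROWS)
        assert len(dom) == len(studydata.AFFECTED_DOMINANT_ROWS)
        rec_genes = {r.gene for r in studydata.AFFECTED_RECESSIVE_ROWS}
        assert {c.gene for c in rec} == rec_genes


class TestSummarize:
    def test_one_gene_two_variants(self):
        calls = [
            # two variants in the same gene, one model block
            _call(("1", 1, "A", "G"), "G1"),
            _call(("1", 2, "A", "G"), "G1"),
        ]
        (row,) = summarize(calls, set())
        assert row.n_genes == 1 and row.n_variants == 2 and row.immune_pct == 0

    def test_immune_percentage_rounding(self):
        calls = [_call(("1", i, "A", "G"), f"G{i}") for i in range(1, 8)]
        rows = summarize(calls, {"G1", "G2"})
        assert rows[0].immune_pct == 29  # 2/7 = 28.57 -> 29

    def test_empty_calls_yield_no_rows(self):
        assert summarize([], {"G1"}) == []


def _call(key, gene, model=Model.RECESSIVE, group=Phenotype.AFFECTED):
    from sibseg.types import SegregationCall
    return SegregationCall(key=key, gene=gene, model=model, group=group,
                           confirming_families=frozenset({"F1", "F2", "F3"}))
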