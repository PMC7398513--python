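import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fawmarkers._iupac import reverse_complement
from fawmarkers.marker_typing import (
    CoiValue,
    HaplotypeRegistry,
    IntronCall,
    IntronStatus,
    NotHomologousError,
    TpiValue,
    anchor_align,
    assign_haplotype_ids,
    call_coib,
    call_tpie4,
    call_tpii4,
    project_to_reference,
    resolve_ambiguities,
)
from fawmarkers.references import COIB_REFERENCE, COIB_SEQ, TPI_REFERENCE, TPI_SEQ

from oracles import needleman_wunsch_identity

INTRON = TPI_SEQ[240:412]


def coib_with(b1164: str, b1287: str) -> str:
    s = list(COIB_SEQ)
    s[240], s[363] = b1164, b1287
    return "".join(s)


def tpie4_with(b183: str) -> str:
    s = list(TPI_SEQ[:240])
    s[182] = b183
    return "".join(s)


def tpii4_query(intron: str) -> str:
    return TPI_SEQ[150:240] + intron + TPI_SEQ[412:452]


class TestAnchorAlign:
    def test_exact_copy_identity_mapping(self):
        aln = anchor_align(COIB_SEQ, COIB_REFERENCE)
        assert aln.identity == 1.0
        assert aln.ref_to_query == tuple(range(len(COIB_SEQ)))

    def test_internal_deletion_maps_remaining_sites(self):
        q = COIB_SEQ[:100] + COIB_SEQ[103:]
        aln = anchor_align(q, COIB_REFERENCE)
        # three reference positions unmapped, the rest maps in order
        gaps = [i for i, v in enumerate(aln.ref_to_query) if v is None]
        assert len(gaps) == 3
        assert aln.ref_to_query[240] is not None
        assert aln.query_base(240) == COIB_SEQ[240]
        assert aln.query_base(363) == COIB_SEQ[363]

    def test_reversed_reference_not_homologous(self):
        # oracle: plain global alignment of the reversed sequence has
        # identity far below the 70% threshold
        rev = COIB_SEQ[::-1]
        assert needleman_wunsch_identity(COIB_SEQ[:80], rev[:80]) < 0.6
        with pytest.raises(NotHomologousError):
            anchor_align(rev, COIB_REFERENCE)

    def test_reverse_complement_retried(self):
        aln = anchor_align(reverse_complement(COIB_SEQ), COIB_REFERENCE)
        assert aln.reverse_complemented
        assert aln.identity == 1.0

    def test_short_query_rejected(self):
        with pytest.raises(NotHomologousError, match="too short"):
            anchor_align("ACGT" * 10, COIB_REFERENCE)

    def test_deterministic(self):
        q = COIB_SEQ[5:370]
        a1 = anchor_align(q, COIB_REFERENCE)
        a2 = anchor_align(q, COIB_REFERENCE)
        assert a1 == a2


class TestCallCoib:
    def test_rs_configuration(self):
        call = call_coib(coib_with("T", "A"))
        assert call.value is CoiValue.COI_RS
        assert (call.base1164, call.base1287) == ("T", "A")

    def test_h2_configuration(self):
        assert call_coib(coib_with("A", "G")).value is CoiValue.COI_H2

    def test_outside_allowed_set_undetermined(self):
        assert call_coib(coib_with("C", "A")).value is CoiValue.UNDETERMINED

    def test_truth_table_exhaustive(self):
        """Classifier agrees with the invariant table over {A,C,G,T,N,R,Y}^2."""
        expected = {
            ("T", "A"): CoiValue.COI_RS,
            ("A", "A"): CoiValue.COI_H1,
            ("A", "G"): CoiValue.COI_H2,
            ("G", "A"): CoiValue.COI_H3,
            ("G", "G"): CoiValue.COI_H4,
        }
        for b1, b2 in itertools.product("ACGTNRY", repeat=2):
            call = call_coib(coib_with(b1, b2))
            assert call.value is expected.get((b1, b2), CoiValue.UNDETERMINED), (b1, b2)
            assert (call.base1164, call.base1287) == (b1, b2)

    def test_site_in_query_gap_undetermined(self):
        q = COIB_SEQ[:230] + COIB_SEQ[250:]  # deletion spanning site 240
        assert call_coib(q).value is CoiValue.UNDETERMINED


@given(
    left=st.integers(0, 50), right=st.integers(0, 50),
    seed=st.integers(0, 2**31), b1=st.sampled_from("ATGC"), b2=st.sampled_from("AG"),
)
@settings(max_examples=25, deadline=None)
def test_flanking_padding_never_changes_call(left, right, seed, b1, b2):
    rng = np.random.default_rng(seed)
    base = coib_with(b1, b2)
    padded = ("".join(rng.choice(list("ACGT"), left)) + base
              + "".join(rng.choice(list("ACGT"), right)))
    assert call_coib(padded) == call_coib(base)


class TestCallTpie4:
    @pytest.mark.parametrize(
        "base,value",
        [("C", TpiValue.TPI_C), ("T", TpiValue.TPI_R), ("Y", TpiValue.TPI_H),
         ("G", TpiValue.UNDETERMINED), ("R", TpiValue.UNDETERMINED)],
    )
    def test_site_mapping(self, base, value):
        call = call_tpie4(tpie4_with(base))
        assert call.value is value
        assert call.base183 == base


class TestCallTpii4:
    def test_clean_intron_haplotype(self):
        call = call_tpii4(tpii4_query(INTRON))
        assert call.status is IntronStatus.HAPLOTYPE
        assert call.haplotype_seq == INTRON

    def test_ambiguity_run_excluded(self):
        intron = INTRON[:60] + "N" * 20 + INTRON[80:]
        assert call_tpii4(tpii4_query(intron)).status is IntronStatus.HET_INDEL_EXCLUDED

    def test_run_at_threshold_excluded_below_kept(self):
        at_k = INTRON[:60] + "RYRYR" + INTRON[65:]
        below = INTRON[:60] + "RYRY" + INTRON[64:]
        assert call_tpii4(tpii4_query(at_k)).status is IntronStatus.HET_INDEL_EXCLUDED
        assert call_tpii4(tpii4_query(below)).status is IntronStatus.HAPLOTYPE

    def test_isolated_ambiguity_resolved(self):
        # oracle: direct scan confirms no run of >= 5 ambiguity codes
        intron = INTRON[:100] + "R" + INTRON[101:]
        runs = max(len(r) for r in
                   __import__("re").findall(r"[RYSWKMBDHVN]+", intron))
        assert runs < 5
        call = call_tpii4(tpii4_query(intron))
        assert call.status is IntronStatus.HAPLOTYPE
        # R -> {A,G}, lexicographically smallest compatible base is A
        assert call.haplotype_seq == INTRON[:100] + "A" + INTRON[101:]

    def test_intron_with_deletion_recovered_exactly(self):
        intron = INTRON[:60] + INTRON[66:]
        call = call_tpii4(tpii4_query(intron))
        assert call.status is IntronStatus.HAPLOTYPE
        assert call.haplotype_seq == intron

    def test_intron_with_insertion_recovered_exactly(self):
        intron = INTRON[:90] + "ACGTA" + INTRON[90:]
        call = call_tpii4(tpii4_query(intron))
        assert call.status is IntronStatus.HAPLOTYPE
        assert call.haplotype_seq == intron

    def test_truncated_window_undetermined(self):
        # query covering only 30 bases of the intron
        q = TPI_SEQ[100:270]
        assert call_tpii4(q).status is IntronStatus.UNDETERMINED


@given(seed=st.integers(0, 2**31), pos=st.integers(10, 120),
       run_len=st.integers(5, 40))
@settings(max_examples=25, deadline=None)
def test_exclusion_monotonicity(seed, pos, run_len):
    """Injecting a frameshift-style ambiguity run always flips
    HAPLOTYPE -> HET_INDEL_EXCLUDED."""
    rng = np.random.default_rng(seed)
    clean = call_tpii4(tpii4_query(INTRON))
    assert clean.status is IntronStatus.HAPLOTYPE
    run = "".join(rng.choice(list("RYSWKMN"), run_len))
    dirty = INTRON[:pos] + run + INTRON[pos + run_len:]
    assert call_tpii4(tpii4_query(dirty)).status is IntronStatus.HET_INDEL_EXCLUDED


class TestResolveAmbiguities:
    def test_lexicographically_smallest(self):
        assert resolve_ambiguities("ARYT") == "AACT"
        assert resolve_ambiguities("ACGT") == "ACGT"
        assert resolve_ambiguities("N") == "A"


class TestAssignHaplotypeIds:
    def make(self, seq):
        return IntronCall(IntronStatus.HAPLOTYPE, haplotype_seq=seq)

    def test_identical_sequences_share_id(self):
        calls, reg = assign_haplotype_ids([self.make("AAA"), self.make("CCC"),
                                           self.make("AAA")])
        assert calls[0].haplotype_id == calls[2].haplotype_id == "Hap01"
        assert calls[1].haplotype_id == "Hap02"
        assert len(reg) == 2

    def test_empty_input(self):
        calls, reg = assign_haplotype_ids([])
        assert calls == [] and len(reg) == 0

    def test_seeded_registry_idempotent(self):
        seed = {"AAA": "Ecu03", "CCC": "Ecu07"}
        batch = [self.make("CCC"), self.make("AAA"), self.make("GGG")]
        calls1, reg1 = assign_haplotype_ids(batch, HaplotypeRegistry(seed))
        calls2, _ = assign_haplotype_ids(batch, HaplotypeRegistry(seed))
        assert [c.haplotype_id for c in calls1] == ["Ecu07", "Ecu03", "Hap08"]
        assert [c.haplotype_id for c in calls1] == [c.haplotype_id for c in calls2]


class TestProjectToReference:
    def test_exact_intron_projects_identically(self):
        assert project_to_reference(INTRON) == INTRON

    def test_deletion_becomes_gap_columns(self):
        intron = INTRON[:60] + INTRON[66:]
        proj = project_to_reference(tpii4_query(intron))
        assert len(proj) == len(INTRON)
        assert proj.count("-") == 6
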