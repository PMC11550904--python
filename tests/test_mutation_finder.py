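import pytest

from macall.genotype_caller import GenotypeCall
from macall.mutation_finder import (
    ANC_NOT_HOMREF,
    ANC_TIE,
    FILTERED,
    LOW_DEPTH,
    MISSING_CALL,
    OK,
    CandidateMutation,
    assess_callability,
    identify_mutations,
    infer_ancestral,
)
from macall.pipeline import RunConfig, run_time_point
from macall.site_filters import FilterVerdict


def call(line, genotype, depth=10):
    gt = tuple(sorted(genotype)) if genotype else None
    return GenotypeCall(line, gt, depth)


def verdict(passed=True):
    return FilterVerdict("s1", 1, frozenset() if passed else frozenset({"COVERAGE"}))


class TestInferAncestral:
    def test_majority_wins(self):
        calls = [call(f"L{i}", "AA") for i in range(13)] + [call("L13", "AC")]
        assert infer_ancestral(calls) == ("A", "A")

    def test_tie_voids_site(self):
        calls = [call(f"L{i}", "AA") for i in range(7)] + [
            call(f"L{i + 7}", "AC") for i in range(7)
        ]
        assert infer_ancestral(calls) is None

    def test_all_no_call_gives_none(self):
        assert infer_ancestral([call("L1", None), call("L2", None)]) is None


class TestAssessCallability:
    def _calls(self, n=14, overrides=None):
        out = [call(f"L{i:02d}", "AA") for i in range(n)]
        for idx, c in (overrides or {}).items():
            out[idx] = c
        return out

    def test_clean_site_is_callable(self):
        rec = assess_callability(
            "s1", 1, "A", verdict(), self._calls(), ("A", "A")
        )
        assert rec.callable and rec.reason == OK

    def test_failed_filter_dominates(self):
        rec = assess_callability(
            "s1", 1, "A", verdict(False), self._calls(), ("A", "A")
        )
        assert rec.reason == FILTERED

    def test_missing_call_detected(self):
        calls = self._calls(overrides={3: call("L03", None, depth=20)})
        rec = assess_callability("s1", 1, "A", verdict(), calls, ("A", "A"))
        assert rec.reason == MISSING_CALL

    def test_low_depth_detected(self):
        calls = self._calls(overrides={3: call("L03", None, depth=5)})
        rec = assess_callability("s1", 1, "A", verdict(), calls, ("A", "A"))
        assert rec.reason == LOW_DEPTH

    def test_het_ancestor_not_callable(self):
        rec = assess_callability(
            "s1", 1, "A", verdict(), self._calls(), ("A", "C")
        )
        assert rec.reason == ANC_NOT_HOMREF

    def test_hom_nonref_ancestor_not_callable(self):
        rec = assess_callability(
            "s1", 1, "A", verdict(), self._calls(), ("G", "G")
        )
        assert rec.reason == ANC_NOT_HOMREF

    def test_consensus_tie_reported(self):
        rec = assess_callability("s1", 1, "A", verdict(), self._calls(), None)
        assert rec.reason == ANC_TIE


class TestIdentifyMutations:
    def _run(self, per_line_genotypes, anc=("A", "A"), reason=OK):
        from macall.mutation_finder import CallabilityRecord

        calls = [
            call(f"L{i:02d}", g) for i, g in enumerate(per_line_genotypes)
        ]
        return identify_mutations(
            [("s1", 1, "A")],
            [calls],
            [CallabilityRecord("s1", 1, reason)],
            [anc],
        )

    def test_single_het_line_yields_candidate(self):
        muts = self._run(["AA"] * 13 + ["AC"])
        assert len(muts) == 1
        m = muts[0]
        assert (m.ancestral_nt, m.mutant_nt, m.line_id) == ("A", "C", "L13")

    def test_two_mutant_lines_discard_site(self):
        assert self._run(["AA"] * 12 + ["AC", "AC"]) == []

    def test_homozygous_mutant_admitted(self):
        muts = self._run(["AA"] * 13 + ["CC"])
        assert len(muts) == 1
        assert muts[0].mutant_nt == "C"
        assert muts[0].called_genotype == ("C", "C")

    def test_uncallable_site_emits_nothing(self):
        assert self._run(["AA"] * 13 + ["AC"], reason=MISSING_CALL) == []

    def test_mutant_equal_ancestral_rejected_by_type(self):
        with pytest.raises(ValueError):
            CandidateMutation("s1", 1, "L01", "A", "A", 1, ("A", "A"))


class TestPipelineEndToEnd:
    def test_toy_candidate_found(self, toy_mutation_table):
        config = RunConfig(min_total_coverage=40, max_total_coverage=400)
        res = run_time_point(toy_mutation_table, None, config)
        # site 101: single het line -> one candidate A->C in L01
        assert len(res.candidates) == 1
        c = res.candidates[0]
        assert (c.position, c.line_id, c.ancestral_nt, c.mutant_nt) == (
            101,
            "L01",
            "A",
            "C",
        )
        # site 202 (two mutant lines) and 303 (monomorphic) yield nothing
        assert res.n_callable >= 2

    def test_zero_mutation_zero_error_data_is_silent(self):
        from .conftest import make_site
        from macall.io_formats import SiteTable

        sites = [
            make_site([(12, 0, 0, 0)] * 14, position=p) for p in range(1, 30)
        ]
        table = SiteTable.from_sites(sites)
        res = run_time_point(
            table, None, RunConfig(min_total_coverage=40, max_total_coverage=400)
        )
        assert res.candidates == []
        assert res.n_callable == len(sites)
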