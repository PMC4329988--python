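"""Decision table, confidence ranking, overlaps and beadome annotation."""

import itertools
import warnings

import numpy as np
import pytest

from silac_ipac.ipac_classify import (
    ClassifierConfig,
    InteractionVerdict,
    ResinEvidence,
    beadome_flag,
    classify_protein,
    empty_evidence,
    overlap_report,
    rank_confidence,
    summarize_resin,
)
from silac_ipac.quant_io import DesignEntry, StudyDesign
from silac_ipac.ratio_model import CallStatus, SignificanceCall


def make_design(resins=("FLAG", "TALON"), reps=2):
    entries = []
    for resin in resins:
        for orient, tag in (("tagged_heavy", "H"), ("tagged_light", "L")):
            for rep in range(1, reps + 1):
                entries.append(DesignEntry(f"{resin}_{tag}{rep}", resin,
                                           orient, rep, "BAIT"))
    return StudyDesign(entries)


DESIGN = make_design()


def call(exp, status, log2=1.0):
    return SignificanceCall("P1", exp, status, 2.0, 1.0, log2)


def evidence(resin, n_exp, n_sig=0, n_near=0, n_dep=0, n_exc=0,
             orients=frozenset(), mean=None):
    return ResinEvidence(
        resin=resin, n_experiments=n_exp, n_significant=n_sig,
        n_near_one=n_near, n_depleted=n_dep, n_exclusive_control=n_exc,
        n_unobserved=n_exp - n_sig - n_near - n_dep - n_exc,
        orientations_supporting=frozenset(orients),
        mean_log2_enrichment=mean,
    )


class TestSummarizeResin:
    def test_counts_supporting_and_near_one(self):
        calls = [
            call("FLAG_H1", CallStatus.SIGNIFICANT_ENRICHED, 2.0),
            call("FLAG_H2", CallStatus.SIGNIFICANT_ENRICHED, 2.2),
            call("FLAG_L1", CallStatus.EXCLUSIVE_TAGGED, float("nan")),
            call("FLAG_L2", CallStatus.NOT_SIGNIFICANT, 0.1),
        ]
        ev = summarize_resin(calls, DESIGN)
        assert (ev.n_significant, ev.n_near_one) == (3, 1)
        assert ev.n_unobserved == 0
        assert ev.orientations_supporting == {"tagged_heavy", "tagged_light"}
        assert ev.mean_log2_enrichment == pytest.approx((2.0 + 2.2 + 0.1) / 3)

    def test_all_unquantified_has_absent_mean(self):
        calls = [call(e, CallStatus.UNQUANTIFIED, float("nan"))
                 for e in ("FLAG_H1", "FLAG_H2")]
        ev = summarize_resin(calls, DESIGN)
        assert ev.n_unobserved == 4  # 2 unquantified + 2 never seen
        assert ev.mean_log2_enrichment is None

    def test_mixed_resins_rejected(self):
        calls = [call("FLAG_H1", CallStatus.NOT_SIGNIFICANT, 0.0),
                 call("TALON_H1", CallStatus.NOT_SIGNIFICANT, 0.0)]
        with pytest.raises(ValueError, match="multiple resins"):
            summarize_resin(calls, DESIGN)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            summarize_resin([], DESIGN)


class TestClassifyProtein:
    def test_enriched_with_both_resins_is_genuine(self):
        per_resin = {"FLAG": evidence("FLAG", 4, n_sig=3, n_near=1),
                     "TALON": evidence("TALON", 4, n_sig=2, n_near=2)}
        v = classify_protein("P1", per_resin)
        assert v.verdict == "genuine"

    def test_exclusive_one_resin_near_one_other_is_tag_artefact(self):
        per_resin = {"FLAG": evidence("FLAG", 2, n_sig=2),
                     "TALON": evidence("TALON", 2, n_near=2)}
        v = classify_protein("P1", per_resin)
        assert v.verdict == "tag_specific_artefact"

    def test_near_one_everywhere_is_non_specific(self):
        per_resin = {"FLAG": evidence("FLAG", 4, n_near=4),
                     "TALON": evidence("TALON", 4, n_near=4)}
        v = classify_protein("P1", per_resin)
        assert v.verdict == "non_specific"

    def test_declared_bait_short_circuits(self):
        per_resin = {"FLAG": evidence("FLAG", 4, n_sig=4),
                     "TALON": evidence("TALON", 4, n_sig=4)}
        v = classify_protein("BAIT", per_resin, bait_accessions={"BAIT"})
        assert v.verdict == "bait"
        assert v.confidence == "not_applicable"

    def test_single_resin_support_with_other_unobserved_is_insufficient(self):
        per_resin = {"FLAG": evidence("FLAG", 4, n_sig=4),
                     "TALON": empty_evidence("TALON", 4)}
        v = classify_protein("P1", per_resin)
        assert v.verdict == "insufficient_data"

    def test_depleted_counts_as_near_one_for_artefact_logic(self):
        per_resin = {"FLAG": evidence("FLAG", 2, n_sig=2),
                     "TALON": evidence("TALON", 2, n_dep=2)}
        v = classify_protein("P1", per_resin)
        assert v.verdict == "tag_specific_artefact"

    def test_two_resin_support_dominates_third_near_one(self):
        per_resin = {"FLAG": evidence("FLAG", 2, n_sig=2),
                     "TALON": evidence("TALON", 2, n_sig=2),
                     "IgG": evidence("IgG", 2, n_near=2)}
        with pytest.warns(UserWarning, match="multi-resin support dominates"):
            v = classify_protein("P1", per_resin)
        assert v.verdict == "genuine"


class TestRankConfidence:
    def _genuine(self, per_resin):
        return InteractionVerdict("P1", "genuine", "not_applicable", per_resin)

    def test_reproducible_in_both_resins_and_orientations_is_high(self):
        per_resin = {
            "FLAG": evidence("FLAG", 4, n_sig=4,
                             orients={"tagged_heavy", "tagged_light"}),
            "TALON": evidence("TALON", 4, n_sig=3, n_near=1,
                              orients={"tagged_heavy"}),
        }
        assert rank_confidence(self._genuine(per_resin)) == "high"

    def test_inconsistent_second_resin_is_low(self):
        per_resin = {
            "FLAG": evidence("FLAG", 4, n_sig=4,
                             orients={"tagged_heavy", "tagged_light"}),
            "TALON": evidence("TALON", 4, n_sig=1, n_near=3,
                              orients={"tagged_heavy"}),
        }
        assert rank_confidence(self._genuine(per_resin)) == "low"

    def test_single_orientation_support_is_medium(self):
        per_resin = {
            "FLAG": evidence("FLAG", 4, n_sig=4, orients={"tagged_heavy"}),
            "TALON": evidence("TALON", 4, n_sig=3, n_near=1,
                              orients={"tagged_heavy"}),
        }
        assert rank_confidence(self._genuine(per_resin)) == "medium"

    def test_non_genuine_is_not_applicable(self):
        v = InteractionVerdict("P1", "non_specific", "not_applicable",
                               {"FLAG": evidence("FLAG", 4, n_near=4)})
        assert rank_confidence(v) == "not_applicable"


# ---------------------------------------------------------------------------
# brute-force oracle for the decision table
# ---------------------------------------------------------------------------

STATUSES = list(CallStatus)


def oracle_verdict(statuses_by_resin, protein="P1", bait="BAIT", min_sig=1):
    """Literal re-application of the decision table from raw statuses."""
    if protein == bait:
        return "bait"
    support = {}
    near_one = {}
    quantified = {}
    for resin, statuses in statuses_by_resin.items():
        support[resin] = sum(
            s in (CallStatus.SIGNIFICANT_ENRICHED, CallStatus.EXCLUSIVE_TAGGED)
            for s in statuses
        )
        near_one[resin] = sum(
            s in (CallStatus.NOT_SIGNIFICANT, CallStatus.SIGNIFICANT_DEPLETED)
            for s in statuses
        )
        quantified[resin] = near_one[resin]
    if sum(s >= min_sig for s in support.values()) >= 2:
        return "genuine"
    if any(s >= 1 for s in support.values()) and any(
        support[r] == 0 and near_one[r] >= 1 for r in statuses_by_resin
    ):
        return "tag_specific_artefact"
    if all(s == 0 for s in support.values()) and any(
        q >= 1 for q in quantified.values()
    ):
        return "non_specific"
    return "insufficient_data"


def _classify_from_statuses(statuses_by_resin, design, protein="P1"):
    per_resin = {}
    for resin, statuses in statuses_by_resin.items():
        exps = [e.experiment_id for e in design.experiments_for(resin)]
        calls = [
            SignificanceCall(protein, exp, s, None if s in (
                CallStatus.EXCLUSIVE_TAGGED, CallStatus.EXCLUSIVE_CONTROL,
                CallStatus.UNQUANTIFIED) else 2.0, 1.0,
                0.0 if s in (CallStatus.SIGNIFICANT_ENRICHED,
                             CallStatus.SIGNIFICANT_DEPLETED,
                             CallStatus.NOT_SIGNIFICANT) else float("nan"))
            for exp, s in zip(exps, statuses)
        ]
        per_resin[resin] = summarize_resin(calls, design,
                                           n_experiments=len(statuses))
    return classify_protein(protein, per_resin, bait_accessions={"BAIT"})


class TestDecisionTableOracle:
    def test_agrees_with_bruteforce_on_random_patterns(self):
        """classify_protein matches a literal decision-table enumeration on
        10,000 random status patterns over up to 4 resins x 4 experiments."""
        rng = np.random.default_rng(2024)
        resin_pool = ("FLAG", "TALON", "Calmodulin", "IgG")
        mismatches = 0
        for _ in range(10_000):
            n_resins = int(rng.integers(2, 5))
            design = make_design(resin_pool[:n_resins], reps=2)
            pattern = {
                resin: [STATUSES[i] for i in
                        rng.integers(0, len(STATUSES),
                                     size=int(rng.integers(1, 5)))]
                for resin in resin_pool[:n_resins]
            }
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = _classify_from_statuses(pattern, design).verdict
            if got != oracle_verdict(pattern):
                mismatches += 1
        assert mismatches == 0

    def test_adding_support_never_demotes(self):
        """Monotonicity: appending a significant-enriched call can only move
        a protein up the order {insufficient, non_specific} < artefact/genuine,
        and can only raise its confidence rank.

        The two bottom classes form one tier: a protein quantified near 1 in
        a single resin (non_specific) that turns significant there becomes a
        single-resin candidate (insufficient_data) — more interesting, not
        demoted, but formally a move between the bottom classes."""
        rank = {"insufficient_data": 0, "non_specific": 0,
                "tag_specific_artefact": 1, "genuine": 1, "bait": 2}
        conf_rank = {"not_applicable": 0, "low": 1, "medium": 2, "high": 3}
        rng = np.random.default_rng(99)
        design = make_design(("FLAG", "TALON"), reps=2)
        for _ in range(400):
            pattern = {
                resin: [STATUSES[i] for i in
                        rng.integers(0, len(STATUSES),
                                     size=int(rng.integers(1, 4)))]
                for resin in ("FLAG", "TALON")
            }
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                before = _classify_from_statuses(pattern, design)
                target = "FLAG" if rng.random() < 0.5 else "TALON"
                augmented = {
                    r: s + [CallStatus.SIGNIFICANT_ENRICHED] if r == target else s
                    for r, s in pattern.items()
                }
                after = _classify_from_statuses(augmented, design)
            assert rank[after.verdict] >= rank[before.verdict]
            if before.verdict == "genuine" and after.verdict == "genuine":
                assert conf_rank[after.confidence] >= conf_rank[before.confidence]


class TestOverlapReport:
    def test_two_set_regions_enumerated(self):
        df = overlap_report({"A": {"a", "b", "c"}, "B": {"b", "c", "d"}})
        assert dict(zip(df["region"], df["count"])) == {
            "A": 1, "B": 1, "A&B": 2,
        }
        assert df.attrs["union"] == 4

    def test_identical_sets_put_all_mass_in_intersection(self):
        df = overlap_report({"A": {"x", "y"}, "B": {"x", "y"}})
        counts = dict(zip(df["region"], df["count"]))
        assert counts == {"A": 0, "B": 0, "A&B": 2}
        assert df.loc[df["region"] == "A&B", "percent_of_union"].item() == 100.0

    def test_three_sets_have_seven_regions_summing_to_union(self):
        df = overlap_report({"A": set(range(10)), "B": set(range(5, 15)),
                             "C": set(range(8, 12))})
        assert len(df) == 7
        assert df["count"].sum() == df.attrs["union"]

    def test_single_set_rejected(self):
        with pytest.raises(ValueError, match="two"):
            overlap_report({"A": {1}})


class TestBeadomeFlag:
    def _verdicts(self):
        per_resin = {"FLAG": evidence("FLAG", 2, n_sig=2),
                     "TALON": evidence("TALON", 2, n_sig=2)}
        return [
            InteractionVerdict("NPM1", "genuine", "low", per_resin),
            InteractionVerdict("P2", "non_specific", "not_applicable",
                               {"FLAG": evidence("FLAG", 2, n_near=2)}),
        ]

    def test_annotation_does_not_veto_the_verdict(self):
        flagged = beadome_flag(self._verdicts(), ["NPM1"])
        assert flagged[0].verdict == "genuine"
        assert flagged[0].in_beadome
        assert not flagged[1].in_beadome

    def test_empty_beadome_flags_nothing(self):
        assert all(not v.in_beadome for v in beadome_flag(self._verdicts(), []))

    def test_gene_level_matching(self):
        flagged = beadome_flag(self._verdicts(), ["ACC9"],
                               match="gene",
                               gene_of={"NPM1": "G1", "ACC9": "G1"})
        assert flagged[0].in_beadome
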