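"""Consensus driver prediction, domain mapping and co-occurrence screening."""

import itertools

import pandas as pd
import pytest

from metex14 import (MissingPredictorError, PredictorProfile, ValidationError,
                     consensus_driver, default_actionable_sets,
                     default_domain_table, map_to_domain, parse_protein_change,
                     predictor_votes, screen_other_actionable,
                     triage_annotations, votes_matrix)

ALL_DRIVER = dict(sift="deleterious", polyphen2="probably_damaging",
                  mutation_taster="disease_causing", cadd_phred=33.0,
                  cgi="predicted_driver")
ALL_BENIGN = dict(sift="tolerated", polyphen2="benign",
                  mutation_taster="neutral", cadd_phred=0.1,
                  cgi="predicted_passenger")


def profile(variant_id="T992I", **kw) -> PredictorProfile:
    base = dict(ALL_DRIVER)
    base.update(kw)
    return PredictorProfile(variant_id=variant_id, **base)


def vector_profile(bits) -> PredictorProfile:
    """Profile whose five votes equal the given driver/non-driver bit vector."""
    return PredictorProfile(
        "T992I",
        sift="deleterious" if bits[0] else "tolerated",
        polyphen2="probably_damaging" if bits[1] else "benign",
        mutation_taster="disease_causing" if bits[2] else "neutral",
        cadd_phred=30.0 if bits[3] else 10.0,
        cgi="predicted_driver" if bits[4] else "predicted_passenger",
    )


class TestPredictorVotes:
    def test_all_damaging_profile_votes_driver_everywhere(self):
        assert set(predictor_votes(profile()).values()) == {"driver"}

    def test_cadd_bound_is_strict(self):
        votes = predictor_votes(profile(cadd_phred=25.0))
        assert votes["cadd"] == "non_driver"
        assert predictor_votes(profile(cadd_phred=25.01))["cadd"] == "driver"

    def test_all_benign_profile_votes_non_driver(self):
        assert set(predictor_votes(profile(**ALL_BENIGN)).values()) == {"non_driver"}

    @pytest.mark.parametrize("cgi,expected", [
        ("known_driver", "driver"), ("predicted_driver", "driver"),
        ("predicted_passenger", "non_driver")])
    def test_cgi_known_and_predicted_both_count(self, cgi, expected):
        assert predictor_votes(profile(cgi=cgi))["cgi"] == expected

    def test_polyphen_possibly_damaging_counts_as_driver(self):
        assert predictor_votes(profile(polyphen2="possibly_damaging"))["polyphen2"] \
            == "driver"

    def test_missing_value_policy(self):
        p = profile(sift=None)
        with pytest.raises(MissingPredictorError):
            predictor_votes(p)
        votes = predictor_votes(p, missing_policy="abstain")
        assert votes["sift"] == "non_driver"

    def test_invalid_category_rejected(self):
        with pytest.raises(ValidationError):
            profile(sift="damaging")


class TestConsensus:
    def test_conjunction_over_all_32_vote_vectors(self):
        """Exhaustive: is_predicted_driver == AND of the five votes."""
        for bits in itertools.product([False, True], repeat=5):
            call = consensus_driver(vector_profile(bits))
            assert call.is_predicted_driver == all(bits), bits

    def test_removing_a_predictor_only_enlarges_the_driver_set(self):
        for bits in itertools.product([False, True], repeat=5):
            full = all(bits)
            for dropped in range(5):
                reduced = all(b for i, b in enumerate(bits) if i != dropped)
                assert reduced or not full  # full consensus implies reduced

    def test_lowering_cadd_threshold_never_shrinks_driver_set(self):
        profiles = [profile(cadd_phred=c) for c in (5.0, 20.0, 25.0, 26.0, 33.0)]
        for hi, lo in [(25.0, 20.0), (25.0, 10.0), (30.0, 25.0)]:
            set_hi = {p.cadd_phred for p in profiles
                      if consensus_driver(p, cadd_threshold=hi).is_predicted_driver}
            set_lo = {p.cadd_phred for p in profiles
                      if consensus_driver(p, cadd_threshold=lo).is_predicted_driver}
            assert set_hi <= set_lo


class TestDomainMapping:
    @pytest.mark.parametrize("residue,domain", [
        (992, "JM"),    # the juxtamembrane hotspot
        (1094, "TK"),   # the kinase-domain hotspot
        (956, "JM"), (1009, "JM"), (1078, "TK"), (1345, "TK"),
        (1, "other"), (1010, "other"), (1400, "other"),
    ])
    def test_default_table(self, residue, domain):
        assert map_to_domain(residue) == domain

    def test_total_single_label(self):
        table = default_domain_table()
        names = {d[0] for d in table.domains} | {"other"}
        for residue in range(1, 1401):
            assert map_to_domain(residue, table) in names

    def test_residue_below_one_rejected(self):
        with pytest.raises(ValidationError):
            map_to_domain(0)

    @pytest.mark.parametrize("vid,expected", [
        ("T992I", ("T", 992, "I")), ("p.H1094Y", ("H", 1094, "Y")),
        ("D1010fs*3", ("D", 1010, "fs*3")), ("not-a-change", (None, None, None)),
    ])
    def test_protein_change_parsing(self, vid, expected):
        assert parse_protein_change(vid) == expected


class TestCooccurrenceScreen:
    @pytest.fixture()
    def sets(self):
        return default_actionable_sets()

    def test_met_only_profile_is_clean(self, sets):
        any_solid, lung = sets
        assert screen_other_actionable([("MET", "VUS")], any_solid, lung) \
            == (False, False)

    def test_egfr_cooccurrence_flags_both(self, sets):
        any_solid, lung = sets
        assert screen_other_actionable([("MET", "VUS"), ("EGFR", "actionable")],
                                       any_solid, lung) == (True, True)

    def test_pik3ca_actionable_any_solid_but_not_lung(self, sets):
        any_solid, lung = sets
        assert screen_other_actionable([("MET", "VUS"), ("PIK3CA", "VUS")],
                                       any_solid, lung) == (True, False)


class TestAnnotationTriage:
    def annotations(self):
        return pd.DataFrame([
            dict(variant_id="T992I", gene="MET", protein_change="T992I",
                 **ALL_DRIVER, clinical_significance="VUS"),
            dict(variant_id="N375S", gene="MET", protein_change="N375S",
                 **ALL_BENIGN, clinical_significance="VUS"),
            dict(variant_id="D1010H", gene="MET", protein_change="D1010H",
                 **ALL_BENIGN, clinical_significance="actionable"),
        ])

    def test_consensus_and_actionable_bypass(self):
        out = triage_annotations(self.annotations())
        by_id = out.set_index("variant_id")
        assert bool(by_id.loc["T992I", "is_predicted_driver"])
        assert not bool(by_id.loc["N375S", "is_predicted_driver"])
        # clinically actionable variants are flagged regardless of votes
        assert bool(by_id.loc["D1010H", "is_actionable"])
        assert not bool(by_id.loc["N375S", "is_actionable"])

    def test_votes_matrix_is_binary_per_predictor(self):
        mat = votes_matrix(triage_annotations(self.annotations()))
        assert list(mat.columns) == ["sift", "polyphen2", "mutation_taster",
                                     "cadd", "cgi"]
        assert mat.loc["T992I"].tolist() == [1, 1, 1, 1, 1]
        assert mat.loc["N375S"].tolist() == [0, 0, 0, 0, 0]
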