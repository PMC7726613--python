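from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import nw_glocal_score, slide_identity
from ampliscreen import calling
from ampliscreen.references import (
    KDR_RESISTANT,
    KDR_SENSITIVE,
    reference_db,
)
from ampliscreen.seqtable import dereplicate

DB = reference_db()
RES = DB["kdr"][KDR_RESISTANT]
SEN = DB["kdr"][KDR_SENSITIVE]


def kdr_table(**columns):
    """columns: sample -> {sequence: count}."""
    return dereplicate({s: Counter(c) for s, c in columns.items()}, "kdr")


def _mutate(seq, k, seed=0):
    rng = np.random.default_rng(seed)
    arr = list(seq)
    for p in rng.choice(len(arr), k, replace=False):
        arr[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[p]]
    return "".join(arr)


class TestMatchReference:
    def test_identical_query_is_full_identity(self):
        hits = calling.match_reference(RES, DB["kdr"])
        assert hits[0].name == KDR_RESISTANT and hits[0].identity == 1.0

    def test_identity_floor_is_70_percent(self):
        # substitutions spread evenly so no gapped re-registration can
        # recover matches: computed identity is exactly the hamming identity
        rng = np.random.default_rng(42)
        base = "".join(rng.choice(list("ACGT"), 100))

        def sub_at(seq, positions):
            arr = list(seq)
            for p in positions:
                arr[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[p]]
            return "".join(arr)

        q_70 = sub_at(base, range(0, 90, 3))  # 30 substitutions
        q_69 = sub_at(base, list(range(0, 90, 3)) + [91])  # 31
        hits = calling.match_reference(q_70, ref := {"r": base})
        assert hits and hits[0].identity == pytest.approx(0.70)
        assert not calling.match_reference(q_69, ref)

    def test_exact_ties_all_returned(self):
        base = "ACGTTGCA" * 10
        refs = {"a": _mutate(base, 4, seed=1), "b": _mutate(base, 4, seed=2)}
        hits = calling.match_reference(base, refs)
        assert len(hits) == 2
        assert hits[0].identity == pytest.approx(hits[1].identity)

    def test_short_query_no_call(self):
        assert calling.match_reference("ACGTACGTACGT", DB["kdr"]) == []

    def test_empty_reference_set_is_error(self):
        with pytest.raises(ValueError):
            calling.match_reference("A" * 30, {})

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        ref_seed=st.integers(0, 10_000),
        ref_len=st.integers(30, 50),
        start=st.integers(0, 15),
        length=st.integers(20, 30),
        n_subs=st.integers(0, 3),
        seed=st.integers(0, 1000),
    )
    def test_alignment_matches_dp_oracle(self, ref_seed, ref_len, start, length, n_subs, seed):
        """The end-gap-free alignment score equals an independent DP oracle,
        and exact substrings score full identity regardless of placement."""
        rng = np.random.default_rng(ref_seed)
        ref = "".join(rng.choice(list("ACGT"), ref_len))
        sub = ref[start:start + length]
        if len(sub) < 20:
            return
        query = _mutate(sub, min(n_subs, len(sub)), seed)
        got_score = calling._ALIGNER.score(query, ref)
        assert got_score == pytest.approx(nw_glocal_score(query, ref))
        if n_subs == 0:
            assert calling._identity(query, ref) == 1.0
        else:
            # any optimal alignment has at least as many matches as the best
            # ungapped placement of the query
            assert calling._identity(query, ref) >= slide_identity(query, ref) - 1e-12


class TestCallKdr:
    def test_homozygous_resistant(self):
        calls = calling.call_kdr(kdr_table(S1={RES: 990, _mutate(RES, 1): 10}), DB)
        c = calls["S1"]
        assert c.call == "RR" and c.ratio == pytest.approx(0.01)

    def test_homozygous_sensitive(self):
        calls = calling.call_kdr(kdr_table(S1={SEN: 1200}), DB)
        assert calls["S1"].call == "SS" and calls["S1"].ratio == 0.0

    def test_heterozygous(self):
        calls = calling.call_kdr(kdr_table(S1={RES: 520, SEN: 480}), DB)
        c = calls["S1"]
        assert c.call == "RS" and c.ratio == pytest.approx(0.48)

    def test_ambiguous_band_no_call(self):
        calls = calling.call_kdr(kdr_table(S1={RES: 700, SEN: 300}), DB)
        assert calls["S1"].call == calling.NO_CALL

    @pytest.mark.parametrize("c1,c2,expected", [
        (850, 150, calling.NO_CALL),   # ratio exactly 0.15
        (650, 350, calling.NO_CALL),   # ratio exactly 0.35
        (860, 140, "RR"),              # 0.14 < 0.15
        (640, 360, "RS"),              # 0.36 > 0.35
    ])
    def test_ratio_cutoffs_are_strict(self, c1, c2, expected):
        calls = calling.call_kdr(kdr_table(S1={RES: c1, SEN: c2}), DB)
        assert calls["S1"].call == expected

    def test_depth_floor(self):
        calls = calling.call_kdr(kdr_table(S1={RES: 999}), DB)
        assert calls["S1"].call == calling.NO_CALL
        calls = calling.call_kdr(kdr_table(S1={RES: 1000}), DB)
        assert calls["S1"].call == "RR"

    def test_scale_invariance(self):
        t1 = kdr_table(S1={RES: 520, SEN: 480})
        t2 = kdr_table(S1={RES: 5200, SEN: 4800})
        assert (
            calling.call_kdr(t1, DB)["S1"].call
            == calling.call_kdr(t2, DB)["S1"].call
            == "RS"
        )


class TestCallSpecies:
    def test_s200_match(self):
        t = dereplicate({"S1": Counter({DB["s200x6"]["Anopheles_gambiae"]: 2917})}, "s200x6")
        empty = dereplicate({}, "cox1")
        c = calling.call_species(t, empty, DB)["S1"]
        assert c.species == "Anopheles_gambiae" and c.evidence_locus == "s200x6"

    def test_hybrid_detection(self):
        t = dereplicate(
            {"S1": Counter({
                DB["s200x6"]["Anopheles_gambiae"]: 1100,
                DB["s200x6"]["Anopheles_coluzzii"]: 900,
            })},
            "s200x6",
        )
        c = calling.call_species(t, dereplicate({}, "cox1"), DB)["S1"]
        assert c.hybrid and c.species == "Anopheles_gambiae_x_coluzzii"

    def test_nili_rescued_via_cox1(self):
        s200 = dereplicate({}, "s200x6")
        cox1 = dereplicate({"S1": Counter({DB["cox1"]["Anopheles_nili"]: 1400})}, "cox1")
        c = calling.call_species(s200, cox1, DB)["S1"]
        assert c.species == "Anopheles_nili" and c.evidence_locus == "cox1"

    def test_both_loci_under_depth(self):
        s200 = dereplicate({"S1": Counter({DB["s200x6"]["Anopheles_gambiae"]: 500})}, "s200x6")
        cox1 = dereplicate({"S1": Counter({DB["cox1"]["Anopheles_gambiae"]: 500})}, "cox1")
        assert calling.call_species(s200, cox1, DB)["S1"].species == calling.NO_CALL


class TestBloodMeal:
    HUMAN = DB["mammal_16s"]["Homo_sapiens"]
    COW = DB["mammal_16s"]["Bos_taurus"]

    def test_below_floor_not_fed(self):
        t = dereplicate({"S1": Counter({self.HUMAN: 999})}, "mammal_16s")
        p = calling.call_blood_meal(t, DB)["S1"]
        assert not p.fed and p.hosts == {}

    def test_multi_host_meal(self):
        t = dereplicate({"S1": Counter({self.HUMAN: 800, self.COW: 600})}, "mammal_16s")
        p = calling.call_blood_meal(t, DB)["S1"]
        assert p.fed and p.hosts == {"Homo_sapiens": 800, "Bos_taurus": 600}

    def test_no_reads(self):
        t = dereplicate({"S1": Counter(), "S2": Counter({self.HUMAN: 2000})}, "mammal_16s")
        p = calling.call_blood_meal(t, DB)["S1"]
        assert not p.fed and p.hosts == {} and p.total_reads == 0


class TestDetections:
    PF = DB["parasite_virus"]["Plasmodium_falciparum"]

    def test_detection_with_full_identity(self):
        t = dereplicate({"M1": Counter({self.PF: 1876})}, "parasite_virus")
        recs = calling.detect_infections(t, DB)
        assert len(recs) == 1
        r = recs[0]
        assert r.species == ("Plasmodium_falciparum",)
        assert r.identity == 100.0 and r.reads == 1876 and r.group == "Apicomplexa"

    def test_control_flagged(self):
        t = dereplicate({"CTL1": Counter({self.PF: 54})}, "parasite_virus")
        recs = calling.detect_infections(t, DB, control_ids=["CTL1"])
        assert recs[0].is_control

    def test_unmatched_sequence_ignored(self):
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(list("ACGT"), 200))
        t = dereplicate({"M1": Counter({junk: 500})}, "parasite_virus")
        assert calling.detect_infections(t, DB) == []


class TestFlagContamination:
    def _rec(self, sample, reads, control=False):
        return calling.DetectionRecord(sample, "Apicomplexa", ("Theileria_sp",), 100.0, reads, control)

    def test_no_controls_no_annotation(self):
        out = calling.flag_contamination([self._rec("M1", 40)])
        assert out[0].annotation == ""

    def test_weak_detection_annotated(self):
        out = calling.flag_contamination(
            [self._rec("M1", 40), self._rec("CTL1", 54, control=True)], ratio_threshold=2
        )
        assert out[0].annotation == "possible contamination"
        assert out[1].annotation == ""

    def test_strong_detection_not_annotated(self):
        out = calling.flag_contamination(
            [self._rec("M1", 5000), self._rec("CTL1", 54, control=True)], ratio_threshold=2
        )
        assert out[0].annotation == ""
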