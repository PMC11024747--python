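"""Segmentation, tagging, status, numeric parsing, projection."""

import pytest
from hypothesis import given, settings, strategies as st

from rehab_extract.preprocess import Section
from rehab_extract.rule_extractor import (
    STATUS_HEP,
    STATUS_IN_OFFICE,
    STATUS_NOT_PERFORMED,
    ConceptMention,
    NumericFinding,
    parse_numeric,
    project,
    resolve_status,
    segment,
    tag,
)

# the two deidentified example sections used as fixed inputs throughout
EXAMPLE_1 = (
    "1: AROM right elbow flx/ext HEP (right arm supported on table) "
    "2: AROM right wrist flx/ext HEP "
    "3: AROM right forearm pronation/supination HEP "
    "4: Thumb opposition HEP "
    "5: Seated AAROM table slide??"
)
EXAMPLE_2 = (
    "1: foam balance (heel/toe rocking): x 30 "
    "2: step taps with 2 taps from foam 12\" block: x 20 B/L "
    "3: tandem walking: 25' x 2 "
    "4: backward walking: 25' x 2 "
    "5: foam Lunges: x 20 B/L "
    "6: Dips 4\" stair: 2x10 B/L "
    "7: side stepping green TB 10 ft x5 each direction "
    "9: bridging with LLE leg lift 1\" off mat x10 "
    "10: tandem stance on foam x 1' "
    "11: Nustep: L5 x 10' (LEs only)"
)


def _section(text, sid="s"):
    return Section(source_filename=sid, text=text, char_span=(0, len(text)),
                   section_id=sid)


class TestSegment:
    def test_example_1_has_five_items(self):
        seqs = segment(_section(EXAMPLE_1))
        assert [q.index_label for q in seqs] == ["1", "2", "3", "4", "5"]

    def test_example_2_has_ten_items_with_gap_preserved(self):
        seqs = segment(_section(EXAMPLE_2))
        assert [q.index_label for q in seqs] == [
            "1", "2", "3", "4", "5", "6", "7", "9", "10", "11"
        ]

    def test_empty_section_and_markerless_text(self):
        assert segment(_section("")) == []
        assert segment(_section("free text with no list at all")) == []

    def test_items_without_content_are_dropped(self):
        seqs = segment(_section("1:  2: squats x10"))
        assert [q.index_label for q in seqs] == ["2"]

    @pytest.mark.parametrize("text", [EXAMPLE_1, EXAMPLE_2])
    def test_spans_partition_the_section(self, text):
        sec = _section(text)
        seqs = segment(sec)
        for a, b in zip(seqs, seqs[1:]):
            assert a.char_span[1] <= b.char_span[0]
        # items plus inter-item text reconstruct the section
        rebuilt = ""
        pos = 0
        for q in seqs:
            rebuilt += sec.text[pos:q.char_span[0]] + q.text
            pos = q.char_span[1]
        rebuilt += sec.text[pos:]
        assert rebuilt == sec.text
        for q in seqs:
            assert sec.text[slice(*q.char_span)] == q.text


class TestTag:
    def test_box_example_line(self, ontology, ruleset):
        ids = {m.concept_id
               for m in tag("AROM right elbow flx/ext HEP", ontology, ruleset)}
        assert ids == {
            "motion_arom", "side_right", "loc_elbow",
            "plane_flexion", "plane_extension", "desc_hep",
        }

    def test_backward_walking_maps_to_gait_training(self, ontology, ruleset):
        ids = {m.concept_id
               for m in tag("backward walking: 25' x 2", ontology, ruleset)}
        assert {"plane_backward", "type_gait"} <= ids

    def test_empty_text(self, ontology, ruleset):
        assert tag("", ontology, ruleset) == []

    def test_longest_match_suppresses_nested_mentions(self, ontology, ruleset):
        mentions = tag("lateral flexion stretch", ontology, ruleset)
        ids = {m.concept_id for m in mentions}
        assert "plane_lateral_flexion" in ids
        assert "plane_lateral" not in ids and "plane_flexion" not in ids

    def test_identical_spans_keep_all_concepts(self, ontology, ruleset):
        mentions = tag("LUE stretch", ontology, ruleset)
        by_id = {m.concept_id: m.char_span for m in mentions}
        assert by_id["side_left"] == by_id["loc_upper_extremity"] == (0, 3)

    def test_mentions_are_ordered_and_nonoverlapping(self, ontology, ruleset):
        mentions = tag("AROM right elbow flx/ext HEP", ontology, ruleset)
        spans = [m.char_span for m in mentions]
        assert spans == sorted(spans)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2 or (s1, e1) == (s2, e2)

    def test_deid_placeholders_are_opaque(self, ontology, ruleset):
        assert tag("[PERSONALNAME] maze", ontology, ruleset) == []

    def test_single_letter_side_needs_location_context(self, ontology, ruleset):
        with_ctx = {m.concept_id for m in tag("L knee squats", ontology, ruleset)}
        assert "side_left" in with_ctx
        without = {m.concept_id for m in tag("Nustep: L5 x 10'", ontology, ruleset)}
        assert "side_left" not in without


class TestResolveStatus:
    def _status(self, text, ontology, ruleset):
        return resolve_status(text, tag(text, ontology, ruleset))

    def test_deferred_marks_not_performed(self, ontology, ruleset):
        text = "24: SL HS activation- with tapping x10 DEFERRED"
        assert self._status(text, ontology, ruleset) == STATUS_NOT_PERFORMED

    def test_hep_marker(self, ontology, ruleset):
        assert (
            self._status("AROM right wrist flx/ext HEP", ontology, ruleset)
            == STATUS_HEP
        )

    def test_default_is_in_office(self, ontology, ruleset):
        assert (
            self._status("foam balance (heel/toe rocking): x 30", ontology, ruleset)
            == STATUS_IN_OFFICE
        )

    def test_not_performed_outranks_hep(self, ontology, ruleset):
        text = "14: SLR- 2x10 deferred to HEP"
        mentions = tag(text, ontology, ruleset)
        assert resolve_status(text, mentions) == STATUS_NOT_PERFORMED
        # both description labels survive in the mention set
        ids = {m.concept_id for m in mentions}
        assert {"desc_not_performed", "desc_hep"} <= ids


def _kinds(text):
    return [(f.kind, f.value) for f in parse_numeric(text)]


class TestParseNumeric:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("Dips 4\" stair: 2x10", [("sets", 2), ("reps", 10)]),
            ("x 30", [("reps", 30)]),
            ("AROM Right wrist ext/flex - 20 x", [("reps", 20)]),
            ("tandem stance on foam x 1'", [("duration_seconds", 60)]),
            ("Nustep: L5 x 10' (LEs only)", [("duration_seconds", 600)]),
            ("3 rep", [("reps", 3)]),
            ("2x10 B/L", [("sets", 2), ("reps", 10)]),
            ("hold 30 sec", [("duration_seconds", 30)]),
            ("bike 5 min", [("duration_seconds", 300)]),
            ("no numbers here", []),
            ("", []),
        ],
    )
    def test_snippets(self, text, expected):
        assert _kinds(text) == expected

    def test_minutes_flagged_as_normalized(self):
        (f,) = parse_numeric("x 2'")
        assert f.kind == "duration_seconds" and f.value == 120
        assert f.unit_normalized

    def test_distance_context_suppresses_duration(self):
        assert _kinds("tandem walking: 25' x 2") == [("reps", 2)]
        found = parse_numeric("tandem walking: 25' x 2", include_distances=True)
        assert ("distance_feet", 25) in [(f.kind, f.value) for f in found]

    @given(
        pad_l=st.text(alphabet=" \t", max_size=3),
        pad_r=st.text(alphabet=" \t", max_size=3),
        upper=st.booleans(),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariant_to_whitespace_and_case(self, pad_l, pad_r, upper):
        base = "squats 2x10"
        text = pad_l + (base.upper() if upper else base) + pad_r
        assert [(f.kind, f.value) for f in parse_numeric(text)] == [
            ("sets", 2), ("reps", 10)
        ]


def _mention(cid, span=(0, 4)):
    return ConceptMention("s#1", cid, span, "t")


class TestProject:
    def test_union_with_status_concept(self):
        labels = project(
            [_mention("side_right"), _mention("loc_elbow", (5, 10))],
            [NumericFinding("reps", 10, (11, 13))],
            STATUS_IN_OFFICE,
        )
        assert labels.binary == {"side_right", "loc_elbow", "desc_in_office"}
        assert labels.reps == 10 and labels.sets is None

    def test_duplicate_mentions_collapse(self):
        labels = project(
            [_mention("plane_flexion"), _mention("plane_flexion", (9, 12))]
        )
        assert labels.binary == {"plane_flexion", "desc_in_office"}

    def test_numeric_collision_first_in_span_order_wins(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            labels = project(
                [],
                [
                    NumericFinding("reps", 20, (10, 12)),
                    NumericFinding("reps", 10, (2, 4)),
                ],
            )
        assert labels.reps == 10
        assert any("conflicting" in r.message for r in caplog.records)

    def test_idempotent_and_order_insensitive(self):
        ms = [_mention("side_left"), _mention("loc_knee", (5, 9))]
        a = project(ms, status=STATUS_HEP)
        b = project(list(reversed(ms)), status=STATUS_HEP)
        assert a.binary == b.binary
        again = project(ms, status=STATUS_HEP)
        assert again.binary == a.binary
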