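"""Hierarchical matcher: span consumption, section precedence, grouping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mlnqa.classifier import (
    UNCLASSIFIED_CATEGORY,
    UNKNOWN_STATION,
    audit_against_truth,
    audit_sample,
    audit_summary,
    classified_frame,
    classify_corpus,
    classify_diagnosis,
    classify_site,
    match_phrases,
    resolve_group,
)
from mlnqa.lexicon import GROUP_HIERARCHY, LexiconError, UNCLASSIFIED
from mlnqa.text import normalize_text
from tests.conftest import make_record


def _is_word(c: str) -> bool:
    return c.isalnum() or c == "_"


def oracle_match(text, lex):
    """Independent matcher: enumerate all boundary-aligned occurrences by
    naive startswith scanning, then accept non-overlapping spans in
    (rank, offset) order."""
    text = normalize_text(text)
    occurrences = []
    for e in lex.entries:
        L = len(e.phrase)
        for s in range(0, len(text) - L + 1):
            if text[s : s + L] != e.phrase:
                continue
            if s > 0 and _is_word(text[s - 1]):
                continue
            if s + L < len(text) and _is_word(text[s + L]):
                continue
            occurrences.append((e.rank, e.phrase, s, s + L, e.category_id))
    occurrences.sort(key=lambda t: (t[0], t[1], t[2]))
    taken = []
    for rank, phrase, s, epos, cid in occurrences:
        if any(not (epos <= ts or s >= te) for ts, te in taken):
            continue
        taken.append((s, epos))
        yield (phrase, cid, s, epos)


class TestMatchPhrases:
    def test_embedded_substring_consumed(self, dx_lex):
        spans = match_phrases("non-small cell carcinoma", dx_lex)
        assert len(spans) == 1
        assert spans[0].category_id == "non_small_cell_carcinoma"

    def test_plain_substring_matches(self, dx_lex):
        spans = match_phrases("small cell carcinoma", dx_lex)
        assert [s.category_id for s in spans] == ["small_cell_carcinoma"]

    def test_word_boundaries(self, site_lex):
        # "7" must not fire inside another number
        assert match_phrases("specimen 17 of 2019", site_lex) == []

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_oracle_equivalence_on_random_concatenations(self, data, dx_lex):
        phrases = [e.phrase for e in dx_lex.entries]
        parts = data.draw(
            st.lists(
                st.one_of(st.sampled_from(phrases), st.sampled_from(["with", "and", "lymph", "cells"])),
                min_size=1,
                max_size=6,
            )
        )
        text = " ".join(parts)
        got = [(s.phrase, s.category_id, s.start, s.end) for s in match_phrases(text, dx_lex)]
        assert got == list(oracle_match(text, dx_lex))


class TestResolveGroup:
    def test_malignant_dominates(self, dx_lex):
        assert resolve_group({"benign_lymphocytes", "adenocarcinoma"}, dx_lex) == "malignant"

    def test_insufficient_outranks_benign(self, dx_lex):
        assert resolve_group({"insufficient", "benign_reactive"}, dx_lex) == "insufficient"

    def test_empty_set_unclassified(self, dx_lex):
        assert resolve_group(set(), dx_lex) == UNCLASSIFIED

    def test_unknown_category_raises(self, dx_lex):
        with pytest.raises(LexiconError):
            resolve_group({"made_up"}, dx_lex)

    def test_full_hierarchy_order(self, dx_lex):
        reps = {
            "malignant": "adenocarcinoma",
            "suspicious": "suspicious_for_malignancy",
            "insufficient": "insufficient",
            "benign": "benign_reactive",
        }
        cats = set()
        for g in reversed(GROUP_HIERARCHY):  # add from least to most severe
            cats.add(reps[g])
            assert resolve_group(cats, dx_lex) == g


class TestClassifyDiagnosis:
    def test_addendum_refines_nscc_to_adenocarcinoma(self, dx_lex):
        rec = make_record(
            diagnosis_text="Non-small cell carcinoma.",
            addenda=["Immunostains support adenocarcinoma."],
        )
        call = classify_diagnosis(rec, dx_lex)
        assert call.category_id == "adenocarcinoma"
        assert call.changed_by_addendum

    def test_favor_phrase_classified_as_refined_type(self, dx_lex):
        rec = make_record(diagnosis_text="Non-small cell carcinoma, favor adenocarcinoma.")
        call = classify_diagnosis(rec, dx_lex)
        assert call.category_id == "adenocarcinoma"
        assert not call.changed_by_addendum

    def test_single_benign_match(self, dx_lex):
        rec = make_record(diagnosis_text="Benign lymphocytes. See comment.")
        call = classify_diagnosis(rec, dx_lex)
        assert call.category_id == "benign_lymphocytes"

    def test_no_match_unclassified(self, dx_lex, site_lex):
        rec = make_record(diagnosis_text="Descriptive findings only.")
        out = classify_corpus([rec], dx_lex, site_lex)[0]
        assert out.diagnosis_category == UNCLASSIFIED_CATEGORY
        assert out.exclusive_group == UNCLASSIFIED

    def test_addendum_restating_original_is_not_a_change(self, dx_lex):
        rec = make_record(
            diagnosis_text="Adenocarcinoma.", addenda=["Confirmed: adenocarcinoma."]
        )
        call = classify_diagnosis(rec, dx_lex)
        assert call.category_id == "adenocarcinoma"
        assert not call.changed_by_addendum

    def test_negation_classified_benign(self, dx_lex):
        rec = make_record(diagnosis_text="Negative for malignant cells.")
        call = classify_diagnosis(rec, dx_lex)
        assert call.category_id == "negative_for_malignancy"

    def test_within_section_severity_wins(self, dx_lex):
        rec = make_record(diagnosis_text="Benign lymphocytes. Also adenocarcinoma present.")
        call = classify_diagnosis(rec, dx_lex)
        assert call.category_id == "adenocarcinoma"


class TestClassifySite:
    @pytest.mark.parametrize(
        "text,station",
        [
            ("EBUS FNA lymph node, station 4R", "4R"),
            ("EUS lymph node subcarinal (station 7)", "7"),
            ("EBUS lymph node, site not specified", UNKNOWN_STATION),
        ],
    )
    def test_examples(self, text, station, site_lex):
        assert classify_site(make_record(source_text=text), site_lex) == station

    def test_synonym_maps_to_station(self, site_lex):
        rec = make_record(source_text="EBUS FNA lymph node, right lower paratracheal")
        assert classify_site(rec, site_lex) == "4R"


def test_groups_partition_corpus(dx_lex, site_lex):
    """Every record gets exactly one exclusive group; group counts sum to
    the corpus size."""
    from mlnqa.rate_tables import tabulate_groups
    from mlnqa.synthetic import SyntheticConfig, generate_corpus

    records, _ = generate_corpus(SyntheticConfig(n_records=400, seed=11, distractor_level="mild"))
    classified = classify_corpus(records, dx_lex, site_lex)
    table = tabulate_groups(classified)
    assert sum(table.counts.values()) == table.total == 400


def test_severity_monotonicity(dx_lex, site_lex):
    """Appending a malignant phrase to the diagnosis text never lowers the
    exclusive group."""
    from mlnqa.synthetic import SyntheticConfig, generate_corpus

    sev = {g: i for i, g in enumerate(GROUP_HIERARCHY)}
    sev[UNCLASSIFIED] = len(GROUP_HIERARCHY)
    records, _ = generate_corpus(SyntheticConfig(n_records=120, seed=13, distractor_level="heavy"))
    before = classify_corpus(records, dx_lex, site_lex)
    for r in records:
        r.diagnosis_text = r.diagnosis_text + " Malignant cells present."
    after = classify_corpus(records, dx_lex, site_lex)
    for b, a in zip(before, after):
        assert sev[a.exclusive_group] <= sev[b.exclusive_group]


@pytest.fixture(scope="module")
def classified(dx_lex, site_lex):
    from mlnqa.synthetic import SyntheticConfig, generate_corpus

    records, truth = generate_corpus(SyntheticConfig(n_records=300, seed=21))
    return classify_corpus(records, dx_lex, site_lex), truth


class TestAudit:
    def test_seeded_sample_reproducible(self, classified):
        cls, _ = classified
        a = audit_sample(cls, 50, seed=42)
        b = audit_sample(cls, 50, seed=42)
        assert list(a["specimen_id"]) == list(b["specimen_id"])

    def test_oversized_sample_rejected(self, classified):
        cls, _ = classified
        with pytest.raises(ValueError):
            audit_sample(cls, 301, seed=0)

    def test_all_correct_verdicts_give_full_accuracy(self, classified):
        cls, _ = classified
        ws = audit_sample(cls, 40, seed=1)
        ws["verdict_category"] = "correct"
        out = audit_summary(ws)
        assert out["percent_correct"] == 100.0
        assert out["percent_categorized"] == 100.0

    def test_accuracy_equals_truth_comparison(self, classified):
        cls, truth = classified
        acc = audit_against_truth(cls, truth)
        manual = np.mean(
            [c.diagnosis_category == t for c, t in zip(cls, truth["category"])]
        )
        assert acc["percent_category_correct"] == pytest.approx(100 * manual)


def test_classified_frame_columns(dx_lex, site_lex):
    rec = make_record()
    df = classified_frame(classify_corpus([rec], dx_lex, site_lex))
    assert set(df.columns) >= {
        "specimen_id",
        "sps_id",
        "pathologist_id",
        "station",
        "diagnosis_category",
        "exclusive_group",
        "changed_by_addendum",
    }
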