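"""BRAT parsing, B/I/O conversion, corpus statistics, kappa and splits."""

import numpy as np
import pytest

from clinseg.corpus import (
    AnnotatedDocument,
    AnnotationIntegrityError,
    BratParseError,
    SpanAnnotation,
    classify_termination,
    cohens_kappa,
    read_brat,
    split_corpus,
    tag_distribution_from_counts,
    termination_stats,
    termination_stats_from_counts,
    to_bio,
    write_brat,
)

# Tag tallies of the two corpora the task was designed around, as printed.
MIMIC_TAG_COUNTS = {"B": 23_648, "I": 200_272, "O": 91_877}
FV_TAG_COUNTS = {"B": 43_636, "I": 336_018, "O": 35_458}
MIMIC_TERMINATION_COUNTS = {
    "period": 12_698,
    "exclamation": 4,
    "question": 24,
    "semicolon": 48,
    "colon": 4_855,
    "quotation": 4,
    "none": 6_018,
}


# ---------------------------------------------------------------------------
# BRAT standoff


def _write_pair(tmp_path, text, ann_lines):
    txt = tmp_path / "doc.txt"
    ann = tmp_path / "doc.ann"
    txt.write_text(text, encoding="utf-8")
    ann.write_text("\n".join(ann_lines) + "\n", encoding="utf-8")
    return ann, txt


def test_read_brat_parses_sentence_and_unsure(tmp_path):
    text = "Diet: thin liquids\nWBC 11.2 HGB 9\n"
    ann, txt = _write_pair(
        tmp_path,
        text,
        ["T1\tSentence 0 18\tDiet: thin liquids", "T2\tUnsure 19 33\tWBC 11.2 HGB 9"],
    )
    doc = read_brat(ann, txt)
    assert [(a.label, a.begin, a.end) for a in doc.annotations] == [
        ("Sentence", 0, 18),
        ("Unsure", 19, 33),
    ]


def test_read_brat_text_mismatch_is_integrity_error(tmp_path):
    ann, txt = _write_pair(tmp_path, "Diet: thin liquids\n", ["T1\tSentence 0 5\tWRONG"])
    with pytest.raises(AnnotationIntegrityError):
        read_brat(ann, txt)


def test_read_brat_malformed_line_names_line_number(tmp_path):
    ann, txt = _write_pair(tmp_path, "abc\n", ["T1\tSentence zero 3\tabc"])
    with pytest.raises(BratParseError, match=":1:"):
        read_brat(ann, txt)


def test_read_brat_skips_foreign_labels_with_warning(tmp_path):
    ann, txt = _write_pair(
        tmp_path, "abc def\n", ["T1\tSentence 0 3\tabc", "T2\tOther 4 7\tdef"]
    )
    with pytest.warns(UserWarning, match="Other"):
        doc = read_brat(ann, txt)
    assert len(doc.annotations) == 1


def test_brat_round_trip_preserves_spans(tmp_path, small_corpus):
    for doc in small_corpus[:3]:
        write_brat(doc, tmp_path)
        back = read_brat(tmp_path / f"{doc.doc_id}.ann", tmp_path / f"{doc.doc_id}.txt")
        assert back.text == doc.text
        assert {(a.label, a.begin, a.end) for a in back.annotations} == {
            (a.label, a.begin, a.end) for a in doc.annotations
        }


# ---------------------------------------------------------------------------
# B/I/O conversion


def test_to_bio_single_sentence():
    text = "Diet: thin liquids"
    doc = AnnotatedDocument("d", text, [SpanAnnotation("Sentence", 0, len(text), text)])
    assert to_bio(doc).tags == ["B", "I", "I", "I"]


def test_to_bio_unsure_rows_are_o():
    text = "120 / 80"
    doc = AnnotatedDocument("d", text, [SpanAnnotation("Unsure", 0, len(text), text)])
    assert to_bio(doc).tags == ["O"] * 6  # tokens: 1, 2, 0, /, 8, 0


def test_to_bio_two_sentences():
    text = "Plan:\nContinue meds"
    doc = AnnotatedDocument(
        "d",
        text,
        [
            SpanAnnotation("Sentence", 0, 5, "Plan:"),
            SpanAnnotation("Sentence", 6, 19, "Continue meds"),
        ],
    )
    assert to_bio(doc).tags == ["B", "I", "B", "I"]


def test_to_bio_unsure_overrides_sentence_overlap():
    text = "ok 12 34"
    doc = AnnotatedDocument(
        "d",
        text,
        [
            SpanAnnotation("Sentence", 0, 8, text),
            SpanAnnotation("Unsure", 3, 8, "12 34"),
        ],
    )
    assert to_bio(doc).tags == ["B", "O", "O", "O", "O"]


def test_to_bio_b_count_matches_token_bearing_spans(small_corpus):
    for doc in small_corpus:
        seq = to_bio(doc)
        n_b = seq.tags.count("B")
        assert n_b == len(doc.spans("Sentence"))


# ---------------------------------------------------------------------------
# Corpus statistics worked examples


def test_tag_distribution_totals_and_percentages():
    mimic = tag_distribution_from_counts(MIMIC_TAG_COUNTS)
    assert mimic.total == 315_797
    assert mimic.percentages == {"B": 7.5, "I": 63.4, "O": 29.1}
    fv = tag_distribution_from_counts(FV_TAG_COUNTS)
    assert fv.total == 415_112
    assert fv.percentages == {"B": 10.5, "I": 80.9, "O": 8.5}
    tiny = tag_distribution_from_counts({"B": 1, "I": 1})
    assert tiny.percentages == {"B": 50.0, "I": 50.0}
    with pytest.raises(ValueError):
        tag_distribution_from_counts({"B": 0, "I": 0})


def test_termination_percentages_reproduce_printed_table():
    stats = termination_stats_from_counts(MIMIC_TERMINATION_COUNTS)
    assert stats.total == 23_651
    assert stats.percentages["period"] == 53.7
    assert stats.percentages["none"] == 25.4
    assert stats.percentages["colon"] == 20.5
    assert stats.percentages["question"] == 0.1
    assert stats.percentages["semicolon"] == 0.2


def test_termination_classification_and_single_item():
    assert classify_termination("Plan:") == "colon"
    assert classify_termination('he said "ok"') == "quotation"
    assert classify_termination("no symbol here") == "none"
    assert classify_termination("done.  ") == "period"
    doc = AnnotatedDocument("d", "Plan:", [SpanAnnotation("Sentence", 0, 5, "Plan:")])
    assert termination_stats([doc]).percentages["colon"] == 100.0


# ---------------------------------------------------------------------------
# Cohen's kappa


def _kappa_oracle(a, b):
    """Brute-force confusion-matrix kappa."""
    labels = sorted(set(a) | set(b))
    n = len(a)
    idx = {l: i for i, l in enumerate(labels)}
    conf = np.zeros((len(labels), len(labels)))
    for x, y in zip(a, b):
        conf[idx[x], idx[y]] += 1
    p_o = np.trace(conf) / n
    p_e = float(np.sum(conf.sum(1) * conf.sum(0))) / n**2
    return (p_o - p_e) / (1 - p_e)


def test_kappa_perfect_agreement():
    assert cohens_kappa(["B", "I", "B"], ["B", "I", "B"]) == pytest.approx(1.0)


def test_kappa_zero_example():
    assert cohens_kappa(["B", "B", "I", "I"], ["B", "I", "B", "I"]) == pytest.approx(0.0)


def test_kappa_matches_brute_force_oracle(rng):
    for _ in range(20):
        a = list(rng.choice(["B", "I", "O"], size=100))
        b = list(rng.choice(["B", "I", "O"], size=100))
        assert cohens_kappa(a, b) == pytest.approx(_kappa_oracle(a, b), abs=1e-12)


def test_kappa_o_exclusion_drops_positions():
    a = ["B", "O", "I", "I"]
    b = ["B", "I", "O", "I"]
    # after dropping positions where either annotator said O: [B,I] vs [B,I]
    assert cohens_kappa(a, b, exclude={"O"}) == pytest.approx(1.0)


def test_kappa_errors():
    with pytest.raises(ValueError):
        cohens_kappa(["B"], ["B", "I"])
    with pytest.raises(ZeroDivisionError):
        cohens_kappa(["B", "B"], ["B", "B"])


# ---------------------------------------------------------------------------
# Splits


def _docs(n):
    return [AnnotatedDocument(f"d{i}", "x", []) for i in range(n)]


def test_split_cv_only_80_20():
    splits = split_corpus(_docs(100), "cv_only", seed=1)
    assert len(splits["train"]) == 80
    assert len(splits["validation"]) == 20
    assert not splits["test"]


def test_split_cv_plus_holdout_40_10_50():
    splits = split_corpus(_docs(100), "cv_plus_holdout", seed=1)
    assert len(splits["train"]) == 40
    assert len(splits["validation"]) == 10
    assert len(splits["test"]) == 50


def test_split_is_deterministic_partition():
    docs = _docs(37)
    a = split_corpus(docs, "cv_plus_holdout", seed=9)
    b = split_corpus(docs, "cv_plus_holdout", seed=9)
    for key in a:
        assert [d.doc_id for d in a[key]] == [d.doc_id for d in b[key]]
    ids = [d.doc_id for part in a.values() for d in part]
    assert sorted(ids) == sorted(d.doc_id for d in docs)


def test_split_too_few_documents():
    with pytest.raises(ValueError):
        split_corpus(_docs(1), "cv_only", seed=0)
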