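"""Query parsing, term matching, evaluation, and the indexed fast path."""

import re

import numpy as np
import pytest

from filterforge.corpus_model import LabeledCorpus, MeshHeading, Record, Subheading
from filterforge.query_engine import (
    ConfusionMatrix,
    CorpusIndex,
    Query,
    QueryParseError,
    TermQuery,
    evaluate,
    match_term,
    parse_query,
)

from conftest import make_corpus


# --- independent matching oracle (naive, reimplemented from the field
# definitions; deliberately shares no code with the engine) -----------------

def _toks(text):
    return [t.lower() for t in re.findall(r"[A-Za-z0-9]+", text)]


def oracle_match(term: TermQuery, rec: Record) -> bool:
    def tok_hit(tokens):
        words = term.pattern.split()
        if len(words) == 1:
            return any(
                t.startswith(term.pattern) if term.truncated else t == term.pattern
                for t in tokens
            )
        for i in range(len(tokens) - len(words) + 1):
            win = tokens[i : i + len(words)]
            head_ok = win[:-1] == words[:-1]
            tail_ok = (
                win[-1].startswith(words[-1]) if term.truncated else win[-1] == words[-1]
            )
            if head_ok and tail_ok:
                return True
        return False

    def cmp(s):
        s = s.lower()
        return s.startswith(term.pattern) if term.truncated else s == term.pattern

    mh = any(cmp(h.descriptor) for h in rec.mesh)
    majr = any(cmp(h.descriptor) for h in rec.mesh if h.is_major)
    sh = any(cmp(s.name) for h in rec.mesh for s in h.subheadings)
    tiab = tok_hit(_toks(rec.title + " " + rec.abstract))
    ti = tok_hit(_toks(rec.title))
    return {
        "tiab": tiab, "ti": ti, "mh": mh, "majr": majr, "sh": sh,
        "tw": tiab or mh or sh, "all": tiab or mh or sh,
    }[term.field]


class TestParseQuery:
    def test_table_style_mesh_or_truncated_tiab(self):
        q = parse_query('"Patient Preference"[mesh] OR Preferen*[tiab]')
        assert q.terms == (
            TermQuery("patient preference", False, "mh"),
            TermQuery("preferen", True, "tiab"),
        )

    def test_bare_single_word(self):
        q = parse_query("Logit")
        assert q.terms == (TermQuery("logit", False, "all"),)

    def test_field_tag_binds_to_preceding_term_only(self):
        q = parse_query("Elicit* OR Choice* OR Prescrib*[tiab]")
        assert [t.field for t in q.terms] == ["all", "all", "tiab"]
        assert all(t.truncated for t in q.terms)

    def test_curly_quotes_and_space_before_bracket(self):
        q = parse_query("“Choice Behavior” [Mesh]")
        assert q.terms == (TermQuery("choice behavior", False, "mh"),)

    @pytest.mark.parametrize("alias,field", [("Mesh", "mh"), ("mh", "mh"), ("MeSH major topic", "majr")])
    def test_field_aliases(self, alias, field):
        q = parse_query(f'"Patient Preference"[{alias}]')
        assert q.terms[0].field == field

    @pytest.mark.parametrize(
        "bad", ["Logit[xyz]", '"unbalanced[tiab]', "two words", "", "   ", "OR", "*[tiab]"]
    )
    def test_malformed_queries_rejected_with_position(self, bad):
        with pytest.raises(QueryParseError):
            parse_query(bad)

    def test_duplicate_terms_normalized_away(self):
        q = parse_query("Logit OR logit OR LOGIT")
        assert len(q.terms) == 1


class TestMatchTerm:
    REC = Record(
        "1",
        "Eliciting patient choices",
        abstract="We measured stated preferences for outcomes.",
        mesh=[
            MeshHeading("Middle Aged", False, ()),
            MeshHeading("Patient Preference", True, (Subheading("psychology", False),)),
        ],
    )

    def test_truncated_prefix_matches_abstract_token(self):
        assert match_term(TermQuery("preferen", True, "tiab"), self.REC)

    def test_whole_token_equality_no_substring(self):
        assert not match_term(TermQuery("preferen", False, "tiab"), self.REC)

    def test_mesh_descriptor_mismatch(self):
        rec = Record("2", "T.", mesh=[MeshHeading("Patient Satisfaction")])
        assert not match_term(TermQuery("patient preference", False, "mh"), rec)

    def test_mesh_equality_case_insensitive(self):
        assert match_term(TermQuery("middle aged", False, "mh"), self.REC)

    def test_majr_requires_major_flag(self):
        assert match_term(TermQuery("patient preference", False, "majr"), self.REC)
        assert not match_term(TermQuery("middle aged", False, "majr"), self.REC)

    def test_subheading_field(self):
        assert match_term(TermQuery("psychology", False, "sh"), self.REC)

    def test_ti_restricted_to_title(self):
        assert match_term(TermQuery("choices", False, "ti"), self.REC)
        assert not match_term(TermQuery("preferences", False, "ti"), self.REC)

    def test_tw_covers_text_mesh_and_subheadings(self):
        assert match_term(TermQuery("middle aged", False, "tw"), self.REC)
        assert match_term(TermQuery("psychology", False, "tw"), self.REC)
        assert match_term(TermQuery("outcomes", False, "tw"), self.REC)

    def test_phrase_requires_consecutive_tokens(self):
        rec = Record("3", "patient reported preference")
        assert not match_term(TermQuery("patient preference", False, "tiab"), rec)


class TestEvaluate:
    def test_query_matching_nothing(self, small_corpus):
        cm = evaluate(Query((TermQuery("zzzznothing", False, "all"),)), small_corpus)
        assert (cm.A, cm.B) == (0, 0)
        assert cm.C == small_corpus.n_relevant
        assert cm.total == len(small_corpus)

    def test_query_matching_everything(self, small_corpus):
        # every token prefix-matches the empty-ish wildcard built from "a"..."z"
        terms = tuple(TermQuery(c, True, "tiab") for c in "abcdefghijklmnopqrstuvwxyz0123456789")
        cm = evaluate(Query(terms), small_corpus)
        assert (cm.C, cm.D) == (0, 0)
        assert cm.A == small_corpus.n_relevant

    def test_record_order_invariance(self, small_corpus):
        q = Query((TermQuery("preferen", True, "tiab"), TermQuery("logit", False, "all")))
        reversed_corpus = LabeledCorpus(
            records=list(reversed(small_corpus.records)), labels=small_corpus.labels
        )
        assert evaluate(q, small_corpus) == evaluate(q, reversed_corpus)

    @pytest.mark.parametrize("seed", range(10))
    def test_against_brute_force_oracle(self, seed):
        """evaluate() equals a per-record naive reimplementation."""
        corpus = make_corpus(seed=seed, n_records=20, n_relevant=3)
        rng = np.random.default_rng(seed + 1000)
        for _ in range(5):
            q = _random_query(rng)
            got = evaluate(q, corpus)
            want = _oracle_confusion(q, corpus)
            assert got == want, str(q)


def _random_query(rng) -> Query:
    from conftest import MESH_POOL, WORDS

    n_terms = int(rng.integers(1, 4))
    terms = []
    for _ in range(n_terms):
        field = str(rng.choice(["all", "tw", "tiab", "ti", "mh", "majr", "sh"]))
        if field in ("mh", "majr"):
            pattern = str(rng.choice(MESH_POOL)).lower()
            trunc = False
        elif field == "sh":
            pattern = str(rng.choice(["psychology", "therapy", "methods"]))
            trunc = False
        else:
            word = str(rng.choice(WORDS))
            trunc = bool(rng.random() < 0.5)
            pattern = word[: int(rng.integers(3, len(word) + 1))] if trunc else word
        terms.append(TermQuery(pattern, trunc, field))
    return Query(tuple(terms))


def _oracle_confusion(q: Query, corpus: LabeledCorpus) -> ConfusionMatrix:
    a = b = c = d = 0
    for rec in corpus.records:
        hit = any(oracle_match(t, rec) for t in q.terms)
        rel = corpus.labels[rec.record_id]
        a += hit and rel
        b += hit and not rel
        c += (not hit) and rel
        d += (not hit) and not rel
    return ConfusionMatrix(a, b, c, d)


class TestCorpusIndex:
    @pytest.mark.parametrize("seed", range(8))
    def test_index_equals_per_record_evaluation(self, seed):
        corpus = make_corpus(seed=seed, n_records=30, n_relevant=5)
        index = CorpusIndex(corpus)
        rng = np.random.default_rng(seed)
        for _ in range(8):
            q = _random_query(rng)
            assert index.evaluate(q) == evaluate(q, corpus), str(q)

    def test_identical_match_sets_identical_matrices(self, small_corpus):
        index = CorpusIndex(small_corpus)
        q1 = parse_query("Preferen*[tiab] OR Logit")
        q2 = parse_query("Logit OR Preferen*[tiab]")
        assert index.evaluate(q1) == index.evaluate(q2)


class TestOrMonotonicity:
    @pytest.mark.parametrize("seed", range(10))
    def test_adding_a_term_never_reduces_retrieval(self, seed):
        corpus = make_corpus(seed=seed, n_records=25, n_relevant=5)
        rng = np.random.default_rng(seed + 500)
        for _ in range(5):
            q = _random_query(rng)
            extra = _random_query(rng).terms[0]
            base = evaluate(q, corpus)
            grown = evaluate(q.with_term(extra), corpus)
            assert grown.A >= base.A
            assert grown.B >= base.B


class TestInvariantErrors:
    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            Query(())

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            evaluate(Query((TermQuery("x", False, "all"),)), LabeledCorpus([], {}))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(-1, 0, 0, 0)
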