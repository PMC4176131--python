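"""Rule-based annotation of clinical notes.

Turns free-text notes into a timestamped patient–feature matrix in three
passes:

1. :func:`match_terms` — case-insensitive exact string matching of lexicon
   terms at word boundaries, longest-match-first;
2. :func:`apply_context` — negation and family-history attribution with
   small, fixed trigger lists in the style of NegEx / ConText;
3. :func:`build_matrix` — first affirmative (non-negated, non-family) mention
   date per patient and concept, plus first family-attributed mention date.

Trigger vocabularies are deliberately compact and fully enumerated below so
that annotation is reproducible bit-for-bit.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .lexicon import Lexicon

# --------------------------------------------------------------------------
# Context rule tables (NegEx/ConText-style, fixed and documented)
# --------------------------------------------------------------------------

#: Negation triggers occurring before a mention (within NEGATION_WINDOW tokens,
#: same sentence).
PRE_NEGATION_TRIGGERS = (
    ("no", "evidence", "of"),
    ("no", "known"),
    ("negative", "for"),
    ("denies",),
    ("without",),
    ("nkda",),
    ("not",),
    ("no",),
)

#: Negation triggers occurring after a mention.
POST_NEGATION_TRIGGERS = (
    ("was", "ruled", "out"),
    ("unlikely",),
)

#: Longer phrases that *contain* a trigger but do not negate.
PSEUDO_TRIGGERS = (
    ("no", "increase"),
    ("not", "only"),
)

#: Tokens that terminate a negation scope between trigger and mention.
SCOPE_TERMINATORS = frozenset({"but", "however", "although", "except", "though"})

#: Family-history triggers; any occurrence before the mention in the same
#: sentence attributes it to a relative.
FAMILY_TRIGGERS = (
    ("family", "history", "of"),
    ("mother",),
    ("father",),
    ("sibling",),
    ("brother",),
    ("sister",),
    ("fhx",),
)

#: Maximum token distance between a negation trigger and the mention.
NEGATION_WINDOW = 6

_SENTENCE_SPLIT = re.compile(r"[.!?\n]")
_TOKEN = re.compile(r"[a-z0-9]+(?:['][a-z0-9]+)?")


@dataclass(frozen=True)
class ClinicalNote:
    """One dictated note: free text with a patient id and timestamp."""

    patient_id: str
    note_id: str
    date: dt.date
    text: str


@dataclass(frozen=True)
class CodedEncounter:
    """One coded visit: a single dotted ICD-9 code on a date."""

    patient_id: str
    date: dt.date
    icd9: str


@dataclass(frozen=True)
class TermMention:
    """One lexicon hit inside one note (0-based half-open char span)."""

    patient_id: str
    note_id: str
    note_date: dt.date
    term: str
    concept_id: str
    start: int
    end: int
    negated: bool = False
    family: bool = False


class AnnotationError(ValueError):
    pass


# --------------------------------------------------------------------------
# Term matching
# --------------------------------------------------------------------------

_matcher_cache: dict[tuple, tuple[re.Pattern, dict[str, str]]] = {}


def _compiled_matcher(lexicon: Lexicon) -> tuple[re.Pattern, dict[str, str]]:
    key = tuple(
        (name, ts.terms, ts.concept_id) for name, ts in sorted(lexicon.term_sets.items())
    )
    if key not in _matcher_cache:
        t2c = lexicon.term_to_concept(expand=True)
        # Longest alternative first so the overlapping-candidate scan prefers
        # the longest term starting at each position.
        alts = sorted(t2c, key=lambda t: (-len(t), t))
        body = "|".join(re.escape(t) for t in alts)
        pat = re.compile(rf"(?=\b({body})\b)", re.IGNORECASE)
        _matcher_cache[key] = (pat, t2c)
    return _matcher_cache[key]


def match_terms(note: ClinicalNote, lexicon: Lexicon) -> list[TermMention]:
    """All lexicon term hits in ``note``, flags unset.

    Matching is case-insensitive and word-boundary anchored; overlapping
    candidates are resolved longest-match-first, then leftmost.  Multi-word
    terms match across single spaces only (the lexicon stores them that way).
    """
    pattern, t2c = _compiled_matcher(lexicon)
    candidates = []
    for m in pattern.finditer(note.text):
        term = m.group(1).lower()
        start = m.start(1)
        candidates.append((-(len(term)), start, term))
    taken: list[tuple[int, int]] = []
    mentions = []
    for neglen, start, term in sorted(candidates):
        end = start - neglen
        if any(s < end and start < e for s, e in taken):
            continue  # inside or overlapping a longer accepted match
        taken.append((start, end))
        mentions.append(
            TermMention(
                note.patient_id, note.note_id, note.date,
                term, t2c[term], start, end,
            )
        )
    mentions.sort(key=lambda m: m.start)
    return mentions


# --------------------------------------------------------------------------
# Negation / family context
# --------------------------------------------------------------------------

def _sentences(text: str) -> list[tuple[int, int]]:
    spans = []
    start = 0
    for m in _SENTENCE_SPLIT.finditer(text):
        spans.append((start, m.start()))
        start = m.end()
    spans.append((start, len(text)))
    return [(s, e) for s, e in spans if e > s]


def _match_trigger_at(tokens: Sequence[str], i: int,
                      triggers: Iterable[tuple[str, ...]]) -> tuple[str, ...] | None:
    for trig in triggers:
        if tuple(tokens[i:i + len(trig)]) == trig:
            return trig
    return None


def _is_pseudo(tokens: Sequence[str], i: int) -> bool:
    return _match_trigger_at(tokens, i, PSEUDO_TRIGGERS) is not None


def apply_context(mentions: Sequence[TermMention], note_text: str) -> list[TermMention]:
    """Set ``negated`` and ``family`` flags on mentions from this note's text.

    Negation: a pre-trigger within :data:`NEGATION_WINDOW` tokens before the
    mention in the same sentence (scope cut by ``but``/``however``/...), or a
    post-trigger within the window after it.  Pseudo-triggers ("no increase",
    "not only") block.  Family: a family trigger anywhere before the mention
    in the same sentence.  Sentences break at ``. ! ?`` and newlines.
    """
    lowered = note_text.lower()
    for m in mentions:
        if lowered[m.start:m.end] != m.term:
            raise AnnotationError(
                f"mention {m.term!r} at {m.start}:{m.end} does not match this text"
            )
    sent_spans = _sentences(note_text)
    # tokenize each sentence once with char offsets
    sent_tokens: list[list[tuple[str, int, int]]] = []
    for s, e in sent_spans:
        toks = [(t.group(0), s + t.start(), s + t.end())
                for t in _TOKEN.finditer(lowered[s:e])]
        sent_tokens.append(toks)

    out = []
    for m in mentions:
        si = next(
            (i for i, (s, e) in enumerate(sent_spans) if s <= m.start and m.end <= e),
            None,
        )
        if si is None:  # mention crosses a sentence boundary: leave flags unset
            out.append(m)
            continue
        toks = sent_tokens[si]
        words = [w for w, _, _ in toks]
        first = next((i for i, (_, ts, _) in enumerate(toks) if ts >= m.start), len(toks))
        last = next((i for i in range(len(toks) - 1, -1, -1) if toks[i][2] <= m.end), -1)

        negated = False
        for i in range(max(0, first - NEGATION_WINDOW), first):
            trig = _match_trigger_at(words, i, PRE_NEGATION_TRIGGERS)
            if trig is None or _is_pseudo(words, i):
                continue
            between = words[i + len(trig):first]
            if not any(w in SCOPE_TERMINATORS for w in between):
                negated = True
                break
        if not negated:
            for i in range(last + 1, min(len(words), last + 1 + NEGATION_WINDOW)):
                trig = _match_trigger_at(words, i, POST_NEGATION_TRIGGERS)
                if trig is not None and not _is_pseudo(words, i):
                    if not any(w in SCOPE_TERMINATORS for w in words[last + 1:i]):
                        negated = True
                        break

        family = any(
            _match_trigger_at(words, i, FAMILY_TRIGGERS) is not None
            for i in range(first)
        )
        out.append(replace(m, negated=negated, family=family))
    return out


def annotate_note(note: ClinicalNote, lexicon: Lexicon) -> list[TermMention]:
    """Match + context for one note (notes are independent of each other)."""
    return apply_context(match_terms(note, lexicon), note.text)


def annotate_corpus(notes: Iterable[ClinicalNote], lexicon: Lexicon) -> list[TermMention]:
    out: list[TermMention] = []
    for note in notes:
        out.extend(annotate_note(note, lexicon))
    return out


# --------------------------------------------------------------------------
# Patient–feature matrix
# --------------------------------------------------------------------------

@dataclass
class PatientFeatureMatrix:
    """First-mention timestamps per (patient, concept).

    ``first_affirmative`` holds the earliest non-negated, non-family mention
    date; ``family_first`` the earliest family-attributed non-negated date.
    """

    patients: list[str]
    concepts: list[str]
    first_affirmative: dict[tuple[str, str], dt.date]
    family_first: dict[tuple[str, str], dt.date]

    def affirmative_date(self, patient_id: str, concept: str) -> dt.date | None:
        return self.first_affirmative.get((patient_id, concept))

    def family_date(self, patient_id: str, concept: str) -> dt.date | None:
        return self.family_first.get((patient_id, concept))

    def has_affirmative(self, patient_id: str, concept: str) -> bool:
        return (patient_id, concept) in self.first_affirmative

    def to_frame(self):
        """Wide patients × concepts table of ISO first-affirmative dates
        (empty string where a concept was never affirmed)."""
        import pandas as pd

        data = {
            c: [
                (self.first_affirmative.get((p, c)) or "")
                and self.first_affirmative[(p, c)].isoformat()
                for p in self.patients
            ]
            for c in self.concepts
        }
        return pd.DataFrame(data, index=self.patients, columns=self.concepts)


def build_matrix(mentions: Iterable[TermMention], patients: Sequence[str]) -> PatientFeatureMatrix:
    """Reduce mentions to first-date maps over a fixed patient universe."""
    known = set(patients)
    first_aff: dict[tuple[str, str], dt.date] = {}
    family_first: dict[tuple[str, str], dt.date] = {}
    concepts: set[str] = set()
    for m in mentions:
        if m.patient_id not in known:
            raise AnnotationError(f"unknown patient id {m.patient_id!r}")
        concepts.add(m.concept_id)
        if m.negated:
            continue
        key = (m.patient_id, m.concept_id)
        if m.family:
            if key not in family_first or m.note_date < family_first[key]:
                family_first[key] = m.note_date
        else:
            if key not in first_aff or m.note_date < first_aff[key]:
                first_aff[key] = m.note_date
    return PatientFeatureMatrix(list(patients), sorted(concepts), first_aff, family_first)


# --------------------------------------------------------------------------
# Evaluation against generator ground truth
# --------------------------------------------------------------------------

def evaluate_against_truth(mentions: Sequence[TermMention],
                           truth_mentions: Sequence) -> dict[str, float]:
    """Mention-level precision/recall and flag accuracies vs ground truth.

    Mentions are keyed by (note_id, start, end, concept); flag accuracy is
    computed over the matched pairs.  Empty truth and empty prediction give
    1.0 by convention.
    """
    pred = {(m.note_id, m.start, m.end, m.concept_id): m for m in mentions}
    true = {(t.note_id, t.start, t.end, t.concept_id): t for t in truth_mentions}
    pred_notes = {m.note_id for m in mentions}
    true_notes = {t.note_id for t in truth_mentions}
    if true_notes and pred_notes and not (true_notes & pred_notes):
        raise AnnotationError("prediction and truth cover disjoint note ids")
    matched = set(pred) & set(true)
    recall = len(matched) / len(true) if true else 1.0
    precision = len(matched) / len(pred) if pred else 1.0
    if matched:
        neg_acc = sum(pred[k].negated == true[k].negated for k in matched) / len(matched)
        fam_acc = sum(pred[k].family == true[k].family for k in matched) / len(matched)
    else:
        neg_acc = fam_acc = 1.0
    return {
        "recall": recall,
        "precision": precision,
        "negation_accuracy": neg_acc,
        "family_accuracy": fam_acc,
    }


def mentions_to_rows(mentions: Iterable[TermMention]) -> list[dict]:
    """TSV-ready row dicts (patient_id, note_id, date, term, concept, span, flags)."""
    return [
        {
            "patient_id": m.patient_id,
            "note_id": m.note_id,
            "date": m.note_date.isoformat(),
            "term": m.term,
            "concept": m.concept_id,
            "start": m.start,
            "end": m.end,
            "negated": int(m.negated),
            "family": int(m.family),
        }
        for m in mentions
    ]
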