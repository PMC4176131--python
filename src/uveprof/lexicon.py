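"""Controlled vocabulary for the JIA / chronic-uveitis profiling pipeline.

The pipeline identifies patients and risk factors from two coordinated
vocabularies:

* ICD-9 code sets — juvenile idiopathic arthritis (JIA) billing codes and the
  acute (364.0x) / chronic (364.1x) uveitis code families;
* term sets — lowercase strings dictated in clinical notes, each normalising
  to a single concept label (diagnosis-confirmation terms, risk-factor terms,
  allergy-medication names, and residual concepts used only in clustering).

The packaged default reproduces the study vocabulary; a user may supply an
edited copy in the same sectioned key-value format (see ``DEFAULT_LEXICON``).
"""

from __future__ import annotations

import configparser
import re
from dataclasses import dataclass, field
from pathlib import Path


class LexiconError(ValueError):
    """Raised when a lexicon file is malformed."""


_CODE_RE = re.compile(r"^\d{3}(?:\.\d{0,2})?$")

#: Factor concepts examined in the association analysis (order = reporting order).
ANALYSIS_FACTORS = (
    "ana_positive",
    "oligoarticular",
    "psoriasis",
    "rf_positive",
    "allergy_terms",
    "allergy_drug",
    "sinusitis",
)


@dataclass(frozen=True)
class CodeSet:
    """A named family of ICD-9 codes in dotted form.

    ``match_mode='prefix'`` lets a 4-digit root such as ``364.1`` match its
    5-digit children (``364.10`` ... ``364.19``).
    """

    name: str
    codes: frozenset[str]
    match_mode: str = "exact"  # 'exact' | 'prefix'

    def __post_init__(self) -> None:
        if self.match_mode not in ("exact", "prefix"):
            raise LexiconError(f"{self.name}: bad match_mode {self.match_mode!r}")
        for code in self.codes:
            if not _CODE_RE.match(code):
                raise LexiconError(f"{self.name}: malformed ICD-9 code {code!r}")


@dataclass(frozen=True)
class TermSet:
    """Lowercase terms that all normalise to ``concept_id``."""

    name: str
    terms: tuple[str, ...]
    concept_id: str

    def __post_init__(self) -> None:
        seen = set()
        for t in self.terms:
            if not t or t != t.strip() or t != t.lower():
                raise LexiconError(f"{self.name}: term {t!r} not lowercase/stripped")
            if t in seen:
                raise LexiconError(f"{self.name}: duplicate term {t!r}")
            seen.add(t)
        if not self.terms:
            raise LexiconError(f"{self.name}: empty term set")


@dataclass(frozen=True)
class DrugLexicon:
    """Brand → generic and generic → class maps for the allergy medications."""

    brand_to_generic: dict[str, str]
    generic_to_class: dict[str, str]

    def generics(self) -> tuple[str, ...]:
        return tuple(sorted(self.generic_to_class))


@dataclass
class Lexicon:
    """The full vocabulary bundle used by the annotator and cohort stages."""

    code_sets: dict[str, CodeSet] = field(default_factory=dict)
    term_sets: dict[str, TermSet] = field(default_factory=dict)
    drugs: DrugLexicon = field(
        default_factory=lambda: DrugLexicon({}, {})
    )

    def term_to_concept(self, expand: bool = True) -> dict[str, str]:
        """Flat term → concept map; raises if a term maps to two concepts."""
        out: dict[str, str] = {}
        for ts in self.term_sets.values():
            ts_x = expand_derivatives(ts) if expand else ts
            for t in ts_x.terms:
                if t in out and out[t] != ts_x.concept_id:
                    raise LexiconError(
                        f"term {t!r} maps to both {out[t]!r} and {ts_x.concept_id!r}"
                    )
                out[t] = ts_x.concept_id
        return out

    def drug_concepts(self) -> tuple[str, ...]:
        return self.drugs.generics()


# ---------------------------------------------------------------------------
# Default vocabulary
# ---------------------------------------------------------------------------
# Sectioned key-value document: [codes.<name>] sections list dotted ICD-9 codes
# (plus a match_mode key); [terms.<name>] sections list one lowercase term per
# line plus a concept key; [drugs] maps brand -> generic; [drug_classes] maps
# generic -> medication class.  Residual term sets (cluster.* concepts) feed
# only the clustering stage and are excluded from cohort selection and the
# association analysis.

DEFAULT_LEXICON = """
[codes.jia]
match_mode = prefix
696.0
714.0
714.2
714.3
714.9
720.2
720.9

[codes.uveitis_acute]
match_mode = prefix
364.0

[codes.uveitis_chronic]
match_mode = prefix
364.1

[terms.jia_confirmation]
concept = jia
juvenile idiopathic arthritis
jia
juvenile rheumatoid arthritis
jra
psoriatic arthritis
juvenile spondyloarthropathy
spondyloarthritis
enthesitis related arthritis
sacroiliitis
reactive arthritis

[terms.uveitis_confirmation]
concept = uveitis
uveitis
iridocyclitis
iritis

[terms.ana_positive]
concept = ana_positive
ana positive
positive ana

[terms.rf_positive]
concept = rf_positive
rheumatoid factor positive
rf positive

[terms.psoriasis]
concept = psoriasis
psoriasis

[terms.oligoarticular]
concept = oligoarticular
oligoarticular
oligo-onset
pauciarticular
pauci-onset
monoarthritis
monoarticular

[terms.allergy_terms]
concept = allergy_terms
allergic
allergy

[terms.sinusitis]
concept = sinusitis
sinusitis

[terms.drug.fluticasone]
concept = fluticasone
flonase
fluticasone

[terms.drug.triamcinolone]
concept = triamcinolone
nasacort
triamcinolone

[terms.drug.fexofenadine]
concept = fexofenadine
allegra
fexofenadine

[terms.drug.cetirizine]
concept = cetirizine
zyrtec
cetirizine

[terms.drug.loratadine]
concept = loratadine
claritin
loratadine

[terms.drug.desloratadine]
concept = desloratadine
clarinex
desloratadine

[terms.drug.diphenhydramine]
concept = diphenhydramine
benadryl
diphenhydramine

[terms.drug.levocetirizine]
concept = levocetirizine
xyzal
levocetirizine

[terms.drug.azelastine]
concept = azelastine
astelin
azelastine

[terms.drug.montelukast]
concept = montelukast
singulair
montelukast

[terms.drug.pseudoephedrine]
concept = pseudoephedrine
sudafed
pseudoephedrine

[terms.cluster.beclomethasone]
concept = beclomethasone
beclomethasone
qvar

[terms.cluster.contact_dermatitis]
concept = contact_dermatitis
contact dermatitis

[terms.cluster.folliculitis]
concept = folliculitis
folliculitis

[terms.cluster.hypersensitivity]
concept = hypersensitivity
hypersensitivity

[terms.cluster.headache]
concept = headache
headache

[terms.cluster.cough]
concept = cough
cough

[terms.cluster.emesis]
concept = emesis
emesis

[terms.cluster.pruritus]
concept = pruritus
pruritus

[terms.cluster.epistaxis]
concept = epistaxis
epistaxis

[drugs]
flonase = fluticasone
nasacort = triamcinolone
allegra = fexofenadine
zyrtec = cetirizine
claritin = loratadine
clarinex = desloratadine
benadryl = diphenhydramine
xyzal = levocetirizine
astelin = azelastine
singulair = montelukast
sudafed = pseudoephedrine

[drug_classes]
fluticasone = nasal steroid
triamcinolone = nasal steroid
fexofenadine = oral antihistamine
cetirizine = oral antihistamine
loratadine = oral antihistamine
desloratadine = oral antihistamine
diphenhydramine = oral antihistamine
levocetirizine = oral antihistamine
azelastine = nasal antihistamine
montelukast = leukotriene inhibitor
pseudoephedrine = decongestant
"""

#: Concepts excluded from the clustering stage (cohort selection + analysis
#: factors); drug generics are appended at load time.
COHORT_AND_ANALYSIS_CONCEPTS = (
    "jia",
    "uveitis",
    "ana_positive",
    "rf_positive",
    "psoriasis",
    "oligoarticular",
    "allergy_terms",
    "sinusitis",
)


# ---------------------------------------------------------------------------
# Derivative expansion
# ---------------------------------------------------------------------------
# "Derivatives" of lexicon terms are produced by a fixed suffix-rule table so
# that matching is reproducible bit-for-bit:
#   plural   — single-word terms of length > 3 not already ending in "s":
#              consonant+"y" -> "ies", otherwise append "s";
#   adjectival — single-word terms ending in "y": replace with "ic"
#              (allergy -> allergic).
# Rules are applied to a fixpoint, so expansion is idempotent by construction.

_VOWELS = set("aeiou")


def _derive(term: str) -> set[str]:
    out: set[str] = set()
    if " " in term or "-" in term:
        return out
    if len(term) > 3 and not term.endswith("s"):
        if term.endswith("y") and term[-2] not in _VOWELS:
            out.add(term[:-1] + "ies")
        else:
            out.add(term + "s")
    if term.endswith("y"):
        out.add(term[:-1] + "ic")
    out.discard(term)
    return out


def expand_derivatives(term_set: TermSet) -> TermSet:
    """Close a term set under the documented suffix rules (idempotent)."""
    terms = set(term_set.terms)
    frontier = set(terms)
    while frontier:
        new = set()
        for t in frontier:
            new |= _derive(t)
        frontier = new - terms
        terms |= new
    ordered = tuple(list(term_set.terms) + sorted(terms - set(term_set.terms)))
    return TermSet(term_set.name, ordered, term_set.concept_id)


# ---------------------------------------------------------------------------
# Code matching
# ---------------------------------------------------------------------------

def code_matches(code: str, code_set: CodeSet) -> bool:
    """True when ``code`` belongs to ``code_set`` under its match mode.

    Prefix mode matches dotted children: ``364.10`` matches a set rooted at
    ``364.1``; exact mode requires string equality.
    """
    if not _CODE_RE.match(code or ""):
        raise LexiconError(f"invalid ICD-9 code {code!r}")
    if code in code_set.codes:
        return True
    if code_set.match_mode == "prefix":
        return any(code.startswith(root) and "." in root for root in code_set.codes)
    return False


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _parse(text: str, source: str) -> Lexicon:
    cp = configparser.ConfigParser(allow_no_value=True, delimiters=("=",))
    cp.optionxform = str.lower  # type: ignore[assignment]
    try:
        cp.read_string(text, source=source)
    except configparser.Error as exc:
        raise LexiconError(f"{source}: {exc}") from exc
    if not cp.sections():
        raise LexiconError(f"{source}: no sections found (empty lexicon)")

    code_sets: dict[str, CodeSet] = {}
    term_sets: dict[str, TermSet] = {}
    brand_to_generic: dict[str, str] = {}
    generic_to_class: dict[str, str] = {}

    for section in cp.sections():
        items = list(cp[section].items())
        if section.startswith("codes."):
            name = section[len("codes."):]
            mode = "exact"
            codes = []
            for key, val in items:
                if key == "match_mode":
                    mode = (val or "").strip()
                else:
                    codes.append(key.strip())
            code_sets[name] = CodeSet(name, frozenset(codes), mode)
        elif section.startswith("terms."):
            name = section[len("terms."):]
            concept = None
            terms = []
            for key, val in items:
                if key == "concept":
                    concept = (val or "").strip()
                else:
                    terms.append(key.strip())
            if not concept:
                raise LexiconError(f"{source}: [{section}] missing concept key")
            term_sets[name] = TermSet(name, tuple(terms), concept)
        elif section == "drugs":
            for brand, generic in items:
                brand_to_generic[brand.strip()] = (generic or "").strip()
        elif section == "drug_classes":
            for generic, cls in items:
                generic_to_class[generic.strip()] = (cls or "").strip()
        else:
            raise LexiconError(f"{source}: unknown section [{section}]")

    lex = Lexicon(
        dict(sorted(code_sets.items())),
        dict(sorted(term_sets.items())),
        DrugLexicon(brand_to_generic, generic_to_class),
    )
    lex.term_to_concept()  # validates the term -> concept relation is a function
    return lex


def load_lexicon(path: str | Path | None = None) -> Lexicon:
    """Load a lexicon file, or the packaged default when ``path`` is omitted.

    Raises :class:`LexiconError` naming the offending entry on malformed input.
    """
    if path is None:
        return _parse(DEFAULT_LEXICON, "<default>")
    p = Path(path)
    return _parse(p.read_text(encoding="utf-8"), str(p))


def excluded_cluster_concepts(lexicon: Lexicon) -> frozenset[str]:
    """Concepts excluded from the clustering stage: cohort-selection terms,
    association-analysis factors, and every allergy-drug generic."""
    return frozenset(COHORT_AND_ANALYSIS_CONCEPTS) | set(lexicon.drug_concepts())
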