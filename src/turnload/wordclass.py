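"""Word classes: content / function / insert, hapax detection, positional profiles.

Tokens are classified from their PoS tag: content words are adjectives,
adverbs, lexical verbs (auxiliaries and modals excluded) and nouns; inserts
are interjections plus the forms "well" and "so" when they carry an adverb
tag (a known tagging quirk in conversational corpora); everything else is a
function word.  Hapax legomena — types occurring exactly once in the counting
universe — proxy maximally novel information and are concentrated in nouns.
"""

from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .corpus import FrequencyTable, TaggedToken, TurnSubset, positioned_words

logger = logging.getLogger(__name__)

WORD_CLASSES = ("content", "function", "insert")
CONTENT_SUBTYPES = ("noun", "adjective", "adverb", "lexical_verb", "none")

#: Pro-forms that typically realise the grammatical subject in conversation:
#: personal pronouns, unattended demonstratives, and existential "there".
DEFAULT_PROFORMS = (
    "i", "you", "he", "she", "it", "we", "they",
    "this", "that", "these", "those", "there",
)

# Ordered tag-pattern rules (first match wins).  The c5 set is the BNC
# five-character tag set; c7 is the finer-grained CLAWS7 set.  Tag lists are
# partial on the function side (the full inventories run to 70 and 138 tags);
# tags matching no rule are admitted as function words with a warning.
_C5_RULES: list[tuple[str, str, str]] = [
    ("AJ*", "content", "adjective"),
    ("AV*", "content", "adverb"),
    ("NN*", "content", "noun"),
    ("NP0", "content", "noun"),
    ("VV*", "content", "lexical_verb"),
    ("ITJ", "insert", "none"),
    # function-word territory: determiners, pronouns, auxiliaries, modals,
    # prepositions, conjunctions, numbers, negation, infinitive marker, etc.
    ("AT0", "function", "none"), ("DT*", "function", "none"),
    ("DPS", "function", "none"), ("EX0", "function", "none"),
    ("PN*", "function", "none"), ("PR*", "function", "none"),
    ("CJ*", "function", "none"), ("CRD", "function", "none"),
    ("ORD", "function", "none"), ("POS", "function", "none"),
    ("TO0", "function", "none"), ("XX0", "function", "none"),
    ("VB*", "function", "none"), ("VD*", "function", "none"),
    ("VH*", "function", "none"), ("VM0", "function", "none"),
    ("PU*", "function", "none"), ("UNC", "function", "none"),
    ("ZZ0", "function", "none"),
]

_C7_RULES: list[tuple[str, str, str]] = [
    ("JJ*", "content", "adjective"),
    ("JK", "content", "adjective"),
    ("R*", "content", "adverb"),
    ("N*", "content", "noun"),
    ("VV*", "content", "lexical_verb"),
    ("UH", "insert", "none"),
    ("A*", "function", "none"), ("D*", "function", "none"),
    ("CC*", "function", "none"), ("CS*", "function", "none"),
    ("EX", "function", "none"), ("GE", "function", "none"),
    ("I*", "function", "none"), ("MC*", "function", "none"),
    ("MD", "function", "none"), ("MF", "function", "none"),
    ("P*", "function", "none"), ("TO", "function", "none"),
    ("X*", "function", "none"), ("VB*", "function", "none"),
    ("VD*", "function", "none"), ("VH*", "function", "none"),
    ("VM*", "function", "none"), ("ZZ*", "function", "none"),
    ("FU", "function", "none"), ("FO", "function", "none"),
]

# Form-specific overrides: (form, tag pattern) -> class.  "well" and "so"
# function as inserts but are tagged as adverbs; the override fires only on
# adverb tags, so e.g. "so" as a conjunction keeps its tag-derived class.
_C5_OVERRIDES: list[tuple[str, str, str, str]] = [
    ("well", "AV*", "insert", "none"),
    ("so", "AV*", "insert", "none"),
]
_C7_OVERRIDES: list[tuple[str, str, str, str]] = [
    ("well", "R*", "insert", "none"),
    ("so", "R*", "insert", "none"),
]


@dataclass
class ClassMap:
    """Ordered tag-pattern -> word-class rules with form-specific overrides.

    ``rules`` is a list of (tag glob pattern, word_class, content_subtype);
    the first matching pattern wins.  ``overrides`` is a list of
    (form, tag pattern, word_class, content_subtype) checked before the tag
    rules.  Tags matching nothing resolve to function words with a warning.
    """

    tagset: str
    rules: list[tuple[str, str, str]]
    overrides: list[tuple[str, str, str, str]] = field(default_factory=list)
    _unknown_seen: set = field(default_factory=set, repr=False)

    @classmethod
    def default(cls, tagset: str = "c7") -> "ClassMap":
        if tagset == "c5":
            return cls(tagset="c5", rules=list(_C5_RULES),
                       overrides=list(_C5_OVERRIDES))
        if tagset == "c7":
            return cls(tagset="c7", rules=list(_C7_RULES),
                       overrides=list(_C7_OVERRIDES))
        raise ValueError(f"no default class map for tagset {tagset!r}")

    def classify(self, form: str, tag: str) -> tuple[str, str]:
        """Resolve a (form, tag) pair to (word_class, content_subtype)."""
        form_cf = form.casefold()
        for o_form, o_pat, o_class, o_sub in self.overrides:
            if form_cf == o_form and fnmatch.fnmatchcase(tag, o_pat):
                return (o_class, o_sub)
        for pat, w_class, sub in self.rules:
            if fnmatch.fnmatchcase(tag, pat):
                return (w_class, sub)
        if tag not in self._unknown_seen:
            self._unknown_seen.add(tag)
            logger.warning(
                "tag %r not covered by the %s class map; treating as function word",
                tag, self.tagset,
            )
        return ("function", "none")

    # --- round-trippable plain-text config -------------------------------
    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "tagset": self.tagset,
            "rules": [list(r) for r in self.rules],
            "overrides": [list(o) for o in self.overrides],
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClassMap":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            tagset=payload["tagset"],
            rules=[tuple(r) for r in payload["rules"]],
            overrides=[tuple(o) for o in payload.get("overrides", [])],
        )


def classify_token(token: TaggedToken, cmap: ClassMap) -> tuple[str, str]:
    """Word class and content subtype of a single tagged token."""
    return cmap.classify(token.form, token.tag)


def classify_frame(df: pd.DataFrame, cmap: ClassMap) -> pd.DataFrame:
    """Add ``word_class`` and ``content_subtype`` columns to a token table."""
    pairs = pd.MultiIndex.from_arrays(
        [df["form"].str.casefold(), df["tag"]]
    ).unique()
    lut = {pair: cmap.classify(*pair) for pair in pairs}
    keyed = list(zip(df["form"].str.casefold(), df["tag"]))
    df = df.copy()
    df["word_class"] = [lut[k][0] for k in keyed]
    df["content_subtype"] = [lut[k][1] for k in keyed]
    return df


def find_hapaxes(table: FrequencyTable) -> set[tuple[str, str]]:
    """Word-tag types with a count of exactly one in the counting universe."""
    return {k for k, c in table.counts.items() if c == 1}


def token_table(
    subset: TurnSubset,
    table: FrequencyTable,
    cmap: ClassMap,
) -> pd.DataFrame:
    """Tidy per-token table with position, frequency, class and hapax status.

    This is the workhorse frame feeding the class profiles, the hapax-noun
    profile and the regression stage.
    """
    df = positioned_words(subset, table)
    df = classify_frame(df, cmap)
    hapaxes = find_hapaxes(table)
    fold = table.case_fold
    keys = [
        (f.casefold() if fold else f, t) for f, t in zip(df["form"], df["tag"])
    ]
    df["is_hapax"] = [k in hapaxes for k in keys]
    return df


def class_position_profile(
    subset: TurnSubset,
    cmap: ClassMap,
    sizes: Sequence[int] | None = None,
    table: FrequencyTable | None = None,
) -> pd.DataFrame:
    """Percentage of each word class per (turn size, position) cell.

    One row per (size, index, word_class); within each (size, index) cell the
    three class percentages sum to 100.  ``sizes`` restricts the profile to
    the requested turn sizes (default: every size present).  Cells for
    requested sizes absent from the subset are flagged with n = 0.
    """
    df = positioned_words(subset)
    df = classify_frame(df, cmap)
    if sizes is None:
        sizes = sorted(df["size"].unique())
    out_rows = []
    present = set(df["size"].unique())
    for size in sizes:
        if size not in present:
            logger.warning("requested turn size %d absent from subset", size)
            for wc in WORD_CLASSES:
                out_rows.append((size, np.nan, np.nan, wc, np.nan, 0))
            continue
        sub = df[df["size"] == size]
        for index, grp in sub.groupby("index"):
            n = len(grp)
            shares = grp["word_class"].value_counts()
            for wc in WORD_CLASSES:
                out_rows.append(
                    (size, index, (index - 1) / (size - 1), wc,
                     100.0 * shares.get(wc, 0) / n, n)
                )
    return pd.DataFrame(
        out_rows,
        columns=["size", "index", "norm_position", "word_class",
                 "percentage", "n"],
    )


def noun_function_insert_profile(
    subset: TurnSubset,
    cmap: ClassMap,
    sizes: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Percentages of nouns, function words and inserts per (size, position).

    The regression-stage variant of the class profile: nouns (not all
    content words) are the class of interest contrasted with function words
    and inserts, each expressed as a share of all tokens at the position.
    Other content words stay in the denominator but are not a modelled
    category, so the three percentages need not sum to 100.
    """
    df = positioned_words(subset)
    df = classify_frame(df, cmap)
    model_class = np.where(
        df["content_subtype"] == "noun", "noun",
        np.where(df["word_class"].isin(["function", "insert"]),
                 df["word_class"], "other"),
    )
    df = df.assign(model_class=model_class)
    if sizes is None:
        sizes = sorted(df["size"].unique())
    out_rows = []
    present = set(df["size"].unique())
    for size in sizes:
        if size not in present:
            logger.warning("requested turn size %d absent from subset", size)
            continue
        sub = df[df["size"] == size]
        for index, grp in sub.groupby("index"):
            n = len(grp)
            shares = grp["model_class"].value_counts()
            for wc in ("noun", "function", "insert"):
                out_rows.append(
                    (size, index, (index - 1) / (size - 1), wc,
                     100.0 * shares.get(wc, 0) / n, n)
                )
    return pd.DataFrame(
        out_rows,
        columns=["size", "index", "norm_position", "word_class",
                 "percentage", "n"],
    )


def class_relative_profile(token_df: pd.DataFrame, n_bins: int = 25) -> pd.DataFrame:
    """Class percentages pooled on a relative-position grid (for plotting)."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(
        np.searchsorted(edges, token_df["norm_position"], side="right") - 1,
        0, n_bins - 1,
    )
    df = token_df.assign(position_bin=which)
    out_rows = []
    for b, grp in df.groupby("position_bin"):
        n = len(grp)
        shares = grp["word_class"].value_counts()
        centre = (edges[b] + edges[b + 1]) / 2
        for wc in WORD_CLASSES:
            out_rows.append((b, centre, wc, 100.0 * shares.get(wc, 0) / n, n))
    return pd.DataFrame(
        out_rows,
        columns=["position_bin", "norm_position", "word_class", "percentage", "n"],
    )


def hapax_noun_profile(
    subset: TurnSubset,
    table: FrequencyTable,
    cmap: ClassMap,
    sizes: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Percentage of hapax nouns out of all words per (size, position) cell.

    Each cell reports 100 x (hapax-noun tokens) / (all tokens at that
    position); the rows carry the cell's normalised position so a polynomial
    trend across relative position can be fitted to the aggregate.
    """
    df = token_table(subset, table, cmap)
    if sizes is not None:
        df = df[df["size"].isin(list(sizes))]
    df = df.assign(
        is_hapax_noun=df["is_hapax"] & (df["content_subtype"] == "noun")
    )
    out = (
        df.groupby(["size", "index"])
        .agg(
            norm_position=("norm_position", "first"),
            percentage=("is_hapax_noun", lambda s: 100.0 * s.mean()),
            n=("is_hapax_noun", "size"),
        )
        .reset_index()
    )
    return out


def proform_early_share(
    subset: TurnSubset,
    proforms: Iterable[str] = DEFAULT_PROFORMS,
    threshold: float = 0.2,
) -> float:
    """Fraction of turns with a pro-form at normalised position <= threshold.

    Positions up to the threshold are the likely subject zone; a high share
    indicates that turns typically carry a pro-form subject rather than a
    full noun phrase.
    """
    proform_set = {p.casefold() for p in proforms}
    if not proform_set:
        raise ValueError("pro-form list must be non-empty")
    n_hit = 0
    for turn in subset:
        n = turn.size
        for i, tok in enumerate(turn.tokens, start=1):
            if (i - 1) / (n - 1) > threshold:
                break
            if tok.form.casefold() in proform_set:
                n_hit += 1
                break
    return n_hit / len(subset.turns) if len(subset) else float("nan")
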