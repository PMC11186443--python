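"""Tagged conversational corpora: turns, size filters, word-tag frequency tables.

The unit of analysis is the turn-at-talk: an ordered sequence of PoS-tagged
grammatical words produced by one speaker.  Frequencies are counted over
word-tag combinations (so ``so_RR`` and ``so_CS`` are distinct types) and
normalised per thousand tokens of the analysis subset.  Word positions within
a turn are mapped onto [0, 1] so that turns of different sizes are comparable.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Columns a vertical transcript file must provide.
VERTICAL_COLUMNS = (
    "conversation_id",
    "turn_id",
    "speaker_id",
    "role",
    "index",
    "form",
    "tag",
)

TAGSETS = ("c5", "c7")


class CorpusFormatError(ValueError):
    """Raised when a vertical transcript file violates the format contract."""


class CorpusIntegrityError(ValueError):
    """Raised when token indices within a turn are not contiguous from 1."""


@dataclass(frozen=True)
class TaggedToken:
    """A word form plus its PoS tag; the unit of frequency counting."""

    form: str
    tag: str

    def __post_init__(self) -> None:
        if not self.form:
            raise ValueError("token form must be non-empty")

    def wordtag_key(self, case_fold: bool = True) -> tuple[str, str]:
        """The (form, tag) pair used as the frequency-counting type."""
        form = self.form.casefold() if case_fold else self.form
        return (form, self.tag)


@dataclass(frozen=True)
class Turn:
    """An ordered token sequence with speaker and conversation identity."""

    conversation_id: str
    turn_id: str
    speaker_id: str
    tokens: tuple[TaggedToken, ...]

    @property
    def size(self) -> int:
        """Turn size: the number of grammatical words."""
        return len(self.tokens)


def count_grammatical_words(tokens: Sequence[TaggedToken]) -> int:
    """Number of grammatical words in a tagged sequence.

    Contractions arrive pre-split by the tagger (``I'm gonna`` is four tagged
    words: ``I_PPIS1 'm_VBM gon_VVGK na_TO``), so the count is simply the
    length of the token sequence.
    """
    return len(tokens)


@dataclass
class TurnSubset:
    """Turns whose sizes fall within configured bounds."""

    turns: list[Turn]
    min_size: int
    max_size: int
    n_input: int

    @property
    def total_tokens(self) -> int:
        return sum(t.size for t in self.turns)

    @property
    def retention(self) -> float:
        """Fraction of input turns retained by the size filter."""
        return len(self.turns) / self.n_input if self.n_input else float("nan")

    def __len__(self) -> int:
        return len(self.turns)

    def __iter__(self):
        return iter(self.turns)


def read_vertical_corpus(
    path: str | Path, tagset: str = "c7"
) -> list[Turn]:
    """Read a tab-separated vertical transcript (one token per row) into turns.

    Rows are grouped by (conversation_id, turn_id) and ordered by the 1-based
    ``index`` column; the file's physical row order is irrelevant.  Indices
    within a turn must be exactly 1..n.

    Parameters
    ----------
    path : file path
        UTF-8 TSV with header columns ``conversation_id, turn_id, speaker_id,
        role, index, form, tag``.
    tagset : {"c5", "c7"}
        Declared tag set; recorded for downstream classification.
    """
    if tagset not in TAGSETS:
        raise ValueError(f"unknown tagset {tagset!r}; expected one of {TAGSETS}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in VERTICAL_COLUMNS if c not in df.columns]
    if missing:
        raise CorpusFormatError(f"{path}: missing column(s) {missing}")
    df["_line"] = np.arange(2, len(df) + 2)  # header is line 1
    bad_form = df.index[df["form"] == ""]
    if len(bad_form):
        lines = df.loc[bad_form, "_line"].tolist()[:10]
        raise CorpusFormatError(f"{path}: empty form at line(s) {lines}")
    try:
        df["index"] = df["index"].astype(int)
    except ValueError as exc:
        raise CorpusFormatError(f"{path}: non-integer index column") from exc
    return turns_from_frame(df, source=str(path))


def turns_from_frame(df: pd.DataFrame, source: str = "<frame>") -> list[Turn]:
    """Build :class:`Turn` objects from a vertical-format DataFrame."""
    turns: list[Turn] = []
    for (conv, tid), grp in df.groupby(["conversation_id", "turn_id"], sort=True):
        grp = grp.sort_values("index")
        idx = grp["index"].to_numpy()
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            lines = grp["_line"].tolist() if "_line" in grp else "?"
            raise CorpusIntegrityError(
                f"{source}: turn ({conv}, {tid}) has non-contiguous indices "
                f"{idx.tolist()[:30]} (rows {lines if lines != '?' else 'unknown'})"
            )
        speakers = grp["speaker_id"].unique()
        if len(speakers) > 1:
            raise CorpusIntegrityError(
                f"{source}: turn ({conv}, {tid}) has multiple speakers {speakers.tolist()}"
            )
        tokens = tuple(
            TaggedToken(form=f, tag=t)
            for f, t in zip(grp["form"], grp["tag"])
        )
        turns.append(
            Turn(
                conversation_id=str(conv),
                turn_id=str(tid),
                speaker_id=str(speakers[0]),
                tokens=tokens,
            )
        )
    return turns


def select_turns(
    turns: Iterable[Turn], min_size: int = 3, max_size: int = 25
) -> TurnSubset:
    """Select turns whose size lies in [min_size, max_size], bounds inclusive."""
    if min_size > max_size:
        raise ValueError(f"min_size {min_size} > max_size {max_size}")
    turns = list(turns)
    kept = [t for t in turns if min_size <= t.size <= max_size]
    subset = TurnSubset(
        turns=kept, min_size=min_size, max_size=max_size, n_input=len(turns)
    )
    if turns and not kept:
        logger.warning(
            "size filter [%d, %d] retained no turns out of %d",
            min_size, max_size, len(turns),
        )
    else:
        logger.info(
            "size filter [%d, %d]: retained %d / %d turns (%.1f%%)",
            min_size, max_size, len(kept), len(turns), 100 * subset.retention
            if turns else float("nan"),
        )
    return subset


@dataclass
class FrequencyTable:
    """Word-tag token counts and per-thousand normalised frequencies."""

    counts: dict[tuple[str, str], int]
    total: int
    case_fold: bool = True
    per_thousand: dict[tuple[str, str], float] = field(init=False)

    def __post_init__(self) -> None:
        if self.total != sum(self.counts.values()):
            raise ValueError("total does not equal the sum of counts")
        self.per_thousand = {
            k: c / self.total * 1000.0 for k, c in self.counts.items()
        }

    def frequency_of(self, token: TaggedToken) -> float:
        """Per-thousand frequency of a token's word-tag type."""
        return self.per_thousand[token.wordtag_key(self.case_fold)]


def build_frequency_table(
    subset: TurnSubset, case_fold: bool = True
) -> FrequencyTable:
    """Count word-tag types over a turn subset and normalise per thousand.

    Frequencies are subset-internal: the counting universe is exactly the
    selected turns, not any larger corpus.
    """
    if len(subset) == 0:
        raise ValueError("cannot build a frequency table on an empty subset")
    counts: Counter[tuple[str, str]] = Counter()
    for turn in subset:
        for tok in turn.tokens:
            counts[tok.wordtag_key(case_fold)] += 1
    return FrequencyTable(counts=dict(counts), total=sum(counts.values()),
                          case_fold=case_fold)


def normalize_position(index: int, size: int) -> float:
    """Map a 1-based word position onto [0, 1]: (index - 1) / (size - 1)."""
    if size < 2:
        raise ValueError("normalized position is undefined for turns of size < 2")
    if not 1 <= index <= size:
        raise ValueError(f"index {index} outside 1..{size}")
    return (index - 1) / (size - 1)


def positioned_words(
    subset: TurnSubset, table: FrequencyTable | None = None
) -> pd.DataFrame:
    """One row per token with its normalised position and frequency.

    Columns: conversation_id, turn_id, speaker_id, size, index, norm_position,
    form, tag, and (if a table is given) freq_per_thousand.  This tidy table
    feeds the class profiles, per-turn slope fits and the regression stage.
    """
    rows = {
        "conversation_id": [], "turn_id": [], "speaker_id": [], "size": [],
        "index": [], "form": [], "tag": [],
    }
    for turn in subset:
        n = turn.size
        for i, tok in enumerate(turn.tokens, start=1):
            rows["conversation_id"].append(turn.conversation_id)
            rows["turn_id"].append(turn.turn_id)
            rows["speaker_id"].append(turn.speaker_id)
            rows["size"].append(n)
            rows["index"].append(i)
            rows["form"].append(tok.form)
            rows["tag"].append(tok.tag)
    df = pd.DataFrame(rows)
    df["norm_position"] = (df["index"] - 1) / (df["size"] - 1)
    if table is not None:
        fold = table.case_fold
        keys = [
            (f.casefold() if fold else f, t)
            for f, t in zip(df["form"], df["tag"])
        ]
        df["freq_per_thousand"] = [table.per_thousand[k] for k in keys]
    return df


def mean_frequency_profile(
    subset: TurnSubset,
    table: FrequencyTable,
    by: str = "turn_size",
    n_bins: int = 25,
) -> pd.DataFrame:
    """Mean per-thousand frequency per word position.

    ``by="turn_size"`` gives one mean per (size, index) cell; the per-size
    rows trace the staircase profile.  ``by="relative_position"`` pools all
    turns on a normalised-position grid of ``n_bins`` equal-width bins.
    Returns a tidy frame with the cell mean and the cell n.
    """
    df = positioned_words(subset, table)
    if by == "turn_size":
        out = (
            df.groupby(["size", "index"])["freq_per_thousand"]
            .agg(mean_frequency="mean", n="size")
            .reset_index()
        )
        out["norm_position"] = (out["index"] - 1) / (out["size"] - 1)
        return out
    if by == "relative_position":
        edges = np.linspace(0.0, 1.0, n_bins + 1)
        which = np.clip(
            np.searchsorted(edges, df["norm_position"], side="right") - 1,
            0, n_bins - 1,
        )
        df = df.assign(position_bin=which)
        out = (
            df.groupby("position_bin")["freq_per_thousand"]
            .agg(mean_frequency="mean", n="size")
            .reset_index()
        )
        out["norm_position"] = (edges[out["position_bin"]] + edges[out["position_bin"] + 1]) / 2
        return out
    raise ValueError(f"unknown profile axis {by!r}")
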