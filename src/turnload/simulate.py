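"""Synthetic conversation + pupillometry generator.

Emulates the joint statistical structure the analysis pipeline assumes:

* a Zipf-distributed lexicon partitioned into word classes, with nouns
  carrying by far the largest (hapax-rich) type inventory;
* turns whose class composition varies by relative position — insert mass
  concentrated at turn starts, noun mass rising toward turn ends — which
  induces an S-shaped decline of mean word frequency across the turn;
* 60 Hz two-eye pupil streams with blink gaps, in which speakers' baselined
  pupil size rises linearly within a turn with a slope negatively coupled
  to that turn's frequency slope, while recipients follow a rise-then-
  plateau quadratic with no coupling; random slope offsets by participant
  and by conversation.

Every output is a pure function of (config, seed), and all latent
parameters are returned in a truth log so recovery tests can compare
estimates against what was programmed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import Turn, TurnSubset, build_frequency_table, select_turns, turns_from_frame, positioned_words
from .slopes import frequency_slopes

CLASS_NAMES = ("insert", "function", "noun", "content_other")

# Forms/tags for the top of each class lexicon (CLAWS7-style tags).  "well"
# and "so" deliberately carry the adverb tag RR, mirroring the mis-tagging
# that the insert classification has to override.
_INSERT_SEED = [("oh", "UH"), ("yeah", "UH"), ("well", "RR"), ("so", "RR"),
                ("mm", "UH"), ("ah", "UH"), ("mhm", "UH"), ("huh", "UH")]
_PROFORM_SEED = [("i", "PPIS1"), ("you", "PPY"), ("it", "PPH1"),
                 ("that", "DD1"), ("he", "PPHS1"), ("they", "PPHS2"),
                 ("she", "PPHS1"), ("we", "PPIS2"), ("this", "DD1"),
                 ("there", "EX"), ("these", "DD2"), ("those", "DD2")]
_FUNCTION_TAGS = ["AT", "II", "CC", "VBZ", "VM", "APPGE", "CS", "XX", "TO", "DB"]
_OTHER_TAGS = ["JJ", "RR", "VV0"]  # adjective / adverb / lexical verb


def _default_curves() -> tuple[list[float], dict[str, list[float]]]:
    """Class-composition curves over relative position.

    Insert probability is concentrated at position 0 and decays fast; noun
    probability rises toward position 1; other content words are flat;
    function words take the remainder (and dominate turn-medial positions).
    """
    grid = np.linspace(0.0, 1.0, 21)
    p_insert = 0.70 * np.exp(-8.0 * grid)
    p_noun = 0.04 + 0.28 * grid ** 2.5
    p_other = np.full_like(grid, 0.18)
    p_function = 1.0 - p_insert - p_noun - p_other
    probs = {
        "insert": p_insert.tolist(),
        "function": p_function.tolist(),
        "noun": p_noun.tolist(),
        "content_other": p_other.tolist(),
    }
    return grid.tolist(), probs


@dataclass
class SimConfig:
    """All knobs of the generator, with defaults at the study conditions.

    Pupil magnitudes are in pixels (pupil areas as stored by a glasses-type
    tracker); durations in milliseconds; the per-word duration is set so
    that a 60 Hz stream yields on the order of 15 samples per word bin.
    """

    seed: int = 0
    n_conversations: int = 3
    participants_per_conversation: int = 2
    n_turns: int = 2000
    turn_size_min: int = 3
    turn_size_max: int = 25
    turn_size_decay: float = 0.85       # geometric weight ratio per extra word
    # lexicon
    zipf_s: float = 1.0
    vocab_insert: int = 8
    vocab_function: int = 300
    vocab_noun: int = 4000
    vocab_content_other: int = 1500
    # class-by-position composition
    curve_positions: list[float] = field(default_factory=lambda: _default_curves()[0])
    curve_probs: dict[str, list[float]] = field(default_factory=lambda: _default_curves()[1])
    # pupil stream model
    sample_rate_hz: float = 60.0
    ms_per_word: float = 260.0
    duration_jitter_sd: float = 0.15    # lognormal sd of turn duration
    gap_ms_mean: float = 400.0          # mean silent gap between turns
    speaker_slope_mean: float = 20.0    # px rise over a full turn
    speaker_slope_sd: float = 8.0
    recipient_amplitude: float = 15.0   # px, rise-plateau curve a*(2t - t^2)
    recipient_amplitude_sd: float = 6.0
    coupling_speaker: float = -0.10     # px slope per unit frequency slope
    coupling_recipient: float = 0.0
    participant_slope_sd: float = 4.0   # random slope offset by participant
    conversation_slope_sd: float = 3.0  # random slope offset by conversation
    noise_sd: float = 25.0              # per-eye sample noise, px
    base_level_px: float = 2000.0       # resting pupil area
    base_level_sd: float = 150.0        # between-participant resting spread
    blink_rate_hz: float = 0.15         # blinks per second per participant
    blink_mean_ms: float = 120.0

    def __post_init__(self) -> None:
        if self.zipf_s <= 0:
            raise ValueError("Zipf exponent must be positive")
        for name in ("speaker_slope_sd", "recipient_amplitude_sd",
                     "participant_slope_sd", "conversation_slope_sd",
                     "noise_sd", "duration_jitter_sd", "base_level_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        probs = np.array([self.curve_probs[c] for c in CLASS_NAMES])
        if probs.min() < -1e-9:
            raise ValueError("class-composition probabilities must be >= 0")
        colsums = probs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError("class probabilities must sum to 1 at each position")

    def class_probs_at(self, t: np.ndarray) -> np.ndarray:
        """(len(t), 4) class probabilities at relative positions t."""
        grid = np.asarray(self.curve_positions)
        out = np.column_stack([
            np.interp(t, grid, np.asarray(self.curve_probs[c]))
            for c in CLASS_NAMES
        ])
        return out / out.sum(axis=1, keepdims=True)

    def participants_of(self, conversation: int) -> list[str]:
        return [f"c{conversation + 1}_p{k + 1}"
                for k in range(self.participants_per_conversation)]


# ---------------------------------------------------------------------------
# Lexicon
# ---------------------------------------------------------------------------

@dataclass
class Lexicon:
    """Per-class vocabularies with Zipfian sampling weights."""

    forms: dict[str, np.ndarray]     # class -> array of forms
    tags: dict[str, np.ndarray]      # class -> array of tags
    weights: dict[str, np.ndarray]   # class -> normalised rank^(-s) weights


def make_lexicon(config: SimConfig) -> Lexicon:
    """Build the class-partitioned vocabulary with rank^(-s) weights.

    Top ranks of the insert and function classes are seeded with real
    high-frequency conversational items (interjections and pro-forms), so
    that downstream classification and the pro-form heuristics see realistic
    forms.  Nouns get the largest inventory, producing a hapax-rich tail.
    """
    sizes = {
        "insert": config.vocab_insert,
        "function": config.vocab_function,
        "noun": config.vocab_noun,
        "content_other": config.vocab_content_other,
    }
    forms: dict[str, np.ndarray] = {}
    tags: dict[str, np.ndarray] = {}
    weights: dict[str, np.ndarray] = {}
    seeds = {"insert": _INSERT_SEED, "function": _PROFORM_SEED,
             "noun": [], "content_other": []}
    fillers = {"insert": ("uh%03d", ["UH"]),
               "function": ("func%04d", _FUNCTION_TAGS),
               "noun": ("noun%05d", ["NN1"]),
               "content_other": ("cw%05d", _OTHER_TAGS)}
    for cls in CLASS_NAMES:
        v = sizes[cls]
        if v < 1:
            raise ValueError(f"vocabulary size for {cls} must be >= 1")
        seed_pairs = seeds[cls][:v]
        pattern, tag_cycle = fillers[cls]
        extra = [(pattern % i, tag_cycle[i % len(tag_cycle)])
                 for i in range(len(seed_pairs), v)]
        pairs = seed_pairs + extra
        forms[cls] = np.array([p[0] for p in pairs])
        tags[cls] = np.array([p[1] for p in pairs])
        ranks = np.arange(1, v + 1, dtype=float)
        w = ranks ** (-config.zipf_s)
        weights[cls] = w / w.sum()
    return Lexicon(forms=forms, tags=tags, weights=weights)


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

def generate_corpus(config: SimConfig, seed: int | None = None) -> list[Turn]:
    """Draw turns with position-dependent class composition.

    Turn sizes follow a truncated geometric distribution on
    [turn_size_min, turn_size_max]; each word's class is drawn from the
    position-composition curves and its form from the class lexicon.
    """
    frame = generate_corpus_frame(config, seed)
    if frame.empty:
        return []
    return turns_from_frame(frame, source="<simulated>")

def generate_corpus_frame(config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Vertical-format (one token per row) frame of the simulated corpus."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lex = make_lexicon(config)
    sizes_support = np.arange(config.turn_size_min, config.turn_size_max + 1)
    size_w = config.turn_size_decay ** (sizes_support - config.turn_size_min)
    size_p = size_w / size_w.sum()
    n = config.n_turns
    if n == 0:
        return pd.DataFrame(columns=["conversation_id", "turn_id", "speaker_id",
                                     "role", "index", "form", "tag"])
    turn_sizes = rng.choice(sizes_support, size=n, p=size_p)
    conv_idx = np.arange(n) % config.n_conversations
    # speakers alternate within each conversation
    speaker_pos = np.zeros(n, dtype=int)
    counters = np.zeros(config.n_conversations, dtype=int)
    for i, c in enumerate(conv_idx):
        speaker_pos[i] = counters[c] % config.participants_per_conversation
        counters[c] += 1
    # token-level arrays
    tok_turn = np.repeat(np.arange(n), turn_sizes)
    tok_index = np.concatenate([np.arange(1, s + 1) for s in turn_sizes])
    tok_size = turn_sizes[tok_turn]
    with np.errstate(invalid="ignore"):
        tok_t = np.where(tok_size > 1, (tok_index - 1) / (tok_size - 1), 0.0)
    probs = config.class_probs_at(tok_t)
    u = rng.random(len(tok_t))
    cum = np.cumsum(probs, axis=1)
    cls_idx = (u[:, None] > cum).sum(axis=1)
    forms = np.empty(len(tok_t), dtype=object)
    tags = np.empty(len(tok_t), dtype=object)
    for ci, cls in enumerate(CLASS_NAMES):
        mask = cls_idx == ci
        if not mask.any():
            continue
        draw = rng.choice(len(lex.forms[cls]), size=int(mask.sum()),
                          p=lex.weights[cls])
        forms[mask] = lex.forms[cls][draw]
        tags[mask] = lex.tags[cls][draw]
    conv_ids = np.array([f"conv{c + 1}" for c in conv_idx])
    turn_ids = np.array([f"t{j + 1:06d}" for j in range(n)])
    speakers = np.array([
        config.participants_of(c)[s] for c, s in zip(conv_idx, speaker_pos)
    ])
    return pd.DataFrame({
        "conversation_id": conv_ids[tok_turn],
        "turn_id": turn_ids[tok_turn],
        "speaker_id": speakers[tok_turn],
        "role": "speaker",
        "index": tok_index,
        "form": forms.astype(str) if len(forms) else forms,
        "tag": tags.astype(str) if len(tags) else tags,
    })


# ---------------------------------------------------------------------------
# Expected frequency profile (analytic truth for recovery tests)
# ---------------------------------------------------------------------------

def expected_frequency_curve(config: SimConfig) -> "callable":
    """Expected per-thousand token frequency as a function of position.

    For a token of class c, the expected subset-internal per-thousand
    frequency of its type is 1000/N x (1 + (N-1) x pi_c x S2_c), where
    pi_c is the overall token share of class c, S2_c the sum of squared
    within-class type probabilities (a size-biased draw lands on frequent
    types proportionally more often), and N the corpus token count.  The
    positional curve mixes these class expectations with the composition
    curve at each position.
    """
    sizes = np.arange(config.turn_size_min, config.turn_size_max + 1)
    size_w = config.turn_size_decay ** (sizes - config.turn_size_min)
    size_p = size_w / size_w.sum()
    # token-weighted class shares pi_c
    pi = np.zeros(len(CLASS_NAMES))
    for s, p in zip(sizes, size_p):
        t = (np.arange(1, s + 1) - 1) / (s - 1)
        pi += p * config.class_probs_at(t).sum(axis=0)
    pi /= (size_p * sizes).sum()
    n_tokens = config.n_turns * float((size_p * sizes).sum())
    lex = make_lexicon(config)
    s2 = np.array([float((lex.weights[c] ** 2).sum()) for c in CLASS_NAMES])
    class_freq = 1000.0 / n_tokens * (1.0 + (n_tokens - 1.0) * pi * s2)

    def curve(t: np.ndarray) -> np.ndarray:
        probs = config.class_probs_at(np.atleast_1d(np.asarray(t, dtype=float)))
        return probs @ class_freq

    return curve


# ---------------------------------------------------------------------------
# Pupil generation
# ---------------------------------------------------------------------------

def generate_pupil(
    turns: Sequence[Turn], config: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """Simulate 60 Hz two-eye pupil streams aligned to the turns.

    Turns are laid out consecutively on each conversation's timeline with
    silent gaps; every participant of a conversation contributes a
    continuous stream.  Within a turn window the participant's latent
    baselined trajectory is

    * speaker:   slope x t,  slope = mean + a_i + c_j + b_s x slope_freq + turn noise
    * recipient: amp x (2t - t^2) + b_r x slope_freq x t,  amp similarly offset,

    with t the relative time in the window.  Per-eye Gaussian noise is added
    and blink gaps (missing runs in both eyes) injected as a Poisson process.

    Returns (streams, windows, truth) where truth holds the latent
    parameters: per-pair latent slopes, per-participant and per-conversation
    offsets, and the frequency slopes used for the coupling.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    turns = list(turns)
    # frequency slopes of the selected turns (the coupling driver)
    subset = select_turns(turns, config.turn_size_min, config.turn_size_max)
    if len(subset) == 0:
        empty_cols = {
            "streams": ["participant_id", "timestamp_ms", "pupil_left_px",
                        "pupil_right_px"],
            "windows": ["conversation_id", "turn_id", "onset_ms", "offset_ms",
                        "participant_id", "role"],
        }
        truth = {
            "pairs": pd.DataFrame(columns=["conversation_id", "turn_id",
                                           "participant_id", "role",
                                           "slope_frequency", "latent_linear",
                                           "latent_quadratic"]),
            "participants": pd.DataFrame(columns=["participant_id", "slope_offset",
                                                  "base_level"]),
            "conversations": pd.DataFrame(columns=["conversation_id",
                                                   "slope_offset"]),
        }
        return (pd.DataFrame(columns=empty_cols["streams"]),
                pd.DataFrame(columns=empty_cols["windows"]), truth)
    table = build_frequency_table(subset)
    fslopes = frequency_slopes(positioned_words(subset, table))
    fslope_by_key = {
        (r.conversation_id, r.turn_id): r.slope_frequency
        for r in fslopes.itertuples(index=False)
    }
    def conv_index(conv_id: str) -> int:
        return int(conv_id.removeprefix("conv")) - 1

    convs = sorted({t.conversation_id for t in turns}, key=conv_index)
    conv_offsets = {c: rng.normal(0.0, config.conversation_slope_sd)
                    for c in convs}
    participants: dict[str, dict] = {}
    for c in convs:
        for pid in config.participants_of(conv_index(c)):
            participants[pid] = {
                "conversation_id": c,
                "slope_offset": rng.normal(0.0, config.participant_slope_sd),
                "base_level": rng.normal(config.base_level_px,
                                         config.base_level_sd),
            }
    dt_ms = 1000.0 / config.sample_rate_hz
    window_rows = []
    truth_rows = []
    # conversation timelines
    turn_layout: dict[str, list] = {c: [] for c in convs}
    for t in subset:
        dur = (t.size * config.ms_per_word
               * float(np.exp(rng.normal(0.0, config.duration_jitter_sd))))
        turn_layout[t.conversation_id].append((t, dur))
    streams = []
    for c in convs:
        cursor = 0.0
        spans = []
        for t, dur in turn_layout[c]:
            onset = cursor
            offset = cursor + dur
            spans.append((t, onset, offset))
            cursor = offset + rng.exponential(config.gap_ms_mean)
        conv_end = cursor + 500.0
        ts = np.arange(0.0, conv_end, dt_ms)
        pids = config.participants_of(conv_index(c))
        for pid in pids:
            info = participants[pid]
            signal = np.zeros_like(ts)
            for t, onset, offset in spans:
                lo = np.searchsorted(ts, onset, side="left")
                hi = np.searchsorted(ts, offset, side="left")
                if hi <= lo:
                    continue
                trel = (ts[lo:hi] - onset) / (offset - onset)
                sf = fslope_by_key[(t.conversation_id, t.turn_id)]
                if pid == t.speaker_id:
                    role = "speaker"
                    slope = (config.speaker_slope_mean
                             + info["slope_offset"]
                             + conv_offsets[c]
                             + config.coupling_speaker * sf
                             + rng.normal(0.0, config.speaker_slope_sd))
                    curve = slope * trel
                    latent_lin, latent_quad = slope, 0.0
                else:
                    role = "recipient"
                    amp = (config.recipient_amplitude
                           + info["slope_offset"]
                           + conv_offsets[c]
                           + rng.normal(0.0, config.recipient_amplitude_sd))
                    curve = (amp * (2.0 * trel - trel ** 2)
                             + config.coupling_recipient * sf * trel)
                    latent_lin = 2.0 * amp + config.coupling_recipient * sf
                    latent_quad = -amp
                signal[lo:hi] += curve
                window_rows.append((c, t.turn_id, onset, offset, pid, role))
                truth_rows.append((c, t.turn_id, pid, role, sf,
                                   latent_lin, latent_quad))
            base = info["base_level"]
            left = base + signal + rng.normal(0.0, config.noise_sd, ts.size)
            right = base + signal + rng.normal(0.0, config.noise_sd, ts.size)
            # blink gaps: Poisson starts, geometric-ish lengths, both eyes
            n_blinks = rng.poisson(config.blink_rate_hz * conv_end / 1000.0)
            if n_blinks > 0:
                starts = rng.integers(0, ts.size, size=n_blinks)
                lengths = np.maximum(
                    1, rng.exponential(config.blink_mean_ms / dt_ms,
                                       size=n_blinks).astype(int))
                for s0, ln in zip(starts, lengths):
                    left[s0:s0 + ln] = np.nan
                    right[s0:s0 + ln] = np.nan
            streams.append(pd.DataFrame({
                "participant_id": pid,
                "timestamp_ms": ts,
                "pupil_left_px": left,
                "pupil_right_px": right,
            }))
    streams_df = (pd.concat(streams, ignore_index=True) if streams
                  else pd.DataFrame(columns=["participant_id", "timestamp_ms",
                                             "pupil_left_px", "pupil_right_px"]))
    windows_df = pd.DataFrame(
        window_rows, columns=["conversation_id", "turn_id", "onset_ms",
                              "offset_ms", "participant_id", "role"],
    )
    truth = {
        "pairs": pd.DataFrame(
            truth_rows, columns=["conversation_id", "turn_id", "participant_id",
                                 "role", "slope_frequency", "latent_linear",
                                 "latent_quadratic"],
        ),
        "participants": pd.DataFrame(
            [(pid, info["slope_offset"], info["base_level"])
             for pid, info in participants.items()],
            columns=["participant_id", "slope_offset", "base_level"],
        ),
        "conversations": pd.DataFrame(
            [(c, o) for c, o in conv_offsets.items()],
            columns=["conversation_id", "slope_offset"],
        ),
    }
    return streams_df, windows_df, truth


# ---------------------------------------------------------------------------
# On-disk bundle
# ---------------------------------------------------------------------------

def generate_dataset(
    config: SimConfig, out_dir: str | Path, seed: int | None = None
) -> dict[str, Path]:
    """Write a complete synthetic bundle: transcript, pupil, windows, truth.

    Identical (config, seed) produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base_seed = config.seed if seed is None else seed
    frame = generate_corpus_frame(config, base_seed)
    turns = turns_from_frame(frame, source="<simulated>") if len(frame) else []
    streams, windows, truth = generate_pupil(turns, config, base_seed + 1)
    paths = {
        "transcript": out / "transcript.tsv",
        "pupil": out / "pupil.csv",
        "windows": out / "windows.csv",
        "truth_pairs": out / "truth_pairs.csv",
        "truth_participants": out / "truth_participants.csv",
        "truth_conversations": out / "truth_conversations.csv",
        "config": out / "config.json",
    }
    frame.to_csv(paths["transcript"], sep="\t", index=False)
    streams.to_csv(paths["pupil"], index=False)
    windows.to_csv(paths["windows"], index=False)
    truth["pairs"].to_csv(paths["truth_pairs"], index=False)
    truth["participants"].to_csv(paths["truth_participants"], index=False)
    truth["conversations"].to_csv(paths["truth_conversations"], index=False)
    cfg = dataclasses.asdict(config)
    cfg["seed"] = int(base_seed)
    paths["config"].write_text(json.dumps(cfg, indent=2, sort_keys=True))
    return paths
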