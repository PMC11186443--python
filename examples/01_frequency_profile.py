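"""Positional word-frequency profile of conversational turns.

Simulates a small tagged conversation corpus, selects 3-25-word turns,
counts word-tag types, and prints the mean per-thousand frequency at the
first, middle and last turn positions.  The decline from turn start to turn
end is the anticlimactic frequency structure: high-frequency inserts and
pro-forms open the turn, low-frequency (often hapax) nouns close it.
"""

import turnload as tl

cfg = tl.SimConfig(n_turns=1000, seed=42)
turns = tl.generate_corpus(cfg)
subset = tl.select_turns(turns, min_size=3, max_size=25)
table = tl.build_frequency_table(subset)

print(f"turns retained: {len(subset)}/{subset.n_input} "
      f"({100 * subset.retention:.0f}%), {subset.total_tokens} tokens, "
      f"{len(table.counts)} word-tag types")

profile = tl.mean_frequency_profile(subset, table, by="relative_position",
                                    n_bins=5)
print("\nmean frequency (per 1,000 words) across relative position:")
for row in profile.itertuples(index=False):
    bar = "#" * int(row.mean_frequency)
    print(f"  position ~{row.norm_position:.1f}: {row.mean_frequency:6.2f}  {bar}")

first = profile["mean_frequency"].iloc[0]
last = profile["mean_frequency"].iloc[-1]
print(f"\nturn-initial words are on average {first / last:.1f}x more frequent "
      "than turn-final words: frequency declines as the turn unfolds.")
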