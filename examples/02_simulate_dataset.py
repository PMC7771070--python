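"""Generate a synthetic benchmark and build a labeled window set.

References carry planted insertion-site signatures (a corrupted inverted
repeat with AT-rich flanks, mimicking transposon ends).  Positives are
100-nt windows centered on truth sites; negatives come from regions at
least 10 kb away from every site, so the classes never overlap.
"""

import hgtsite as h

config = h.SimulationConfig(
    n_refs=2, ref_length=60_000, sites_per_ref=40,
    arm_length_range=(8, 8), corruption=0.05, seed=1,
)
sample_set, refs, sites = h.simulate_labeled_set(config, n_pos=80, n_neg=80)
sample_set = h.split_dataset(sample_set, (0.8, 0.1, 0.1), seed=1)

labels = sample_set.labels()
print(f"{len(refs)} references of {config.ref_length:,} bp, {len(sites)} truth sites")
print(f"{len(sample_set)} windows: {labels.sum()} positive / {(labels == 0).sum()} negative")
for name in ("train", "validation", "test"):
    print(f"  {name}: {len(sample_set.subset(name))}")

pos = next(
    s for s in sample_set
    if s.label == 1
    and any(x.start <= 46 and x.end >= 54
            for x in h.find_palindromes(s.sequence, 10, "strict"))
)
print("\none positive window, the 32 bp around the junction:")
print(" ", pos.sequence.bases[34:66])
print("  strict palindromes >= 10 bp:",
      [(x.start, x.end) for x in h.find_palindromes(pos.sequence, 10, "strict")])
# The planted signature sits mid-window: an 8 bp arm and its reverse
# complement spanning offsets 42-58 (occasionally fragmented by the 5%
# corruption), flanked by AT-enriched sequence.
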