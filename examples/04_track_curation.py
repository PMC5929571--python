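"""Repairing fragmented tracks by scored gap closing.

Breaks half of the simulated tracks at random frames, then restores them
with the distance-threshold auto-linker (threshold = 2x the per-frame
step).  A guided review session then walks the remaining loose ends
depth-first, the way a human curator would, and its decision log is
replayed to show the process is deterministic.
"""

import trajkit as tk
from trajkit.curation import QueueExhausted

forest, _ = tk.simulate_embryo(tk.EmbryoSimConfig(seed=1, noise_sigma=0.0))
frag, truth = tk.fragment_tracks(forest, break_rate=0.5, gap=1, seed=1)
print(f"fragmented: {forest.n_tracks} -> {frag.n_tracks} tracks "
      f"({len(truth.joins)} true joins)")

linked, log = tk.auto_link(frag, max_gap=1, distance_threshold=3.0)
made = {(e["end_track_id"], e["start_track_id"]) for e in log}
true = set(truth.joins)
print(f"auto-link: {len(log)} links, "
      f"{100*len(made & true)/len(true):.1f}% of true joins restored, "
      f"{len(made - true)} false")

# guided review of whatever the auto pass left (movie-end tracks etc.)
session = tk.CurationSession(linked, mode="depth-first", max_radius=5.0)
reviewed = accepted = 0
while True:
    try:
        tid, cands = session.next_review_item()
    except QueueExhausted:
        break
    reviewed += 1
    if cands:
        session.apply_decision(1)  # accept the top-ranked suggestion
        accepted += 1
    else:
        session.apply_decision("reject")
print(f"review: {reviewed} items, {accepted} links accepted")

replayed = tk.replay_decision_log(linked, session.decision_log(),
                                  mode="depth-first", max_radius=5.0)
print(f"replay reproduces the curated forest: "
      f"{set(replayed.tracks) == set(session.forest.tracks)}")
summary = tk.curation_summary(session.decision_log())
print(summary["choice"].value_counts().to_dict())
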