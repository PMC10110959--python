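"""Polish an imperfectly tracked trajectory.

Degrades a clean synthetic track with a short and a long tracking gap,
then applies the standard cleaning chain: split at gaps >= 10 min,
spline-fill shorter gaps on the 1-min grid, filter by quality criteria
and cut the survivors into one-hour segments.
"""

from modewalk import (
    degrade,
    filter_tracks,
    fixture,
    preprocess_trajectory,
    segment_trajectory,
)

clean = fixture("brownian", {"n_points": 241, "step_sd": 2.0}, seed=5)
damaged = degrade(clean, [(50.0, 4.0), (130.0, 15.0)])
print(f"raw track: {clean.n_points} points; after dropouts: {damaged.n_points}")

pieces = preprocess_trajectory(damaged)
for p in pieces:
    print(f"  piece {p.track_id}: {p.n_points} points, "
          f"{p.times[0]:.0f}-{p.times[-1]:.0f} min")

kept, removed = filter_tracks(pieces)
print(f"kept {len(kept)} piece(s), removed {len(removed)}")
for tr, reasons in removed:
    print(f"  removed {tr.track_id}: violated {', '.join(reasons)}")

segments = [s for tr in kept for s in segment_trajectory(tr)]
print(f"classifiable one-hour segments: {len(segments)}")

# The 15-min dropout splits the track in two; the 4-min dropout is filled
# by the spline, so the first piece keeps its full one-hour windows.
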