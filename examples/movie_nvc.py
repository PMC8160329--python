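"""Single-vessel neurovascular coupling from a two-channel movie.

Renders a movie of a vessel that dilates shortly after each neuronal
calcium transient, detects the calcium events, classifies the vessel
response, and computes the per-event NVC index (dilation peak / calcium
peak).
"""

import numpy as np

from oxyflow import nvc, synth, vesselgeom
from oxyflow.traces import FluorescenceTrace

rate = 5.0
n_frames = 300
events = (20.0, 40.0)
diam = np.full(n_frames, 5.0)
t = np.arange(n_frames) / rate
for te in events:
    diam[(t >= te + 1.0) & (t < te + 4.0)] += 0.4  # 8% dilation, 1 s latency

truth = synth.MovieTruth(n_frames=n_frames, frame_rate=rate,
                         diameter_timecourse=diam,
                         calcium_event_times=events,
                         calcium_amplitudes=(1.0, 1.2),
                         noise_sd=0.01, seed=2)
movie, roi_traces, _ = synth.make_movie(truth)

diameter = vesselgeom.frame_diameter_trace(movie)
calcium = FluorescenceTrace(values=roi_traces["roi0"].to_numpy(), frame_rate=rate)
detected = nvc.detect_calcium_events(calcium)

print(f"detected {len(detected)} calcium events (truth {len(events)})")
for ev in detected:
    i = int(round(ev.peak_time * rate))
    pre, post = int(5 * rate), int(10 * rate)
    rec = nvc.classify_response(diameter.values[i - pre:i + post + 1], rate,
                                calcium_peak=ev.peak_dff)
    print(f"  t={ev.peak_time:5.1f} s  dF/F={ev.peak_dff:.2f}  "
          f"responsive={rec.responsive}  dilation={rec.dilation_peak:.3f}  "
          f"NVC index={rec.nvc_index:.3f}")

null = nvc.shuffled_null(diameter, [e.peak_time for e in detected],
                         n_iter=100, seed=0)
print(f"shuffled-null response rate: {100 * null:.1f}%")
print("Aligned events respond reliably; after shuffling the diameter trace")
print("in time, 'responses' occur only at the chance rate of the 1-SD/0.5-s rule.")
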