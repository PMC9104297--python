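"""Sparse phasic/tonic decomposition of one baseline segment.

Simulates a subject, preprocesses the finger channel (resample 100 -> 8 Hz,
zero-phase order-6 Butterworth at 0.6 Hz), decomposes the first 120 s and
compares recovered skin conductance responses with the ground truth.
"""

import numpy as np

from edasites import (
    DecompositionConfig,
    SimulationConfig,
    decompose,
    detect_scrs,
    lowpass_filter,
    resample_signal,
    simulate_recording,
)

cfg = SimulationConfig(seed=3)
rec, truth = simulate_recording(cfg, 0)

x8 = lowpass_filter(resample_signal(rec.channel("finger"), rec.fs, 8.0), 8.0)
segment = x8[: int(120 * 8)]

# match the response kernel to the preprocessing low-pass
dcfg = DecompositionConfig(match_lowpass_order=6, match_lowpass_cutoff_hz=0.6)
res = decompose(segment, 8.0, dcfg)

true_events = truth.event_times_s["finger"]
true_events = true_events[true_events < 120]
scrs = detect_scrs(res.phasic, 8.0, threshold_fraction=0.05)

print(f"solver: {res.solver_message}, converged={res.converged}, "
      f"{res.n_iterations} iterations")
print(f"reconstruction error: {np.max(np.abs(res.reconstruction() - segment)):.2e} uS")
print(f"tonic level ~ {res.tonic.mean():.2f} uS; "
      f"driver support {np.count_nonzero(res.driver)} samples")
print(f"true SCR events in segment: {true_events.size}; detected: {len(scrs)}")
print("detected peak times (s):", np.round([t for t, _ in scrs], 1))
print("true event times (s):   ", np.round(true_events, 1))
# Detected peaks lag events by ~1.1 s: the biexponential kernel's rise time.
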