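"""Simulate a short mVEP speller session and look at the evoked waveform.

Builds a 6-block session (6 buttons, 5 trials per block, 8 channels at
1000 Hz) and prints the structure plus the P1/N2/P2 peak latencies of the
noise-free target response at the best channel.
"""

import numpy as np

from mvep_adapt import (DriftModel, ParadigmConfig, WaveModel, simulate_epoch,
                        simulate_session)

paradigm = ParadigmConfig(n_blocks=6)
wave = WaveModel()
session = simulate_session(paradigm, wave, DriftModel(kind="none"), seed=42)

print(f"blocks: {session.n_blocks}, epochs: {len(session.all_epochs())} "
      f"({paradigm.trials_per_block} trials x {paradigm.n_buttons} buttons "
      "per block)")
print(f"trial duration {paradigm.trial_duration_ms:.0f} ms, "
      f"block duration {paradigm.block_duration_s:.1f} s")
print("target button per block:", session.target_buttons)

# noise-free target epoch: the canonical P1 / N2 / P2 morphology
clean = simulate_epoch(WaveModel(noise_sd=0.0), is_target=True, seed=0,
                       paradigm=paradigm)
best = int(np.argmax(wave.topography))
sig = clean.data[best]
t = np.arange(sig.size)  # ms at 1000 Hz
p1 = t[:160][np.argmax(sig[:160])]
n2 = t[np.argmin(sig)]
p2 = t[200:][np.argmax(sig[200:])]
print(f"channel {best}: P1 {sig[p1]:+.2f} uV at {p1} ms, "
      f"N2 {sig[n2]:+.2f} uV at {n2} ms, P2 {sig[p2]:+.2f} uV at {p2} ms")
print("The target response is a positive-negative-positive complex; the")
print("negative N2 near 180 ms is the largest and most stable component.")
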