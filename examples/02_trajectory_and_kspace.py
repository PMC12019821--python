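"""Phyllotaxis trajectory geometry, preset timings and a short k-space simulation.

Prints the interleave/duration bookkeeping of the six preset acquisitions,
then simulates 20 seconds of multi-coil radial data from the moving phantom.
"""

import numpy as np

import freecine as fc

for label in range(1, 7):
    n = fc.preset_interleaves(label)
    d = fc.duration_of(n)
    print(f"{label}-min preset: {n:5d} interleaves -> {d:6.1f} s "
          f"({int(round(d)) // 60}:{int(round(d)) % 60:02d})")

traj = fc.phyllotaxis_trajectory(fc.interleaves_for_duration(20.0), n_samples=32)
sg_dt = np.diff(traj.timestamps[traj.is_sg])
print(f"\n20 s trajectory: {traj.n_readouts} readouts "
      f"({int(traj.is_sg.sum())} self-gating), SG cadence {sg_dt[0] * 1000:.2f} ms")

phantom = fc.default_phantom(grid=32)
physio = fc.generate_physio(fc.PhysioConfig(seed=1), traj.duration() + 1, traj.tr)
kdata = fc.simulate_kspace(phantom, traj, physio, noise_sd=0.05, seed=1)
print(f"k-space: {kdata.samples.shape} (readouts x samples x coils), "
      f"sample RMS {np.abs(kdata.samples).std():.3f}")
# Each readout is a full diameter through k-space; the first readout of every
# interleave points superior-inferior and carries the self-gating signal.
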