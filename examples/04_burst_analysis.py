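"""From a raw photon stream to a corrected FRET histogram.

Simulates a pulsed-interleaved-excitation measurement -- diffusing molecules,
incomplete labeling, leakage, direct excitation, background -- then runs the
burst pipeline: interval-smoothing burst search, correction-factor estimation
from the single-label subpopulations, stoichiometry selection and the
corrected efficiency histogram.
"""

import numpy as np

from akdyn.fret import burst_search, estimate_corrections, fret_histogram, select_double_labeled
from akdyn.fret.bursts import apply_corrections
from akdyn.simulate import FretSimConfig, simulate_photon_stream

cfg = FretSimConfig(
    E_open=0.37, E_closed=0.72,
    k_open=5000 / 1.16, k_close=5000 * 0.16 / 1.16,   # apo-like, K_C = 0.16
    n_bursts=1500, photon_rate=4e5, acceptor_exc_rate=4e5,
    leakage=0.05, direct_excitation=0.06,
    donor_only_fraction=0.2, acceptor_only_fraction=0.15,
    background_rate_donor=1000.0, background_rate_acceptor=800.0,
    seed=7,
)
stream, truth = simulate_photon_stream(cfg)
print(f"photon stream: {len(stream):,} photons over "
      f"{stream.timestamps_ns[-1] / 1e9:.1f} s")

bursts = burst_search(stream)
print(f"burst search: {len(bursts)} bursts of >= 50 photons")

factors = estimate_corrections(bursts)
print(f"corrections from single-label populations: leakage = {factors.leakage:.3f} "
      f"(true 0.050), direct excitation = {factors.direct_excitation:.3f} (true 0.060)")

apply_corrections(bursts, factors)
selected = select_double_labeled(bursts)
print(f"stoichiometry selection: {len(selected)} double-labeled bursts kept")

hist = fret_histogram(selected, bins=25)
peak = hist.loc[hist["density"].idxmax()]
print(f"corrected FRET histogram peaks in [{peak.E_left:.2f}, {peak.E_right:.2f}] "
      "with a tail toward high E")
# The low-E peak with a high-E shoulder is the apo signature: the enzyme is
# mostly open, visiting the closed state transiently.
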