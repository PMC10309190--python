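"""Recruitment timing on phagosomes, end to end.

Simulates one experiment of ten engulfed-yeast events whose reporter
follows the phagosomal preset (half-max arrival 2 min after engulfment,
~20 min retention), runs the full segment/track/ring pipeline, and
prints the recovered timings.
"""

import numpy as np

from phagoflux.kinetics import extract_timing
from phagoflux.pipeline import synthetic_cohort_traces
from phagoflux.profiles import get_preset

traces = synthetic_cohort_traces(
    get_preset("snxa_phagosome"), n_events=10, n_frames=185, seed=1
)
timings = [extract_timing(tr) for tr in traces]

arrivals = [t.t_arrival / 60 for t in timings]
dwells = [t.dwell / 60 for t in timings]
print(f"events analysed:        {len(timings)}")
print(f"median arrival:         {np.median(arrivals):.2f} min after engulfment")
print(f"median dwell:           {np.median(dwells):.1f} min")
print(f"peak fold-enrichment:   {np.median([tr.values.max() for tr in traces]):.2f}")
# Arrival is the half-max crossing of the fold-enrichment trace; dwell is
# the time between the half-max rise and fall. The generator's ground
# truth is 2.0 min and 20.0 min, so values here show pipeline accuracy.
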