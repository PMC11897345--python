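"""Write and read a trace bundle, with junction-potential correction.

Simulates a short current-clamp recording, applies the +12 mV liquid
junction potential correction, round-trips it through the on-disk bundle
format (meta.json + per-sweep CSVs) and verifies exact recovery.
"""

import tempfile
from pathlib import Path

import numpy as np

from neuroexhaust import synth
from neuroexhaust.trace_io import (
    apply_junction_correction,
    build_step_protocol,
    read_bundle,
    write_bundle,
)

protocol = build_step_protocol(-20.0, 20.0, 10.0, step_duration=0.5,
                               pre_duration=0.1, post_duration=0.1)
rec = synth.simulate_current_clamp(synth.ARCHETYPES["T3-control"],
                                   protocol, seed=0, cell_id="demo")
corrected = apply_junction_correction(rec, jp_mv=12.0)
print(f"protocol: {len(protocol.step_levels)} steps, "
      f"{protocol.sweep_duration:.1f} s per sweep")
print(f"pre-stim V before/after correction: "
      f"{rec.sweeps[0][0]:.2f} / {corrected.sweeps[0][0]:.2f} mV")

with tempfile.TemporaryDirectory() as tmp:
    path = write_bundle(corrected, Path(tmp) / "demo_cell")
    back = read_bundle(path)
    same = all(np.array_equal(a, b)
               for a, b in zip(corrected.sweeps, back.sweeps))
    print(f"bundle round trip exact: {same}")
    print(f"files written: {sorted(p.name for p in path.iterdir())}")
# The corrected trace sits exactly 12 mV below the recorded one, and the
# plain-text bundle reproduces every sample bit for bit.
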