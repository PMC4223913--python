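"""End-to-end synthetic vibrography pipeline.

Forward model -> synthetic displacement traces (reference motion, 10%
second-harmonic loudspeaker contamination, additive noise) -> reference
subtraction and Fourier amplitude extraction -> measured FRF.  With the
seed fixed the run is bit-reproducible.
"""

import numpy as np

from ocuvib import FlapConfig
from ocuvib.oct import assemble_frf, extract_amplitude
from ocuvib.synth import SynthSpec, make_records

spec = SynthSpec(
    model_cfg=FlapConfig(),
    drive_frequencies=tuple(np.arange(120.0, 240.0, 10.0)),
    amplitude_scale=300e-9,  # peak oscillation ~300 nm, as seen in flaps
    reference_amplitude=2e-6,  # rigid whole-setup motion, cancelled later
    harmonic_fraction=0.10,
    noise_sd=3e-9,
    seed=7,
)
records = make_records(spec)
print(f"{len(records)} synthetic records at {spec.sampling_rate / 1e3:.0f} kHz")

for rec in records[:3]:
    amp, phase = extract_amplitude(rec)
    truth = rec.metadata["true_amplitude_m"]
    print(
        f"  {rec.drive_frequency:5.0f} Hz: extracted {amp * 1e9:7.2f} nm, "
        f"truth {truth * 1e9:7.2f} nm  (err {abs(amp - truth) / truth * 100:.2f}%)"
    )

frf = assemble_frf(records)
peak = frf.frequencies[np.argmax(frf.amplitude)]
print(f"\nmeasured FRF peaks at ~{peak:.0f} Hz over the {len(frf.frequencies)}-point grid")
print("amplitude extraction stays within a percent of truth at this noise level.")
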