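"""Scintillation-count correction: raw DPM to decay-corrected nCi.

Builds a tiny measurement table (two leaf disks and one forager measured a
few days after trial start), applies blank subtraction, counting-efficiency
correction, decay back-correction to the trial start, and conversion at
1 DPM = 4.556e-13 Ci.
"""

import pandas as pd

from gudscale import TracerCalibration, process_measurements

cal = TracerCalibration(
    counting_efficiency=0.9,
    blank_dpm=25.0,
    reference_time=0.0,  # trial start, days
)
measurements = pd.DataFrame(
    {
        "subject_id": ["disk_01", "disk_02", "forager_01"],
        "subject_kind": ["disk", "disk", "forager"],
        "raw_dpm": [48000.0, 31000.0, 9000.0],
        "measurement_time": [5.0, 5.0, 5.0],  # days after trial start
    }
)
out = process_measurements(measurements, cal)
print(out.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(
    "\ncharge_nci is the activity each subject carried at trial start:"
    "\n(raw - blank)/efficiency, multiplied by 2**(5/14.268) to undo five days"
    "\nof 32P decay, then converted to nanocuries."
)
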