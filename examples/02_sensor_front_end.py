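"""Characterize the sensor and analog front-end digital twin.

Measures the static calibration slopes, the dynamic step response and
the filter corners of the conditioning chain by swept-sine analysis —
the same bench measurements one would run on the physical hardware.
"""

import numpy as np

import scgpipe as sp
from scgpipe.forward_model import (
    AnalogChainParams,
    measure_cutoff,
    measure_notch_center,
    measure_step_times,
)

forces = np.linspace(0.0, 0.2, 11)
slope_lo = np.polyfit(forces, sp.static_response(forces), 1)[0]
forces = np.linspace(0.6, 0.8, 5)
slope_hi = np.polyfit(forces, sp.static_response(forces), 1)[0]
print(f"sensitivity 0-0.2 N: {slope_lo:.2f} V/N   0.6-0.8 N: {slope_hi:.2f} V/N")

rise, fall = measure_step_times(step_force_n=0.1, fs_hz=4000.0)
print(f"step response: 10-90% rise {rise*1000:.0f} ms, 90-10% fall {fall*1000:.0f} ms")

f_lp = measure_cutoff("lowpass", 1.0, 200.0, fs_hz=4000.0)
f_hp = measure_cutoff("highpass", 0.1, 5.0, fs_hz=4000.0, kind="highpass")
f_notch = measure_notch_center(fs_hz=4000.0)
print(f"low-pass -3 dB: {f_lp:.1f} Hz   high-pass corner: {f_hp:.2f} Hz   "
      f"notch center: {f_notch:.1f} Hz")

p = AnalogChainParams()
print(f"ADC: {p.adc_bits} bits, {p.adc_full_scale_v} V full scale, "
      f"LSB {p.lsb_v*1000:.3f} mV")

# The twin reproduces the hardware's printed figures: 3.76 / 0.10 V/N
# sensitivity, 20 / 60 ms response and recovery, a 33.9 Hz third-order
# Butterworth low-pass, a ~0.8 Hz high-pass, a 50 Hz mains notch and a
# 12-bit 0.732 mV-per-code converter.
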