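"""Analyze one synthetic carotid recording.

Builds a waveform pair whose true compression/expansion peaks are known
(calibrated to W1 = 5400, W2 = 1900 mmHg·m/s³ at HR 77), runs the
single-patient analysis and prints what it recovers.
"""

from nwistrat import analyze_recording, calibrate_params, generate_waveform

params = calibrate_params(w1_target=5400.0, w2_target=1900.0, heart_rate=77.0)
recording = generate_waveform(params, seed=42)
result = analyze_recording(recording, smooth=True)

print(f"beats used        : {result.n_beats_used}")
print(f"heart rate        : {result.heart_rate:6.1f} beats/min")
print(f"W1 compression    : {result.w1:7.0f} mmHg·m/s³  (true 5400)")
print(f"W2 expansion      : {result.w2:7.0f} mmHg·m/s³  (true 1900)")
print(f"beta stiffness    : {result.beta:7.1f}")
print(f"pressure range    : {result.p_min:.0f}-{result.p_max:.0f} mmHg")
print()
print("W1 is the early-systolic wave-intensity maximum: the energy the")
print("ventricle pushes into the artery at ejection onset. Recovering it")
print("within a few percent despite measurement noise is what makes the")
print("5-beat ensemble average clinically usable.")
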