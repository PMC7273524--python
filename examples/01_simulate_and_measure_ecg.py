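"""Simulate one exercise-test ECG and recover its Tpe traits.

Builds a 435 s synthetic bicycle-ergometer recording (15 s rest, 6 min
exercise, 1 min recovery; Gaussian T waves whose widths encode the
ground-truth Tpe per phase), runs the full processing chain
(band-limiting, QRS detection, 15 s signal averaging, tangent-method
delineation), and compares the recovered Tpe values with the truth.
"""

from tpewas import measure_recording, simulate_ecg
from tpewas.traits import TraitRecord, tpe_response_exercise, tpe_response_recovery

sim = simulate_ecg(tpe_by_phase=(62.0, 55.0, 60.0), noise_sd=0.0, seed=1)
m = measure_recording(sim.recording)

print("window    truth-Tpe   estimated-Tpe   mean-RR")
for window in ("rest", "peak", "recovery"):
    print(
        f"{window:<9} {sim.truth_tpe(window):7.1f} ms {m.tpe_ms[window]:10.1f} ms"
        f" {m.rr_ms[window]:9.0f} ms"
    )

rec = TraitRecord(
    id="demo",
    tpe_rest=m.tpe_ms["rest"], tpe_peak=m.tpe_ms["peak"],
    tpe_recovery=m.tpe_ms["recovery"],
    rr_rest=m.rr_ms["rest"], rr_peak=m.rr_ms["peak"],
    rr_recovery=m.rr_ms["recovery"],
)
print(f"\nTpe response to exercise: {tpe_response_exercise(rec):.4f} ms/ms")
print(f"Tpe response to recovery: {tpe_response_recovery(rec):.4f} ms/ms")
print(
    "\nOn a noise-free record the estimates land within the 2 ms sampling"
    "\nresolution of the truth; the responses are the Tpe changes normalized"
    "\nby the RR changes, so small fiducial errors propagate into them."
)
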