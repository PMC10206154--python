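"""Ideal information gain from time integration.

The translation channel integrates T = kd_m/kd_g transcript correlation
times; the noise-free integration output of an NB(r, p) transcript
channel is NB(rT, p), so the ideal capacity c_ideal(T) is computed
without simulation.  The printed curves rise monotonically with T
(averaging suppresses transcript noise as T^-0.5) and saturate at the
input entropy log2 |X|; higher transcription power starts the curve
higher at T = 1.
"""

from cdchannel import PromoterControl, ideal_gain_curve

ctrl = PromoterControl(alpha=1.0, leak=0.01)
T_grid = (1, 2, 5, 10, 20, 50, 100, 200, 500, 1000)

print("T      " + "".join(f"power={p:<6g}" for p in (0.1, 1.0, 10.0)))
curves = [
    ideal_gain_curve(ctrl, k_m=p * 0.1, kd_m=0.1, T_grid=T_grid, n_inputs=16)
    for p in (0.1, 1.0, 10.0)
]
for i, T in enumerate(T_grid):
    row = "".join(f"{c.c_ideal[i]:<12.3f}" for c in curves)
    print(f"{T:<7g}{row}")
print("\nbits of information about the input available from an ideal "
      "integrator; ceiling = log2(16) = 4 bits")
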