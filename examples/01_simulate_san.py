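"""Simulate spontaneous SAN pacemaking and extract action-potential features.

Runs the calibrated single-cell model for 10 s, discards the convergence
transient, and prints the beating rate, cycle length, diastolic
depolarisation (DD) slope and maximum diastolic potential (MDP).
"""

from biopace import compute_ap_metrics, default_cell_params, simulate

params = default_cell_params()
print(f"total funny-current conductance: {params.g_f_total:.3f} nS/pF "
      f"(HCN1:HCN2:HCN4 = 3:1:6)")

trace = simulate(params, duration=10.0)
m = compute_ap_metrics(trace, discard_beats=20)

print(f"beating rate     : {m.rate:6.1f} bpm   (spontaneous limit-cycle rate)")
print(f"cycle length     : {m.cycle_length:6.1f} ms")
print(f"DD slope         : {m.dd_slope:6.3f} V/s  (diastolic depolarisation)")
print(f"MDP              : {m.mdp:6.1f} mV   (maximum diastolic potential)")
print(f"analysed beats   : {m.n_beats}")
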