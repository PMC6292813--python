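"""The four-rung simulation ladder: SAN -> SAP -> SAP-TBX18 -> SAP-TBX18+RYR2.

Each rung rescales the per-isoform funny-current conductances to that
preparation's measured transcript abundances (the final rung additionally
scales the SR Ca2+ release rate by the RYR2 fold-change), simulates to the
limit cycle and reports rate and diastolic depolarisation slope.
"""

from biopace import RunConfig, run_ladder

report = run_ladder(RunConfig(duration_s=10.0))

print(f"{'preparation':<16} {'rate (bpm)':>10} {'DD (V/s)':>9} "
      f"{'g_f tot':>8} {'RYR2':>5}")
for prep, vals in report["preparations"].items():
    print(f"{prep:<16} {vals['rate_bpm']:>10.1f} "
          f"{vals['dd_slope_v_per_s']:>9.3f} {vals['g_f_total']:>8.3f} "
          f"{vals['ryr2_scale']:>5.2f}")
print("\nExpected ordering: SAP < SAP_TBX18 < SAP_TBX18_RYR2 < SAN — the")
print("HCN2/HCN1 upregulation recovers most of the rate deficit, the RYR2")
print("increase a little more, without restoring the SAN's HCN4 level.")
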