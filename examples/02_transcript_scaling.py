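"""From qPCR Ct tables to isoform-specific funny-current conductances.

Generates a synthetic triplicate Ct table whose true abundances follow the
shipped SAN / SAP / SAP-TBX18 table, inverts it with the
efficiency-corrected delta-Ct method, prints the HCN4-relative isoform
ratios, and rescales the SAN cell parameters to the SAP-TBX18 preparation.
"""

from biopace import default_cell_params, isoform_ratios, scale_conductances
from biopace.synthetic_data import default_qpcr_config, gen_qpcr
from biopace.transcript_scaling import abundance_from_qpcr

# triplicate Ct table with 0.15-cycle technical noise
table = abundance_from_qpcr(gen_qpcr(default_qpcr_config(noise_sd=0.15, seed=1)))
print("HCN isoform ratios (HCN4-relative) recovered from the noisy Ct table:")
print(isoform_ratios(table).round(3))
print("  (reference triplets: SAN 1/0.07/0.17, SAP 1/0.97/2.07, "
      "SAP-TBX18 1/3.3/11.5 as HCN4/HCN1/HCN2)")

base = default_cell_params()
scaled = scale_conductances(base, table.row("SAP_TBX18"), table.row("SAN"))
print("\nper-isoform conductances (nS/pF), SAN base -> SAP-TBX18 scaled:")
for iso, ip in base.if_isoforms.items():
    print(f"  {iso.value}: {ip.g_max:.4f} -> "
          f"{scaled.if_isoforms[iso].g_max:.4f}")
print(f"RYR2 SR-release scale: {base.ryr2_scale:.2f} -> {scaled.ryr2_scale:.2f}")
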