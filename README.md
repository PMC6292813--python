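# biopace

Single-cell sinoatrial-node (SAN) pacemaker modelling with an
isoform-specific funny current, qPCR-driven transcript-to-conductance
scaling, and rhythm-stability analytics.

## Who this is for

Cardiac electrophysiology and biopacemaking researchers who want to ask:
*if a gene-therapy intervention shifts the HCN isoform balance of a slow
subsidiary atrial pacemaker (SAP), what does that do to its beating rate
and diastolic depolarisation?* — and who need the supporting toolchain:
ΔCt quantification of qPCR tables, beat detection on extracellular
electrogram-like signals, heart-rate-variability (HRV) statistics, and
overdrive-pacing recovery measures.

## The model in brief

A compact mouse-type SAN cell model (membrane clock I_CaL, I_CaT, I_Kr,
I_to, I_NaK, I_NCX, background Na⁺; Ca²⁺ clock with SERCA uptake and
RYR2-mediated SR release) in which the funny current is a sum of three
independently gated isoform components,

    I_f = Σ_iso g_iso · y_iso · [ f_Na (V − E_Na) + (1 − f_Na)(V − E_K) ],
    y∞(V) = 1 / (1 + exp((V − V½)/s)),

with measured activation midpoints V½(HCN1) = −75.2 mV, V½(HCN2) = −92.0 mV,
V½(HCN4) = −91.2 mV, kinetic ordering τ(HCN1) < τ(HCN2) < τ(HCN4) and a
basal conductance split g_HCN1 : g_HCN2 : g_HCN4 = 3 : 1 : 6.

Measured transcript abundances scale the conductances per isoform,

    g_iso(prep) = g_iso(SAN) · a(prep, iso) / a(SAN, iso),

and a measured RYR2 fold-change scales the SR Ca²⁺ release rate.  The
shipped abundance table encodes the HCN4-relative isoform ratio triplets
(SAN 1/0.07/0.17, SAP 1/0.97/2.07, SAP-TBX18 1/3.3/11.5, as HCN4/HCN1/HCN2).
See `docs/methods.md` for the full model description and calibration.

## Worked example

```sh
python examples/03_simulation_ladder.py
```

```
preparation      rate (bpm)  DD (V/s)  g_f tot  RYR2
SAN                   310.6     0.228    0.092  1.00
SAP                   266.7     0.168    0.020  1.00
SAP_TBX18             290.1     0.201    0.035  1.00
SAP_TBX18_RYR2        297.5     0.213    0.035  2.17

Expected ordering: SAP < SAP_TBX18 < SAP_TBX18_RYR2 < SAN — the
HCN2/HCN1 upregulation recovers most of the rate deficit, the RYR2
increase a little more, without restoring the SAN's HCN4 level.
```

Reading the numbers: the SAN configuration paces at ~310 bpm with a
diastolic depolarisation slope of ~0.23 V/s.  Rescaling the three funny-
current conductances to the SAP preparation's transcript levels (losing
most of the dominant HCN4 component) slows the cell to ~267 bpm and
flattens the DD slope; the TBX18-induced HCN2/HCN1 upregulation recovers
most of the deficit, and the RYR2-driven boost to SR Ca²⁺ release adds a
few bpm more via diastolic Na⁺/Ca²⁺-exchanger current.

Other capabilities, one script each, under `examples/`: single-cell
simulation and AP features (`01`), ΔCt quantification and conductance
scaling (`02`), HRV stability metrics with Poincaré outlier clusters
(`04`), electrogram beat detection with ectopic labelling (`05`), and
corrected recovery time after overdrive pacing (`06`).

There is also a thin CLI:

```sh
biopace ladder --out-dir runs/demo
biopace simulate --duration 10 --out trace.csv && biopace metrics trace.csv
biopace synth rr --regime SAP-like --seed 1 --out rr.csv && biopace hrv rr.csv
```

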