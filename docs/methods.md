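# Methods

## Scientific setting

Subsidiary atrial pacemaker (SAP) tissue at the inferior crista terminalis
paces like a slow, unstable sinoatrial node (SAN): it is bradycardic, shows
pauses and ectopy, and responds weakly to β-adrenergic stimulation. TBX18
overexpression in this tissue shifts the HCN channel isoform balance
(a large HCN2 increase, an HCN1 trend, little HCN4 change) and raises RYR2.
This package implements the computational counterpart of that biology:

1. a single-cell SAN ionic model whose funny current I_f is decomposed into
   HCN1/HCN2/HCN4 components with isoform-specific activation midpoints and
   kinetics;
2. transcript-to-conductance scaling that maps qPCR-derived relative mRNA
   abundances onto per-isoform maximal conductances (and the RYR2
   fold-change onto the SR Ca²⁺ release rate);
3. action-potential feature extraction (rate, cycle length, diastolic
   depolarisation slope, maximum diastolic potential);
4. rhythm-stability analytics for beat-interval series (SDRR, RMSSD,
   Poincaré SD1, outlier clusters, rate-response ratios, corrected recovery
   time after overdrive pacing);
5. seeded synthetic-data generators for every input (RR series,
   electrogram-like signals, qPCR Ct tables).

## The cell model

### Chassis

The chassis is a compact mouse-type central-SAN cell model written for this
package. It keeps the standard division of labour of SAN models — a
"membrane clock" (I_CaL, I_CaT, I_Kr, I_to, I_NaK, background Na⁺) and a
"Ca²⁺ clock" (SERCA uptake, RYR2-mediated Ca²⁺-induced Ca²⁺ release and a
diastolic SR leak feeding the electrogenic Na⁺/Ca²⁺ exchanger) — but with a
deliberately small state vector (13 states) so the full simulation ladder
runs in seconds on one CPU. Intracellular Na⁺ and K⁺ are held fixed;
Ca²⁺ in cytosol and SR is dynamic. Published mouse-SAN formulations whose
complete equation sets are not reproducible here are therefore not copied;
instead the chassis is calibrated once (see *Calibration*) to the reference
basal behaviour of the mouse SAN simulations it emulates — spontaneous rate
≈ 308.6 bpm and diastolic depolarisation slope ≈ 0.23 V/s — and then frozen.

Conventions: mV, ms, mM; current densities in pA/pF and conductances in
nS/pF, so membrane capacitance only enters the Ca²⁺ flux bookkeeping
(C_m = 25 pF, cytosolic volume 2 pL, SR volume 0.2 pL).

### Isoform-specific funny current

I_f is the sum of three independently gated components:

    I_f,iso = g_iso · y_iso · [ f_Na (V − E_Na) + (1 − f_Na)(V − E_K) ]

* Steady-state activation is a Boltzmann, y∞(V) = 1/(1+exp((V−V½)/s)),
  with measured midpoints V½ = −75.2 mV (HCN1), −92.0 mV (HCN2),
  −91.2 mV (HCN4). The source literature gives only midpoints, so a common
  slope factor s = 9 mV is used for all three isoforms (configurable per
  isoform).
* The activation time constant is a bell-shaped function of voltage shared
  by all isoforms, multiplied by an isoform speed factor (defaults 0.25 /
  1.0 / 2.5 for HCN1 / HCN2 / HCN4). Only the kinetic *ordering*
  HCN1 < HCN2 < HCN4 is asserted by the biology; the absolute values are
  configurable.
* Each isoform carries Na⁺ and K⁺ with fraction f_Na = 0.38, placing the
  composite reversal near −25 mV as in lumped I_f formulations; per-isoform
  permeability ratios are not available, so f_Na is identical across
  isoforms by default.
* The basal conductance split is g_HCN1 : g_HCN2 : g_HCN4 = 3 : 1 : 6,
  HCN4 being the dominant native component.

At a maximum diastolic potential near −70 mV, HCN1 (midpoint −75.2 mV) is
substantially activated while HCN2/HCN4 (≈ −92 mV) sit on the foot of their
activation curves; this is what makes the rung-to-rung isoform shifts —
not just the total conductance — matter for rate.

### Transcript-to-conductance scaling

Relative abundance from qPCR uses the efficiency-corrected ΔCt form

    abundance = eff_ref^Ct(18S) / eff_gene^Ct(gene),

with technical triplicates averaged on the Ct scale before exponentiation
(the SEM of replicates is reporting-only). Scaling assumes transcript level
is proportional to functional membrane protein:

    g_iso(prep) = g_iso(SAN) · abundance(prep, iso) / abundance(SAN, iso).

The shipped abundance table is reconstructed from the measured
within-preparation isoform ratios (HCN4/HCN1/HCN2 = 1/0.07/0.17 for SAN,
1/0.97/2.07 for SAP, 1/3.3/11.5 for SAP-TBX18) and the measured HCN2
absolute abundances (SAP 1.01×10⁻⁵, SAP-TBX18 2.8×10⁻⁵ a.u.). Those
measurements leave one degree of freedom — the absolute SAN anchor (the SAN
HCN4 abundance in the same units) — which is exposed as a single config
scalar and fixed by the calibration below. The RYR2 row is stored as a
fold-change (1.0 for SAN/SAP; the SAP-TBX18 fold is a calibrated scalar,
see below) and multiplies the SR release and leak rate constants on the
RYR2 rung only.

### Calibration (performed once, then frozen)

Free quantities not fixed by the source measurements — the chassis
conductances, the common I_f slope and tau shape, the SAN abundance anchor,
and the RYR2 fold/coupling — were calibrated in a single derivative-free
optimisation against the reference simulated behaviours of the four-rung
ladder (rates 308.6 / 265.3 / 288.8 / 298.5 bpm; DD slopes 0.23 / 0.17 /
0.20 V/s), then frozen as the package defaults. No further adjustment is
performed anywhere in the code or tests.

Frozen values: total g_f = 0.092 nS/pF (split 3:1:6), g_CaL = 0.3592,
g_CaT = 0.17868, g_Kr = 0.63536, g_to = 0.08273 nS/pF, I_NaK,max =
0.07981 pA/pF, SAN HCN4 anchor = 1.3675×10⁻⁴ a.u., RYR2 fold
(SAP-TBX18) = 2.17.  With these defaults the ladder reproduces
310.6 / 266.7 / 290.1 / 297.5 bpm and DD 0.228 / 0.168 / 0.201 V/s
(10-s simulations, first 20 beats discarded).  Defaults live in code
(`default_cell_params`, `default_abundance_table`) and any configuration
can be exported/loaded as YAML/CSV via `biopace.io`.

### Numerics

* Stiff-capable adaptive integration (LSODA), rtol 1e-6, atol 1e-8,
  max step 1 ms, output sampled at 0.25 ms. Deterministic for a given
  parameter set and solver configuration.
* Limit-cycle protocol: simulate 10 s, detect beats, discard the first 20
  beats as convergence transient, compute metrics on the remainder
  (≥ 10 beats).
* Voltage-clamp I–V: because the gating ODEs are linear at fixed voltage,
  clamp relaxation is evaluated in closed form (exponential toward y∞ with
  tau(V_test)); end-of-pulse |dI/dt| above tolerance flags an unreached
  steady state.

## Feature extraction

* Beat fiducial: time of maximum dv/dt, robust to MDP differences between
  parameter sets; refractory separation 50 ms.
* DD slope: linear least-squares fit of v(t) from 5 ms after the MDP to the
  first sample with dv/dt > 0.5 V/s (the upstroke foot); the published
  measurement window is not stated anywhere, so both edges are configurable
  and the reported slopes carry that window-definition sensitivity.
* MDP: per-cycle minimum between successive fiducials.

## Rhythm-stability analytics

Sample statistics use ddof = 1 throughout. SD1 is computed geometrically
(SD of perpendicular distances of (RR[n], RR[n+1]) to the identity line);
the test suite verifies it equals SD(ΔRR)/√2 to 1e-9 against brute-force
loops. Outlier clusters on the Poincaré cloud replace visual ectopy
categorisation with a reproducible rule: |RR − median| > k·MAD (default
k = 5), short-coupled beats and pauses reported separately. Rate response
is the percent change of mean-RR-derived rate. Corrected recovery time is
cRT = (first post-train spontaneous beat − last paced beat) − spontaneous
cycle length, averaged over trains, with a timeout flag for suppression
failures. A "2-hour analysis window" maps to "the full provided series";
cropping is an option, not a default.

## Synthetic data

The generators emulate the *structure* of the experimental inputs, not
their physiology:

* `gen_rr`: i.i.d. Gaussian cycle-length jitter (optionally Student-t for
  heavy tails) with a per-beat event mixture of pauses (factor × CL > 1)
  and short-coupled ectopics (factor < 1), ground-truth labels attached.
  Preset regimes: "SAP-like" (base CL 416 ms ≈ 144 bpm, jitter 35 ms,
  1% pauses, 2% ectopics) and "TBX18-like" (280 ms ≈ 214 bpm, jitter 6 ms)
  — derived from the measured preparation rates; they are calibration
  targets for *ordering and separation*, not reproductions of measured HRV
  values, which come from ex vivo recordings that are not deposited.
* `gen_signal`: biphasic (sine × Hann) template at cumulative beat times,
  ectopics rendered with an inverted, wider, lower-amplitude template,
  Gaussian noise at configured SNR. Real electrograms have baseline wander,
  far-field components and non-stationary morphology; passing round-trip
  tests therefore demonstrates detector correctness, not field performance.
* `gen_qpcr`: Ct = Ct(18S) − ln(abundance)/ln(efficiency) plus Gaussian
  replicate noise; the noise-free table inverts exactly, and averaging Ct
  before exponentiation leaves a small lognormal bias that stays within
  sampling error at the default 0.2-cycle noise.

All generators use `numpy.random.Generator` (PCG64) seeded explicitly;
identical seeds give identical output on any platform.

## Known limitations

* The chassis is a compact model: it reproduces rate, DD slope, MDP and
  their responses to I_f/RYR2 scaling, but it is not a complete reproduction
  of any published mouse SAN formulation; absolute current densities and
  AP morphology details (e.g. upstroke velocity) are not calibration
  targets.
* Rate increases monotonically with uniform funny-current scaling across
  the calibrated range; far outside it (≳ 2× total g_f) the Ca²⁺ subsystem
  can enter alternans-like regimes, as real pacemaker models also do.
* mRNA → protein 1:1 proportionality is an explicit modelling assumption.
* No tissue-level propagation, no autonomic modelling, no channel-level
  pharmacodynamics (CsCl/isoprenaline effects appear only as rate-ratio
  statistics on RR series).
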