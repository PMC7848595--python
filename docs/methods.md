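# Methods

`emcell` simulates single human ventricular cardiomyocytes in which
electrophysiology and active contraction are strongly (bidirectionally)
coupled, and uses them for in-silico drug trials with simple pore-block
pharmacology. This note documents the model composition, the coupling,
the numerical scheme, the calibration, the synthetic-data generator, and
the design choices that were genuinely open.

## Model composition

Two human ventricular electrophysiology models are implemented as
alternative backends:

* **ToR-ORd** — the Tomek–Rodriguez revision of the O'Hara–Rudy model:
  re-evaluated L-type calcium current with ionic-activity (Davies
  equation) driving forces and a junctional/bulk split (80%/20%), a
  five-state Markov IKr, a ten Tusscher-style INa, an instantaneous
  rectifying IK1, and calcium-sensitive plus background chloride
  currents. 43 states.
* **ORd** — the original O'Hara–Rudy model with the Dutta conductance
  rescaling (GKr ×1.013, GKs ×1.87, GK1 ×1.698, GNaL ×2.661,
  PCa ×1.007), the parameterisation used in regulatory in-silico
  proarrhythmia work. 41 states.

Model equations are transcribed from the source publications. The
transcription is audited three ways: (i) a *current-sum oracle* — an
independent, readable re-implementation of every membrane current
(`emcell.ep.reference`) against which the compiled kernel's dV/dt must
agree to 1e-12 relative on randomised states; (ii) a *calcium
bookkeeping audit* — the volume-weighted derivative of total cell
calcium (free + buffered in myoplasm, subspace, and both SR
compartments) must balance the net sarcolemmal calcium flux to 1e-8;
(iii) *behavioural validation* — pacing the ORd backend (with the
original 2011 conductances) from the published 1-Hz steady state leaves
every concentration within 0.3% over 50 beats, and both backends
reproduce the published resting potentials, APD90 and calcium-transient
kinetics.

Transmural cell types are derived from the endocardial base exclusively
by the source models' multiplicative scalings. For ToR-ORd:
epi = {GNaL ×0.6, Gto ×2, PCa ×1.2, GKr ×1.3, GKs ×1.4, GK1 ×1.2,
Gncx ×1.1, Pnak ×0.9, GKb ×0.6, SERCA ×1.3, calmodulin ×1.3, and the
epicardial Ito inactivation-time modifier}; mid = {Gto ×2, PCa ×1.8,
GKr ×0.8, GK1 ×1.3, Gncx ×1.4, Pnak ×0.7, RyR release ×1.7}. For ORd
the same structure with Ito ×4 and PCa ×2.5 (mid). The ATP-sensitive
potassium current of ToR-ORd is omitted; its published baseline open
fraction is zero, so it contributes no current in any protocol here.

Active tension comes from the Land human contraction model: calcium
binding to troponin C (Hill coefficient `n_trpn = 2`, rate
`k_trpn = 0.1/ms`, half-activation `ca50 = 0.805 uM` with linear length
correction), cooperative tropomyosin blocking/unblocking, and a
three-state crossbridge cycle (unattached → weakly bound → strongly
bound) with distortion variables. Tension is reported in kPa with the
identity 1 kPa = 1 mN/mm², so experimental twitch amplitudes apply
directly. All single-cell protocols are isometric at extension ratio
λ = 1 (dλ/dt = 0); λ is validated to [0.8, 1.2].

## Bidirectional coupling

The free intracellular calcium of the electrophysiology model drives
the contraction model; the contraction model's dynamic troponin-C
occupancy is fed back into the calcium ODE: the troponin term of the
steady-state buffer factor is removed and replaced by an explicit flux
`-[TRPN]_tot * d(CaTRPN)/dt` with `[TRPN]_tot = 0.07 mM` (the
electrophysiology models' own total troponin concentration). Calmodulin
and the subspace/SR buffers are untouched. The electrophysiology-only
comparator (`coupled=False`) retains the published steady-state
troponin buffer while the contraction model is driven one-way, i.e. it
is exactly the uncoupled published model plus a passive force readout.
There are no stretch-activated currents: the mechano-electric feedback
is via troponin buffering only.

## Numerical scheme

The coupled ODE system is advanced by a deterministic hybrid scheme
compiled with numba:

* gates and all other states of `(x_inf - x)/tau` or linear
  inflow/outflow form use the exponential (Rush–Larsen) update, which
  is unconditionally stable — this matters for the ToR-ORd IKr Markov
  chain, whose closed-state deactivation rates reach ~50/ms at
  diastolic potentials; the Markov chain is renormalised onto the
  probability simplex each step;
* membrane potential, concentrations, CaMKII and the contraction
  fractions use forward Euler;
* the step is 0.005 ms while |dV/dt| > 1 mV/ms or the subspace calcium
  changes faster than 5%/ms, and 0.05 ms otherwise, always landing
  exactly on stimulus edges and output samples.

The schedule is fixed, so repeated runs are bit-identical (there is no
randomness anywhere in the forward model). Halving both step sizes
changes APD90 by < 0.5 ms and peak tension by < 0.5%, and a one-beat
comparison against SciPy's adaptive stiff solver (LSODA, rtol 1e-7)
run on the same right-hand side agrees to < 0.5 ms in APD90 — both are
enforced in the test suite. An implicit ode15s-family solver was
considered and kept available through the Python-level
`coupled_rhs`/`solve_ivp` route, but the compiled fixed-schedule scheme
was adopted as the primary integrator for determinism and for the speed
the 200-beat drug protocols require.

Stimuli follow the source models: −53 uA/uF for 1 ms (ToR-ORd),
−80 uA/uF for 0.5 ms (ORd), applied at the start of each cycle and
booked into the potassium balance. Output is sampled at 0.5 ms
(resolves EAD morphology; halving it moves APD90 by < 0.5 ms).

## Steady state and snapshots

"Steady state" is operationalised as: the relative spread of APD90,
calcium-transient peak and tension peak over the last 10 beats falls
below 0.05%, with a cap of 1500 beats (non-convergence is reported, not
fatal). Pre-paced snapshots for the standard configurations (variant ×
cell type × cycle length × coupling mode) are regenerated by
`scripts/make_snapshots.py` and shipped as JSON with metadata (state
ordering is versioned and validated on load). The 0.25 Hz
configurations hit the 1500-beat cap with a residual APD90 drift of
~0.003 ms/beat, which is negligible for every comparison made from
them; all other configurations converge. Protocols in tests and the
acceptance script start from these snapshots and re-settle for 2–30
beats, which keeps the default suite fast without changing any result.

## Calibration

The coupled models' calcium transients are close to human myocyte
recordings but smaller and faster than the transient the contraction
model was originally fitted to, so the contraction model is
recalibrated — exactly two parameters are varied: the Hill coefficient
of cooperative (tropomyosin) activation `n_tm` (published value 5) and
the tropomyosin rate constant `k_tm` (published 0.021/ms). Targets are
isometric twitch biomarkers of intact human ventricular preparations at
1–1.2 Hz, encoded as intervals (mean ± 2 SEM, pooled across studies):
amplitude [10.1, 25.6] mN/mm², time to peak [137, 179] ms, rt50
[101, 133] ms, rt95 [248, 539] ms. The cost is the weighted distance to
the interval, normalised by interval width — zero iff every biomarker
is inside. Each cost evaluation re-paces the coupled cell for 30 beats
from the baseline snapshot (contraction parameters feed back on calcium
only weakly, so this settles; verified by drift tests). The optimiser
is a deterministic coarse grid seed followed by bounded Nelder–Mead.
Fitted values (stored with provenance in
`src/emcell/data/calibrated_land.json`, regenerated by
`scripts/calibrate.py`): ToR-ORd+Land `n_tm = 2.0, k_tm = 0.020`;
ORd+Land `n_tm = 2.5, k_tm = 0.020`; both reach cost 0 and leave AP and
calcium biomarkers untouched (< 0.5 ms).

## Biomarkers and abnormality detectors

Times-to-peak are measured from stimulus onset; APDx from the AP onset
(maximal upstroke velocity) to the interpolated crossing of
`peak - x%·(peak - resting)`; resting/diastolic references are the
pre-stimulus values so distorted beats keep defined thresholds; rtX is
the time from a transient's peak to X% decay of (peak − diastolic).
The calcium-transient duration used for the electro-mechanical window
is `tp + rt90`, i.e. EMw = APD90 − (CaT tp + rt90); the convention is
held fixed across every compared condition, so convention-dependent
offsets cancel in differences. Signed EMw is negative at baseline in
these cells (mechanical systole outlasts electrical systole), so the
*size* of the window is its magnitude |EMw|: the coupled formulation's
faster calcium decay makes |EMw| smaller, and drug-induced "EMw
shortening" is the reduction of |EMw|. All cross-condition EMw
statements in the tests use this magnitude reading.

Early afterdepolarisations are flagged when dV/dt exceeds +0.01 mV/ms
for ≥ 2 ms inside the repolarisation window. The window opens 150 ms
after the AP peak and requires V > resting + 10 mV: the delay keeps the
physiological epicardial notch-and-dome rise (an early positive slope)
from being a false positive, while drug-induced EADs in these models
take off hundreds of milliseconds into the plateau. Aftercontractions
are detected analogously on tension with a threshold of 0.02% of the
beat's peak tension per ms sustained for ≥ 10 ms: at slow pacing a
genuine aftercontraction can rise by several kPa at only ~0.05% of
peak per ms, so a steep slope threshold with short persistence (the
first design tried) misses it, whereas the deterministic traces are
strictly monotone during normal relaxation and tolerate a lower slope
threshold when paired with the longer persistence. Both tolerances are
arguments. A beat is a contractility escape when its developed tension
is below 10% of the drug-free steady-state developed tension (the
fraction is configurable; the source definition is qualitative).
Detector specificity — zero false flags across drug-free steady states
of both variants, three cell types, 0.25–2 Hz — is a test.

## Drug trials

Drug action is conductance scaling by simple pore block:
`g -> g * (1 - c^h / (c^h + IC50^h))` per affected current; no
state-dependent binding. The trial protocol: reach drug-free steady
state, apply the drug, pace 200 further beats at the same rate without
re-converging, inspect the last 10 beats; biomarker deltas are
control-subtracted at identical cycle length. Dose–response curves
report the percentage reduction of peak developed tension versus
control and are summarised by a least-squares Hill fit on
log-concentration with the maximal effect fixed at 100% (full block of
the driving calcium current abolishes contraction in the limit, and the
two-parameter summary matches how such curves are reported).

The compound potency table (`src/emcell/data/drug_table.csv`) is
transcribed from the multichannel manual patch-clamp dataset used for
human in-silico drug trials. Two entries are anchored by the analysis
itself (verapamil ICaL 0.2 uM/0.8; quinidine IKr 0.72 uM/1.06); the
remaining entries carry dataset-transcription uncertainty, and
minor-channel potencies (late-sodium and IK1 block for verapamil and
quinidine) whose source values could not be transcribed confidently are
omitted rather than guessed — the table header says so. Because the
late sodium current carries a substantial fraction of the plateau
inward current, this omission biases simulated drug-induced APD90
prolongations upward by roughly 10–15% relative to a table that blocks
INaL, which should be kept in mind when comparing absolute ΔAPD90
values against other implementations; fitted tension IC50s are far less
sensitive.

## Synthetic-data generator

`emcell.waveforms` produces closed-form beat trains — triangular action
potentials and raised-cosine transients, with optional injected EAD
humps, aftercontraction bumps, or dropped beats — together with their
exact analytic biomarkers. It emulates only waveform geometry: no
channel noise, no beat-to-beat variability, no baseline drift, no
fluorescence-style distortion of real recordings. Tests passing on
these waveforms therefore establish the *extractors'* correctness
(interpolation, windows, thresholds), not robustness to experimental
noise; robustness on model output is covered separately by the
determinism and resolution-halving tests.

## Problem sizes used

Default-suite protocols settle 2–50 beats from shipped snapshots; the
oracle checks use 50–1000 random states; drug-trial tests run the full
200-beat protocol per concentration (5 verapamil, 7 quinidine, 5
modified-verapamil, 2 ORd-verapamil concentrations at 1 Hz; 4
dofetilide concentrations at 0.25 Hz in both coupled and uncoupled
modes); the calibration recovery test fits 2 parameters with ~50 cost
evaluations of 15 settling beats each.

## Known limitations

* No after-load or sarcomere-length dynamics: contraction is isometric
  at fixed λ; length-dependence is probed only through static λ values.
* No tissue-level electrotonic coupling; single-cell EAD/escape
  behaviour stands in for tissue phenomena.
* The potency table's minor-channel omissions (above) shift absolute
  ΔAPD90 under multichannel compounds.
* The resting ToR-ORd state reproduces the published resting potential
  to ~0.4 mV and published steady concentrations to a few percent;
  residual transcription differences of that size are possible in
  currents that the oracle and behavioural checks constrain only
  weakly (e.g. exact Markov IKr rate constants).
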