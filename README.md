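# emcell

Strongly coupled human ventricular electro-mechanical cell models and
an in-silico drug-trial engine for joint pro-arrhythmia and inotropy
assessment.

## The problem

Cellular drug-safety screening has mostly treated electrophysiology and
contraction separately, yet they are one system: the calcium transient
that triggers force is shaped by the action potential, and the calcium
bound to troponin C is removed from the free pool that feeds back on
membrane currents. `emcell` implements virtual human ventricular
cardiomyocytes in which the two are strongly coupled, for users who
want to ask — in one simulation — whether a compound prolongs the
action potential, triggers early afterdepolarisations (EADs) or
aftercontractions, and how much it depresses (or augments) contraction.

## The model

Electrophysiology: the ToR-ORd human ventricular model (default) or the
O'Hara–Rudy model with the Dutta conductance set, for endocardial,
epicardial and mid-myocardial cells. Contraction: the Land human active
tension model (troponin-C and tropomyosin kinetics, three-state
crossbridge cycle with distortion). Coupling is bidirectional: Caᵢ
drives the contraction model, and the troponin term of the calcium ODE
is replaced by the dynamic flux −[TRPN]ₜₒₜ·d(CaTRPN)/dt. Drug action is
simple pore block: each affected conductance is scaled by
1 − cʰ/(cʰ + IC50ʰ). The contraction model is recalibrated (two
parameters: the tropomyosin cooperativity n_tm and rate constant k_tm)
so the coupled models reproduce human isometric twitch data; the fitted
values ship with provenance in `src/emcell/data/calibrated_land.json`.

Biomarkers follow the standard definitions: AP time-to-peak and
APD50/APD90; calcium-transient tp and rt50/rt90; tension tp and
rt50/rt95 (1 kPa = 1 mN/mm²); the electro-mechanical window
EMw = APD90 − CaTD90; plus detectors for EADs (positive repolarisation
slope), aftercontractions (secondary tension rise) and contractility
escapes (stimulus without a contraction).

## Worked example

```python
from emcell import make_params, pace, default_protocol, Variant, full_report
from emcell.snapshots import get_steady_state
from emcell.drugs import get_drug, drug_trial

# calibrated ToR-ORd+Land endocardial cell, 1 Hz steady state
y0, mech = get_steady_state("torord", "endo", cl=1000.0, coupled=True)
ep = make_params("torord", "endo")
proto = default_protocol(Variant.TORORD, cl=1000.0, n_beats=2, record_last=1)
trace, _ = pace(y0, ep, mech, proto)
rep = full_report(trace, 0)
print(f"APD90 = {rep.ap['apd90']:.1f} ms, CaT tp = {rep.cat['tp']:.1f} ms, "
      f"peak tension = {rep.ta['peak'] - rep.ta['diastolic']:.1f} kPa, "
      f"EMw = {rep.emw:.1f} ms")

# a 200-beat verapamil trial at 1 uM
res = drug_trial("torord", "endo", get_drug("verapamil"), c=1.0)
print(f"verapamil 1 uM: dAPD90 = {res.deltas['ap_apd90']:+.1f} ms, "
      f"peak-tension change = {res.deltas['ta_peak']:+.1f} kPa ({res.outcome})")
```

prints

```
APD90 = 270.3 ms, CaT tp = 42.5 ms, peak tension = 23.9 kPa, EMw = -80.0 ms
verapamil 1 uM: dAPD90 = +113.9 ms, peak-tension change = -23.5 kPa (escape)
```

The drug-free beat sits inside the human experimental ranges (APD90
178–443 ms; twitch amplitude 10–26 mN/mm²; calcium time-to-peak
38–58 ms), and the negative EMw reflects the faster calcium decay of
the coupled formulation. Verapamil at 1 uM blocks most of ICaL and much
of IKr: the AP prolongs while developed tension collapses below the
10%-of-control escape threshold — the classic negative-inotropic
signature. `emcell.drugs.dose_response_tension` summarises such runs
into a Hill curve (verapamil: IC50 0.05 uM, Hill 1.0).

A CLI mirrors the library:

```sh
emcell pace --variant torord --beats 10 --out trace.csv
emcell biomarkers --trace trace.csv --out report.json
emcell trial --drug dofetilide --conc 0.06 --cl 4000 --out trial.json
emcell dose-response --drug verapamil --out dr.json
```

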