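# neocirc

A lumped-parameter simulator of cerebral haemodynamics and oxygen metabolism
in the preterm neonatal brain. The model takes arterial blood pressure,
arterial oxygen saturation, arterial CO2 tension and a dimensionless neuronal
demand signal as inputs, and produces the observables of functional
near-infrared spectroscopy — changes in oxy-, deoxy- and total haemoglobin
(ΔHbO2, ΔHHb, ΔHbT, μM) and in oxidised cytochrome-c-oxidase (ΔoxCCO) —
together with cerebral blood flow (CBF), oxygen consumption (CMRO2) and blood
volume (CBV).

## Model

Three dynamic states are integrated: vascular smooth-muscle tone, tissue
oxygen concentration and the oxidised CuA fraction of cytochrome-c-oxidase.
Pressure constricts the vasculature; CO2, low tissue oxygen and neuronal
demand dilate it; flow follows a quartic radius law against the
arterial-to-intracranial pressure gradient. Demand weakly raises oxygen
consumption and strongly dilates, producing functional hyperemia. All closure
constants are solved at calibration so the published normal values (adult and
preterm parameter columns) are an exact equilibrium.

Stimuli follow a peak-normalised haemodynamic response function (difference
of two gamma kernels convolved with the stimulus boxcar), scaled by three
amplitudes: `alpha` (demand), `beta` (pressure decrease, mmHg) and `gamma`
(direct radius reduction). Six named scenarios reproduce the published
simulations, including the CBF-clamped variants. A note on units: blood
haemoglobin is carried in mM *haem* (one O2 binding site per haem), which
makes baseline oxygen extraction fractions physiologically sensible
(≈ 0.22 preterm, ≈ 0.36 adult).

## CLI

```sh
neocirc list-scenarios
neocirc simulate --scenario roche_labarbe --out roche.csv
neocirc autoreg --preset preterm --pmin 15 --pmax 50 --step 1 --out curve.csv
neocirc make-fixture --scenario usz_neonate1 --noise 0.05 --seed 1 --out fix.csv
neocirc fit --traces fix.csv --scenario usz_neonate1 --free alpha --seed 1 --out fit.json
```

`simulate` writes a trajectory CSV
(`time,dHbO2,dHHb,dHbT,dOxCCO,rCBF,rCMRO2,rCBV,Pa,u`) plus a JSON metadata
sidecar. `fit` performs bounded multi-start least squares of the chosen
amplitudes against measured Δ-signal traces (CSV with columns
`time,dHbO2,dHHb[,dHbT]`, any channel subset) and reports a
Jacobian-condition identifiability diagnostic.

## Python API

```python
import numpy as np
import neocirc

params = neocirc.load_preset("preterm")       # calibrated parameter set
traj = neocirc.run_scenario("roche_labarbe")  # Trajectory with Δ-signals
p, cbf = neocirc.autoregulation_curve(params, np.arange(15.0, 50.0, 1.0))
```

Parameter presets (`adult`, `preterm`, `neonate1`, `neonate2`) ship as YAML
under `neocirc/presets/`; subject presets apply haemoglobin (g/dL → mM haem)
and baseline SpO2 overrides to the preterm population values.

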