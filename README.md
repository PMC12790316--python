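# co2screen

Virtual screening of carbon-centered nucleophiles for thermodynamically
stable CO2 adducts.

Base-mediated C–H carboxylation uses CO2 as a C1 building block: a base
deprotonates a C–H acid, and the resulting carbanion attacks CO2 to form
a carboxylate. Because CO2 is a thermodynamic sink, most carbanions do
not form *stable* adducts, and synthesizing every candidate to find out
is expensive. `co2screen` automates the desk-side alternative: given
only SMILES strings of candidate carbanions, it predicts the **CO2
affinity**

> CO2A = −ΔG°(R⁻ + CO2 → RCOO⁻)  (kcal mol⁻¹)

so that CO2A > 0 marks a thermodynamically stable adduct. The target
structures share one pattern: a carbanionic site **CA** (carbon, formal
charge −1) with exactly two carbon neighbors **C1**/**C2**.

## The model

CO2 affinity is predicted by a three-parameter multivariate linear
regression on z-scored descriptors:

* **ε_HOMO** (Hartree) — energy of the highest occupied molecular
  orbital; a higher (less negative) value means an electron pair that is
  easier to donate into CO2's π* system,
* **μ_CA** (a.u.) — magnitude of the Hirshfeld atomic dipole at CA;
  larger values indicate stronger electrostatic attraction of CO2,
* **buried B1** (Å) — Verloop's minimal steric half-width at CA,
  averaged over the CA→C1 and CA→C2 axes and restricted to atoms within
  a 5.5 Å sphere; local bulk that shields the formed adduct.

Each descriptor is computed per conformer and aggregated over the
ensemble four ways (min, max, Boltzmann-weighted average, lowest-energy
conformer). A cheap pre-screen discards candidates with
ε_HOMO < −0.140 E_h (boundary inclusive) before any refined-level
calculation — in the two-round workflow only survivors get the
expensive affinity-level treatment.

The electronic-structure numbers come from a pluggable backend: parse
engine output files, adapt an external engine, or use the deterministic
(non-physical) mock backend that ships with the package for pipeline
work without an engine.

## Worked example

Train a model on a descriptor table with a `co2a` response column
(here, a bundled synthetic table with three informative descriptors and
three decoys, n = 31):

```bash
$ python -c "
from co2screen.fixtures import SyntheticSpec, make_descriptor_table
make_descriptor_table(SyntheticSpec(n_samples=31, n_decoys=3, seed=2)) \
    .to_csv('desc.csv', index_label='id')"
$ co2screen train --table desc.csv --subset-size 3 --out train_out
model: ['x1', 'x2', 'x3']
R2(train) = 0.931, R2(test) = 0.909, Q2(LOO) = 0.902, R2(5-fold) = 0.900
```

The exhaustive subset search evaluated all C(6,3) = 20 descriptor
triples, ranked them by leave-one-out Q², and recovered the three
informative descriptors; `train_out/` holds the full leaderboard, the
fitted model (JSON) and the metrics report.

Screen a batch of carbanions end to end (mock backend):

```bash
$ cat batch.smi
[CH-]1C=Cc2ccccc21 indenide
[CH-](C#N)C#N malononitrile
CC(=O)[CH-]C(C)=O acac
[CH3-] methide
$ co2screen screen --input batch.smi --model model.json --backend mock --out run1
$ cat run1/results.csv
id,epsilon_homo,passed_homo_filter,co2a_pred,stability_call
indenide,-0.1380782897,True,1.4579860011416075,stable
malononitrile,-0.1578195348,False,,screened-out
acac,-0.141401469,False,,screened-out
$ cat run1/rejects.tsv
id	line	reason
methide	4	carbanionic site has 0 carbon neighbors, need 2
```

Every input line is accounted for: methide lacks the CA(C1)(C2) pattern
and lands in the rejects report; malononitrile and acac fall below the
−0.140 E_h HOMO screen (no affinity is predicted for them, and no
refined-level backend calls were spent on them); indenide passes and
gets a predicted affinity of +1.46 kcal mol⁻¹, i.e. a stable adduct
call. `run1/` also contains `summary.json`, an affinity-ranking bar
chart and the ε_HOMO-vs-site-dipole descriptor map (marker size =
buried B1, color = affinity).

All results are cached content-addressed by structure and settings:
rerunning the same command performs zero backend calls and reproduces
the report bit for bit.

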