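# nfkbuv

A minimal ordinary-differential-equation model of NF-κB/IκBα negative
feedback in human epithelial cells under IL-1β, UVB, MG132 and cycloheximide
stimulation — with the χ² fitting machinery, model-variant discrimination
and synthetic-data tooling needed to study how UVB switches NF-κB from a
transient to a sustained activity mode.

## The scientific problem

IL-1β activates IKKβ, which marks IκBα for proteasomal degradation and
frees NF-κB to enter the nucleus; NF-κB then drives IκBα resynthesis, and
the negative feedback loop shuts the signal off within about two hours.
Co-stimulation with UVB radiation breaks this loop: IκBα does not recur and
NF-κB remains active. Two mechanisms can explain the broken feedback, and
both are in the model:

* **PP2Ac deactivation** — UVB deactivates the catalytic subunit of the
  phosphatase PP2A at rate `k_uv`, so IKKβ stays partially phosphorylated;
* **translational inhibition** — UVB attenuates protein synthesis by a
  fraction `uvinh` (applied to IκBα *and* IL-1-receptor synthesis).

The reference model `M_ref` carries both; nested variants delete one each
(`M_P`: `k_uv = 0`, `M_T`: `uvinh = 0`). Which mechanism matters, and when,
is decided by fitting all variants to time courses of three observables
(phospho-IKKβ, total cellular IκBα, nuclear NF-κB) and by discriminating
*in-silico* experiments.

## The model

Eight states: normalised IL-1 receptor (`ILR`), active receptor complex
(`ILRc`), active PP2Ac (`PP2A`), phosphorylated IKKβ (`IKKp ∈ [0,1]`),
IκBα mRNA, free cytosolic IκBα, free nuclear IκBα and nuclear NF-κB (µM).
Mass conservation closes the system: `IKK = 1 − IKKp` and
`IκBα·NF-κB = nfkb_tot − NFκB_n/k_v`, where `k_v = 2.9` is the
cytoplasm:nucleus volume ratio and `nfkb_tot` follows from 60 000 NF-κB
molecules in a 2 pl cell. Key rate laws:

    dPP2A/dt  = −k_uv·uv·PP2A
    dIKKp/dt  = (k_p·ILRc + k_pconst)·(1−IKKp) − k_dp·PP2A·IKKp/(km + IKKp)
    dIκBα/dt  = c_4a·(1−uvinh·uv)·(1−chx)·IκBα_t − (a_2·IKKp + c_5a)·(1−mg)·IκBα − …

with the step inputs `il` (0 or 0.000588 µM), `uv`, `chx`, `mg`. CHX gates
all synthesis, MG132 gates all proteasomal degradation, UVB gates synthesis
partially (`uvinh`) and kills PP2Ac. Simulations relax the system for 120 h
before the first stimulus and restart the stiff solver at every input
discontinuity.

The fit objective is `χ² = Σ ((y_ijk − ŷ_ijk)/σ_ijk)²` over all settings,
observables and time points, optimised by a multistart schedule: runs of
trust-region least-squares fits started from the incumbent best perturbed
per-coordinate by `10^ε`, `ε ~ N(0, n²)`, with widths n = 4, 1, 0.1, 0.01
in the reference schedule.

## Worked example

```python
import numpy as np
from nfkbuv import default_parameters, standard_protocols, simulate
from nfkbuv.discrimination import predict_chx, kpconst_scan_summary

params = default_parameters()
print(round(predict_chx(params), 2))            # 6.08
scan = kpconst_scan_summary(params, factors=(10.0, 1.0, 0.1))
print(round(scan["metrics"][("UVB", 10.0)]["degraded_4h"], 3))   # 0.967
print(round(scan["metrics"][("UVB", 0.1)]["degraded_16h"], 3))   # 0.595
print(round(scan["max_deviation"]["IL1"], 3))                    # 0.006
```

The numbers mean: under cycloheximide (no synthesis) total IκBα decays with
a half-life of ≈6 h, set by the weak constitutive degradation; under UVB
alone a ten-fold larger constitutive IKKβ phosphorylation rate degrades
IκBα essentially completely within 4 h, a ten-fold smaller one only ≈60%
by 16 h — while IL-1 responses barely notice the same scan, because active
PP2A absorbs small changes in basal phosphorylation.

The same operations are exposed on the command line:

```
nfkbuv simulate --protocol IL1_UVB --out traj.csv
nfkbuv generate --seed 1 --out data/
nfkbuv fit --data data/datasets.csv --variant ref --seed 1 --out fit.json
nfkbuv report --out report.json
```

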