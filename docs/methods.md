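# Methods

## Model structure and assumptions

The model couples a normalised IKKβ phosphorylation module to a reduced
IκBα–NF-κB feedback module. The reductions baked into its structure:

* The IKK module is normalised: `ILR(rest) = 1`, `PP2A(rest) = 1`,
  `IKK + IKKp = 1`. Receptor turnover uses one rate constant `k_ilr` for
  synthesis and degradation (possible without loss of generality after
  normalisation); receptor-complex internalisation is fast (`k_int`),
  consistent with IL-1 (as opposed to TNF) signalling.
* IKKβ dephosphorylation is Michaelis–Menten in IKKp,
  `k_dp·PP2A·IKKp/(km + IKKp)`, because the PP2Ac amount available to the
  IKK complex can saturate. `km = 0` degenerates gracefully to mass action
  `k_dp·PP2A` (and to zero flux at `IKKp = 0`).
* Fast intermediates are eliminated by quasi-steady-state arguments: free
  cytosolic NF-κB, the nuclear IκBα·NF-κB complex and the IKK–IκBα
  complexes are not states. Release of NF-κB from the cytosolic complex
  appears directly as nuclear NF-κB gain with the compartment factor `k_v`.
* NF-κB is neither synthesised nor degraded; the complex concentration is
  the conservation remainder `nfkb_tot − NFκB_n/k_v`.
* A20 feedback, IκB isoforms other than α, and all downstream apoptosis
  biology are outside the model.

Nuclear transport of free IκBα carries compartment factors
(`+k_v·i_1a·IκBα` in the nuclear equation, `+e_1a·IκBα_n/k_v` back in the
cytosolic one) so that molecule numbers — not concentrations — are
conserved; with synthesis and proteasomal degradation both blocked
(CHX + MG132) the total `IκBα + IκBα_n/k_v + IκBα·NFκB` is exactly
constant, which the test suite checks at the vector-field level. The
export rate is constrained to `e_1a = 2·i_1a` throughout and is never a
free parameter.

Stimulation semantics: `il` is a molar step (10 ng/ml of the 17 kDa
cytokine = 0.000588 µM); `uv`, `chx`, `mg` are unit steps. CHX gates all
protein synthesis; MG132 gates the `a_2`, `a_3`, `c_5a` and `c_6a`
degradation routes (mRNA decay `c_3a` is untouched); UVB multiplies all
synthesis by `(1 − uvinh)` from its onset (eIF2α phosphorylation is
effectively immediate, so the inhibition is constant) and deactivates
PP2Ac at `k_uv`. Pre-treatments carry negative event times; the 120 h
relaxation always precedes the earliest event.

## Parameters

Structural constants are measured values: `k_v = 2.9`, `volume = 2 pl`,
`numnfkb = 60 000`, giving `nfkb_tot ≈ 0.067 µM` and a maximal
transcription rate constant `c_1a,max = 0.16/(numnfkb·k_v) ≈ 9.2e-7 s⁻¹`.
Fitting bounds with literature derivations: `k_ilr ∈ [9.3e-6, 2.8e-5] s⁻¹`,
`k_p ≤ 0.095 s⁻¹`, `a_1 ∈ [0.3, 1] µM⁻¹s⁻¹`, `a_2, a_3 ≤ 0.8 s⁻¹`
(1 µM⁻¹s⁻¹ × 0.8 µM maximal IKK), `c_3a` from mRNA half-lives of 15–45 min,
`c_5a` from free-IκBα half-lives of 6–20 min, `uvinh ≤ 1`,
`c_1a ≤ c_1a,max`. The nuclear import rate `i_1a` is given a broad
documented range (1e-4 … 5e-2 s⁻¹) because its literature-derived bounds
are not available numerically; `c_4a`, `c_6a`, `k_dp`, `km`, `k_uv`,
`k_act`, `k_int` and `k_pconst` are fitted without bounds, as are all
scaling factors.

The default parameter set (`default_parameters()`) is a calibrated
reference parameterisation: values inside every bound above, chosen once so
that the model reproduces the benchmark behaviours of the system —
IL-1: IKKβ phosphorylation peaking within ~10 min and falling below 10% of
peak by 2 h, complete IκBα degradation followed by an overshoot, NF-κB
activity terminated by ~2–3 h; IL-1+UVB: sustained IKKp (>0.2 of peak at
4 h), no IκBα recurrence, sustained NF-κB; UVB alone: IκBα degradation
starting after ~4 h; CHX: total-IκBα half-life ≈ 6 h; `uvinh = 0.9`
(≈90% translational inhibition); the constitutive-phosphorylation scan:
complete degradation by 4 h at 10×`k_pconst`, ≈60% degradation at 16 h at
0.1×`k_pconst`, and IL-1 responses nearly invariant under the same scan;
MG132 added 15 min after IL-1+UVB: IκBα recovery to about its initial
level. The calibration was frozen before the test suite was written and is
not a fit to any dataset; `a_2 > a_3` in the defaults (both well under
their common bound) because the ×10/÷10 scan behaviours and the resting
state cannot otherwise be met simultaneously.

At the calibrated defaults the relaxed resting state has ~98.6% of NF-κB
in the cytosolic complex and `IKKp ≈ 7.5e-6`; the model's IL-1 IκBα
overshoot (~2.1× initial) is larger than blot time courses typically
suggest (~1.3–1.5×) — a known cosmetic limitation that does not affect the
discriminating behaviours.

## Units and numerics

Time is seconds internally; the API and all files use hours.
Concentrations are µM; IKK-module states dimensionless. The integrator is
LSODA with `rtol = 1e-8`, `atol = 1e-10` for plain simulation; the fitting
path uses `rtol = 1e-7`, `atol = 1e-9` (halving tolerances changes
observables by <0.01%, which the suite verifies). The solver is restarted
at every input discontinuity; it never steps across one. Steady states are
obtained by 120 h relaxation from the fully-bound initial condition; a
`RuntimeWarning` is emitted if the end state is not stationary to 1e-10.
Relaxed states are cached per (dynamics-parameters, tolerances), which is
what makes a χ² evaluation cheap inside optimisation loops.

## Observables and standardisation

`IKKp_obs = scale_ikk·IKKp` (one global factor), `IkBa_obs = scale_ikba·
(IκBα + IκBα·NFκB + IκBα_n/k_v)` (one global factor; whole-cell lysate
with the nuclear pool volume-corrected), `NFkB_obs = scale_nfkb[stim]·
NFκB_n` (one factor per stimulation — EMSA has no absolute reference
across experiments). Data conventions: NF-κB replicates are scaled to mean
1 then averaged; IκBα series standardised to initial value 1; phospho-IKK
referenced to maximal phosphorylation — when several stimulations are
measured in one replicate experiment they share that maximum, which is why
the synthetic generator normalises IKK series jointly per replicate.
Across-replicate SDs are floored at 10% of each pooled series' maximum.
All conventions are invariant to rescaling a replicate by a constant, so
the ground truth's scaling factors are pure gauge.

Scaling factors are ordinary unbounded fit parameters by default; an
analytic profiling mode
(closed-form weighted-least-squares optimum per scaling group) is
available and is what the fast tests use — it has the identical optimum
and removes the gauge directions from the search space.

## Fitting

Free positive rate constants are optimised in log10 space (the multistart
perturbation `10^ε` is then additive); `uvinh` stays on its linear [0, 1]
scale. `ε ~ N(0, n²)` reads the perturbation width n as a standard
deviation (the convention is configurable in principle; this reading is
the package's decision). Out-of-bounds starts are clipped into the box
(resampling available behind a flag). The local optimiser is
bound-constrained trust-region least squares on the SD-weighted residual
vector (`ftol = xtol = 1e-10`, capped function evaluations). Each start's
perturbation comes from a substream seeded by (seed, run, start), so traces
are bit-reproducible and order-independent. Simulation failures inside the
objective yield +inf, not an exception. The reference schedule is four
runs of 1000 fits with widths 4, 1, 0.1, 0.01; the reduced schedule used
for synthetic work is (1.0, 40), (0.1, 20), and the scripted analyses use
smaller schedules still — problem sizes chosen so the whole scripted
analysis completes in minutes on one core.

## What the synthetic data do and do not show

The generator emulates the *structure* of quantified Western-blot/EMSA
time courses: 5 protocols, 11 (observable, stimulation) series, sparse
grids (minutes-scale for IL-1 responses, out to 16 h for UVB/CHX), three
replicates, multiplicative Gaussian noise (rel. SD 0.1, truncated at
−90%), pooling and SD-flooring as above. It does not emulate blot
saturation, loading artefacts, membrane-to-membrane transfer effects or
biological replicate-to-replicate kinetic variability. Passing recovery
and discrimination tests therefore shows the estimation machinery is
sound and the mechanisms are identifiable under the stated noise model —
not that the biological parameters are identifiable from any particular
real dataset.

Under the pooling convention, χ² at the true parameters is *not* expected
to equal the point count: averaging three replicates shrinks the residual
variance threefold while the floored SD (10% of max) dominates the
attached uncertainty, so E[χ²]/N ≈ 0.10 for the default design (a frozen
property of the convention, asserted by the suite). The clean calibration
statement uses noise drawn at exactly the attached floored SD, for which
E[χ²] = N; the acceptance machinery checks that identity over 50 seeds.

## Design choices where the design was open

* Variant comparison starts both variants from the same incumbent
  parameter set and schedule; nestedness (`χ²_ref ≤ χ²_variant` within 1%)
  is asserted rather than assumed.
* Qualitative-feature conventions are constants, not measurements:
  overshoot threshold 1.1× initial, sustained-IKKp ratio 0.2 at 4 h,
  MG132 "moderate recovery" band [0.5, 1.5]× initial.
* The "PP2Ac activity" scaling in the altered-cell-type scenario
  (`mef_like_scenario`) multiplies the maximal dephosphorylation capacity
  `k_dp`, because the PP2A state itself is normalised to 1.
* The MG132 prediction uses the standardised pre-stimulation level (=1) as
  the fold-change reference.
* SBML export is not provided; the model definition lives in
  `model.py`/`params.py` and the YAML parameter files.

## Known limitations

Deterministic population-average model only: no single-cell variability,
no oscillation statistics, no spatial effects. The IκBα overshoot
amplitude is exaggerated (see above). Parameters outside the printed
bounds (e.g. `k_act`, `k_dp`, `km`, `k_uv`) are calibrated, not measured;
conclusions that depend on their absolute values rather than the
behaviours listed above should be treated accordingly. Fits to real data
require user-supplied digitised time courses in the dataset CSV dialect.
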