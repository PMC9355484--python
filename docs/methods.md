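# Methods

This note documents the models implemented in `leafphys`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## Quenching calculus

The fluorescence module implements the standard saturating-pulse quenching
analysis. From dark-adapted (Fo, Fm) and light-adapted (Fs, Fm′, Fo′)
levels:

| quantity | formula | meaning |
|---|---|---|
| Fv/Fm | (Fm − Fo)/Fm | maximal PSII photochemical efficiency |
| Fv′/Fm′ | (Fm′ − Fo′)/Fm′ | light-adapted maximal efficiency |
| ΦPSII | (Fm′ − Fs)/Fm′ | effective PSII quantum yield |
| ΦNO | Fs/Fm | non-regulated dissipation yield |
| ΦNPQ | Fs/Fm′ − Fs/Fm | regulated dissipation yield |
| qP | (Fm′ − Fs)/(Fm′ − Fo′) | photochemical quenching (puddle model) |
| qL | qP·Fo′/Fs | photochemical quenching (lake model) |
| NPQ | (Fm − Fm′)/Fm′ | Stern–Volmer non-photochemical quenching |

The three yields partition absorbed excitation energy; their sum is one
*algebraically* (ΦPSII + ΦNPQ + ΦNO = (Fm′−Fs)/Fm′ + Fs/Fm′ = 1), so the
partition identity is a structural property of the implementation, not a
numerical coincidence, and the suite asserts it to 1e−12. Likewise
ΦPSII = qP · Fv′/Fm′ holds exactly. 1−qL (the reduction state of the primary
quinone acceptor QA) is reported as its own field because it is the quantity
typically plotted.

ETR = ΦPSII·Q·α·f uses leaf absorptance α = 0.84 and PSII fraction f = 0.5 —
the community defaults for C3 leaves — both overridable per record. When the
far-red Fo′ measurement is absent, the Oxborough–Baker reconstruction
Fo′ = Fo/(Fv/Fm + Fo/Fm′) is used; it reduces to Fo when Fm′ = Fm and is
monotone in Fm′, and it never produces qP > 1.

## Stomatal indices and Rubisco velocities

WUE = A/gs, Ci/Ca and Ls = 1 − Ci/Ca are direct per-observation arithmetic
(Ls + Ci/Ca = 1 exactly by construction). The Rubisco velocities use the
fluorescence-based partitioning with electron costs of 4 per carboxylation
and 4 per oxygenation:

    Vc = (ETR + 8(A + Rd)) / 12,   Vo = 2(ETR − 4(A + Rd)) / 12,

the unique solution of A = Vc − 0.5·Vo − Rd and ETR = 4(Vc + Vo). This
estimator was chosen because it needs exactly the two data streams a
combined IRGA/fluorometer records simultaneously; a Γ*-and-Cc-based
estimator would give the same ordering but different magnitudes and requires
mesophyll assumptions this package does not make. The stoichiometric
constants are exposed. Rd defaults to the A/Ci-fitted value when available,
else 1.0–1.5 µmol m⁻² s⁻¹ (configurable); when ETR < 4(A+Rd) the implied Vo
is negative and the pair is flagged invalid rather than raised.

## FvCB A/Ci fitting

Forward model at chloroplastic CO2 Cc (Cc = Ci − A/gm; gm defaults to
infinite, i.e. Ci-basis fitting):

    Ac = Vcmax (Cc − Γ*)/(Cc + Kc(1 + O/Ko)) − Rd
    Aj = J (Cc − Γ*)/(4Cc + 8Γ*) − Rd
    Ap = 3·TPU − Rd
    A  = min(Ac, Aj, Ap)

Kinetic constants default to the Bernacchi 25 °C values (Kc = 404.9
µmol mol⁻¹, Ko = 278.4 mmol mol⁻¹, Γ* = 42.75 µmol mol⁻¹, O = 210
mmol mol⁻¹), the set embedded in the widely used spreadsheet fitting tools;
all are estimator parameters. An Arrhenius normalization to 25 °C with
configurable activation energies is provided (identity at 25 °C, exactly
invertible; with the standard Ea(Vcmax) = 65.33 kJ mol⁻¹, one degree from
24 to 25 °C scales Vcmax by 9.3 %).

**Fitting.** Points are sorted by Cc and every monotone assignment of the
sequence Rubisco → RuBP → TPU (either tail block possibly empty) is
enumerated. Given an assignment and fixed gm, the residuals are *linear* in
(Vcmax, J, TPU, Rd), so each candidate is solved exactly with bounded linear
least squares (all rates ≥ 0, Rd ∈ [0, 20]) — no iterative multi-start is
needed, and the solution is deterministic. A candidate is *admissible* when
every point's assigned limitation agrees with the min rule at the fitted
parameters within a 2 % band of |A|; the band tolerates a noisy crossover
point while leaving noiseless labelings exact. The admissible candidate with
minimal SSE wins; candidates within 1e−6 relative SSE are ties and go to the
assignment with more Rubisco-limited points (the conservative Vcmax). If no
candidate is admissible the best raw fit is returned flagged
`admissible=False` with a warning.

Identifiability rules: J is reported unidentifiable when no point is
RuBP-limited (e.g. a curve confined to low Ci); TPU is reported infinite
unless at least two points support the plateau (a single-point TPU block
always zeroes its own residual and would be selected spuriously on noisy
data). Rd is weakly identified by A/Ci data generally — noiseless round
trips recover it exactly, but under noise its relative error is much larger
than Vcmax's or J's.

## Light-response fitting

Four response families are registered: rectangular hyperbola, non-rectangular
hyperbola with curvature θ ∈ (0,1] (evaluated in the θ→0-stable root form),
exponential saturation, and the Ye modified rectangular hyperbola
A = φ(1−βI)/(1+γI)(I−Ic), the only candidate with an explicit supra-optimal
(photoinhibition) decline. Each family is fitted by bounded least squares
from moment-based initial values with 7 jittered restarts (seeded, hence
deterministic); model selection keeps the lowest SSE, with ties inside a
1e−6 window going to the family with fewer parameters.

Cardinal points: Ic is the root of A(I) = 0 (a parameter of the Ye family,
a bracketed Brent root otherwise); Φi is the analytic derivative dA/dI at
I = Ic (the I = 0 slope is also reported — the two differ only through the
curvature between 0 and Ic, and the Ic-slope is the convention consistent
with the Ye formulation); Pmax is the saturated net rate (asymptote
Pmax − Rd for the saturating families, global maximum for Ye); Ik is the
intersection of the initial-slope line with the plateau, Ik = Pmax/Φi + Ic.
Amax is reported at I = 1500 µmol m⁻² s⁻¹ — the conventional top measured
level and the default for treatment comparisons — alongside the model's
global maximum. Fits flag `physiological=False` when Φi exceeds the
theoretical quantum-yield ceiling of 0.125 mol CO2 (mol photons)⁻¹.

Small-sample behavior: with additive noise of SD ≈ 1.2 µmol m⁻² s⁻¹ on a
12-point curve, the fitted Amax(1500) carries a per-curve SD near 1.1 and a
small (~1–2 %) downward bias from model selection at the β ≥ 0 bound; the
recovery tests average over replicate curves accordingly.

## RCBD statistics

The design is a 2 × 2 factorial (cultivar × treatment) in B complete blocks
with multiple plants per block-cell. Plants are pseudo-replicates and are
averaged to plot means before ANOVA, so the error degrees of freedom are
(ab − 1)(B − 1) = 9 for 2 × 2 × 4; a flag disables the aggregation for
plant-level models. For a balanced Gaussian response this fixed-effects
decomposition reproduces the F tests of the mixed-model formulations used by
commercial packages. Sums of squares come from an OLS fit
(`value ~ cultivar*treatment + block`); the test suite checks the
decomposition against an independent projection oracle and verifies the
empirical type-I error at α = 0.05 over 2000 null simulations.

Mean separation is Fisher's protected LSD,
LSD = t(1−α/2, df_e)·√(2·MSE/n), gated on the joint F test of the treatment
structure: when the gate is non-significant all cells share one letter.
Letters come from a descending-mean sweep assigning maximal runs within one
LSD; the assignment is invariant to input order. The pooled SEM of a cell
mean is √(MSE/n) from the ANOVA error term. Shapiro–Wilk normality uses
Royston's approximation (via scipy); Pearson correlations use the
product-moment formula with t-transform p-values (n−2 df) and α = 0.05
stars. α is fixed at 0.05 throughout; p-values are two-sided; no
multiple-testing correction is applied across traits.

## Synthetic experiment generator

The generator encodes a two-cultivar (one stress-tolerant, one sensitive)
waterlogging experiment as a `ScenarioConfig`: control-cell means, fractional
treatment effects per cultivar (decline-positive sign convention), per-cell
FvCB and Ye-model presets, per-cell fluorescence yield targets, and noise
scales. The default preset fixes the morphology declines at 8/8/14/8 %
(LN/LA/FM/DM, tolerant cultivar) and 14/17/25/25 % (sensitive); gs/E/WUE at
22/14/52 % and 24/13/40 %; Ci at +6/+4 %; Vcmax/J at 14/15 % and 33/14 %;
ETR at 23/26 %; and light-saturated Amax at 8/20 % with control Amax(1500)
of 23.62 and 19.59 µmol m⁻² s⁻¹.

Design choices where the inputs were underdetermined or mutually
inconsistent:

- **Absolute control means are not authoritative.** Only relative changes
  are; control morphology and gas-exchange means are fixed at realistic
  values for ~24-day cucumber seedlings (e.g. FM 10 g, gs 0.45 mol m⁻² s⁻¹)
  and declared as such.
- **Ci control means follow from joint consistency.** Given a Ci increase
  d and an Ls decline e under treatment, Ls = 1 − Ci/Ca forces
  Ci/Ca = e/(e + d) in the control (0.878 and 0.895 for the two cultivars);
  both stated effects are then realized simultaneously.
- **A is derived, not primary.** Since WUE = A/gs, the generator draws gs
  and WUE and sets A = WUE·gs, so the configured WUE and gs effects are
  realized exactly; the implied A decline is whatever those two force.
- **ETR effects drive the yield targets.** ΦPSII targets under treatment are
  scaled by the ETR effect (ETR ∝ ΦPSII at fixed Q·α·f); the nominal ΦPSII
  effects differ from the ETR effects only at rounding precision and cannot
  be realized independently.
- **Fm is held constant across treatments** and Fv/Fm declines slightly
  (0.78→0.765 / 0.77→0.755), which keeps dark-adapted Fv/Fm inside the
  healthy 0.75–0.79 range; a simultaneous Fo *decrease* is algebraically
  incompatible with those two choices and is not realized.

**Noise model.** Each trait gets a Gaussian plot effect shared within a
block-cell plus plant-level error at half the plot SD. Plot SDs for
morphology are the pooled SEMs of a 4-block design scaled by √4 (LN 0.136,
LA 13.928, FM 0.403, DM 0.046 → ×2). Strictly positive gas traits use
multiplicative noise with CV = SEM·√4/mean, capped at 0.15: the nominal gs
SEM (0.153 mol m⁻² s⁻¹) implies a ~65 % between-plot CV at any realistic gs
mean, under which Gaussian draws produce non-positive conductances and
divergent per-record WUE, so the cap is the largest CV compatible with
physically admissible records. Fluorescence noise is drawn in *yield* space
(plot SDs 0.016 for Fv/Fm, 0.06 for ΦPSII, 0.03 for ΦNO, 8.5 % CV on Fm),
re-closed so the energy partition sums to one, and inverted to raw F-levels
through the exact inverse construction (Fm = scale, Fo = Fm(1−Fv/Fm),
Fm′ = Fm/(1+NPQ), Fs = ΦNO·Fm, Fo′ by Oxborough–Baker, clamped to Fs in the
rare tail where the reconstruction would exceed it). A/Ci curves get 2 %
multiplicative per-point noise; light curves get additive per-point noise of
SD 1.23 µmol m⁻² s⁻¹, the reference steady-state SEM used as the scatter of a
single reading. Response curves are generated on the instrument setpoint
grids (11 CO2 setpoints 50–1500 treated as the Ci grid, with the
ambient-start point behind a protocol flag; 12 PPFD levels 0–1500).

Determinism: one integer seed drives independent per-component substreams,
so a fixed seed reproduces the bundle bit for bit and generating a subset of
components reproduces exactly what a full simulation would give. With all
noise scales zero the simulated cell means equal the configured means
exactly.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: time-course dynamics over the stress period
(endpoint only), mechanistic hypoxia physiology (root oxygen, aerenchyma,
hormones), correlated trait noise within a plant beyond the shared plot
effect, instrument drift and matching artifacts, non-Gaussian measurement
error, and any coupling between the steady-state gas table and the A/Ci or
light-curve presets beyond their shared effect structure. Parameter-recovery
results demonstrate that the estimators are unbiased at realistic noise
under this model, not that the field data satisfied the model.

## Problem sizes

The test suite and the acceptance script use replicated small experiments
chosen to hold Monte-Carlo error well below the comparison tolerances: 200
replicate experiments for the cheap paths (morphology, steady-state indices,
fluorescence; per-experiment percent-change SD ≈ 4–10 points), and 12
replicates where per-curve optimization is involved (A/Ci, light response;
per-experiment SD ≈ 0.7–2.2 points). The full suite and the acceptance
script each complete in well under five minutes on one CPU.

## Known limitations

- Rd from A/Ci fits is weakly identified (documented above); treat fitted Rd
  as a nuisance parameter.
- TPU is only estimated when two or more points support the plateau.
- Finite-gm fitting conditions on measured A when computing Cc; gm itself is
  not estimated.
- The LSD letter display, like all compact letter displays, is not unique
  under near-ties; the sweep used here is deterministic and order-invariant.
- The light-response Amax(1500) estimator carries a ~1–2 % downward
  small-sample bias at the default noise level (β-bound truncation during
  model selection); recovery comparisons should average replicate curves, as
  the provided scripts do.
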