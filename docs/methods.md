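# Methods

## The microdomain model

An open Ca²⁺-conducting channel is modelled as a point source of flux into
a hemisphere of cytosol containing a single mobile buffer. In the
linearised (non-saturating) buffer approximation the steady-state free
Ca²⁺ at distance *d* from the pore is

    [Ca²⁺](d) = [Ca²⁺]_ss + i_Ca/(4π F d D_Ca) · exp(−d/λ),  λ = √(D_Ca/(k_on·[B]))

Parameters and defaults:

| parameter | meaning | default |
|---|---|---|
| `D_Ca` | Ca²⁺ diffusion coefficient | 3×10⁻¹⁰ m² s⁻¹ |
| `k_on` | buffer Ca²⁺-binding on-rate | 6×10⁸ (BAPTA), 1.5×10⁶ (EGTA) M⁻¹ s⁻¹ |
| `[B]` | buffer concentration | condition-dependent (0.8–20 mM) |
| `Ca_ss` | bulk cytosolic Ca²⁺ | 0 (negligible next to mM chelator) |
| `i_Ca` | unitary Ca²⁺ current | 5 fA at −100 mV, voltage-scaled |
| `d` | sensor distance (`SENSOR_DISTANCE`) | 3 nm |

The flux divisor is written with the bare Faraday constant — no factor of
2 for the divalent charge. This is a deliberate modelling convention: the
package's reference predictions (1.38 µM at 2.2 fA/3 nm/8 mM BAPTA and
5.56 µM at 6.2 fA/3 nm/10 mM EGTA) hold only in the bare form, and all
downstream calibration is consistent with it. The textbook i/(2F)
conversion is available behind `divalent_correction=True` for sensitivity
analysis; it halves every concentration and would simply rescale the
fitted K_d values.

Unitary-current voltage scaling has three modes. The default `table` mode
pins the measured values (5 fA at −100 mV, 2.2 fA at −60 mV, 6.2 fA at
−120 mV); these are *not* consistent with linear driving-force scaling
toward the +53.5 mV net reversal (which would give 3.7 fA at −60 mV), so
where the measured values exist they win. The `driving_force` mode —
i(V) = i_ref·(E_rev−V)/(E_rev−V_ref), clipped at zero above E_rev — is
used by the simulator, which needs i(V) at arbitrary voltages.

Assumptions and limits: single channel (no overlapping microdomains), one
mobile buffer species, no buffer saturation, steady state. The profile
equilibrates in microseconds, far faster than millisecond gating, so the
simulator treats sensor Ca²⁺ as an instantaneous function of voltage.

## The CDI gating scheme

Fast CDI is modelled with a three-state chain,

    Ca + O ⇌(k₁, k₂) Ca·O ⇌(α, β) I

O and Ca·O conduct; only I is silent. Making Ca·O non-conducting would
collapse Ca²⁺ binding and the inactivating conformational change into a
single step; keeping both conducting preserves the two-step structure
(binding sets the Ca²⁺ sensitivity through K_d = k₂/k₁, the α/β step sets
the depth and recovery kinetics of inactivation).

The occupancy dynamics are linear for a given Ca²⁺ time course, so
propagation over piecewise-constant Ca²⁺ uses exact 3×3 matrix
exponentials (cached per (Ca²⁺, Δt) pair); the probability simplex is
conserved to round-off at every step, and the default step of 0.2 ms
matches the 5 kHz acquisition rate. The steady state follows detailed
balance with weights 1 : k₁·ca/k₂ : (k₁·ca/k₂)(α/β), with limiting forms
when unbinding or recovery rates vanish.

### Coupling to the microdomain

During simulation the sensor sees the local Ca²⁺ produced by its own
channel's unitary flux at the present voltage (self-microdomain coupling;
other channels and bulk feedback are out of scope). Below the net reversal
potential the sensor flux follows driving-force scaling. **Above** the net
reversal a small residual Ca²⁺ influx remains, parameterised as a fixed
fraction of the reference unitary current (`residual_ca_fraction`, default
0.05) times the external-Ca²⁺ factor. The physical argument: +53.5 mV is
where the *net* current through the pore reverses, but the Nernst
potential for Ca²⁺ itself sits far positive of +100 mV, so unidirectional
Ca²⁺ entry does not cease at the net reversal — it only shrinks. This term
is what makes recovery during a +100 mV interpulse depend on external
Ca²⁺, reproducing the observed ordering (strong recovery in 2 mM, weak in
110 mM Ca²⁺ₒ). Setting `residual_ca_fraction=0` removes it; the whole-cell
*current* is always clipped at the net reversal regardless.

External Ca²⁺ is emulated multiplicatively (110 mM → 2×, 20 mM → 1×,
2 mM → 0.35×, divalent-free → zero sensor flux) rather than through a
permeation model; in divalent-free conditions a monovalent unitary current
(default 8 fA at −100 mV, reversal +50 mV) keeps the conducted current
non-zero while CDI is absent.

### Shipped parameter sets and their calibration

The recordings constrain the scheme only through macroscopic observables,
so the rate constants are the package's calibration, chosen once against
the qualitative pattern set and not per-analysis:

| | k₁ (M⁻¹s⁻¹) | k₂ (s⁻¹) | α (s⁻¹) | β (s⁻¹) | K_d |
|---|---|---|---|---|---|
| `wt_like` | 8×10⁶ | 120 | 70 | 10 | 15 µM |
| `sensitized` | 3.2×10⁸ | 120 | 70 | 10 | 0.375 µM |

Calibration anchors: ~50% extent of inactivation at −100 mV in 10 mM EGTA
for `wt_like`; decay constants in the ~5 ms / ~50 ms range; ~90% recovery
from inactivation within 200 ms at depolarized potentials (β ≈ 10 s⁻¹);
and the four headline orderings (wild-type extent EGTA > BAPTA, sensitized
reversed, sensitized paired-pulse enhancement decreasing with Ca²⁺ₒ,
normalisation restoring the wild-type ordering). A grid scan over
(K_d, sensitisation factor, α, β, residual fraction) showed that a 10×
K_d shift cannot satisfy the ordering reversal and the paired-pulse
pattern simultaneously — the EGTA-10/BAPTA-8 sensor concentrations at 3 nm
differ by only ~1.4×, so the extent-vs-Ca²⁺ curve of a first-order scheme
is too shallow — while a 40× shift passes everything with the widest
margins. Hence `sensitized` is `wt_like` with k₁ scaled 40×, and
`sensitized_with_stim1` (the STIM1-normalisation phenomenon, modelled
purely as a K_d restoration) is the sensitised variant with k₁ back at the
wild-type value.

`n_channels` defaults to 10,000, giving ~40 pA peak whole-cell currents at
−100 mV — a typical over-expression current density for a ~15 pF cell.

## Voltage protocols

Protocols are declarative sweep lists from a +30 mV holding potential:
`standard_ramp` (100 ms at −100 mV + 100 ms ramp −100→+100 mV, 1 s
intervals), `cdi_family` (300 ms steps to −120/−100/−80/−60 mV, one per
sweep), `paired_pulse` (300 ms at −100, 200 ms at +100, 300 ms at −100).
Segment windows are half-open so a sample belongs to exactly one segment;
time zero is the first segment onset. Stored voltages are the reported
(liquid-junction-corrected, −10 mV) values; the correction is metadata and
is never applied twice.

## Trace analysis

Extent of inactivation is 1 − |I_ss|/|I_peak|: the peak is the largest
current magnitude within the first 20 ms of the step (excluding the first
0.4 ms — two samples at 5 kHz — standing in for the capacitance
transient), the steady state is the mean over the final 10% of the step.
Both windows are overridable; negative extents (potentiation) pass through
as negative, and an O(ε) summation residue is snapped to exactly zero so
flat steps report 0. Decay fits use
offset + a_f·exp(−t/τ_f) + a_s·exp(−t/τ_s) on the post-peak,
peak-normalised samples: a fixed τ grid {2, 10, 50, 150} ms (pairs with
τ_f < τ_s, amplitudes seeded by linear least squares) picks the start
point — ties broken by residual then smaller τ_f — and one bounded
trust-region refinement with fixed tolerances finishes it, so identical
inputs give identical parameters; failure is reported through `fit_ok`,
never an exception. An additive offset is always included (fitting without
one biases τ_slow when the current does not decay to zero). Note a single
buffer/voltage condition of the three-state scheme is intrinsically close
to bi-exponential only when the binding and conformational time scales
separate; fitted τ pairs can legitimately merge.

I–V curves pair (V, I) over a strictly monotone ramp window, sorted by
voltage; the reversal potential interpolates the zero crossing linearly, a
run of exact zeros (a clipped simulated current) counts once at its onset,
and multiple crossings raise an error listing the candidates. Leak
subtraction accepts a matching-grid trace or an I–V curve evaluated at the
trace voltages, marks the metadata, and refuses a second application.

## The synthetic-data generator

The generator emulates the recording chain in the order hardware applies
it: deterministic simulation at 25 kHz (5× oversampled), a per-cell
multiplicative scale drawn from a unit-mean lognormal (CV 0.3, emulating
cell-to-cell channel-count spread — cell-size variation is the dominant
variance component in current-density bar graphs), a causal 4-pole Bessel
low-pass at 1 kHz (forward only; zero-phase filtering would distort onset
peaks, and the filter state is pre-charged to the first sample to avoid a
spurious onset transient), decimation to 5 kHz, then additive Gaussian
noise (σ = 0.5 pA, a typical post-filter whole-cell noise floor). Per-trace
seeds are derived by hashing the condition identity
(variant|protocol|buffer|Ca²⁺ₒ|cell) into a seed sequence rooted at the
base seed, so regenerating any subset is reproducible and adding
conditions never perturbs existing ones. The default grid covers EGTA
10/20 and BAPTA 0.8/8/20 mM × Ca²⁺ₒ 2/20/110 mM/DVF × three variants with
6 cells per condition (cell counts in comparable datasets run ~4–17).

What the generator does *not* emulate: seal/access-resistance drift,
capacitance transients, series-resistance error, slow rundown, and any
STIM1 gating kinetics (activation is constitutive). Passing tests on this
synthetic data therefore demonstrate correctness of the analysis chain and
internal consistency of the model — not that the model captures every
feature of real recordings.

## E-FRET

Three-cube sensitized emission with the two-constant correction
Fc = I_DA − a·I_AA − d·I_DD and E = Fc/(Fc + G·I_DD); a = 0.12, d = 0.33,
G = 1.85 by default, with the minor cross-talk constants b = 0.008 and
c = 0.002 stored but unused by the default correction (they belong to
four-constant variants of the formalism). Negative corrected Fc reports
E = 0 rather than a negative efficiency. The expression-ratio gate keeps
2 ≤ I_AA/I_DD ≤ 6 inclusive. The synthetic generator inverts the formalism
exactly, so generator→analyzer round trips are machine-precision.

## Numerical choices and file format

All internal computation is SI (m, s, A, V, molar), with unit constants at
the API boundary (`cracdi.units`); the microdomain evaluation spans ~15
orders of magnitude and a single conversion point avoids the classic
mol·m⁻³/M slip. Trace files are CSV (`time_s`, `voltage_mV`, `current_pA`)
plus a JSON sidecar; values carry 17 significant digits, the time column
round-trips bit-exactly, and scaled columns round-trip bit-exactly where a
double is representable as column·unit (the writer nudges by one ulp to
make it so) and within half an ulp otherwise.

## Problem sizes used in checks

The built-in checks use single-sweep simulations at 0.2 ms steps (1,500
samples per 300 ms step), 100 random kinetic models for the steady-state
oracle, 100 noise seeds for the τ-recovery study, and a 21-point E-FRET
grid — small enough to run in seconds while exercising every code path at
the actual experimental sampling rate.

## Known limitations

- The three-state scheme under-represents the observed multi-exponential
  decay structure; it is the minimal scheme consistent with a separate
  binding and gating step.
- The Ca²⁺ₒ dependence is a multiplicative emulation, not a permeation
  model; absolute currents across Ca²⁺ₒ conditions are not quantitative.
- The STIM1 normalisation is reduced to a K_d restoration. Under the
  shipped calibration it restores the wild-type buffer ordering and
  re-enables step-evoked CDI in EGTA, but it does not reproduce a *reduction*
  of absolute CDI in 8 mM BAPTA relative to the un-normalised mutant: in a
  first-order scheme that direction requires a small (10–20×) sensitisation
  shift, which is incompatible with the paired-pulse recovery pattern.
- Microdomains do not overlap and buffers do not saturate; very high
  channel densities or sub-millimolar buffer conditions violate both.
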