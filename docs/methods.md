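# Methods

## Model and assumptions

The package treats the closed gate of a voltage-gated channel as a
static, symmetric Eckart barrier U(x) = G sech²(x/L). This is a
steady-state, single-particle picture: no Hodgkin–Huxley gating
dynamics, no ion–ion interactions inside the pore, no asymmetric or
temperature-dependent barrier shapes, and no molecular-dynamics
estimate of the barrier profile — G and L are free parameters scanned
over the experimentally plausible ranges (G of order 10⁻²⁰ J, L of
order 1 Å).

The kinetic energy of an ion arriving at the gate is side-dependent:
extracellular ions are accelerated by the membrane field and carry
qV_m/n + (3/2)k_BT, where the location index n ∈ {1,2,3,4} gives the
fraction of the potential drop in front of the gate (n = 1: gate at the
intracellular end, the full drop available); intracellular ions carry
only the thermal term. The membrane potential is handled throughout as
an absolute (positive, inside-negative) value.

Transmission comes in two forms. The exact Eckart closed form

    T_Q = (cosh a − 1)/(cosh a + cosh b),
    a = 2πL√(2mE_K)/ħ,  b = 2π·(1/2)√(8mGL²/ħ² − 1),

and the large-argument exponential
T_Q = exp[−(2πL√(2m)/ħ)(√G − √E_K)], obtained from the exact form by
cosh x ≈ e^x/2 (valid for x ≥ 3) and by dropping the −1 under the
square root. The exponential coefficient 2π√(2m)/ħ is the unique
reading consistent with deriving the exponential from the closed form
(the exponent is b − a); the worked exponent for intracellular sodium
(G = 2×10⁻²⁰ J, L = 1 Å → ln T ≈ −101) confirms it. The exponential
form is the default everywhere (it is the form the reference sweeps are
built on); the exact form is selectable (`transmission_mode="exact"`),
and a flag restores the −1 (applied only where 8mGL²/ħ² ≥ 1, below
which the argument would go negative).

## Parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| G | scanned 4→1 ×10⁻²⁰ | J | closed-gate barrier height |
| L | 1×10⁻¹⁰ (settings 0.5–2×10⁻¹⁰) | m | gate length, U(L) = 0.42 G |
| n | 1 (settings 1–4) | — | gate location index |
| D | 10¹⁰ (= 10²/μm²) | channels/cm² | channel density for depolarization sweeps |
| MC_K, MC_Na | 0.5, 0.01 | mS/cm² | basolateral leak conductances (100:2) |
| [Na]_E/I, [K]_E/I | 140/15, 5/120 | mmol/L | perilymph/cytosol concentrations |
| [Ca]_E/I | 1.4 / 0 | mmol/L | free cytosolic Ca²⁺ negligible |
| m_Na | 3.8×10⁻²⁶ | kg | sodium ion mass |
| m_K, m_Ca | 6.5, 6.64 ×10⁻²⁶ | kg | bare atomic masses (39 u, 40 u); configurable |
| T | 310 | K | body temperature |
| V_m(Thr) | 0.055 | V | firing threshold (absolute), with D = 10⁸/cm² |
| axon r, L | 0.5, 100 | μm | cylinder: surface 314 μm², V_I 78.5 μm³ |
| V_E/V_I | 0.67 | — | extracellular/intracellular volume ratio |
| N_AP | 1.37×10⁶ | ions | K⁺ released per action potential per segment |

Physical constants are stored at the rounded precision the worked
values were computed with (h = 6.6×10⁻³⁴ J s, ħ = 1.05×10⁻³⁴ J s,
k_B = 1.38×10⁻²³ J/K, R = 8.31, F = 96485.33, N_A = 6.02×10²³). h and ħ
are therefore mutually inconsistent in the fourth digit; each is used
where the model uses it (h in the conductance quantum and ħ in the
tunneling exponent), which reproduces the printed-precision worked
values exactly. Potassium and calcium masses are not fixed by the
source parameter set; bare atomic masses are used (hydration shells are
assumed stripped in the constriction) and both are overridable on
`IonSpecies`.

## GHK solvers

The classical relation S1 = e^(−FV_m/RT)S2 has the closed form
V_m = (RT/F)ln(S2/S1) = 0.0730 V at the defaults. The quantum
monovalent equation adds MC_Q(E)(V_m)·[ion]_E on the outside and
MC_Q(I)·[ion]_I inside; the divalent (Ca²⁺) version uses the
quadratic-form relation

    (S1−S2) + √((S1+S2)² + 4(S1H2 + S2H1 + H1H2)) = 2e^(−FV_m/RT)(S2+H2)

with H1 = MC_Q(Ca,E)[Ca]_E, H2 = MC_Q(Ca,I)[Ca]_I (H2 = 0 by default).
The divalent quantum term is always assembled from first principles as
(q²/h)·T_Q·D·[Ca]_E — the conductance quantum times density times
concentration — rather than from any pre-multiplied constant. All sums
use mixed mS/cm² × mmol/L units; only like terms are compared, so no
conversion is needed, while F/RT uses SI (37.45 V⁻¹).

Because the extracellular kinetic energy contains the V_m being solved
for, the equations are solved self-consistently as a scalar root
problem in V_m over the bracket [0, 0.12] V (Brent, xtol 10⁻¹³, ≤ 200
iterations; converged roots have relative residual < 10⁻⁹). A
frozen-kinetic-energy mode (E_K evaluated at a fixed potential, default
the classical resting value) is provided for sensitivity analysis. The
left-minus-right residual is monotone increasing in V_m for all
parameter sets explored, so the root is unique; a coarse 49-point scan
still checks for multiple sign changes and records any in
`branch_note`. If the left side exceeds the right even at V_m = 0, the
membrane is reported fully depolarized at the boundary
(`branch_note="fully_depolarized"`) rather than silently clamped.
Sweeps over descending G warm-start each solve from the previous root,
keeping curves on the branch continuous with the classical resting
state. Non-converged points are flagged in the output table, never
dropped.

## Quantum synapse

The release chain is cylinder geometry → extracellular volume
(V_E = 0.67·πr²L) → concentration rise [K]_AP = N_AP/(N_A·V_E) →
hits per channel N_K = (ions/μm²)/(channels/μm²), rounded to the
nearest integer for use as a Bernoulli trial count (the unrounded value
is also returned). The threshold relation

    S1 + [K]_AP·(q²/h)·T_Q·D = e^(−F·V_m(Thr)/RT)·S2

is solved for the product T_Q·[K]_AP; its right side deliberately omits
the intracellular quantum term, a conservative simplification since
T_Q(I) ≪ T_Q(E). Re-deriving the reference threshold numbers from the
unrounded inputs lands ≈1% away from their printed values (9.71×10⁻⁷
vs 9.64×10⁻⁷; 2.26×10⁻⁵ vs 2.24×10⁻⁵): the printed chain passed
through two-significant-figure intermediates that cannot be
reconstructed, so validation compares at 2% relative tolerance and
records the residual deviation.

The induction cascade P1/P2/P3 is accumulated as ln(1−P) via `log1p`,
making the closed-form identity 1−P3 = (1−T_Q)^(N_K·D·N) hold to
floating-point accuracy for T_Q down to 10⁻³⁰⁰ and avoiding
catastrophic cancellation. The binomial mass helper delegates to
scipy's log-space implementation. In the induction sweeps V_m is an
independent axis (the affected neuron's potential is externally set),
so T_Q uses the fixed base V_m = 0.07 V rather than a self-consistent
solve.

## Sweep and scenario conventions

The standard barrier-height grid is 50 points descending over
(4→1)×10⁻²⁰ J. The membrane-potential sweeps emit every combination of
ion ∈ {Na, K, Ca} with L ∈ {0.5, 1, 1.5, 2}×10⁻¹⁰ m or n ∈ {1,2,3,4}.
The induction sweeps use the base point L = 1×10⁻¹⁰ m, V_m = 0.07 V,
N_K = 100, D = 100/μm², N = 100 patches; the base barrier height for
single-axis sweeps defaults to 2.5×10⁻²⁰ J, the midpoint of the
investigated range. Curve-family values for the V_m/N_K/D/N sweeps are
not fixed by the source parameter set; the defaults
(V_m ∈ {55,60,65,70} mV, N_K ∈ {44,100,500,1000}, D ∈ {1,10,100,1000},
N ∈ {1,10,100,1000}) span the physiologically plausible ranges, and the
curves are validated by shape — V_m(G) non-increasing and P3(G)
non-decreasing as G falls, depolarization onset ordered Ca > Na/K and
delayed by larger L and n — not by absolute positions. CSV output uses
10 significant digits; the model has no stochastic component, so
identical inputs give byte-identical files.

## Limitations

* The Eckart barrier is symmetric and static; real gate profiles from
  potential-of-mean-force calculations are asymmetric, and the
  symmetric form likely underestimates transmission.
* Steady-state only: no time-domain spiking, no K⁺ diffusion or
  clearance between axons, no endocochlear-potential or
  mechanotransduction modelling — only the basolateral leak parameter
  set.
* The "minute concentration" [K]_AP is treated as an instantaneous,
  well-mixed rise in a fixed extracellular volume.
* Over-barrier transport is clamped to T_Q = 1 in the exponential form;
  use the exact form where genuine over-barrier reflection matters.
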