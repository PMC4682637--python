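# Methods

## Model

A "capillary unit" comprises one capillary (cap) with its share of
endothelium (ec), pericapillary interstitium (is1) and cardiomyocyte
compartment (myo).  Unlabeled fatty acid (Fa) enters the capillary bound to
albumin, advects along the axial coordinate z, exchanges through the
luminal endothelial membrane, the abluminal endothelial membrane and the
sarcolemma, and is consumed in myo by a lumped first-order sink
g_met = R_met·A_myo·[Fa]_myo.  Free Fa concentration is the potential for
every diffusive step; within each aqueous compartment Fa equilibrates with
its carrier protein Cp (albumin in cap/is1, FABP in ec/myo) by mass action
with constant K_CpFa.

Each membrane crossing is three resistances in series: the aqueous boundary
zone on the donor side, the bilayer (P_mem = C_lipid·D_mem/h_mem), and the
boundary zone on the acceptor side.  The boundary-zone permeability comes
from the linearized steady reaction–diffusion problem for free Fa and CpFa
next to an impermeable-to-Cp wall:

    d_Fa = sqrt(D_Fa·K_CpFa·tau_CpFa/[Cp]0)          (decay length)
    x_b  = -d_Fa·ln(1 + d_Cp/d_Fa)                   (contact-pathway shift)
    P_b  = (1+alpha)(1-exp(-h/d_Fa))·(D_Fa/d_Fa)(1 + d_Cp/d_Fa)

with alpha = D_Fa·K_CpFa·[Cp_tot]/(D_Cp·[Cp]0²) the ratio of free to
carrier-mediated diffusion far from the wall.  Two derivational notes
uncovered while validating against an independent finite-difference
solution of the full nonlinear system (`boundary_bvp_oracle`):

- the decay-length expression is the square root of D_Fa·K·tau/[Cp]0 (the
  only dimensionally consistent form; equivalently sqrt(D/k_on') with
  rebinding rate k_on' = [Cp]0/(K·tau));
- the analytic solution is first order in alpha as well as in flux: the
  exact linearized decay length is d_Fa/sqrt(1+alpha).  The difference is
  O(alpha) ≤ 3·10⁻³ (ec) and ≤ 2·10⁻⁴ elsewhere, so the analytic form is
  used everywhere and the oracle tests assert 0.1 % agreement on the
  alpha ≪ 1 compartments and an O(alpha) band for ec.

The contact-pathway boundary condition is implemented as
phi_CpFa(x_b) = -d_Cp·(association excess)/(K·tau); this is the sign that
reproduces the virtual-shift identity above and makes P_b strictly
increasing in d_Cp (a transfer-facilitating membrane protein can only add
permeability).

[Cp]0, the free-carrier concentration extrapolated to the boundary, is
approximated by the donor compartment's bulk free Cp; albumin's three
heterogeneous binding sites are modeled as 3× identical sites with the
average K.

## Capillary length dispersion

Log-length is normal with dispersion sigma_cap = 0.5 around mean length z0;
velocity is inversely proportional to length.  Closed forms (error
functions) give the z-dependent summed cross-section A_cap, flow q_cap,
wall-circumference density and mean velocity; the Monte-Carlo ensemble
oracle (sampled lognormal lengths, flow ∝ 1/length) confirms them within
sampling error.  z0 defaults to 800 µm; outflow-curve shapes are invariant
to z0 because it only scales the z axis (transit times depend on V_cap and
q_tot alone).

## Parameters

SI internally; configs use mmol/l (≡ mol/m³), nm, µm.  Defaults (packaged
`data/default.yaml`): volume fractions cap/ec/is1/is2/myo =
0.094/0.018/0.019/0.060/0.731; membrane surface densities 75 200 / 82 200 /
89 100 m²/m³; h_mem = 5 nm; C_lipid = 8·10⁵; D_Fa = 4.8·10⁻¹⁰ m²/s;
D_Cp = 9.35·10⁻¹¹ (albumin) and 1.87·10⁻¹⁰ m²/s (FABP); K_CpFa = 9·10⁻⁶
mol/m³; n_Alb = 3 binding sites; [Cp]_is1 = 86 % of capillary; [Cp]_ec =
0.007, [Cp]_myo = 0.170 mol/m³; d_Cp = 5 nm on every face (per-face
override available to emulate transfer-facilitating membrane proteins);
D_mem = 4·10⁻¹² m²/s, giving P_mem = 640 m/s.

**Dissociation time constant.** Literature stopped-flow values for the
albumin–palmitate complex (≈0.08–0.14 s) are explicit upper bounds — the
technique cannot resolve faster dissociation.  Those upper bounds are
mutually inconsistent with the tabulated boundary-zone decay lengths
(11.5–94 nm across three perfusion conditions) and with the observed
extractions of 0.12/0.32 at the given flows: all twelve tabulated d_Fa
values back-compute to an effective K·tau ≈ 9·10⁻⁸ mol·s/m³, i.e.
tau ≈ 0.01 s.  The package default is therefore tau_CpFa = 0.01 s for all
carriers, which reproduces the tabulated boundary permeabilities within
~5–25 % and the composite membrane permeabilities within ~10 %, and makes
the experimentally observed extraction fractions attainable.

The remaining tabulated per-condition permeability values depend on
steady-state free-Cp values that are not published; they are treated as
qualitative anchors, except the closed-form identities (membrane storage
C_lipid·S·h and the series-rule composites), which are exact on printed
inputs and checked to printed precision.

## Numerical scheme

**Steady state.** Finite-volume grid over z ∈ [0, z_max] (area cutoff
10⁻⁴, cell volumes renormalized to V_cap): a uniformly-spaced head segment
before any capillary ends, then log-spaced cells across the dispersed
range.  Per cell, upwind marching solves q·(C_prev − C) = G_series·(u(C) −
u_myo) with Newton on the binding quadratic (bisection fallback); the
single well-mixed myo state (a cardiomyocyte borders several capillaries,
so it has no meaningful z) is found by a bracketing root solve of uptake =
metabolism.  Permeabilities depend on free Cp, giving a mild outer
nonlinearity solved by damped (0.5) fixed-point iteration to 10⁻⁸ relative.
The global audit inflow − outflow = metabolism closes to solver precision
(≈10⁻¹⁶ relative in practice).  R_met tuning brackets the extraction
root to |achieved − target| < 10⁻⁴; targets beyond the diffusion-limited
maximum raise an informative error.

**Tracers.** On the frozen steady state, labeled albumin (intravascular
only — albumin does not cross the endothelium) and labeled Fa evolve
linearly; the labeled free fraction per compartment is K/(K + [Cp_free]).
Method of lines: conservative first-order upwind advection (capillaries
terminating inside a cell drain its concentration to the vein),
per-cell exchange conductances G = P_composite·ΔS_mem, one myo pool whose
storage capacity includes the non-pericapillary interstitial (is2) albumin
(its entrance area is ~2 % of the sarcolemma, so it stores but does not
conduct).  Membranes carry no storage term by default, matching the
storage-free transient equations; an optional ``membrane_storage`` flag
adds per-bilayer equilibrium pools with capacity C_lipid·h_mem·S, split
between the adjacent compartments, for tail-shape studies.  Time integration is Crank–Nicolson with a pre-factorized
sparse operator (exchange rates P·S/V are orders of magnitude faster than
transit, so the system is stiff); dt = 0.02 s, horizon 150 s (600 s in
conservation tests).  Axial diffusion is omitted: its fractional
contribution relative to convection is ~10⁻³ (albumin spreads ~30 µm over
a 10 s transit versus capillary lengths of ~800 µm).  The default 120
z-cells and dt = 0.02 s were chosen so halving dt or doubling the cell
count changes outflow curves by < 1 % L1; the impulse response's mean
transit time matches V_cap/q_tot to < 0.1 %.

**Deconvolution.** The observed albumin schedule samples (interval means,
30 × 1 s + 30 × 4 s) are reconstructed to a uniform 0.1 s grid by a
monotone cubic corrected iteratively so its own interval means reproduce
the samples, then the capillary inlet is recovered by nonnegative least
squares on the causal convolution matrix with a squared-second-difference
penalty.  The smoothing weight (default 10⁻⁴) was set once so the
noiseless round trip deconvolve(convolve(f, H), H) recovers f to < 2 % L1;
dividing it by 10 changes the downstream simulated Fa washout by well
under the ±2 % robustness band expected of a stable deconvolution.

## Synthetic experiments

The generator emulates the isolated perfused rabbit-heart protocol: a
deterministic lagged-normal (exponentially modified Gaussian) inlet bolus
of ~1–2 s width standing in for the unknowable arterio-venous dispersion
of the true injection; forward-simulated albumin and Fa outflow; the
30+30 sampling schedule; multiplicative lognormal noise (default CV 2 %)
emulating counting statistics while preserving nonnegativity.  Presets A/B/C
carry the three perfusion conditions (albumin 0.11/0.0147/0.44 mmol/l, Fa
0.10/0.0133/0.40 mmol/l, flow 0.035/0.061/0.061 s⁻¹, extraction targets
0.12/0.32/0.02).  What passing round-trip tests show is that the analysis
chain is self-consistent at realistic noise; they cannot certify the
unmodeled features of real data — catheter dispersion beyond the
lagged-normal family, radioactive counting dead time, flow pulsatility, or
inter-animal parameter variability.

## Known limitations

- The boundary-zone treatment is first order in total flux and in alpha;
  strongly nonlinear loading (free Fa comparable to K·[Cp]) is outside the
  tracer regime the solver targets.
- ec/is1 intra-compartment diffusion resistance (P_aqu) is reported but not
  inserted into the exchange chain, matching the three-resistance membrane
  law; Table-level values show P_aqu ≫ P_b, so the omission is ~1 %.
- T-tubules, large vessels and interstitial cells are volume bookkeeping
  only; is2 contributes storage, not transport.
- First-order upwind advection smears plug-flow fronts; resolution was
  chosen by the convergence criterion above rather than by scheme order.
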