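# Methods

## Model overview

The package treats the systemic circulation downstream of an aortic arch
with four outlets (BCA, LCCA, LSA, descending aorta) as three-element
Windkessel (RCR) circuits: a proximal resistance Rp in series with a
parallel pair of compliance C and distal resistance Rd. Units are CGS
throughout (resistance g cm⁻⁴ s⁻¹, compliance g⁻¹ cm⁴ s², pressure barye);
mmHg appears only at I/O boundaries (1 mmHg = 1333.22 barye). Blood density
is 1.060 g/cm³.

The pipeline has four stages:

1. **Total calibration** — one aggregate RCR for the whole downstream bed,
   fitted to catheter pressure statistics (Pmax, Pmin, Pmean) under a
   prescribed inlet flow.
2. **Area distribution** — the totals shared among outlets in inverse
   (resistance) / direct (compliance) proportion to cross-sectional area,
   with the minimum coarctation cross-section standing in for the
   descending-aorta area before stenting.
3. **α redistribution** — a dimensionless split value scaling supra-aortic
   resistances by (1+α), with the descending-aorta resistance forced by
   conservation of the parallel total.
4. **gPC propagation** — α treated as uniform on [−0.15, −0.08] and
   propagated through a 0D forward model via Legendre chaos at
   Gauss–Legendre collocation nodes.

## Windkessel response and periodic initialization

The RCR pressure response to a flow Q(t) is evaluated in closed form; the
convolution integral uses the trapezoidal rule on the waveform's own grid
with the exponential kernel evaluated exactly at the nodes, via an O(n)
recursion (I(t_{k+1}) = e^(−Δt/τ) I(t_k) + panel term) that is
algebraically identical to the naive O(n²) sum. Accuracy is second order
in the grid spacing; at 4096 samples per cycle the response agrees with an
independent stiff ODE integration (LSODA at rtol 1e-11) to better than
1e-8 relative.

P(0) is always taken as the unique periodic value: the solution is affine
in P(0), so imposing P(T) = P(0) gives it in closed form. This reproduces
exactly the limit that multi-cycle warm-up simulation approaches, and makes
the choice of "which cycle to summarize" moot. The formula divides by
1 − e^(−T/τ) and raises an explicit error when that factor underflows
(T ≪ τ), rather than returning garbage.

Pressure summaries (Pmax, Pmin from samples; Pmean by trapezoid with
periodic closure) tolerate a few ulps of roundoff on flat waveforms, where
the quadrature mean can exceed the sampled max, by clamping the mean into
[pmin, pmax] within a 1e-9 relative band.

## Calibration: GA design

The optimization minimizes (Pmean error)² subject to band constraints on
Pmax and Pmin, over a box bounded by default at rp ∈ [5, 300],
rd ∈ [100, 5000], c ∈ [1e-4, 1e-2] (brackets both the pre- and
post-stenting published totals by roughly 5×). Each axis is discretized
into a uniform grid (default 1024 points); the initial population is a
scrambled Sobol sequence snapped to the grid. Operators and probabilities:
directional crossover 0.5 (offspring moves toward a better partner, away
from a worse one, by an independent Uniform(0,1) fraction per coordinate),
uniform mutation of one coordinate to a random grid value 0.1, selection
(replacement by a copy of a better individual) 0.05. Defaults: population
40, generations 250.

Two choices were genuinely open and are resolved as follows:

- **Constraint handling**: static penalty (1e3 mmHg per mmHg of violation)
  with feasibility-first ranking — any feasible individual beats any
  infeasible one.
- **Offspring acceptance**: a child replaces its parent only if its
  penalized fitness is not worse. This elitist (steady-state) acceptance
  makes every slot monotonically non-worsening and is what lets the small
  population polish the optimum to sub-grid accuracy within the default
  budget; with unconditional replacement the same budget stalls several
  mmHg away.

The published constraint tolerance ε = 0.001 mmHg is kept as the problem's
nominal band, but a practical band `eps_run` (default 0.5 mmHg) governs
feasibility during the search: 0.001 mmHg is below the discretization error
of any affordable grid, so ranking against it would make every individual
infeasible and erase the constraint signal. Both are configurable.

Identifiability: three scalar targets cannot pin down three parameters plus
a waveform shape. The guaranteed surface is the achieved pressure summary
(for constant inflow only rp + rd is identified; the compliance is
invisible). Tests and the acceptance script therefore assert summary
recovery (within 0.5 mmHg on synthetic problems), never triplet recovery.

## Distribution and α redistribution

`distribute_by_area` implements Rᵢ = R̄·A_tot/Aᵢ, Cᵢ = C̄·Aᵢ/A_tot;
`apply_alpha` implements R_supra,i = (1+α)·R_tot·A_tot/Aᵢ and
R_DA = k·R_tot·A_tot/A_DA-pathway with
k = A_CoA/(A_tot − Σ_supra Aᵢ/(1+α)). Two splitting rules are not stated
anywhere and were fixed by inspecting the published per-outlet tables:

- each outlet's α-modified total resistance splits into proximal and distal
  parts in the constant ratio R̄p : R̄d (every printed row satisfies this
  to <0.5%);
- compliances are α-independent (the printed C columns are identical across
  α rows).

The admissible α range is guarded by positivity of the k denominator
(an explicit domain error), not by hard-coding the study interval, so other
geometries work.

**Coarctation area precision.** The source data prints both the coarctation
cross-section (0.75 cm²) and the minimum coarctation diameter (0.98 cm).
The circular area of the printed diameter, π·0.49² ≈ 0.7543 cm², rounds to
the printed area and reproduces every entry of the pre-stenting per-outlet
table within 0.5%, whereas the rounded 0.75 leaves the most
area-sensitive entries (descending aorta at α = −0.15, where the k
denominator nearly cancels) at ~1.5% error. The patient fixture therefore
carries the diameter-derived value as the higher-precision form of the same
measurement.

Two known discrepancies in the published tables are documented rather than
matched: (i) the printed per-outlet compliances sum to ≈1.6e-3, about
1.51× the calibrated total C̄ = 1.06e-3, inconsistent with the stated
area-fraction rule, which this package follows; (ii) the post-stenting
table implies area fractions that match neither the printed post-operative
cross-sections under either descending-aorta area choice, so it is not used
as a verification target. The post-stenting fixture defaults to the true
descending-aorta area for the DA pathway (the narrowing has been removed);
the pre/post choice is the `da_area_mode` flag.

## 0D forward model

A single junction feeds all four outlets: zero proximal branch impedance,
so the flow split is decided entirely by the outlet parameters — the
surrogate adds no split bias of its own. The only states are the four
compliance pressures; the junction pressure is eliminated algebraically at
every evaluation from mass conservation (hence flow conservation holds to
machine precision at every sample). Integration is classical RK4 with the
junction recomputed per stage; default dt = 0.002 s. Cycles repeat until
the junction-pressure waveform changes by less than a relative tolerance
(default 1e-6) cycle-to-cycle, up to `max_cycles` (default 6, matching
common practice for transient washout); non-convergence is reported in the
result, not raised. With the pre-stenting parameter sets the periodic state
needs ~17 cycles at 1e-6, so invariant tests and the propagation runs use
`max_cycles = 40`.

An optional stenosis element adds ΔP = K·(ρ/2)·(Q/A_CoA)²·sign(Q) in series
on the descending-aorta pathway; the junction equation is then solved by
safeguarded Newton (the residual is strictly monotone in the junction
pressure). It is off by default: the α mechanism already carries the
coarctation resistance, and the reported ΔP (junction to descending-aorta
terminal) is an analogue of the clinically measured drop, not a replica —
the catheter-based measurement spans the supra-aortic ostia, which no 0D
topology can reproduce.

Any substitute forward model (including imported 3D-CFD results, via the
CSV bundle reader) satisfies the same contract: (inflow, outlet set) →
per-outlet flows + pressures with conserved flow.

## Polynomial chaos

Basis: Legendre polynomials mapped to [low, high] and normalized to be
orthonormal under the *probability* measure (Φ_k = √(2k+1)·P_k), so all
Galerkin denominators are 1, the mean is a₀ and the variance is Σ_{k≥1}aₖ².
Collocation uses exact Gauss–Legendre abscissae with weights normalized to
sum to 1; projection is the discrete quadrature inner product, applied per
time sample for waveform outputs. Default order 3 with 4 nodes (Gauss
exactness covers the required degree). A least-squares projection accepts
arbitrary node sets — e.g. hand-rounded α values such as −0.15, −0.13,
−0.10, −0.08, which are the 4-point Gauss nodes of the default interval
rounded to two decimals — whenever the node count exceeds the order.

PDFs are produced by resampling the surrogate (uniform draws, fixed seed)
and histogramming — no kernel bandwidth to choose, bit-reproducible given
the seed. Truncation adequacy is monitored as |a_Λ|/‖a‖ (max over time
samples); for the descending-aorta flow at order 3 it is ~0.02, and for
smooth test functions on the narrow default interval it is < 1e-4.

## Synthetic data

The patient flow waveforms exist only as figures in the source study, so
the generator emulates them: a half-sine systolic lobe (width = systolic
fraction × period, default 0.4) over a diastolic baseline (default 0),
single-peaked like the measured pulses, with closed-form mean
d + (2/π)·s·(peak − d). "Parabolic" in the source refers to the spatial
velocity profile, not the temporal shape. The fixture pulse peak is chosen
so the mean flow equals Pmean/(R̄p+R̄d) — for the pre-stenting stage
≈118 cm³/s mean, peak ≈464 cm³/s — making fixture pressures and totals
mutually consistent for closed-loop tests. Optional Gaussian sample noise
(default sd 2 cm³/s, an arbitrary visible amplitude; the measured
error bars are figure-only) is added only when a seed is supplied.

What passing tests on these fixtures do **not** show: agreement with the
patient's absolute flows, ΔP or TAWSS values, which depend on the 3D
geometry and the true measured waveforms. The qualitative stochastic
structure — variability concentrated at the systolic peak
(systolic/diastolic std ratio ≈4.4 for descending-aorta flow), monotone
descending-aorta flow in α, ΔP far less α-sensitive in relative terms —
is reproduced and is what the acceptance checks assert.

## Problem sizes and determinism

Default study sizes: 256–512 samples per cycle for calibration waveforms,
350 time steps per cycle (dt = 0.002 s at T = 0.7 s) in the 0D model,
4 collocation nodes / order 3 for gPC, GA 40×250, 1e5 draws for PDFs, 1e6
draws for Monte-Carlo oracle checks. Every random element (Sobol
scrambling, GA operators, noise, PDF resampling) is seeded; identical
seeds give bit-identical results.

## Known limitations

- The 0D surrogate's flow split ignores branch inertia and wave travel;
  its ΔP is a junction-to-terminal drop, not a catheter ΔP.
- TAWSS handling covers the temporal-averaging operator and its stochastic
  moments for user-supplied |WSS|(s, t) fields; no spatial WSS can be
  computed without a 3D solve.
- Calibration returns *a* triplet matching the pressure summary, not the
  unique physiological one.
- The GA is a global heuristic: the convergence guarantee is empirical
  (seeded tests), not theoretical.
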