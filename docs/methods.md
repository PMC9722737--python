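# Methods

## Model

`csfsim` treats the craniospinal CSF space as an incompressible
hydraulic circuit driven by volumetric flow sources and drained by
windkessel absorption outlets. Two levels of spatial detail are
provided.

**0D model.** All inflows are summed into a single pressure node
drained by one 2-element windkessel (resistance R_tot, compliance
C_tot, external pressure 0). The governing ODE
`Q = P/R + C dP/dt`, discretized with a backward difference at step
Δt, gives the recurrence

    P_n = (Q_n R + P_{n-1} C R / Δt) / (1 + C R / Δt)

which is a stable first-order IIR filter; `simulate_0d` evaluates it
with `scipy.signal.lfilter`. Its discrete frequency response,
`H(ω) = R / (1 + C R (1 − e^{−iωΔt})/Δt)`, is used in the test suite
as an independent closed-form oracle; as Δt → 0 it converges to the
continuous windkessel gain `R/√(1+(ωRC)²)`.

**Network model.** Four rigid compartments — `ventricles`, `basilar`
(the CSF around the basilar artery), `cranialSAS`, `spinalSAS` — are
joined by linear conduits: `aqueduct` (ventricles→basilar),
`tentorial` (basilar→cranialSAS) and `foramen_magnum`
(basilar→spinalSAS). Compartments are rigid, so they store no volume;
all storage lives in the outlet compliances, and per time step the
model is a small linear system in the node pressures. Sources attach
as in the anatomy: production and the ventricle-wall arterial
pulsation at the ventricles, the basilar arterial pulsation at the
basilar compartment, the respiratory venous term at the cranial SAS.
The interstitial, lymphatic and arachnoid-villi outlets drain the
cranial SAS; the spinal outlet drains the spinal SAS.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| production | 6.67e-3 | ml/s | choroid-plexus production, ≈0.4 ml/min |
| arterial1 amplitude | 0.11 | ml/s | pulsatile flow at the third-ventricle level |
| arterial2 amplitude | 5.05 | ml/s | sized from cervical flow amplitude via `(Q_c − Q_v3)/c_sp` |
| venous1 amplitude | 1.01 | ml/s | respiratory venous volume change, 0.2 Hz |
| cardiac / respiratory frequency | 1.0 / 0.2 | Hz | 60 bpm, 12 breaths/min |
| ICP target | 10 | mmHg | centre of the 7–15 mmHg physiological band |
| R_tot | 1500 | mmHg·s/ml | ICP_target / production |
| outflow fractions q | 20/20/30/30 | % | int/sp/lym/av split of net absorption |
| C_tot | 0.17 / 0.51 / 1.01 | ml/mmHg | case A fit; cases B–E inputs (below) |
| Δt | 0.05 | s | resolves the 1 Hz pulsation with 20 samples/cycle |
| fluid | 998.2, 1.003e-3 | kg/m³, Pa·s | water at body-ish conditions |
| aqueduct | L 15 mm, A 10 mm² | | gives ≈1.2 cm/s peak velocity at peak flow |
| tentorial / foramen | L 30 mm, A 150 mm² | | wide passages; sub-0.01 mmHg spatial drops |

Conduit resistances are Poiseuille values for circular tubes,
`8 μ L/(π r⁴)`, converted with 1 mmHg = 133.322 Pa (the package works
in clinical units throughout: mmHg, ml/s, ml/mmHg, s).

All pulsatile sources share phase 0 at t = 0 and have zero net volume
over a whole period. The venous amplitude is deliberately taken from
the same parameter table that defines the cases (1.01 ml/s ≈ 20 % of
the arterial sum) rather than from the rule-of-thumb "half the
arterial amplitude", which would give 2.53 ml/s; the tabulated value
is the one that keeps all five cases mutually consistent.

## Compliance tuning

`tune_total_compliance` simulates the 0D model from P0 = 0 for 5 s at
Δt = 0.05 s for 1000 compliance values evenly spaced on (0, 1.2]
ml/mmHg (C = 0 is a pure resistor and is excluded as an evaluation
point), measures the half peak-to-peak pressure amplitude over the
full window — the startup drift of the slow mean transient is
deliberately included, as the evaluation mimics reading the first five
cardiac cycles of a recording — and returns the compliance where the
amplitude crosses the 5 mmHg target. The amplitude is strictly
decreasing in C, so the crossing is unique; linear interpolation
between the bracketing grid points refines it below the 0.0012
grid spacing. An unreachable target raises an error naming the
achieved amplitude range.

Two conventions deserve note. First, amplitude means *half* of
(max − min): with this convention the respiration-free fit lands at
0.164 ml/mmHg, i.e. the literature-scale 0.17 value; reading
(max − min) as the full amplitude would instead give ≈ 0.33. Second,
only case A's compliance is a fit output. Applying the same protocol
to the respiration-on inflow gives ≈ 0.33 ml/mmHg, not the 0.51
carried by cases B–D; those values (and case E's doubled 1.01) are
therefore treated as case *inputs*, consistent with in-vivo reports of
0.4–1.2 ml/mmHg.

## Solvers

**Monolithic.** The outlet relations are assembled into the node
system: an outlet at node j contributes admittance `1/R + C/Δt` to the
diagonal and `P_out/R + C P_prev/Δt` to the right-hand side. A single
`numpy.linalg.solve` per step yields the pressures; conduit and outlet
flows follow algebraically, and the per-node mass residual (sources +
conduit inflow − outlet outflow) is recorded; it stays at round-off
(< 1e-9 ml/s) for every run in the test suite.

**Partitioned.** When the flow solver must be treated as a black box,
the coupling works on the outlet-bearing nodes: prescribe their
pressures (Dirichlet), solve the interior, and read back the net
outflow each such node must deliver. Aggregating the windkessels at a
node into `F_j = g_j P_j − h_j` (with `g_j = Σ 1/R_k + C_k/Δt`,
`h_j = Σ P_out,k/R_k + C_k P_prev,k/Δt`), the scheme is:

1. first iterate: explicit update `P = (F + h)/g` from the flows at
   the previous pressures (with `tol = inf` this explicit-coupling
   result is returned as-is — useful for demonstrating why the
   implicit coupling is needed: spatial pressure differences are
   orders of magnitude smaller than the temporal swings, so the
   explicit step misplaces the node pressures by ~0.1 mmHg);
2. otherwise: estimate the sensitivity `J = ∂F/∂P` by probing each
   outlet node with a 1e-3 mmHg perturbation, then iterate
   quasi-Newton updates `P ← P + (diag(g) − J)^{-1} (F − gP + h)`,
   re-solving the flow after each update, until the equivalent
   pressure residual drops below `tol` (default 1e-9 mmHg, up to 50
   iterations; failure raises `ConvergenceError` with the residual).

Because the network is linear, the first Newton step is exact and the
scheme converges in two iterations; on all five reference cases it
matches the monolithic solution to better than 1e-6 mmHg. Outlets
co-located at one node see the same pressure by construction, so
grouping them loses nothing; in a genuinely 3D flow domain each outlet
would be a distinct boundary surface with its own pressure.

A single-compartment network reduces exactly to the 0D recurrence;
the test suite asserts this equivalence at 1e-12.

## Initial conditions and metrics

Outlet time constants `R_tot C_tot` are 255–1515 s, so the mean
pressure transient far outlives a 25 s run. Reference-case runs
therefore start all node and outlet pressures at the 10 mmHg target
(`run_case(..., initial_pressure=10.0)`); transient studies (including
the tuning protocol) start at 0. Even mean-initialized, the pulsatile
particular solution is not phase-matched at t = 0, so a slowly
decaying homogeneous offset of a few mmHg rides on a 25 s run — means
quoted over such windows sit above the asymptotic 10 mmHg, and only
the long 0D runs (≈ 2000 s) recover it.

Metrics are evaluated over the last 5 s of a run (five cardiac cycles;
also one full respiratory cycle). Means use the half-open window
(t0, t1], which at Δt = 0.05 s contains an exact whole number of
samples per source period, so pulsatile means vanish to round-off and
the mean aqueduct flow equals production exactly. Amplitudes are half
peak-to-peak of the sampled trace; the sampled extremes can sit up to
half a sample off the true peaks (≤ 1.2 % at 1 Hz), which is accepted
as part of the measurement convention — tests that verify the filter
*gain* instead read the Fourier component at the driving frequency,
which is exact for uniform sampling over whole cycles.

The ventricle-to-spinal-SAS pressure difference is the pointwise
difference of the two node pressures. The spinal-SAS "cross-section
flow" is the foramen-magnum conduit flow; "aqueduct flow" is the
aqueduct conduit flow; peak aqueduct velocity is max |Q|/A over the
window.

## What the surrogate does and does not capture

The network reproduces the boundary-condition physics exactly: mass
conservation, the outlet windkessel dynamics, the compliance flow-split
law (pulsatile outlet flow ∝ its compliance fraction in the ωRC ≫ 1
regime, so the spinal outlet carries ≈ c_sp × the total pulsatile
inflow, ≈ 3.5 ml/s for case A), the insensitivity of aqueduct flow to
everything downstream, and the inverse scaling of pressure pulsation
amplitude with total compliance.

Spatial pressure structure is only caricatured. With the default
circular-tube geometry the ventricle-to-spinal-SAS difference
amplitude is O(0.004) mmHg — three orders below the temporal swings,
the qualitatively correct regime — but its split between the aqueduct
and foramen paths is geometry-dependent: here the aqueduct term
dominates, so halving the spinal compliance (case D) reduces the
difference by only ~15 %, whereas a domain whose cervical path
dominates the resistance would show a ~2× reduction. Absolute spatial
differences from this surrogate should not be quoted against imaging
or catheter data; only their orders of magnitude and directions of
change are meaningful.

Other simplifications: rigid compartments (no tissue poroelasticity or
fluid–structure interaction), sinusoidal single-harmonic sources, no
gravity or postural effects, laminar fully developed flow in conduits
(Reynolds numbers are O(10–100), checked via `reynolds_number`), and
absorption lumped into four discrete sites.

## Numerical choices and degenerate inputs

- Δt defaults to 0.05 s everywhere; the recurrence is unconditionally
  stable (backward difference), so accuracy, not stability, sets Δt.
- C = 0 outlets reduce exactly to the algebraic resistor law.
- Networks must be connected and have ≥ 1 outlet; a source or outlet
  referencing an unknown compartment, non-positive resistances, or a
  singular step system raise `ValueError` at construction/solve time.
- Outflow fractions must be strictly positive and sum to 1 (an outlet
  with zero outflow must be omitted, not zero-weighted); compliance
  fractions must be non-negative and sum to 1.
- The model is deterministic end to end: repeated runs of one
  configuration are bit-identical, and the CSV writer preserves this
  (shortest round-trip float formatting, round-trip parsing on read).
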