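# Methods

## Scope and model

`d4refit` implements the analysis layer of a system-specific protocol for
tuning semi-classical dispersion corrections: given cluster geometries,
per-structure total energies from an electronic-structure method and from a
high-accuracy benchmark, and pairwise dispersion parameters, it forms
one-body-subtracted interaction-energy deviations and refits the S6/S8
scaling factors to minimize the mean absolute deviation. It deliberately
does **not** run electronic-structure calculations (energies are ingested
data), does not implement charge- or coordination-dependent dispersion
coefficients (fixed effective per-pair C6 values are used, or per-structure
components are ingested from an external dispersion code), and neglects
three-body and higher dispersion terms throughout.

The dispersion energy is the strict a<b pair sum over orders n = 6, 8 with
rational (Becke–Johnson) damping `f_n(r) = r^n/(r^n + (sr_n·R0)^n)`,
`R0 = a1·√(C8/C6) + a2`, and the recursion `C8 = 3·C6·√(Q_a·Q_b)`. E_dis is
stored positive and subtracted from the method total; many codes use the
opposite sign convention, so report files state this explicitly. The sum is
evaluated once per structure at unit scaling, split by order into
`(e6_raw, e8_raw)`; every downstream energy at arbitrary (S6, S8) is the dot
product `S6·e6_raw + S8·e8_raw`, which is exact because the factors enter
the sum multiplicatively.

## Parameters

- **Damping and scaling defaults** (`data/d4_params.yaml`): the published
  Becke–Johnson damping defaults per functional (a1 dimensionless, a2 in
  bohr, converted to Å at load). The S8 defaults round to the commonly
  quoted values (B3LYP 2.029, PBE 0.959, revPBE 1.746, revPBE0 1.571); S6 = 1
  and sr8 = 1 by convention.
- **Q factors** (H 4.0295, O 6.7268 bohr²) follow the standard
  √Z·⟨r⁴⟩/⟨r²⟩-based effective values used by the D3/D4 family.
- **Pair C6** (H–H 3.0884, H–O 5.7385, O–O 10.3708 hartree·bohr⁶) are fixed
  effective coefficients representative of water. Exact agreement with a
  full coordination/charge-dependent dispersion code is a non-goal: whenever
  exact coefficients matter, per-structure components computed externally
  are ingested via the component TSV and everything downstream is unchanged.
- **Units**: Å and kcal/mol internally (1 hartree = 627.509474 kcal/mol,
  1 bohr = 0.52917721 Å); table readers normalize units once at the boundary.

## One-body treatment

The reference monomer is O–H = 0.95865 Å, H–O–H = 104.348°. Three backends
supply monomer energies: (i) tabulated per-monomer columns in the energy
table, used when present; (ii) a built-in harmonic two-stretch/one-bend
potential about the reference geometry (k_r = 1200 kcal·mol⁻¹·Å⁻² per O–H,
k_θ = 100 kcal·mol⁻¹·rad⁻², magnitudes representative of the water
molecule's vibrational force field), used by all synthetic tests; (iii) an
extension point for an accurate fitted intramolecular potential
(Partridge–Schwenke-style), whose parameters are out of scope here. The
benchmark side receives the same treatment as the method side — the backend
is per-method configurable, defaulting to a shared one.

Monomers are identified by nearest-oxygen assignment of hydrogens with an
O–H acceptance cutoff of 1.3 Å: comfortably above distorted covalent O–H
(~0.96 Å) and below the shortest hydrogen-bond H···O contact (~1.6 Å).
Cluster compactness is measured by the radius of gyration; mass-weighted by
default (the convention is recorded in outputs), with oxygen-only and
uniform variants selectable since the ordering convention is not uniquely
fixed by common usage.

## Fitting

With the linear decomposition, MAE(S6, S8) is a convex piecewise-linear
function. The 1-D minimizer (S8 with S6 fixed, or S6 with S8 pinned to 0) is
found **exactly** among the breakpoints `(d_i − S6·e6_i)/e8_i` clipped to
bounds, plus the bounds themselves; ties resolve to the smallest factor so
the correction stays minimal. Bounds default to S8 ∈ [0, 5], S6 ∈ [0, 2].
If every relevant component vanishes the objective is flat: the lower bound
is returned with `flat_flag` set — a degenerate but legitimate outcome, not
an error.

The joint mode alternates exact 1-D minimizations until the objective
improves by < 1e-10 (bounded iterations), then applies an exact
linear-programming polish (L1 regression as an LP, solved with HiGHS).
The polish exists because coordinate descent on a polyhedral objective can
stall at a vertex that is optimal along each axis but not jointly; the LP
guarantees the global minimum, and the final coordinate pass puts the
reported factors back on breakpoints. The objective is MAE, matching the
deviation statistics being reported; a least-squares (MSE) objective is
available behind the `objective` switch for sensitivity analysis, minimized
in closed form per coordinate. Per-size training (fit on one designated
cluster size, validate on the rest) is available through the command line,
with pooled fitting weighting each configuration equally.

"Err" is the mean signed deviation over configurations — the interpretation
under which Err = ±MAE whenever all deviations share a sign. Displayed
tables round to 2 decimals, half away from zero; JSON output keeps full
precision.

## Synthetic data

The generator emulates ensembles of non-equilibrium water clusters:
oxygens placed by rejection sampling with a minimum O–O distance (default
2.5 Å) in a box whose side scales as n^(1/3) with a packing factor swept
from 2.9 to 3.9 Å across each size's configurations, giving a
compressed-to-extended gyration ladder whose mean radius grows with n.
Monomers are built at the reference geometry, uniformly randomly oriented
(quaternion method), and distorted by Gaussian perturbations of the two O–H
lengths (σ = 0.02 Å) and the bend angle (σ = 2°) — distortions that give
one-body energies of a few tenths of kcal/mol, the regime where one-body
subtraction visibly matters.

Mock energy tables are built so the construction is exactly invertible: the
method total is `base + Σ onebody`, the benchmark total is
`base + Σ onebody − (S6*·e6_raw + S8*·e8_raw) + ε`, with `base` an additive
O–O Lennard-Jones-like term (ε = 5 kcal/mol, r_min = 2.9 Å) standing in for
hydrogen bonding. The base model cancels identically in the deviation, so
its exact form only sets realistic magnitudes (tens of kcal/mol per
cluster). The pre-dispersion deviation is therefore
`S6*·e6_raw + S8*·e8_raw − ε` and the refit must recover the true factors —
exactly at ε = 0. Noise is per cluster, Gaussian, with σ = 0.1·n kcal/mol by
default, emulating a stochastic benchmark whose statistical error is
~0.1 kcal/mol per monomer. Every generator output is a pure function of its
spec, including the seed; ladder specs derive distinct per-structure seeds
deterministically from the base seed.

What passing synthetic tests do **not** show: the generator samples neither
thermodynamically realistic hydrogen-bond networks nor real
electronic-structure error patterns (which correlate with structure, unlike
the additive noise used here). Results on real data additionally depend on
the quality of the ingested dispersion coefficients and one-body potential.

## Problem sizes and tolerances

Test and acceptance runs use ladders of 100 clusters (25 each of
n = 6, 9, 15, 27; up to 81 atoms) — ample for exact-recovery checks whose
answer is analytic, and matched to the configuration-count scale of typical
benchmark sets. Noiseless recovery is asserted to 1e-8; noisy recovery
(σ = 0.1·n, 100 configurations) is asserted within ±0.26 of the true S8,
about four replicate standard deviations measured over 50 independent
repeats of the whole experiment (replicate std 0.065). The dense-grid
oracle for the breakpoint optimizer uses a 10⁻⁴ step over [0, 5]; the
linear-decomposition oracle requires 1e-12 relative agreement with direct
re-summation.

## Known limitations

- Fixed per-pair C6 ignores coordination and charge effects; use ingested
  component tables for production coefficients.
- No counterpoise/BSSE correction and no basis-set extrapolation (ingested
  energies are taken as given).
- No periodic systems, no analytic gradients, no non-water solvents in the
  monomer partitioner.
- No uncertainty quantification on the fitted factors; the replicate-spread
  figures above characterize the synthetic construction, not real data.
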