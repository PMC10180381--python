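# d4refit

System-specific refitting of semi-classical (Grimme-style) dispersion
corrections to density functional theory, driven by benchmark interaction
energies of molecular clusters of growing size. The package targets water
clusters (H₂O)ₙ with n ≈ 6–27, where general-purpose DFT-D parametrizations
can over- or under-stabilize hydrogen-bonded assemblies and a small,
system-tailored adjustment of the dispersion scaling factors brings the mean
absolute deviation per monomer down to the intrinsic accuracy of the
benchmark (~0.1 kcal/mol).

## The model

The dispersion-corrected total energy is `E_DFT-D = E_DFT − E_dis`
(three-body and higher terms neglected), with the two-body correction

```
E_dis = Σ_{a<b} Σ_{n=6,8}  S_n · C_n^{ab} / r_ab^n · f_n(r_ab)
```

where `C6^{ab}` are pairwise dispersion coefficients, `C8^{ab} = 3·C6^{ab}·√(Q_a·Q_b)`
is derived recursively from per-element multipole ratios, and
`f_n(r) = r^n / (r^n + (sr_n·R0)^n)` with `R0 = a1·√(C8/C6) + a2` is the
rational (Becke–Johnson) damping function. `S6` is conventionally 1 and `S8`
is the customary empirical knob per exchange–correlation functional.

For each cluster the quantity compared against the benchmark is the
**one-body-subtracted interaction-energy deviation**

```
deviation = ΔEⁿ − ΔEⁿ_1-body
ΔEⁿ_X        = Eⁿ_X − n·E^ref_X
ΔEⁿ_1-body,X = Σ_i (Eⁱ_X − E^ref_X)
```

i.e. the method-minus-benchmark difference of total interaction energies,
minus the same difference for the sum of monomer distortion energies
(reference monomer: O–H = 0.95865 Å, H–O–H = 104.348°). Removing the
one-body part isolates the intermolecular interaction — the only piece a
dispersion correction can improve.

Because `E_dis` is exactly linear in `(S6, S8)`, the mean absolute deviation
over a set of clusters is a convex piecewise-linear function of the factors.
`d4refit` minimizes it **exactly**: the 1-D optimum lies on a breakpoint
`s = residual_i / component_i` (or a bound), and the joint (S6, S8) fit
alternates exact 1-D minimizations with a linear-programming polish.

## Worked example

```
$ d4refit gen --sizes 6,9,15,27 --n-per-size 25 --seed 1 \
      --s6-true 1.0 --s8-true 2.0 --noise-sigma 0.0 --out-dir run
[d4refit:gen] structures=100 out=run seed=1
$ d4refit fit --energies run/energies.tsv --components run/components.tsv \
      --mode s8_only --functional b3lyp --out-dir run/fit
[d4refit:fit] mode=s8_only s6=1.000000 s8=2.000000 mae=0.000000 out=run/fit
```

The `gen` step builds 100 synthetic non-equilibrium water clusters (25 each
of n = 6, 9, 15, 27, spanning compressed to extended configurations) and
mock energy tables whose benchmark-minus-DFT gap is, by construction,
`1.0·e6_raw + 2.0·e8_raw` per cluster. The `fit` step re-assembles the
one-body-subtracted deviations from the files alone and recovers
`S8 = 2.000000` with a residual MAE of `0.000000` kcal/mol — exact recovery,
as it must be on noiseless data. `run/fit/tables.tsv` reports Err, MSE, MAE
and MAE-per-molecule per cluster size for both the refit and the default
B3LYP parametrization (S8 = 2.029), and `run/fit/scan.tsv` tabulates the
convex MAE(S8) curve.

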