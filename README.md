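# noefold

NOE-restrained structure refinement and analysis of DNA–bis-intercalator
complexes, built around the 2:1 complex of the anticancer bis-intercalator
XR5944 with the estrogen-response element of the TFF1 promoter
(the 15-mer duplex 5′-AGGTCACGGTGGCCA / 5′-TGGCCACCGTGACCT).

The package is aimed at structural-NMR practitioners who want a tested,
self-contained implementation of the classical solution-structure
workflow for drug–DNA complexes:

1. **Topology & coordinates** — duplex pairing/numbering (sense 1..n,
   complement n+1..2n, antiparallel), idealized B-DNA construction from
   standard-reference-frame base templates, and placement of the two
   bis-phenazine drug copies into opened intercalation gaps.
2. **Distance restraints** — isolated-spin-pair calibration of NOESY
   volumes, `r = r_ref (V_ref/V)^{1/6}`, referenced to the cytosine
   H5–H6 distance (2.45 Å) with ±20 % flat bounds, pseudo-atom
   corrections, Watson–Crick hydrogen-bond restraints, and the skewed
   bi-harmonic flat-well penalty (30 / 60 kcal mol⁻¹ Å⁻² for NOE /
   hydrogen-bond restraints at full strength).
3. **Restrained simulated annealing** — velocity-Verlet dynamics with a
   per-step rescaling thermostat on a surrogate force field; the staged
   protocol (300 K equilibration, heating to 1000 K, force-constant
   ramp, 25 K cooling decrements of 1000 × 3 fs steps, coordinate
   averaging, 250-step minimization) is encoded as data and scalable.
4. **Analysis** — base-pair frames, per-step rise/twist, site unwinding
   against the 36°/step B-DNA reference, Kabsch superposition, pairwise
   ensemble RMSD and restraint-violation statistics.
5. **Binding** — the fluorescent-intercalator-displacement (FID)
   titration model `[X₂T]/[T₀] = B[X]/(K_D+[X])` with equal-site
   approximation, 2:1 free-ligand mass balance, least-squares K_D fit
   and bootstrap confidence intervals.

A synthetic-data module generates ground-truth complexes (intercalation
gaps at the four binding steps with rises 5.95/6.01/6.34/5.86 Å and
32°/28° site unwinding), r⁻⁶ NOESY peak lists with log-normal volume
noise, and noisy titration tables, so the entire pipeline is testable
offline.

## Worked example

```sh
python examples/build_and_analyze.py
```

builds the complex at its refined geometry and measures it back:

```
unwinding over the first drug site (steps 5-7):  32.0 deg
unwinding over the second drug site (steps 9-11): 28.0 deg
```

with per-step output showing the four intercalation gaps (rise ≈ 5.9–6.3 Å
against 3.4 Å elsewhere).  `examples/calibrate_restraints.py` simulates
and calibrates a NOESY peak list (the ±20 % bounds cover essentially all
true distances at 10 % volume noise), `examples/anneal_and_select.py`
refines a 1 Å-perturbed start back to the gap geometry, and
`examples/fit_binding_constant.py` fits the binding constant:

```
K_D = 9.255e-07 M  (true 9.650e-07 M)
95% CI: [7.670e-07, 1.170e-06] M
```

A thin CLI wraps the same functions (`noefold pipeline --seed 1 --out out/`
chains every stage end-to-end; see `noefold --help`).

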