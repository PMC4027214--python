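# Methods

This note documents the models, numerical choices and known limitations
behind `noefold`.  The package re-creates, on synthetic data, the
classical NMR structure-determination workflow for a 2:1
bis-intercalator–DNA complex, plus the displacement-assay binding fit.

## Coordinate model

Bases are encoded as heavy-atom templates in the standard base reference
frame (origin on the pairing axis, x toward the major groove, base plane
z = 0); a Watson–Crick partner is the 180° rotation about x.  The
deoxyribose/phosphate backbone is grown from C1′ by internal-coordinate
(NeRF) construction with a C2′-endo pucker (pseudorotation P = 162°,
amplitude 38°) and B-form torsions.  Four branch torsions and the
glycosidic χ were calibrated once by least squares so that the uniform
36°/3.4 Å helix closes the sugar ring (C4′–O4′ ≈ 1.45 Å) and yields
contiguous O3′–P links (1.58–1.61 Å on both strands); the fitted values
(χ = −115.3°, γ = 42.2°, β = 150.6°) are frozen in the source.  The atom
set is all heavy atoms plus the protons that NOE work needs:
non-exchangeable sugar/base protons, the imino protons (bookkeeping for
pairing), and single pseudo-protons (Q-prefixed) at methyl centroids.
5′-terminal residues carry a free 5′-OH (no phosphate).

A duplex is assembled pair by pair from per-step (rise, twist) lists, so
the builder's inputs are exactly the helical parameters the analysis
module measures back; the builder/analyzer round trip is exact to
numerical precision on gap-free duplexes.

The drug is modelled as two planar phenazine tricycles (atoms C1–C10A,
N5, N10; aromatic protons H2–H4 and H6–H8; a C9 methyl), each carrying a
C1 carboxamide-aminoethyl half-linker whose γ-amino nitrogen is
protonated (+1 at pH 7), joined by a central ethylene.  Placement drops
a phenazine centroid at the midpoint of an opened gap's flanking pair
origins (a step must have rise ≥ 5 Å to accept a chromophore), long axis
along the mean pair axis and linker on the major-groove side; the bridge
ethylene is interpolated in cylindrical coordinates and dipped toward
the groove floor (radius 7 Å) so it follows the groove rather than
cutting through the backbone.

## Synthetic data = study conditions

`tff1_complex_spec()` encodes the refined-complex geometry: gaps
at steps C5pA6, C7pG8, G9pT10 and G11pG12 with rises 5.95, 6.01, 6.34
and 5.86 Å; 13°/6°/13° twist deficits over the first 3-step site (32°
total) and 12°/4°/12° over the second (28°); 7° at the central G8pG9
step; and 4.5° spill-over into the ±1 neighbouring steps.  The per-step
split of the site totals is the package's choice — only the totals, the
central step and the 4–5° neighbour range are constrained by the
measurements being emulated.

NOESY simulation emits one peak per proton pair within a 5.5 Å cutoff
(a typical NOESY detection range) with volume V = C·r⁻⁶·e^ε,
ε ~ N(0, σ); σ defaults to 10 % (multiplicative log-normal volume
error).  The cytosine H5–H6 reference peak is emitted with its volume
computed from the nominal 2.45 Å calibration distance, making noise-free
calibration round-trip distances exactly.  Spin diffusion, spectral
overlap, linewidths and chemical shifts are not simulated; the pipeline
is pure isolated-spin-pair throughout.

Titrations are generated under the equal-site 2:1 binding model at the
assay conditions: duplex 16.7 µM, drug totals 0–100 µM (13 points),
3 replicates, replicate noise N(0, 0.02·B).

Because the generators and the analysis share these definitions, passing
tests show the pipeline is self-consistent and numerically correct under
ISPA assumptions — not that it would reproduce a real spectrometer's
peak lists, which carry spin diffusion and assignment ambiguity.

## Restraints

Calibration: r = 2.45·(V_ref/V)^(1/6); bounds 0.8 r and 1.2 r; upper
bounds inflated by pseudo-atom corrections (+1.0 Å methyl, +0.9 Å
non-stereoassigned methylene, +2.0 Å aromatic-equivalent pairs — the
standard corrections).  Non-positive volumes are rejected and counted.
Categories are re-derived from atom identity (intraresidue, sequential —
adjacent same-strand residues or cross-strand within one pair step —
drug, drug–DNA, plus a normally-empty long-range bucket); hydrogen-bond
restraints keep their creation flag.  Hydrogen bonds contribute two
restraints per selected pair (N1···N3 and the carbonyl···amino pair)
with targets measured from the package's own template pairing geometry
and ±0.2 Å flat bounds; the default subset is all non-terminal pairs,
and the 12-pair inventory subset excludes the weak-site pair whose imino
proton shifts least.  The restraint penalty is the flat-well skewed
bi-harmonic: zero inside the bounds, k·skew·(d − bound)² outside, with
k = 30 (NOE) or 60 (hydrogen bond) kcal mol⁻¹ Å⁻² at full schedule
strength and a 1:1 skew default (the asymmetry is configurable; no value
is dictated by the protocol being emulated).

## Surrogate force field

Exact reproduction of a 1990s CHARMM/X-PLOR parameterization is not a
goal; the engine uses a self-consistent surrogate whose ideal covalent
values (bond r₀, angle θ₀, improper and proper-torsion φ₀) are measured
from the package's own idealized build of the same topology — the
starting model, constructed with the NOE-deduced intercalation gaps,
*is* the covalent reference, mirroring how a starting model fixes
topology-dependent terms in practice.  Terms:

* harmonic bonds (k = 300), angles (k = 50), impropers (k = 25, one per
  ≥3-coordinate center, holding sp² planarity and sp³ chirality), and
  proper dihedrals (k = 5 kcal mol⁻¹ rad⁻², all bonded quadruples)
  holding rotamers — glycosidic torsion, pucker, backbone — near the
  reference conformation;
* soft quartic repulsion k(σ−r)⁴ with σ = 0.85 × summed vdW radii, so
  aromatic stacking contacts (~3.0 Å plane separation at an opened gap)
  sit outside the repulsive core;
* a Gaussian dispersion well (depth 0.05 kcal mol⁻¹, width 0.5 Å,
  centred at vdW contact) between heavy atoms.  Early versions without
  cohesion let stacked interfaces drift to the top of the NOE bound
  slack during the 1000 K stages and freeze ~1 Å too open on cooling;
  the shallow well restores the stacking preference a real vdW term
  provides while leaving the restraint network in control;
* Coulomb electrostatics among formal charges only (phosphate −1 split
  over OP1/OP2, γ-amino +1) under a distance-dependent dielectric
  ε(r) = 4r, emulating aqueous screening without explicit solvent.

Exclusions are 1-2/1-3/1-4; the neighbour list is a k-d-tree rebuild
every 15 steps at a 5.5 Å radius.  Hydrogen masses are repartitioned to
12 amu so the protocol's 3 fs cooling timestep integrates stably under
per-step velocity rescaling; kinetic temperature therefore matches each
stage target exactly by construction.

## Annealing protocol

The schedule is data: 300 K/20 ps at 1 fs with all restraint force
constants at 1 kcal mol⁻¹ Å⁻²; 1000 K/3 ps; a 24 ps linear ramp to
(30, 60); cooling from 1000 K to 300 K in 25 K decrements of 1000 × 3 fs
steps (28 cycles); 3 ps equilibration; a 3 ps coordinate-averaging
window; then 250 steps of minimization (L-BFGS on the full energy).
Each ensemble member draws Maxwell–Boltzmann velocities from seed + i
and the run is deterministic given (inputs, seed).  Model selection is
lexicographic — fewest violations > 0.2 Å, then lowest total energy,
stable index tie-break — a documented choice where the emulated
procedure states only "minimal energy terms and minimal number of
violations"; the candidate count before selection is likewise free
(default 50 in configuration, far fewer in routine runs).

A `scale` factor shrinks stage durations (never temperatures or force
constants).  Routine runs and the test suite use scale 0.1 (a ~7 700-step
protocol, about a minute per model on one core) — problem sizes chosen
so the whole suite stays comfortably interactive; scale 1.0 reproduces
the full protocol.

At desk scale, annealing a 1.0 Å-RMS-jittered start against noise-free
restraints recovers all four gap rises within 0.3 Å with zero violations
> 0.2 Å.  The published ensemble statistics (2.38 ± 0.99 violations,
0.024 Å violation RMSD, 0.78 Å pairwise RMSD) are *not* reproducible in
this surrogate world — they depend on the original force field and the
undeposited experimental restraint list — and the recovery property
above substitutes for them.

## Analysis conventions

Base-pair frames come from least-squares (Kabsch) fits of observed ring
atoms to the templates, complement frames flipped about x, the pair
frame the geodesic midpoint of the two base rotations.  Step rise is the
inter-origin vector projected on the mid-step z-axis; twist is the
rotation of the x-axes about it; unwinding is 36° − twist.  No published
convention is being matched exactly (different analysis programs differ
at the < 0.2 Å / < 2° level on distorted steps), which is why geometry
tests on the emulated complex carry 0.2 Å / 2° tolerances.  Pairwise
ensemble RMSD uses all DNA + ligand heavy atoms after optimal
superposition (terminal residues included; the selection is a mask
argument).  Violation excess is measured against the violated bound, not
the target.

## Binding model

Bound fraction f = B·[X]/(K_D + [X]) with [X] free drug; free drug from
totals by the 2-per-duplex mass balance x = X_t − 2 T₀ B x/(K_D + x),
solved by bracketed Brent iteration (the closed-form quadratic root is
the independent test oracle).  How free concentrations were obtained
from dispensed totals is not specified by the emulated assay write-up;
this mass balance is the package's documented assumption.  The fit
optimizes (log K_D, B) by Levenberg–Marquardt least squares with free
drug recomputed per iteration, multi-started from {0.1, 1, 10} × the K_D
start; uncertainty comes from seeded case-resampling bootstrap (95 %
percentile intervals).  Fluorescence correction maps raw readings to
fractions via 1 − (F − blank)/(F₀ − blank), clipped to [0, 1.05].

## Degenerate inputs and tie-breaks

Empty site lists build plain B-DNA; a zero-length schedule returns the
input coordinates bit-identically; divergent trajectories (non-finite or
> 10⁹ kcal mol⁻¹ energies) are flagged, never silently dropped; zero
drug total gives zero free drug without iteration; model-selection ties
resolve by candidate index.

## Limitations

Uniform fiber geometry only (no sequence-dependent propeller/roll); no
explicit solvent, Ewald sums or constraint algorithms; no relaxation-
matrix treatment of spin diffusion; no EtBr-competition model beyond the
proportional-fluorescence assumption; the surrogate force field is
self-referential by design and is not transferable to structures built
outside the package.  Atomic partial charges beyond the formal set are
deliberately omitted — no source for them exists within the emulated
protocol's description.
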