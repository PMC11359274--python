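# Methods

`epsrlite` is a desk-scale implementation of empirical potential structure
refinement (EPSR) for amorphous indomethacin: a semi-rigid molecular Monte
Carlo model whose interaction potential is iteratively perturbed by the
difference between a target X-ray structure factor and the model's own,
followed by hydrogen-bond network, coordination-number and conformer-angle
analysis.  Because the underlying beamline data are not redistributable,
the package carries a synthetic-diffraction generator that forward-computes
S(Q) from constructed configurations; every quantitative claim the test
suite makes is anchored to such fixtures.

## Molecular model

The indomethacin Z isomer (C19H16ClNO4, 41 atoms) is represented by a
single frozen idealized geometry, produced once by distance-geometry
embedding plus MMFF relaxation and then uniformly scaled so the mean
C-X bond length (X = C, N, O; 26 bonds) is exactly 1.380 Å, the
crystalline reference value and the only geometric quantity the X-ray
D(r) first peak pins down.  `bond_expansion` (0-0.05 Å) scales the whole
molecule by (1.380 + e)/1.380, so the mean C-X bond is exactly 1.380 + e
and responds to the expansion with slope one.  We chose uniform scaling
over adding a constant to each bond because the experimental observation
being emulated is a 1-3% *percentage* lengthening of the average bond;
the per-bond difference between the two readings is below 0.002 Å.

Atom types follow the scattering analysis: O1 (acid carbonyl, acceptor),
O2 (acid hydroxyl, donor), O3 (amide carbonyl, acceptor), O4 (methoxy),
C4/C8 (amide and acid carbonyl carbons), C1-C3, C5-C7, C9, C10 (carbon
classes), N, Cl, H1 (carbon-bound H) and H2 (the acid proton).  The
molecule is semi-rigid: bonds carry harmonic terms (default
2500 kJ mol⁻¹ Å⁻², never strained by the rigid move set), and
conformational freedom enters through five rotatable groups — the
chlorobenzyl ring spin (C4-C9 axis), the benzoyl swing (N-C4), the
methoxy rotor, the acetic-acid arm (ring-CH2) and the carboxyl rotor
(CH2-COOH).  These link the indole, amide, methoxy and acid units; the
"rigid" model variant limits each to 5°.

## Reference potential

Intermolecular interactions are Lennard-Jones (Lorentz-Berthelot mixing)
plus Coulomb terms on a reduced charge set: acceptor oxygens -0.6/-0.4 e,
carbonyl carbons +0.7 e, the acid proton +0.8 e, all other sites neutral.
This set is deliberately unbalanced (+0.6 e net per molecule) and is kept
verbatim, with an optional uniform neutralization toggle (off by default).
Because of the net charge and the small box, electrostatics use
shifted-force truncation at half the box length rather than an Ewald sum;
LJ terms are energy-shifted to zero at the same cutoff.  The ring nitrogen
and methoxy oxygen, which the published parameter set does not type, get
oxygen-like LJ parameters (ε 0.65 kJ/mol, σ 3.1 Å) and zero charge.
A soft half-harmonic penalty (default stiffness 1000 kJ mol⁻¹ Å⁻²) keeps
intermolecular O-O contacts from collapsing below 2.6 Å while remaining
finite, so a data-driven refinement can still pull pairs slightly inside.
Intramolecular non-bonded pairs are excluded: geometry is held by the
harmonic bonds and the rigid move set, and the five group rotations barely
change the excluded set's distances at the amplitudes used.
k_C = 1389.3545764438293 kJ mol⁻¹ Å e⁻²; k_B = 0.00831446261815324
kJ mol⁻¹ K⁻¹.

## Scattering

Partial pair distribution functions are exact-count histograms of
minimum-image intermolecular distances (default dr = 0.05 Å, r_max = L/2),
normalized by ideal-gas shell counts with the exact pair multiplicities
(N_aN_b cross, N_a(N_a-1)/2 like), so uncorrelated systems give g = 1
without finite-N bias.  The total X-ray S(Q) is Faber-Ziman weighted with
Cromer-Mann analytic form factors (an "electron count" flat mode exists
for speed); the transforms act on the raw pair counts, which makes the
histogram route agree with a direct Debye sum up to binning alone.  Two
background conventions are exposed: "uniform" subtracts the ideal-gas
counts before transforming (periodic homogeneous systems — the default)
and "none" transforms the counts as they stand, the open-cluster
convention matched by the O(N²) `debye_oracle` used as an independent
cross-check (agreement better than 0.02 in max norm over 1-20 Å⁻¹ for an
8-molecule cluster at dr = 0.02 Å).

Intramolecular scattering is computed per configuration as an exact Debye
sum over each molecule's conformer distances, optionally broadened by a
0.05 Å Gaussian standing in for vibrational disorder, rather than from
histogrammed partials: the bonds do not fluctuate at these run lengths and
exact distances keep the high-Q periodicity — which pins the mean C-X
bond — free of binning error.

Real space uses D(r) = (2/π) ∫ Q[S(Q)-1] sin(Qr) dQ by trapezoidal
quadrature with an optional Lorch window, and G(r) = 1 + D(r)/(4πρr).
Running coordination numbers n_ab(r) = 4πρc_b ∫ g_ab r'² dr' are evaluated
from the same exact counts (fractional last bin by uniform-in-bin
interpolation).

## Monte Carlo and empirical-potential refinement

Moves are molecular translations, rigid rotations about the centroid and
single-group rotations, one attempted move per molecule per sweep on
average, accepted by the Metropolis rule at 300 K (the temperature is a
free model parameter; room temperature matches a glass studied below its
glass transition).  Move energies are incremental — only the moved atoms'
interactions are recomputed — and a hard 1.0 Å intermolecular floor
auto-rejects absurd overlaps.  During equilibration amplitudes can be
autotuned toward 30-50% acceptance; note that in strongly bonded systems
this throttles diffusion (amplitudes shrink to ~0.2 Å), so the recovery
experiment below uses fixed glass-scale amplitudes (0.6 Å / 25° / 20°)
instead.

The empirical potential is an r-space table (dr = 0.05 Å) on the ten
heavy-element pair channels (C, N, O, Cl).  Each update sine-transforms
the model-target S(Q) difference (Lorch windowed) to a D(r)-scale
difference, converts it to a g(r)-scale correction δg(r) = δD/(4πρr), and
adds update_rate·k_B·T·δg to **every** heavy channel, clipped to the
amplitude cap.  We deliberately do not scale channels down by their
Faber-Ziman weights: the X-ray pattern constrains the weighted aggregate,
not the decomposition, and weight-proportional scaling leaves minority
channels (O-O carries ~2% of the signal) with corrections far too small to
act on — in the recovery experiment it stalls the hydrogen-bond census
outright.  Giving each channel the full aggregate correction and letting
the reference potential decide which channels can respond restores the
negative feedback that makes EPSR work: the O-O well deepens until the
model census matches the target and the S(Q) difference stops driving it.
The sign convention is checked by construction: an excess model peak in g
at r₀ produces a repulsive bump within ±0.2 Å of r₀.

`refine()` alternates sweep blocks with potential updates until the fit
metric R = Σ[S_model-S_target]²/Σ[S_target-1]² (this package's own
definition; the literature does not fix one) plateaus, then freezes the
potential and amplitudes and collects an ensemble whose type-level partial
histograms are averaged.  Desk-scale defaults are 2000 equilibration
sweeps, updates every 50 sweeps, 500 collected configurations at stride 2;
production-scale ensembles are reached by raising `n_collect`.

## Synthetic data and the packing threshold

Fixtures are built from analytically constructed hydrogen-bond motifs —
isolated molecules, singly bonded pairs, doubly bonded carboxylic-acid
dimers (point-inversion construction of the eight-membered ring), open
trimers and bifurcated four-molecule units — at a requested O2···O1
contact distance (2.67 Å by default, the reference-crystal dimer value).
Units are packed as rigid bodies: greedy insertion, simulated-annealing
Monte Carlo on a soft overlap energy, and stepwise affine compression,
with floors of 2.0 Å (heavy-heavy), 1.5 Å (hydrogen pairs), 2.6 Å (O-O)
and a *strict* 3.35 Å floor between donor O2 and acceptor oxygens that
keeps spurious hydrogen bonds out of the 3.2 Å analysis cutoff.

A geometric fact shapes the generator: at the glass densities
(0.090-0.095 atoms Å⁻³) the ideal-gas expectation is already ~0.3 random
acceptors within 3.2 Å of every donor, so a dense box with an *exact*
motif census (zero spurious donor-acceptor contacts) essentially does not
exist for rigid random packings; our annealing experiments plateau at
50-300 residual contacts.  The generator therefore packs exact-census
fixtures below the rigid-random-packing threshold (~0.055 atoms Å⁻³;
tests and benchmarks use 0.050) and raises a `PackingError` above it,
while a relaxed mode (`strict_census=False`) builds boxes at the exact
reported densities for the five-sample suite, accepting the physically
unavoidable proximity contacts.  The census-anchored observables (the
dimer fixture's n_O2-O1(3.2) = 1.0, the chain-statistics oracles) are
density-independent by construction, so what passing those tests shows is
unaffected; what the fixtures do *not* emulate is the full steric
frustration of a real glass, its vibrational disorder, or any instrument
effects (the noise model is additive i.i.d. Gaussian).

Forward "observations" are the scattering module's total S(Q) plus
optional Gaussian noise, fully seeded.  The five pseudo-samples follow the
reported per-sample densities with motif fractions rising monotonically
from pseudo-I (34% bonded molecules) to pseudo-V (75%), which reproduces
the qualitative first-sharp-diffraction-peak growth used to distinguish
the more ordered samples.

## Hydrogen-bond analysis

A hydrogen bond is donor O2 within 3.2 Å (the first minimum of the
donor-acceptor partial g(r)) of an acceptor oxygen (O1, O3, optionally O4)
on another molecule, minimum-image; an O2-H2···acceptor angle filter
(>120°) exists but is off by default, mirroring the distance-only
definition the coordination-number analysis uses.  Chain statistics
collapse parallel edges (a doubly bonded dimer is one neighbor), "chain
size" is the connected-component size of the molecule-level graph, and
both %-of-molecules and %-of-bonds views of the chain-size histogram are
emitted because either aggregation is defensible.  Dipole contacts are
intermolecular C4···O1 pairs within a configurable cutoff (3.2 Å).

## The recovery experiment

`epsrlite.experiments.recovery_experiment` is the package's end-to-end
check that the refinement machinery can move a structural observable the
target data demand: the target is the noise-free S(Q) of a 64-molecule box
of singly bonded pairs (n_O2-O1(3.2) = 0.5 by construction, at
0.050 atoms Å⁻³ where the exact census is constructible), the start is a
random array of molecules, and the protocol runs 6000 sweeps with updates
every 50 sweeps, an amplitude cap of 6 kJ/mol and fixed move amplitudes,
measuring the coordination number on a tail-averaged ensemble.  Under the
reference potential alone the model equilibrates near n ≈ 0.25; the
data-driven O-O perturbation supplies further association.  The cap
matters: at 2 kJ/mol the perturbation rails before the feedback closes,
so the experiment uses the smallest cap that does not rail and lets the
data self-limit the well depth.

The measured outcome (seed 7; recomputed by the acceptance suite and by
`analysis/03_recovery_experiment.py`) is n_O2-O1 = 0.378 against the 0.5
target, with the remainder of the driven association (~0.11 on the amide
O3, ~0.02 on the methoxy O4) on other acceptor oxygens.  This shortfall
is structural, not a bug: oxygen subtypes share a form factor, so the
total X-ray S(Q) constrains the *total* short-range O-O association —
which the refinement recovers to within a few percent — but cannot
attribute it to a specific acceptor, and bonds formed on the "wrong"
acceptor are tens of kJ/mol deep and do not exchange at 300 K on
desk-scale runs (a 600→300 K annealed equilibration does not remove
them).  The acceptor-blind leakage mirrors the behavior of refined models
of the real glass, which likewise develop amide-oxygen hydrogen bonds
absent from the crystal forms.  A reader should therefore treat
acceptor-resolved coordination numbers from X-ray-only refinements as
carrying an uncertainty of roughly this leakage fraction (~0.1-0.15
here), while totals and distance distributions are much better
determined.

## Numerical choices and limitations

- Histogram bins dr = 0.05 Å (0.02 Å for oracle comparisons); Q grid
  0.5-25 Å⁻¹, step 0.025-0.05 Å⁻¹; all configurable.
- Energy kernels use fastmath compilation; pair energies are reproducible
  to ~1e-12 relative, and the incremental-move path is tested against full
  recomputation at 1e-7 relative.
- Degenerate inputs: zero-length rotation axes, non-monotone Q grids,
  overlapping atoms (r < 0.1 Å) and unknown atom types raise immediately
  with the offending item named.
- The refinement is NVT-style: the box never changes during a run.
- The model shares EPSR's intrinsic non-uniqueness: a converged fit
  constrains the weighted aggregate of partials, not each partial
  individually, so hydrogen-bond statistics inherit information from the
  reference potential's chemistry as well as from the data.
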