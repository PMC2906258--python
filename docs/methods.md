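# Methods

This note records the models implemented in `xtalaudit`, the numerical
choices behind them, what the synthetic battery does and does not emulate,
and the places where the design was genuinely open.

## Symmetry and geometry

All geometry flows through `CrystalFrame`: the PDB orthogonalization
convention (a along x, b in the xy plane), d-spacings from the reciprocal
metric, and a built-in operator table for twenty common space groups keyed
by Hermann–Mauguin symbol (REMARK 290 operators override the table when
present). The canonical asymmetric-unit representative of a Miller index is
the lexicographically greatest member of its orbit, with the Friedel mate
folded in unless the data are anomalous; any deterministic convention works,
and this one is order-independent, which makes merging reproducible.
Centric flags and ε multiplicities come from direct operator enumeration.

An anisotropic ADP is accepted as physical when its smallest eigenvalue
exceeds 1e-9 Å². The strict tolerance is deliberate: hydrogens deposited
with exactly zero ADPs must classify as nonphysical, and a loose tolerance
would let them through.

## Structure factors

Direct summation evaluates, per reflection,
F(h) = Σ occ·f(s)·DW·exp(2πi h·x) over all symmetry-expanded atoms of all
models; multi-model ensembles are summed directly because their occupancies
already carry the ensemble weighting. Isotropic Debye–Waller factors use
exp(−B s²/4); anisotropic ones exp(−2π² sᵀUs) with U rotated per symmetry
operator in Cartesian space. X-ray form factors are the standard 4-Gaussian
+ constant parameterization; neutron scattering uses per-isotope coherent
lengths (negative for H, positive for D, which is why H/D substitution is
observable).

The FFT route samples each atom as a sum of real-space Gaussians on a grid
of spacing ≤ d_min/4, with two safeguards: every term is smeared by an
artificial B of 12 Å² (divided out exactly in reciprocal space afterwards),
which makes the constant form-factor term representable and pushes aliased
spectral weight below ~1e-6; and each Gaussian is truncated where its
density falls to 1e-7 of peak. With these settings the two routes agree to
an amplitude R of ~1e-7 % on the battery's crystals — orders of magnitude
inside the 0.01 % equivalence bound asserted by the tests, so the choice of
route never affects a reported statistic.

## Bulk solvent and scaling

The flat-solvent mask is the classic two-parameter construction: voxels
within (r_vdw + r_solv) of any symmetry-expanded atom are non-solvent, and
boundary voxels outside all van der Waals spheres but within r_shrink of
solvent are reassigned back to solvent (shrink truncation). Defaults are
r_solv = 1.11 Å, r_shrink = 0.9 Å; the alternative 0.8/1.2 pairing used by
other programs is exposed as parameters, and `scripts/pdb_spot_check.py`
reports both, since mask-convention differences are a known source of
percent-level R discrepancies between programs.

Scaling fits k_overall, a zero-trace anisotropic tensor U_cryst constrained
to the point group, and (k_sol, B_sol), by: a coarse grid
(k_sol ∈ 0…0.6 step 0.05 × B_sol ∈ 10…150 step 10) with the overall scale
analytic at each node, a log-linear least-squares update of U_cryst
(symmetrized by group averaging; the isotropic part is removed because it is
degenerate with k_overall and the atomic B's), and a Nelder–Mead polish of
(k_sol, B_sol) minimizing the working-set R. Updates are only accepted when
they lower R, which guarantees the fit never does worse than the best plain
isotropic scale. Below 50 working reflections the solvent correction is
disabled rather than fitted. The exponential-tensor form of the anisotropic
correction is a documented choice; the exact parameterization used by any
particular refinement program is not reproduced here.

## Twinning

Candidate merohedral twin laws are integer matrices with entries in
{−1,0,1} that preserve the cell metric (tolerances 0.1 Å / 1°) but lie
outside the Laue group, reduced to coset representatives of order 2 or 3.
Pseudo-merohedry (laws that only approximately fix the metric of a lower
symmetry lattice) is out of scope — covering it would require a
lattice-reduction engine and is not needed for exact-metric merohedral
cases. Per law, |F_twin|² = (1−α)F²(h) + αF²(law·h) is fitted with α
scanned on [0, 0.5] in 0.01 steps plus a bounded 1-D polish, rescaling the
overall factor analytically at each α; reflections whose twin mate is
absent from the data are skipped and counted. The final verdict — untwinned
or a specific law — is simply the configuration with the lowest R, the same
decision logic the ADP-convention heuristic uses.

## TLS

REMARK 3 TLS groups are parsed in both widespread dialects (residue-range
selections vs free-text selections); the dialect is detected from the
selection line style. Defective records never raise: they are classified as
(a) selection, (b) origin or (c) matrix problems, and the affected group is
simply withheld — in a survey most of the information content is in *which*
category a file fails. Overlapping selections are ambiguity, category (a);
the parser does not guess intent.

L matrices are stored in deg² exactly as deposited and converted to rad²
only inside the reconstruction U = T + A·L·Aᵀ + A·S + Sᵀ·Aᵀ, where A is the
cross-product matrix with Aλ = λ×(x−origin). This is the covariance of
small rigid-body displacements u = t + λ×d with ⟨λλᵀ⟩ = L, ⟨ttᵀ⟩ = T,
⟨λtᵀ⟩ = S, and the tests verify it against a 2·10⁵-sample Monte-Carlo
rigid-body simulation.

Whether deposited B values are total or residual is resolved empirically:
the full scale+R pipeline runs once as-is and once with U_TLS added, and
the lower R_work wins; differences under 0.1 percentage points keep the
deposited convention for determinism. The solvent mask is shared between
the two runs because it depends only on coordinates. When all TLS groups
are defective the convention is forced to "total" and the defects attach to
the result — the R penalty this causes on residual-B depositions is itself
a diagnostic.

## Data statistics

Amplitude-vs-intensity detection computes the acentric second moment
⟨v²⟩/⟨v⟩² per resolution bin (expected 4/π ≈ 1.273 for Wilson amplitudes,
2 for exponential intensities) and picks the nearer expectation; any
negative value forces "intensity". Below 200 acentric reflections the call
is returned with low confidence rather than withheld. Intensities convert
to amplitudes by F = √max(I,0) with first-order error propagation
σ_F = σ_I/2F — not a French–Wilson Bayesian estimate, which is noted as an
extension; the conversion is isolated behind one function.

Free-flag conventions: a 0/1 column whose minority is ≤ 25 % marks the
minority as test set; an integer 0…N column (N ≥ 5) marks value 0; a
constant column is treated as absent with a warning, and with no flags at
all R_free is reported as n.a. rather than fabricated.

The Wilson B is a straight-line fit of ln(⟨I⟩/(ε·Σf²)) against s²/2 over
d < 4 Å (slope = −B). Outlier rejection is an expected-extreme-value test
on normalized intensities: a reflection is excluded when its Wilson tail
probability (exp(−z) acentric, erfc(√(z/2)) centric) times the number of
reflections drops below 0.01. Both are deliberately simple, testable
stand-ins for the cited likelihood procedures in the literature, kept
behind their own functions so a fuller treatment can replace them without
touching callers. Resolution shells are near-equal-count with boundaries at
d quantiles, so reflections with identical d never straddle a shell.

## σ_A, maps and correlation

σ_A is estimated per resolution bin (bins under 20 reflections merge into a
neighbor) by maximizing the Rice (acentric) / Woolfson (centric)
log-likelihood of |E_obs| given |E_model| on (0, 1−1e-6); figures of merit
are m = I₁/I₀(X) acentric and tanh(X/2) centric with
X = 2σ_A|E_o||E_c|/(1−σ_A²), and D comes from σ_A times the bin amplitude
ratio rather than a joint ML fit — a documented simplification isolated
inside `estimate_sigma_a`. Maps are synthesized with Hermitian completion
and sigma-scaled (mean 0, sd 1). Real-space correlation uses spheres of
2.0 Å around each atom (union of spheres per residue), Pearson over voxels,
with the F_calc reference map restricted to observed indices so that
incompleteness biases both maps equally; per-atom reporting is used below
2.0 Å resolution, per-residue above. The sphere radius and the granularity
threshold are conventions, not derived quantities; both are single
constants.

## The synthetic battery

Fixtures are random toy crystals: heavy atoms placed uniformly with a
1.2 Å minimum separation (against all symmetry images), optional hydrogens
riding at 1.0 Å from a parent, B values drawn uniformly from a stated
range. Observations are simulated through the production F_model path
(optionally with TLS applied, twin mixing on intensities, multiplicative
Gaussian noise, a seeded 5 % free set), and every fixture carries its
generating parameters as a JSON-serializable manifest. The standard crystal
is 150 heavy atoms + 30 % H in P2₁ at 1.5 Å with 3 % noise and
k_sol = 0.35 / B_sol = 46 Å² — parameter magnitudes chosen to sit in the
middle of the range reported for real depositions. Recovery-test problem
sizes (40–200 atoms, 1.5–2.0 Å, ~400–2000 reflections, 10 seeds where a
claim is statistical) are chosen so the whole battery runs in minutes on
one core while keeping the recovered-parameter scatter well inside the
asserted tolerances.

What the generator does **not** emulate: real protein geometry and
connectivity, ordered solvent networks, experimental σ models beyond
multiplicative noise, radiation damage, anisotropic diffraction limits, or
anomalous substructure beyond per-type f′/f″. Consequently a passing
battery shows the *algorithms* are correct and self-consistent — parameter
recovery, convention resolution, invariances — not that any particular real
entry will reproduce its header statistics; for that, the spot-check script
runs the same pipeline on deposited files.

## Numerical choices and degenerate inputs

- FFT grid: spacing ≤ d_min/4 on FFT-friendly dimensions; smearing B 12 Å²;
  Gaussian truncation at 1e-7 of peak.
- Occupancy-sum tolerance 1e-3 (PDB columns carry two decimals).
- Empty models produce an all-solvent mask with a warning, not an error;
  hydrogens with no heavy neighbor within 1.3 Å keep their own ADPs with a
  warning.
- Degenerate cells (volume ≤ 0, angles outside (0°, 180°)) and operator
  sets lacking the identity are rejected at construction.
- ADP-convention ties (< 0.1 pp) resolve to "total"; all tie-breaks are
  deterministic so reports are byte-stable.
- (0,0,0) is excluded everywhere a d-spacing is needed; systematic absences
  are excluded from completeness denominators.

## Known limitations

- The space-group table covers common groups, not all 230; non-standard
  settings and Hall symbols are out of scope (explicit operators can always
  be supplied).
- Binary reflection formats are not read; text export is assumed.
- Unmerged multi-observation data are only averaged over exact duplicate
  indices, not scaled.
- Wilson-B, outlier rejection, σ_F propagation and the D estimate are the
  simplified forms described above.
- Water building, restraint generation, geometry validation and
  multipolar/interatomic-scatterer models are outside the package's scope.
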