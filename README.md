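# xtalaudit

Crystallographic model-vs-data statistics: given a macromolecular model (PDB
format) and reduced experimental amplitudes or intensities, `xtalaudit`
recomputes the numbers a depositor reports and audits everything that
commonly makes those numbers irreproducible.

It is aimed at structural biologists and methods developers who want a quick,
scriptable answer to "does this model actually fit this data as well as the
header claims?" — at deposition time, during validation, or when surveying an
archive of entries of mixed provenance.

## What it computes

The central quantity is the crystallographic R factor

    R = Σ ||F_obs| − |F_model|| / Σ |F_obs|

over working and cross-validation (free) reflections, where

    F_model(h) = k_overall · exp(−2π² sᵀ U_cryst s) ·
                 |F_calc(h) + k_sol · exp(−B_sol s²/4) · F_mask(h)|

combines the atomic structure factors `F_calc` with the flat bulk-solvent
model (mask transform `F_mask`, parameters `k_sol`, `B_sol`, mask radii
r_solv = 1.11 Å / r_shrink = 0.9 Å) and an anisotropic overall scale
(zero-trace tensor `U_cryst`). On top of that the pipeline handles:

- **Structure factors** by direct summation or FFT density sampling
  (the two routes agree to an amplitude R far below 0.01%), for X-ray or
  neutron scattering, with ANISOU tensors, multi-model ensembles and
  user-supplied f′/f″.
- **Merohedral twinning**: twin laws enumerated from the cell metric; per
  law, the twin fraction α is fitted against
  |F_twin|² = (1−α)·F²(h) + α·F²(law·h) and the configuration with the
  lowest R wins.
- **TLS**: group records are parsed from REMARK 3 in both common dialects;
  rigid-body ADPs are reconstructed as U = T + A·L·Aᵀ + A·S + Sᵀ·Aᵀ, and the
  total-vs-residual ADP ambiguity is resolved by running the full pipeline
  both ways and keeping the lower R_work.
- **Data statistics**: amplitude-vs-intensity detection from acentric Wilson
  moments (⟨v²⟩/⟨v⟩² ≈ 4/π for amplitudes, ≈ 2 for intensities), merging to
  the asymmetric unit, free-flag convention detection, completeness in
  resolution shells, a Wilson-plot B factor, and extreme-value outlier
  rejection under the Wilson distribution.
- **Maps**: σ_A estimated per resolution bin by Rice/Woolfson maximum
  likelihood; 2mFo−DFc, mFo−DFc, 3Fo−2Fc, Fobs-filled and anomalous
  difference coefficients; sigma-scaled synthesis; real-space correlation
  per atom or residue against an F_calc map restricted to observed indices.
- **Audits**: non-positive-definite and zero ADPs, negative occupancies,
  unknown scattering types, alternative-conformer occupancy sums,
  H/D-exchange sites summing below 1, per-site occupancy totals across
  multi-model entries, and a three-way defect taxonomy for broken TLS
  records (selection / origin / matrix problems).

## Worked example

The package ships a synthetic-crystal generator whose defaults mirror the
conditions of the validation battery; here it plays the role of a deposited
entry with known ground truth (`k_sol = 0.35`, `B_sol = 46 Å²`, 3% noise):

```python
from xtalaudit.synthetic import make_toy_crystal, GroundTruth, simulate_fobs
from xtalaudit.fitting import CrystalFit

ens = make_toy_crystal(50, "P21", (16., 17., 15., 90, 102, 90),
                       h_fraction=0.3, seed=7)
truth = GroundTruth(k_sol=0.35, b_sol=46.0, noise=0.03, seed=7)
rs = simulate_fobs(ens, truth, 1.6)          # 1088 reflections to 1.6 A
print(CrystalFit(ens, rs, twin="auto").fit().summary())
```

prints

```
Model-to-data fit
========================================
ADP convention total            R_work 2.31  R_free 2.25 *
k_overall 0.9941  k_sol 0.351  B_sol 46.2 A^2
reflection outliers removed: 0
```

R_work of 2.31% is the expected floor for 3% multiplicative noise
(≈ 0.03·√(2/π)), and the fitted solvent parameters recover the generating
values to well within their uncertainties. The same pipeline runs from the
shell on files:

```sh
xtalaudit model.pdb data.hkl --cc auto --map 2mfo-dfc --map-out coeffs.txt \
          --json report.json
```

which prints the four-section plain-text report (model, data, fit, header)
and writes its machine-readable twin. Map coefficients are exported as
`h k l amplitude phase` text columns.

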