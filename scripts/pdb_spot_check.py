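#!/usr/bin/env python
"""Recompute R factors for a locally supplied deposited entry.

This is the accession-based spot check: it needs the deposited coordinates
(PDB format) and structure factors (SHELX/CNS/column text) on disk — they
are not bundled and are not fetched.  Example:

    python scripts/pdb_spot_check.py 1jvx.pdb 1jvx-sf.txt

Prints R_work/R_free at the shipped mask defaults (r_shrink 0.9 / r_solv
1.11) and at the alternative 0.8 / 1.2 radii for comparison with the
corresponding published values.
"""

from __future__ import annotations

import argparse

from xtalaudit.fitting import CrystalFit
from xtalaudit.pdbio import parse_pdb
from xtalaudit.reflections import (
    extract_free_flags,
    guess_data_kind,
    merge_to_asu,
    read_reflections,
    to_amplitudes,
)


def fit_with_radii(ensemble, rs, r_solv, r_shrink):
    res = CrystalFit(ensemble, rs, r_solv=r_solv, r_shrink=r_shrink).fit()
    return res.r_work, res.r_free


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("model")
    parser.add_argument("data")
    parser.add_argument("--data-kind", choices=["auto", "F", "I"],
                        default="auto")
    args = parser.parse_args()

    ensemble = parse_pdb(args.model)
    miller, value, sigma, flags = read_reflections(args.data, "auto")
    if args.data_kind == "auto":
        kind, _, _ = guess_data_kind(miller, value, ensemble.frame)
    else:
        kind = "amplitude" if args.data_kind == "F" else "intensity"
    rs, n_red = merge_to_asu(miller, value, sigma, ensemble.frame, kind=kind,
                             free_flag=flags)
    mask, convention = extract_free_flags(
        None if rs.free_flag is None else rs.free_flag.astype(int))
    rs.free_flag = mask
    rs = to_amplitudes(rs)

    def fmt(x):
        return "n.a." if x is None else f"{100 * x:.1f}"

    for label, r_solv, r_shrink in (
        ("defaults r_shrink=0.9 r_solv=1.11", 1.11, 0.9),
        ("alternative r_shrink=0.8 r_solv=1.2", 1.20, 0.8),
    ):
        rw, rf = fit_with_radii(ensemble, rs, r_solv, r_shrink)
        print(f"{label}: R_work {fmt(rw)}  R_free {fmt(rf)}")
    print(f"(data kind: {kind}; free-flag convention: {convention}; "
          f"{n_red} redundant input rows)")


if __name__ == "__main__":
    main()
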