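"""Scattering-factor tables.

X-ray form factors use the standard 4-Gaussian-plus-constant parameterization

    f(s) = sum_i a_i exp(-b_i s^2 / 4) + c,      s = 1/d = 2 sin(theta)/lambda

with International Tables (IT92 / Cromer-Mann) coefficients.  Neutron
scattering is a single real coherent scattering length per isotope (fm,
Sears compilation); hydrogen's is negative, deuterium's positive, which is
why H/D substitution changes structure factors qualitatively in neutron work.

Van der Waals radii (A) feed the bulk-solvent mask.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "XRAY_FORM_FACTORS",
    "NEUTRON_LENGTHS",
    "VDW_RADII",
    "xray_form_factor",
    "scattering_value",
    "resolve_scattering_type",
]

# element -> (a1..a4, b1..b4, c)
XRAY_FORM_FACTORS: dict[str, tuple[tuple[float, ...], tuple[float, ...], float]] = {
    "H": ((0.493002, 0.322912, 0.140191, 0.040810),
          (10.5109, 26.1257, 3.14236, 57.7997), 0.003038),
    # deuterium is electron-identical to hydrogen for X-rays
    "D": ((0.493002, 0.322912, 0.140191, 0.040810),
          (10.5109, 26.1257, 3.14236, 57.7997), 0.003038),
    "C": ((2.31000, 1.02000, 1.58860, 0.865000),
          (20.8439, 10.2075, 0.568700, 51.6512), 0.215600),
    "N": ((12.2126, 3.13220, 2.01250, 1.16630),
          (0.005700, 9.89330, 28.9975, 0.582600), -11.5290),
    "O": ((3.04850, 2.28680, 1.54630, 0.867000),
          (13.2771, 5.70110, 0.323900, 32.9089), 0.250800),
    "P": ((6.43450, 4.17910, 1.78000, 1.49080),
          (1.90670, 27.1570, 0.526000, 68.1645), 1.11490),
    "S": ((6.90530, 5.20340, 1.43790, 1.58630),
          (1.46790, 22.2151, 0.253600, 56.1720), 0.866900),
    "NA": ((4.76260, 3.17360, 1.26740, 1.11280),
           (3.28500, 8.84220, 0.313600, 129.424), 0.676000),
    "MG": ((5.42040, 2.17350, 1.22690, 2.30730),
           (2.82750, 79.2611, 0.380800, 7.19370), 0.858400),
    "CL": ((11.4604, 7.19640, 6.25560, 1.64550),
           (0.010400, 1.16620, 18.5194, 47.7784), -9.55740),
    "K": ((8.21860, 7.43980, 1.05190, 0.865900),
          (12.7949, 0.774800, 213.187, 41.6841), 1.42280),
    "CA": ((8.62660, 7.38730, 1.58990, 1.02110),
           (10.4421, 0.659900, 85.7484, 178.437), 1.37510),
    "MN": ((11.2819, 7.35730, 3.01930, 2.24410),
           (5.34090, 0.343200, 17.8674, 83.7543), 1.08960),
    "FE": ((11.7695, 7.35730, 3.52220, 2.30450),
           (4.76110, 0.307200, 15.3535, 76.8805), 1.03690),
    "ZN": ((14.0743, 7.03180, 5.16520, 2.41000),
           (3.26550, 0.233300, 10.3163, 58.7097), 1.30410),
}

# coherent neutron scattering lengths, fm
NEUTRON_LENGTHS: dict[str, float] = {
    "H": -3.7390,
    "D": 6.6710,
    "C": 6.6460,
    "N": 9.3600,
    "O": 5.8030,
    "P": 5.1300,
    "S": 2.8470,
    "NA": 3.6300,
    "MG": 5.3750,
    "CL": 9.5770,
    "K": 3.6700,
    "CA": 4.7000,
    "MN": -3.7300,
    "FE": 9.4500,
    "ZN": 5.6800,
}

VDW_RADII: dict[str, float] = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80,
    "S": 1.80, "NA": 2.27, "MG": 1.73, "CL": 1.75, "K": 2.75, "CA": 2.31,
    "MN": 1.19, "FE": 1.26, "ZN": 1.39,
}


def resolve_scattering_type(symbol: str) -> str:
    """Normalize an element / scattering-type symbol; raise on unknown.

    The unknown-type marker 'X' (seen in some depositions) and anything else
    not in the tables raises KeyError so callers can report the offending
    atoms before any computation starts.
    """
    key = symbol.strip().upper()
    if key not in XRAY_FORM_FACTORS:
        raise KeyError(f"unknown scattering type {symbol!r}")
    return key


def xray_form_factor(symbol: str, s_sq) -> np.ndarray:
    """f(s) for element ``symbol`` at squared reciprocal distance s^2 (1/A^2)."""
    a, b, c = XRAY_FORM_FACTORS[resolve_scattering_type(symbol)]
    s_sq = np.asarray(s_sq, dtype=float)
    out = np.full(s_sq.shape, c)
    for ai, bi in zip(a, b):
        out += ai * np.exp(-bi * s_sq / 4.0)
    return out


def scattering_value(symbol: str, s_sq, mode: str = "xray") -> np.ndarray:
    """Form factor (xray) or constant scattering length (neutron)."""
    if mode == "xray":
        return xray_form_factor(symbol, s_sq)
    if mode == "neutron":
        key = symbol.strip().upper()
        if key not in NEUTRON_LENGTHS:
            raise KeyError(f"no neutron scattering length for {symbol!r}")
        return np.full(np.asarray(s_sq, dtype=float).shape, NEUTRON_LENGTHS[key])
    raise ValueError(f"unknown scattering mode {mode!r}")
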