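"""Reflection-data I/O, merging and Wilson statistics.

Supported text formats: SHELX HKL (fixed 3I4,2F8 with the 0 0 0 terminator),
CNS-style free text (``INDE h k l FOBS= ... SIGMA= ... [TEST= n]``) and a
plain column layout ``h k l value sigma [flag]``.  Binary formats are out of
scope; a practitioner exports to one of these.

Beyond parsing this module answers the questions a model-vs-data run needs
before any fitting: are these amplitudes or intensities (acentric Wilson
moment test), which reflections are cross-validation (free) reflections under
the common flag conventions, how complete is the data per resolution shell,
what is the Wilson B, and which reflections are statistical outliers under
the Wilson distribution (an expected-extreme-value test; flagged reflections
are excluded from scaling but reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import erfc

from .core import CrystalFrame
from .scattering import xray_form_factor

__all__ = [
    "ReflectionSet",
    "read_reflections",
    "guess_data_kind",
    "to_amplitudes",
    "merge_to_asu",
    "extract_free_flags",
    "completeness_shells",
    "wilson_b",
    "wilson_outliers",
    "assign_shells",
]


@dataclass
class ReflectionSet:
    """Unique Miller indices with amplitudes or intensities.

    ``value`` is on an arbitrary experimental scale.  ``free_flag`` is a
    boolean test-set mask or None when no cross-validation flags exist.
    """

    miller: np.ndarray               # (N, 3) int, canonical under the frame
    value: np.ndarray                # (N,)
    sigma: np.ndarray                # (N,) >= 0
    kind: str                        # 'amplitude' | 'intensity'
    frame: CrystalFrame
    free_flag: np.ndarray | None = None
    anomalous: bool = False
    _centric: np.ndarray | None = field(default=None, repr=False)
    _epsilon: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.value)

    @property
    def d(self) -> np.ndarray:
        return self.frame.d_spacing(self.miller)

    @property
    def centric(self) -> np.ndarray:
        if self._centric is None:
            c, e = self.frame.centric_and_epsilon(self.miller)
            self._centric, self._epsilon = c, e
        return self._centric

    @property
    def epsilon(self) -> np.ndarray:
        if self._epsilon is None:
            _ = self.centric
        return self._epsilon

    @property
    def intensity(self) -> np.ndarray:
        return self.value**2 if self.kind == "amplitude" else self.value

    def select(self, mask: np.ndarray) -> "ReflectionSet":
        return replace(
            self,
            miller=self.miller[mask],
            value=self.value[mask],
            sigma=self.sigma[mask],
            free_flag=None if self.free_flag is None else self.free_flag[mask],
            _centric=None if self._centric is None else self._centric[mask],
            _epsilon=None if self._epsilon is None else self._epsilon[mask],
        )


# --------------------------------------------------------------------------
# reading
# --------------------------------------------------------------------------


def _read_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    s = str(source)
    if "\n" not in s and len(s) < 4096:
        with open(s) as fh:
            return fh.read()
    return s


def _sniff_format(lines: list[str]) -> str:
    for ln in lines[:50]:
        if ln.strip().upper().startswith(("INDE", "NREF", "DECL")):
            return "cns"
    for ln in lines[:50]:
        if not ln.strip():
            continue
        if len(ln.rstrip()) >= 28:
            try:
                int(ln[0:4]); int(ln[4:8]); int(ln[8:12])
                float(ln[12:20]); float(ln[20:28])
                return "shelx"
            except ValueError:
                pass
        return "columns"
    return "columns"


def read_reflections(source, fmt: str = "auto"):
    """Read raw reflections; returns (miller (N,3) int, value, sigma, flag).

    ``flag`` is an integer array or None.  Raises ValueError with the line
    number on unparseable content and on empty input.
    """
    text = _read_text(source)
    lines = text.splitlines()
    if fmt == "auto":
        fmt = _sniff_format(lines)

    hkl, val, sig, flg = [], [], [], []
    have_flag = False

    if fmt == "shelx":
        for i, ln in enumerate(lines, start=1):
            if not ln.strip():
                continue
            try:
                h, k, l = int(ln[0:4]), int(ln[4:8]), int(ln[8:12])
                if (h, k, l) == (0, 0, 0):
                    break  # terminator
                v, s = float(ln[12:20]), float(ln[20:28])
                f = ln[28:32].strip()
            except (ValueError, IndexError) as exc:
                raise ValueError(f"unparseable SHELX line {i}: {ln!r}") from exc
            hkl.append((h, k, l)); val.append(v); sig.append(s)
            if f:
                have_flag = True
                flg.append(int(f))
            else:
                flg.append(0)
    elif fmt == "cns":
        for i, ln in enumerate(lines, start=1):
            toks = ln.split()
            if not toks or toks[0].upper() not in ("INDE", "INDEX"):
                continue
            try:
                h, k, l = int(toks[1]), int(toks[2]), int(toks[3])
                kv = {}
                j = 4
                while j < len(toks):
                    key = toks[j].rstrip("=").upper()
                    if toks[j].endswith("="):
                        kv[key] = float(toks[j + 1]); j += 2
                    else:
                        kv[key] = float(toks[j + 1]); j += 2
                v = kv.get("FOBS", kv.get("IOBS"))
                s = kv.get("SIGMA", kv.get("SIGI", 0.0))
                if v is None:
                    raise ValueError("no FOBS/IOBS")
            except (ValueError, IndexError) as exc:
                raise ValueError(f"unparseable CNS line {i}: {ln!r}") from exc
            hkl.append((h, k, l)); val.append(v); sig.append(s)
            if "TEST" in kv:
                have_flag = True
                flg.append(int(kv["TEST"]))
            else:
                flg.append(0)
    elif fmt == "columns":
        for i, ln in enumerate(lines, start=1):
            if not ln.strip() or ln.lstrip().startswith("#"):
                continue
            toks = ln.split()
            if len(toks) < 5:
                raise ValueError(f"unparseable column line {i}: {ln!r}")
            try:
                h, k, l = int(toks[0]), int(toks[1]), int(toks[2])
                v, s = float(toks[3]), float(toks[4])
            except ValueError as exc:
                raise ValueError(f"unparseable column line {i}: {ln!r}") from exc
            hkl.append((h, k, l)); val.append(v); sig.append(s)
            if len(toks) >= 6:
                have_flag = True
                flg.append(int(float(toks[5])))
            else:
                flg.append(0)
    else:
        raise ValueError(f"unknown reflection format {fmt!r}")

    if not hkl:
        raise ValueError("no reflections found in input")
    miller = np.array(hkl, dtype=np.int64)
    return (miller, np.array(val), np.array(sig),
            np.array(flg) if have_flag else None)


# --------------------------------------------------------------------------
# amplitude vs intensity
# --------------------------------------------------------------------------


def guess_data_kind(miller, values, frame: CrystalFrame, n_bins: int = 10):
    """Decide amplitude vs intensity from acentric Wilson moments.

    The acentric second moment <v^2>/<v>^2, computed on values normalized per
    resolution bin, is 4/pi for Wilson amplitudes and 2 for exponential
    intensities; the call picks the nearer expectation.  Any negative value
    forces 'intensity'.  Returns (kind, confidence, moment_ratio).
    """
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        return "intensity", "high", float("nan")
    centric, _ = frame.centric_and_epsilon(np.asarray(miller))
    v = values[~centric]
    d = frame.d_spacing(np.asarray(miller)[~centric])
    if len(v) < 200:
        return "amplitude", "low", float("nan")
    shells = assign_shells(d, min(n_bins, max(1, len(v) // 100)))
    ratios, weights = [], []
    for sh in np.unique(shells):
        x = v[shells == sh]
        m1 = x.mean()
        if m1 <= 0 or len(x) < 20:
            continue
        ratios.append((x**2).mean() / m1**2)
        weights.append(len(x))
    if not ratios:
        return "amplitude", "low", float("nan")
    ratio = float(np.average(ratios, weights=weights))
    kind = "amplitude" if abs(ratio - 4 / np.pi) < abs(ratio - 2.0) else "intensity"
    return kind, "high", ratio


def to_amplitudes(rs: ReflectionSet) -> ReflectionSet:
    """Convert intensities to amplitudes: F = sqrt(max(I,0)); sigma_F by
    first-order propagation sigma_I/(2F), or sqrt(sigma_I) where F = 0."""
    if rs.kind == "amplitude":
        return rs
    intensity = rs.value
    f = np.sqrt(np.clip(intensity, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        sig = np.where(f > 0, rs.sigma / (2 * np.maximum(f, 1e-30)),
                       np.sqrt(np.abs(rs.sigma)))
    return replace(rs, value=f, sigma=sig, kind="amplitude")


# --------------------------------------------------------------------------
# merging
# --------------------------------------------------------------------------


def merge_to_asu(miller, value, sigma, frame: CrystalFrame,
                 kind: str = "amplitude", anomalous: bool = False,
                 free_flag=None):
    """Map to canonical ASU indices and average exact duplicates.

    Returns ``(ReflectionSet, n_redundant)`` where ``n_redundant`` counts
    input rows beyond the first per unique index.
    """
    miller = np.asarray(miller, dtype=np.int64)
    canon, _, _ = frame.map_to_asu(miller, anomalous=anomalous)
    order = np.lexsort((canon[:, 2], canon[:, 1], canon[:, 0]))
    canon = canon[order]
    value = np.asarray(value, dtype=float)[order]
    sigma = np.asarray(sigma, dtype=float)[order]
    if free_flag is not None:
        free_flag = np.asarray(free_flag)[order]
    uniq, first, counts = np.unique(
        canon, axis=0, return_index=True, return_counts=True
    )
    grp = np.repeat(np.arange(len(uniq)), counts)
    v_sum = np.bincount(grp, weights=value, minlength=len(uniq))
    s_sum = np.bincount(grp, weights=sigma**2, minlength=len(uniq))
    v_mean = v_sum / counts
    s_mean = np.sqrt(s_sum) / counts
    ff = None
    if free_flag is not None:
        ff = free_flag[first]
    n_redundant = int(len(canon) - len(uniq))
    rs = ReflectionSet(miller=uniq, value=v_mean, sigma=s_mean, kind=kind,
                       frame=frame, free_flag=ff, anomalous=anomalous)
    return rs, n_redundant


# --------------------------------------------------------------------------
# free flags
# --------------------------------------------------------------------------


def extract_free_flags(flags):
    """Interpret an integer flag column as a test-set mask.

    Conventions: a 0/1 column whose minority fraction is <= 25% marks the
    minority as the test set; an integer column 0..N (N >= 5) marks value 0
    as the test set.  A constant column is treated as absent (with a
    warning).  Returns (mask or None, convention label).
    """
    import warnings

    if flags is None:
        return None, "absent"
    flags = np.asarray(flags).astype(int)
    uniq = np.unique(flags)
    if len(uniq) == 1:
        warnings.warn("free-flag column is constant; treating as absent")
        return None, "absent"
    if set(uniq) <= {0, 1}:
        frac1 = np.mean(flags == 1)
        minority = 1 if frac1 <= 0.5 else 0
        if min(frac1, 1 - frac1) <= 0.25:
            return flags == minority, "binary-minority"
        return flags == 0, "binary-zero"
    if uniq.max() >= 5:
        return flags == 0, "multi-bin-zero"
    return flags == uniq.min(), "min-value"


# --------------------------------------------------------------------------
# shells and completeness
# --------------------------------------------------------------------------


def assign_shells(d, n_shells: int) -> np.ndarray:
    """Near-equal-count resolution shells (0 = lowest resolution/largest d).

    Boundaries sit at d quantiles so reflections with identical d always
    share a shell.
    """
    d = np.asarray(d, dtype=float)
    if len(d) == 0:
        return np.zeros(0, dtype=int)
    edges = np.quantile(-d, np.arange(1, n_shells) / n_shells)
    return np.searchsorted(edges, -d, side="left")


def completeness_shells(rs: ReflectionSet, n_shells: int = 10) -> pd.DataFrame:
    """Per-shell completeness: observed unique vs all possible ASU indices.

    Possible indices are enumerated by brute force over the index box,
    excluding systematic absences.
    """
    d = rs.d
    shells = assign_shells(d, n_shells)
    labels = [sh for sh in range(n_shells) if (shells == sh).any()]
    # shell edges at midpoints between adjacent shells so that every possible
    # index falls in exactly one shell
    mins = np.array([d[shells == sh].min() for sh in labels])
    maxs = np.array([d[shells == sh].max() for sh in labels])
    inner_edges = [(mins[i] + maxs[i + 1]) / 2.0 for i in range(len(labels) - 1)]

    possible = rs.frame.unique_reflections(float(d.min()) - 1e-6)
    d_poss = rs.frame.d_spacing(possible)
    # bin index: number of inner edges greater than d
    poss_bin = np.searchsorted(-np.asarray(inner_edges), -d_poss, side="right")

    rows = []
    for i, sh in enumerate(labels):
        mask = shells == sh
        n_obs = int(mask.sum())
        n_poss = int(np.sum(poss_bin == i))
        rows.append({
            "shell": sh, "d_max": maxs[i], "d_min": mins[i],
            "n_observed": n_obs, "n_possible": n_poss,
            "completeness": min(n_obs / n_poss, 1.0) if n_poss else np.nan,
            "mean_value": float(rs.value[mask].mean()),
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Wilson statistics
# --------------------------------------------------------------------------


def wilson_b(rs: ReflectionSet, scattering_types: list[str],
             d_cut: float = 4.0, n_shells: int = 10):
    """Wilson-plot B estimate from the resolution falloff of mean intensity.

    Straight-line fit of ln(<I>_shell / (eps * sum_i f_i^2(s))) against
    s^2/2 over d < ``d_cut``; the slope is -B.  Returns (B, scale) or
    (None, None) when the data do not extend beyond ``d_cut``.
    """
    d = rs.d
    sel = d < d_cut
    if sel.sum() < 30:
        return None, None
    intensity = rs.intensity[sel]
    eps = rs.epsilon[sel].astype(float)
    d_sel = d[sel]
    shells = assign_shells(d_sel, n_shells)
    xs, ys = [], []
    for sh in np.unique(shells):
        m = shells == sh
        s_sq = float(np.mean(1.0 / d_sel[m] ** 2))
        f_sq = sum(
            float(np.mean(xray_form_factor(t, s_sq) ** 2))
            for t in scattering_types
        )
        mean_i = float(np.mean(intensity[m] / eps[m]))
        if mean_i <= 0 or f_sq <= 0:
            continue
        xs.append(s_sq / 2.0)
        ys.append(np.log(mean_i / f_sq))
    if len(xs) < 3:
        return None, None
    slope, intercept = np.polyfit(xs, ys, 1)
    return float(-slope), float(np.exp(intercept))


def wilson_outliers(rs: ReflectionSet, n_shells: int = 10,
                    threshold: float = 0.01) -> np.ndarray:
    """Expected-extreme-value outlier test on normalized intensities.

    z = I / (eps * S_shell) with S the shell mean of I/eps.  A reflection is
    an outlier when the Wilson tail probability of seeing a value at least as
    large, multiplied by the number of reflections, falls below ``threshold``
    (acentric tail exp(-z); centric tail erfc(sqrt(z/2)))."""
    n = len(rs)
    if n == 0:
        return np.zeros(0, dtype=bool)
    intensity = rs.intensity
    eps = rs.epsilon.astype(float)
    centric = rs.centric
    shells = assign_shells(rs.d, min(n_shells, max(1, n // 50)))
    z = np.zeros(n)
    for sh in np.unique(shells):
        m = shells == sh
        s_mean = np.mean(intensity[m] / eps[m])
        if s_mean <= 0:
            continue
        z[m] = intensity[m] / (eps[m] * s_mean)
    p = np.where(centric, erfc(np.sqrt(np.clip(z, 0, None) / 2.0)), np.exp(-z))
    return p * n < threshold
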