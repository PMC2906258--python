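"""Unit-cell and space-group mathematics.

Everything geometric flows through :class:`CrystalFrame`: fractional/Cartesian
conversion (PDB orthogonalization convention: *a* along x, *b* in the xy
plane), d-spacings from the reciprocal metric, mapping of Miller indices to a
canonical asymmetric-unit representative, centric/epsilon classification and
systematic-absence tests.

Symmetry operators come from a built-in table of common space groups keyed by
Hermann-Mauguin symbol (compact or spaced form), or can be supplied explicitly
(e.g. parsed from REMARK 290).  The table deliberately does not try to cover
all 230 groups; it covers the groups that occur in the synthetic fixtures and
the large majority of macromolecular depositions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

__all__ = [
    "CrystalFrame",
    "parse_triplet",
    "triplet_of",
    "space_group_operators",
    "B_TO_U",
    "u_iso_from_b",
    "b_from_u_iso",
    "is_positive_definite",
]

# B = 8 pi^2 u_iso
B_TO_U = 1.0 / (8.0 * np.pi**2)


# --------------------------------------------------------------------------
# symmetry-operator triplets
# --------------------------------------------------------------------------

#: Hermann-Mauguin symbol -> tuple of "x,y,z"-style operator triplets.
#: Cross-checked operator-by-operator against an independent symmetry library
#: in the test suite.
SPACE_GROUP_TABLE: dict[str, tuple[str, ...]] = {
    "P1": ("x,y,z",),
    "P-1": ("x,y,z", "-x,-y,-z"),
    "P2": ("x,y,z", "-x,y,-z"),
    "P21": ("x,y,z", "-x,y+1/2,-z"),
    "C2": ("x,y,z", "-x,y,-z", "x+1/2,y+1/2,z", "-x+1/2,y+1/2,-z"),
    "P222": ("x,y,z", "-x,-y,z", "x,-y,-z", "-x,y,-z"),
    "P2221": ("x,y,z", "-x,-y,z+1/2", "x,-y,-z", "-x,y,-z+1/2"),
    "P21212": ("x,y,z", "-x,-y,z", "x+1/2,-y+1/2,-z", "-x+1/2,y+1/2,-z"),
    "P212121": (
        "x,y,z",
        "-x+1/2,-y,z+1/2",
        "x+1/2,-y+1/2,-z",
        "-x,y+1/2,-z+1/2",
    ),
    "C2221": (
        "x,y,z",
        "-x,-y,z+1/2",
        "x,-y,-z",
        "-x,y,-z+1/2",
        "x+1/2,y+1/2,z",
        "-x+1/2,-y+1/2,z+1/2",
        "x+1/2,-y+1/2,-z",
        "-x+1/2,y+1/2,-z+1/2",
    ),
    "P4": ("x,y,z", "-y,x,z", "-x,-y,z", "y,-x,z"),
    "P41": ("x,y,z", "-y,x,z+1/4", "-x,-y,z+1/2", "y,-x,z+3/4"),
    "P43": ("x,y,z", "-y,x,z+3/4", "-x,-y,z+1/2", "y,-x,z+1/4"),
    "P3": ("x,y,z", "-y,x-y,z", "-x+y,-x,z"),
    "P31": ("x,y,z", "-y,x-y,z+1/3", "-x+y,-x,z+2/3"),
    "P32": ("x,y,z", "-y,x-y,z+2/3", "-x+y,-x,z+1/3"),
    "P6": ("x,y,z", "x-y,x,z", "-y,x-y,z", "-x,-y,z", "-x+y,-x,z", "y,-x+y,z"),
    "P61": (
        "x,y,z",
        "x-y,x,z+1/6",
        "-y,x-y,z+1/3",
        "-x,-y,z+1/2",
        "-x+y,-x,z+2/3",
        "y,-x+y,z+5/6",
    ),
    "P23": (
        "x,y,z", "-x,-y,z", "x,-y,-z", "-x,y,-z",
        "z,x,y", "z,-x,-y", "-z,x,-y", "-z,-x,y",
        "y,z,x", "-y,z,-x", "-y,-z,x", "y,-z,-x",
    ),
    "I23": (
        "x,y,z", "-x,-y,z", "x,-y,-z", "-x,y,-z",
        "z,x,y", "z,-x,-y", "-z,x,-y", "-z,-x,y",
        "y,z,x", "-y,z,-x", "-y,-z,x", "y,-z,-x",
        "x+1/2,y+1/2,z+1/2", "-x+1/2,-y+1/2,z+1/2",
        "x+1/2,-y+1/2,-z+1/2", "-x+1/2,y+1/2,-z+1/2",
        "z+1/2,x+1/2,y+1/2", "z+1/2,-x+1/2,-y+1/2",
        "-z+1/2,x+1/2,-y+1/2", "-z+1/2,-x+1/2,y+1/2",
        "y+1/2,z+1/2,x+1/2", "-y+1/2,z+1/2,-x+1/2",
        "-y+1/2,-z+1/2,x+1/2", "y+1/2,-z+1/2,-x+1/2",
    ),
}


def _normalize_symbol(symbol: str) -> str:
    s = symbol.strip().replace(" ", "").upper()
    # 'P1211' / 'P121' style full monoclinic symbols -> short symbol
    aliases = {
        "P121": "P2", "P1211": "P21", "C121": "C2",
        "P411": "P4", "P312": None,  # not covered
    }
    if s in aliases and aliases[s]:
        return aliases[s]
    return s


def parse_triplet(triplet: str) -> tuple[np.ndarray, np.ndarray]:
    """Parse an 'x,y+1/2,-z' operator into (3x3 int rotation, translation).

    Translations are returned as floats in [0, 1).
    """
    rot = np.zeros((3, 3), dtype=np.int64)
    trans = np.zeros(3)
    axes = {"X": 0, "Y": 1, "Z": 2}
    parts = triplet.upper().replace(" ", "").split(",")
    if len(parts) != 3:
        raise ValueError(f"malformed symmetry triplet: {triplet!r}")
    for i, part in enumerate(parts):
        # tokenize into signed terms
        terms: list[str] = []
        cur = ""
        for ch in part:
            if ch in "+-" and cur:
                terms.append(cur)
                cur = ch
            else:
                cur += ch
        if cur:
            terms.append(cur)
        for term in terms:
            sign = -1 if term.startswith("-") else 1
            body = term.lstrip("+-")
            if not body:
                raise ValueError(f"malformed term in triplet: {triplet!r}")
            if body in axes:
                rot[i, axes[body]] += sign
            else:
                trans[i] += sign * float(Fraction(body))
    return rot, trans % 1.0


def triplet_of(rot: np.ndarray, trans: np.ndarray) -> str:
    """Inverse of :func:`parse_triplet` (canonical ordering x,y,z then shift)."""
    names = "xyz"
    out = []
    for i in range(3):
        s = ""
        for j in range(3):
            c = int(rot[i, j])
            if c == 0:
                continue
            s += ("-" if c < 0 else ("+" if s else "")) + names[j]
        t = Fraction(trans[i]).limit_denominator(12) % 1
        if t:
            s += f"+{t}"
        out.append(s)
    return ",".join(out)


def space_group_operators(symbol: str) -> list[tuple[np.ndarray, np.ndarray]]:
    key = _normalize_symbol(symbol)
    if key not in SPACE_GROUP_TABLE:
        raise ValueError(
            f"space group {symbol!r} not in built-in table; "
            "supply operators explicitly (e.g. from REMARK 290)"
        )
    return [parse_triplet(t) for t in SPACE_GROUP_TABLE[key]]


# --------------------------------------------------------------------------
# crystal frame
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CrystalFrame:
    """Unit cell plus space-group operators.

    Parameters
    ----------
    cell : (a, b, c, alpha, beta, gamma) with lengths in Angstrom, angles in
        degrees.
    spacegroup : Hermann-Mauguin symbol ('P 21 21 21' or 'P212121').
    symops : optional explicit operator list [(R, t), ...]; when given it
        overrides the symbol lookup (used for REMARK 290 input).
    """

    cell: tuple[float, float, float, float, float, float]
    spacegroup: str = "P1"
    symops: tuple[tuple[np.ndarray, np.ndarray], ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        a, b, c, al, be, ga = self.cell
        if min(a, b, c) <= 0:
            raise ValueError("cell lengths must be positive")
        if not all(0.0 < x < 180.0 for x in (al, be, ga)):
            raise ValueError("cell angles must lie in (0, 180) degrees")
        if self.symops is None:
            object.__setattr__(
                self, "symops", tuple(space_group_operators(self.spacegroup))
            )
        else:
            object.__setattr__(
                self,
                "symops",
                tuple((np.asarray(r, dtype=np.int64), np.asarray(t, dtype=float))
                      for r, t in self.symops),
            )
        if self.volume <= 0:
            raise ValueError("degenerate cell (volume <= 0)")
        # identity must be present
        if not any(
            np.array_equal(r, np.eye(3, dtype=np.int64)) and np.allclose(t % 1, 0)
            for r, t in self.symops
        ):
            raise ValueError("symmetry operator set lacks the identity")

    # -- metric ------------------------------------------------------------

    @property
    def orthogonalization(self) -> np.ndarray:
        """Orthogonalization matrix A with x_cart = A @ x_frac (PDB convention)."""
        a, b, c, al, be, ga = self.cell
        ca, cb, cg = np.cos(np.radians([al, be, ga]))
        sg = np.sin(np.radians(ga))
        v = np.sqrt(max(1.0 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg, 0.0))
        return np.array(
            [
                [a, b * cg, c * cb],
                [0.0, b * sg, c * (ca - cb * cg) / sg],
                [0.0, 0.0, c * v / sg],
            ]
        )

    @property
    def fractionalization(self) -> np.ndarray:
        return np.linalg.inv(self.orthogonalization)

    @property
    def volume(self) -> float:
        return float(np.linalg.det(self.orthogonalization))

    @property
    def recip_matrix(self) -> np.ndarray:
        """B with s_cart = B @ h; columns are the reciprocal basis vectors (1/A)."""
        return self.fractionalization.T

    @property
    def metric(self) -> np.ndarray:
        """Real-space metric tensor G = A^T A."""
        A = self.orthogonalization
        return A.T @ A

    def frac_to_cart(self, x_frac) -> np.ndarray:
        return np.asarray(x_frac, dtype=float) @ self.orthogonalization.T

    def cart_to_frac(self, x_cart) -> np.ndarray:
        return np.asarray(x_cart, dtype=float) @ self.fractionalization.T

    def s_vectors(self, hkl) -> np.ndarray:
        """Cartesian reciprocal vectors (1/A) for Miller indices, shape (..., 3)."""
        return np.asarray(hkl, dtype=float) @ self.recip_matrix.T

    def d_spacing(self, hkl) -> np.ndarray | float:
        """Resolution d = 1/|s| in Angstrom for one or many Miller indices."""
        h = np.atleast_2d(np.asarray(hkl, dtype=float))
        if np.any(np.all(h == 0, axis=1)):
            raise ValueError("d-spacing undefined for (0,0,0)")
        s = np.linalg.norm(self.s_vectors(h), axis=-1)
        d = 1.0 / s
        return float(d[0]) if np.ndim(hkl) == 1 else d

    # -- point group -------------------------------------------------------

    @property
    def rotations(self) -> np.ndarray:
        """Unique rotation parts, shape (m, 3, 3)."""
        seen, out = set(), []
        for r, _ in self.symops:
            key = tuple(r.ravel())
            if key not in seen:
                seen.add(key)
                out.append(r)
        return np.stack(out)

    def cartesian_rotations(self) -> np.ndarray:
        """Rotation parts expressed in the Cartesian frame (orthonormal)."""
        A = self.orthogonalization
        Ai = self.fractionalization
        return np.einsum("ij,njk,kl->nil", A, self.rotations.astype(float), Ai)

    # -- ASU mapping and reflection classes --------------------------------

    def _images(self, hkl, anomalous: bool) -> np.ndarray:
        """All symmetry images h @ R (and Friedel mates), shape (n_img, N, 3)."""
        h = np.atleast_2d(np.asarray(hkl, dtype=np.int64))
        rots = self.rotations
        img = np.einsum("nk,mkj->mnj", h, rots)
        if not anomalous:
            img = np.concatenate([img, -img], axis=0)
        return img

    def map_to_asu(self, hkl, anomalous: bool = False):
        """Map Miller indices to the canonical ASU representative.

        The canonical choice is the lexicographically greatest equivalent
        (Friedel mate folded in unless ``anomalous``), which is deterministic
        and order-independent.

        Returns ``(h_canonical, op_index, friedel)``; for the Friedel-derived
        images ``op_index`` refers to the rotation applied before negation.
        """
        single = np.ndim(hkl) == 1
        img = self._images(hkl, anomalous)  # (n_img, N, 3)
        n_rot = self.rotations.shape[0]
        # encode for lexicographic argmax; |h| < 2**20 comfortably
        enc = (
            (img[..., 0].astype(np.int64) << 42)
            + (img[..., 1].astype(np.int64) << 21)
            + img[..., 2].astype(np.int64)
        )
        best = np.argmax(enc, axis=0)  # (N,)
        N = img.shape[1]
        canon = img[best, np.arange(N), :]
        friedel = best >= n_rot
        op_index = np.where(friedel, best - n_rot, best)
        if single:
            return canon[0], int(op_index[0]), bool(friedel[0])
        return canon, op_index, friedel

    def centric_and_epsilon(self, hkl):
        """(centric flags, epsilon multiplicities) for one or many indices."""
        single = np.ndim(hkl) == 1
        h = np.atleast_2d(np.asarray(hkl, dtype=np.int64))
        img = np.einsum("nk,mkj->mnj", h, self.rotations)
        centric = np.any(np.all(img == -h[None, :, :], axis=-1), axis=0)
        epsilon = np.sum(np.all(img == h[None, :, :], axis=-1), axis=0)
        if single:
            return bool(centric[0]), int(epsilon[0])
        return centric, epsilon.astype(np.int64)

    def is_absent(self, hkl):
        """Systematic-absence test: some op fixes h but shifts its phase."""
        single = np.ndim(hkl) == 1
        h = np.atleast_2d(np.asarray(hkl, dtype=np.int64))
        absent = np.zeros(h.shape[0], dtype=bool)
        for r, t in self.symops:
            img = h @ r
            fixes = np.all(img == h, axis=1)
            phase = h @ t
            shifts = np.abs(phase - np.round(phase)) > 1e-6
            absent |= fixes & shifts
        if single:
            return bool(absent[0])
        return absent

    def unique_reflections(self, d_min: float, d_max: float | None = None) -> np.ndarray:
        """Brute-force enumeration of present, ASU-unique indices with
        d_min <= d (< d_max), excluding (0,0,0) and systematic absences."""
        B = self.recip_matrix
        # bounding box: |h_i| <= a_i* ... use row norms of inverse
        lim = np.ceil(np.linalg.norm(self.orthogonalization, axis=1) / d_min).astype(int)
        hs = np.stack(
            np.meshgrid(
                np.arange(-lim[0], lim[0] + 1),
                np.arange(-lim[1], lim[1] + 1),
                np.arange(-lim[2], lim[2] + 1),
                indexing="ij",
            ),
            axis=-1,
        ).reshape(-1, 3)
        hs = hs[np.any(hs != 0, axis=1)]
        s = np.linalg.norm(hs @ B.T, axis=1)
        d = 1.0 / s
        keep = d >= d_min - 1e-9
        if d_max is not None:
            keep &= d < d_max + 1e-9
        hs = hs[keep]
        canon, _, _ = self.map_to_asu(hs)
        uniq = np.unique(canon, axis=0)
        uniq = uniq[~self.is_absent(uniq)]
        return uniq


# --------------------------------------------------------------------------
# ADP helpers
# --------------------------------------------------------------------------


def u_iso_from_b(b_iso):
    """Convert isotropic B (A^2) to u_iso (A^2): u = B / (8 pi^2)."""
    return np.asarray(b_iso, dtype=float) * B_TO_U


def b_from_u_iso(u_iso):
    return np.asarray(u_iso, dtype=float) / B_TO_U


def is_positive_definite(u_cart: np.ndarray, tol: float = 1e-9) -> bool:
    """True iff the symmetric ADP tensor has smallest eigenvalue > tol (A^2).

    The tolerance deliberately rejects exact-zero ADPs (e.g. hydrogen B=0
    depositions) as nonphysical.
    """
    u = np.asarray(u_cart, dtype=float)
    if u.shape != (3, 3):
        raise ValueError("ADP tensor must be 3x3")
    if not np.allclose(u, u.T, atol=1e-8):
        raise ValueError("ADP tensor must be symmetric")
    return bool(np.linalg.eigvalsh(u)[0] > tol)
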