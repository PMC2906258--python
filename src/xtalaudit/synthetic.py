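"""Synthetic crystals and simulated observations with known ground truth.

Every fixture is a toy crystal (random heavy atoms, optionally with attached
hydrogens, in a chosen space group) plus amplitudes simulated through the
production bulk-solvent/scaling model, optionally twin-mixed, with
multiplicative Gaussian noise and a seeded 5% free set.  The generating
parameters travel with the data as a :class:`GroundTruth` manifest so that
recovery tests (k_sol, B_sol, twin fraction, ADP convention, Wilson B) can
close the loop.

``degrade`` applies exactly one documented corruption per call — the
pathologies that make deposited statistics irreproducible in the wild —
and records it in the manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace

import numpy as np

from .core import CrystalFrame, u_iso_from_b
from .fitting import ScaleModel, f_model_amplitudes, u_from_tls
from .pdbio import AtomRecord, ModelEnsemble, TLSGroup, strip_hydrogens
from .reflections import ReflectionSet
from .sfcalc import f_mask, fcalc_direct, solvent_mask

__all__ = [
    "GroundTruth",
    "make_toy_crystal",
    "simulate_fobs",
    "degrade",
    "standard_fixture",
    "tls_remark_lines",
]


@dataclass
class GroundTruth:
    k_sol: float = 0.0
    b_sol: float = 0.0
    u_cryst: list = field(default_factory=lambda: np.zeros((3, 3)).tolist())
    twin_law: list | None = None
    twin_fraction: float = 0.0
    noise: float = 0.0
    h_fraction: float = 0.0
    adp_convention: str = "total"
    mode: str = "xray"
    seed: int = 0
    degradations: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


# --------------------------------------------------------------------------
# model generation
# --------------------------------------------------------------------------

MIN_SEPARATION = 1.2  # A between heavy atoms
H_BOND_LENGTH = 1.0   # A


def make_toy_crystal(n_atoms: int, spacegroup: str, cell,
                     b_range=(10.0, 30.0), h_fraction: float = 0.0,
                     seed: int = 0,
                     elements=("C", "C", "C", "N", "O", "S")) -> ModelEnsemble:
    """Random toy crystal: heavy atoms with minimum separation, optional
    hydrogens riding 1 A from a heavy parent.  Deterministic under seed."""
    rng = np.random.default_rng(seed)
    frame = CrystalFrame(tuple(cell), spacegroup=spacegroup)
    placed_frac: list[np.ndarray] = []
    attempts = 0
    while len(placed_frac) < n_atoms:
        attempts += 1
        if attempts > 200 * n_atoms:
            raise RuntimeError("cannot place atoms with required separation; "
                               "cell too small")
        x = rng.uniform(0.0, 1.0, 3)
        # separation against all placed atoms and all their symmetry images,
        # minimum-image convention
        ok = True
        for rot, trans in frame.symops:
            for y in placed_frac:
                dy = (x - ((y @ rot.T) + trans)) % 1.0
                dy = np.where(dy > 0.5, dy - 1.0, dy)
                if np.linalg.norm(frame.frac_to_cart(dy)) < MIN_SEPARATION:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            placed_frac.append(x)

    atoms: list[AtomRecord] = []
    for i, xf in enumerate(placed_frac):
        el = str(rng.choice(elements))
        atoms.append(AtomRecord(
            serial=i + 1, name=el, altloc="", resname="ALA", chain="A",
            resseq=i + 1, icode="", xyz=frame.frac_to_cart(xf),
            occupancy=1.0, b_iso=float(rng.uniform(*b_range)),
            u_aniso=None, element=el, scattering_type=el,
        ))
    n_h = int(round(n_atoms * h_fraction))
    parents = rng.choice(n_atoms, size=n_h, replace=False) if n_h else []

    def min_dist_to_others(xyz, skip_serial):
        best = np.inf
        xf = frame.cart_to_frac(xyz)
        for rot, trans in frame.symops:
            for other in atoms:
                if other.serial == skip_serial:
                    continue
                yf = (frame.cart_to_frac(other.xyz) @ rot.T) + trans
                dy = (xf - yf) % 1.0
                dy = np.where(dy > 0.5, dy - 1.0, dy)
                best = min(best, float(np.linalg.norm(frame.frac_to_cart(dy))))
        return best

    for j, pi in enumerate(parents):
        parent = atoms[pi]
        # keep the riding H at least 1 A from every atom but its parent
        for _ in range(100):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            xyz = parent.xyz + H_BOND_LENGTH * direction
            if min_dist_to_others(xyz, parent.serial) >= 1.0:
                break
        atoms.append(AtomRecord(
            serial=n_atoms + j + 1, name="H", altloc="",
            resname=parent.resname, chain=parent.chain,
            resseq=parent.resseq, icode="",
            xyz=xyz,
            occupancy=1.0, b_iso=parent.b_iso, u_aniso=None,
            element="H", scattering_type="H",
        ))
    return ModelEnsemble(models=[atoms], frame=frame)


# --------------------------------------------------------------------------
# observation simulation
# --------------------------------------------------------------------------


def simulate_fobs(ensemble: ModelEnsemble, truth: GroundTruth, d_min: float,
                  free_fraction: float = 0.05,
                  apply_truth_tls: bool = False) -> ReflectionSet:
    """Simulate observed amplitudes from the ensemble and truth parameters.

    F_obs runs through the production F_model path (bulk solvent + scaling),
    then twin mixing on intensities, then multiplicative Gaussian noise
    sigma = noise * |F|.  Free flags are a seeded 5% draw by default.
    """
    from .fitting import apply_tls

    frame = ensemble.frame
    miller = frame.unique_reflections(d_min)
    if len(miller) < 30 and d_min > 5.0:
        raise ValueError("too few reflections at this resolution")
    ens = apply_tls(ensemble) if apply_truth_tls else ensemble
    f_calc = fcalc_direct(ens, miller, mode=truth.mode)
    smask = solvent_mask(ensemble, d_min)
    fmask_vals = f_mask(smask, frame, miller)
    scale = ScaleModel(k_overall=1.0, u_cryst=np.asarray(truth.u_cryst),
                       k_sol=truth.k_sol, b_sol=truth.b_sol)
    f = f_model_amplitudes(scale, f_calc, fmask_vals, frame, miller)

    if truth.twin_law is not None and truth.twin_fraction > 0:
        law = np.asarray(truth.twin_law, dtype=np.int64)
        lookup = {tuple(h): i for i, h in enumerate(miller)}
        canon, _, _ = frame.map_to_asu(miller @ law)
        mate = np.array([lookup.get(tuple(h), -1) for h in canon])
        alpha = truth.twin_fraction
        i_twin = np.where(
            mate >= 0,
            (1 - alpha) * f**2 + alpha * f[mate] ** 2,
            f**2,
        )
        f = np.sqrt(i_twin)

    rng = np.random.default_rng(truth.seed)
    sigma = truth.noise * f
    f_obs = f + rng.normal(0.0, 1.0, len(f)) * sigma
    f_obs = np.clip(f_obs, 0.0, None)
    free = rng.random(len(f)) < free_fraction
    return ReflectionSet(miller=miller, value=f_obs, sigma=sigma,
                         kind="amplitude", frame=frame, free_flag=free)


# --------------------------------------------------------------------------
# degradations
# --------------------------------------------------------------------------


def degrade(obj, mode: str, truth: GroundTruth | None = None, **params):
    """Apply exactly one documented corruption; returns the corrupted object.

    Model modes: drop_anisou, non_pd_adp, zero_h_adp, strip_h, strip_waters,
    negative_occupancy, multi_model_16x.
    Data modes: relabel_I (intensities passed off as amplitudes).
    """
    if truth is not None:
        truth.degradations.append({"mode": mode, **params})

    if mode == "strip_h":
        return strip_hydrogens(obj)
    if mode == "drop_anisou":
        models = [[replace(a, u_aniso=None) for a in m] for m in obj.models]
        return replace(obj, models=models)
    if mode == "non_pd_adp":
        serials = set(params.get("serials", [a.serial for a in obj.models[0][:1]]))
        u_bad = np.diag([0.01, 0.01, -0.01])
        models = [
            [replace(a, u_aniso=u_bad.copy()) if a.serial in serials else a
             for a in m]
            for m in obj.models
        ]
        return replace(obj, models=models)
    if mode == "zero_h_adp":
        models = [
            [replace(a, b_iso=0.0) if a.is_hydrogen else a for a in m]
            for m in obj.models
        ]
        return replace(obj, models=models)
    if mode == "strip_waters":
        models = [[a for a in m if a.resname != "HOH"] for m in obj.models]
        return replace(obj, models=models)
    if mode == "negative_occupancy":
        serials = set(params.get("serials", [obj.models[0][0].serial]))
        models = [
            [replace(a, occupancy=-abs(params.get("occupancy", 0.2)))
             if a.serial in serials else a for a in m]
            for m in obj.models
        ]
        return replace(obj, models=models)
    if mode == "multi_model_16x":
        n = params.get("n_models", 16)
        occ = params.get("occupancy", 0.06)
        base = [replace(a, occupancy=occ) for a in obj.models[0]]
        return replace(obj, models=[[replace(a) for a in base]
                                    for _ in range(n)])
    if mode == "relabel_I":
        # the stored values are really intensities, but the label says
        # amplitude — the classic mislabelling
        return replace(obj, value=obj.value**2, sigma=2 * obj.value * obj.sigma,
                       kind="amplitude")
    raise ValueError(f"unknown degradation mode {mode!r}")


# --------------------------------------------------------------------------
# TLS REMARK text
# --------------------------------------------------------------------------


def tls_remark_lines(groups: list[TLSGroup], dialect: str = "refmac",
                     drop_origin: bool = False) -> list[str]:
    """Render TLS groups as REMARK 3 lines in either dialect (fixture aid)."""
    out = ["REMARK   3  TLS DETAILS", ]
    out.append(f"REMARK   3   NUMBER OF TLS GROUPS  : {len(groups)}")
    for g in groups:
        out.append(f"REMARK   3   TLS GROUP : {g.group_id}")
        if dialect == "refmac":
            out.append("REMARK   3    NUMBER OF COMPONENTS GROUP : "
                       f"{len(g.ranges)}")
            out.append("REMARK   3    COMPONENTS        C SSSEQI TO C SSSEQI")
            for chain, lo, hi in g.ranges:
                out.append(
                    f"REMARK   3    RESIDUE RANGE :   {chain}  {lo:4d}"
                    f"        {chain}  {hi:4d}"
                )
        else:
            sels = " or ".join(
                f"chain {c} and resseq {lo}:{hi}" for c, lo, hi in g.ranges
            )
            out.append(f"REMARK   3    SELECTION: {sels}")
        if not drop_origin:
            out.append(
                "REMARK   3    ORIGIN FOR THE GROUP (A): "
                f"{g.origin[0]:9.4f}{g.origin[1]:9.4f}{g.origin[2]:9.4f}"
            )
        T, L, S = g.T, g.L, g.S
        out.append("REMARK   3    T TENSOR")
        out.append(f"REMARK   3      T11: {T[0,0]:8.4f} T22: {T[1,1]:8.4f}")
        out.append(f"REMARK   3      T33: {T[2,2]:8.4f} T12: {T[0,1]:8.4f}")
        out.append(f"REMARK   3      T13: {T[0,2]:8.4f} T23: {T[1,2]:8.4f}")
        out.append("REMARK   3    L TENSOR")
        out.append(f"REMARK   3      L11: {L[0,0]:8.4f} L22: {L[1,1]:8.4f}")
        out.append(f"REMARK   3      L33: {L[2,2]:8.4f} L12: {L[0,1]:8.4f}")
        out.append(f"REMARK   3      L13: {L[0,2]:8.4f} L23: {L[1,2]:8.4f}")
        out.append("REMARK   3    S TENSOR")
        out.append(f"REMARK   3      S11: {S[0,0]:8.4f} S12: {S[0,1]:8.4f} "
                   f"S13: {S[0,2]:8.4f}")
        out.append(f"REMARK   3      S21: {S[1,0]:8.4f} S22: {S[1,1]:8.4f} "
                   f"S23: {S[1,2]:8.4f}")
        out.append(f"REMARK   3      S31: {S[2,0]:8.4f} S32: {S[2,1]:8.4f} "
                   f"S33: {S[2,2]:8.4f}")
    return out


# --------------------------------------------------------------------------
# the standard fixture
# --------------------------------------------------------------------------

STANDARD_N_HEAVY = 150
STANDARD_H_FRACTION = 0.30
STANDARD_D_MIN = 1.5
STANDARD_NOISE = 0.03
STANDARD_CELL = (18.0, 20.0, 17.0, 90.0, 104.0, 90.0)
STANDARD_SPACEGROUP = "P21"


def standard_fixture(seed: int = 0, *, k_sol: float = 0.35, b_sol: float = 46.0,
                     noise: float = STANDARD_NOISE,
                     h_fraction: float = STANDARD_H_FRACTION,
                     d_min: float = STANDARD_D_MIN):
    """The battery's default crystal: 150 heavy atoms + 30% H in P21 at
    1.5 A with 3% noise and Table-1-scale solvent parameters."""
    ens = make_toy_crystal(STANDARD_N_HEAVY, STANDARD_SPACEGROUP,
                           STANDARD_CELL, h_fraction=h_fraction, seed=seed)
    truth = GroundTruth(k_sol=k_sol, b_sol=b_sol, noise=noise,
                        h_fraction=h_fraction, seed=seed)
    rs = simulate_fobs(ens, truth, d_min)
    return ens, rs, truth
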