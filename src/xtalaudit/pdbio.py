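"""PDB model I/O and model audits.

Parses fixed-column PDB v3 coordinate files: ATOM/HETATM with merged ANISOU,
MODEL/ENDMDL ensembles, CRYST1, REMARK 290 symmetry operators and the
REMARK 3 header block including TLS group records in the two common dialects
(refmac-style RESIDUE RANGE selections and phenix-style free-text
selections).  TLS records in the wild are frequently broken; parsing never
raises on them — malformed groups are returned as classified defects
(category a: selection problems, b: origin problems, c: matrix problems) so
that a survey over many files keeps running.

The audit functions flag the model pathologies that make deposited R factors
irreproducible: non-positive-definite ADPs, zero ADPs, negative occupancies,
unknown scattering types, alternative-conformer occupancy sums away from 1,
under-occupied H/D exchange sites, and per-site occupancy totals across
multi-model ensembles.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

from .core import CrystalFrame, is_positive_definite

__all__ = [
    "AtomRecord",
    "TLSGroup",
    "TlsDefect",
    "HeaderInfo",
    "ModelEnsemble",
    "ModelAudit",
    "parse_pdb",
    "write_pdb",
    "parse_tls_header",
    "audit_model",
    "strip_hydrogens",
    "set_h_adp_from_parent",
]


@dataclass
class AtomRecord:
    serial: int
    name: str
    altloc: str
    resname: str
    chain: str
    resseq: int
    icode: str
    xyz: np.ndarray          # Cartesian, Angstrom
    occupancy: float         # may legitimately be negative or > 1 on input
    b_iso: float             # Angstrom^2; may be 0
    u_aniso: np.ndarray | None  # 3x3 Cartesian U, Angstrom^2, or None
    element: str
    scattering_type: str     # element symbol, 'D', or unknown marker such as 'X'
    hetero: bool = False

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def site_key(self):
        return (self.chain, self.resseq, self.icode, self.resname,
                self.name, self.altloc)


@dataclass
class TLSGroup:
    """One TLS group: selection, origin and T/L/S matrices as deposited.

    L is stored in deg^2 exactly as written; conversion to rad^2 happens only
    when the rigid-body ADP contribution is reconstructed.
    """

    group_id: int
    selection_text: str
    # parsed selection: list of (chain, resseq_min or None, resseq_max or None)
    ranges: list[tuple[str, int | None, int | None]]
    origin: np.ndarray            # Angstrom
    T: np.ndarray                 # A^2
    L: np.ndarray                 # deg^2
    S: np.ndarray                 # A * deg
    dialect: str                  # 'refmac' or 'phenix'

    def applies_to(self, atom: AtomRecord) -> bool:
        for chain, lo, hi in self.ranges:
            if chain not in ("*", atom.chain):
                continue
            if lo is not None and atom.resseq < lo:
                continue
            if hi is not None and atom.resseq > hi:
                continue
            return True
        return False


@dataclass
class TlsDefect:
    group_id: int | None
    category: str                 # 'a', 'b' or 'c'
    message: str
    line_number: int | None = None


@dataclass
class HeaderInfo:
    """Statistics quoted in the file header; any field may be absent."""

    reported_r_work: float | None = None
    reported_r_free: float | None = None
    d_min: float | None = None
    d_max: float | None = None
    sigma_cutoff: float | None = None
    reported_wilson_b: float | None = None


@dataclass
class ModelEnsemble:
    models: list[list[AtomRecord]]
    frame: CrystalFrame
    tls_groups: list[TLSGroup] = field(default_factory=list)
    tls_defects: list[TlsDefect] = field(default_factory=list)
    header: HeaderInfo = field(default_factory=HeaderInfo)

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def n_atoms(self) -> int:
        return sum(len(m) for m in self.models)

    def all_atoms(self) -> list[AtomRecord]:
        return [a for m in self.models for a in m]

    def atom_arrays(self):
        """Vectorized view over all models (multi-model sums run directly
        over the concatenation; occupancies carry the ensemble weighting)."""
        atoms = self.all_atoms()
        return {
            "xyz": np.array([a.xyz for a in atoms], dtype=float).reshape(-1, 3),
            "occ": np.array([a.occupancy for a in atoms], dtype=float),
            "b_iso": np.array([a.b_iso for a in atoms], dtype=float),
            "u_aniso": [a.u_aniso for a in atoms],
            "scattering_type": [a.scattering_type for a in atoms],
        }


# --------------------------------------------------------------------------
# parsing
# --------------------------------------------------------------------------

_U_SCALE = 1e-4  # ANISOU stores U * 1e4 in A^2


def _infer_element(name: str, element_field: str) -> str:
    if element_field.strip():
        return element_field.strip().upper()
    core = name.strip().lstrip("0123456789")
    if not core:
        return ""
    # two-letter elements start in column 13; a name starting at column 14
    # with an H/D first letter is a hydrogen/deuterium
    first = core[0].upper()
    if first in ("H", "D"):
        return first
    return first


def _parse_atom_line(line: str, serial_fallback: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = serial_fallback
    name = line[12:16]
    element_field = line[76:78] if len(line) >= 78 else ""
    xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    occ = float(line[54:60]) if line[54:60].strip() else 1.0
    b = float(line[60:66]) if line[60:66].strip() else 0.0
    element = _infer_element(name, element_field)
    return AtomRecord(
        serial=serial,
        name=name.strip(),
        altloc=line[16].strip(),
        resname=line[17:20].strip(),
        chain=line[21].strip() or "A",
        resseq=int(line[22:26]) if line[22:26].strip() else 0,
        icode=line[26].strip(),
        xyz=xyz,
        occupancy=occ,
        b_iso=b,
        u_aniso=None,
        element=element,
        scattering_type=element if element else "X",
        hetero=line.startswith("HETATM"),
    )


def _parse_cryst1(line: str) -> CrystalFrame | None:
    try:
        cell = (
            float(line[6:15]), float(line[15:24]), float(line[24:33]),
            float(line[33:40]), float(line[40:47]), float(line[47:54]),
        )
        sg = line[55:66].strip() or "P1"
    except ValueError:
        return None
    return CrystalFrame(cell, spacegroup=sg)


def _parse_remark290(lines: list[str]):
    """SMTRY matrices -> explicit operator list, or None if none present."""
    rows: dict[int, list[tuple[list[float], float]]] = {}
    for ln in lines:
        parts = ln.split()
        # REMARK 290 SMTRYn  k  r1 r2 r3 t
        if len(parts) >= 8 and parts[2].startswith("SMTRY"):
            axis = int(parts[2][-1]) - 1
            op_no = int(parts[3])
            vals = [float(x) for x in parts[4:8]]
            rows.setdefault(op_no, [None, None, None])[axis] = (vals[:3], vals[3])
    if not rows:
        return None
    ops = []
    for op_no in sorted(rows):
        mats = rows[op_no]
        if any(m is None for m in mats):
            continue
        rot = np.array([m[0] for m in mats])
        trans = np.array([m[1] for m in mats])
        ops.append((np.round(rot).astype(np.int64), trans))
    return ops or None


_HEADER_PATTERNS = [
    ("reported_r_work", "R VALUE            (WORKING SET)"),
    ("reported_r_work", "R VALUE          (WORKING SET)"),
    ("reported_r_free", "FREE R VALUE                    "),
    ("d_min", "RESOLUTION RANGE HIGH"),
    ("d_max", "RESOLUTION RANGE LOW"),
    ("sigma_cutoff", "DATA CUTOFF            (SIGMA(F))"),
    ("reported_wilson_b", "FROM WILSON PLOT"),
]


def _parse_header_info(remark3: list[str]) -> HeaderInfo:
    info = HeaderInfo()
    for ln in remark3:
        body = ln[10:] if len(ln) > 10 else ""
        if ":" not in body:
            continue
        label, _, value = body.partition(":")
        label_u = label.strip().upper()
        value = value.strip()
        for attr, pat in _HEADER_PATTERNS:
            if pat.strip().upper().startswith(label_u) or label_u.startswith(pat.strip().upper()):
                try:
                    v = float(value.split()[0])
                except (ValueError, IndexError):
                    continue
                if getattr(info, attr) is None:
                    setattr(info, attr, v)
    return info


def parse_pdb(source, extra_sources=()) -> ModelEnsemble:
    """Parse one or several PDB files/streams/strings into an ensemble.

    Multiple sources are concatenated (split depositions); all must agree on
    or omit CRYST1 after the first.  ANISOU records are merged onto the
    immediately preceding ATOM/HETATM with the same serial.
    """
    texts = []
    for src in (source, *extra_sources):
        if hasattr(src, "read"):
            texts.append(src.read())
        else:
            try:
                p = str(src)
                if "\n" not in p and len(p) < 4096:
                    with open(p) as fh:
                        texts.append(fh.read())
                else:
                    texts.append(p)
            except (OSError, ValueError):
                texts.append(str(src))

    frame: CrystalFrame | None = None
    remark290: list[str] = []
    remark3: list[str] = []
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    in_model = False

    for text in texts:
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.rstrip("\n")
            rec = line[:6]
            if rec == "CRYST1":
                parsed = _parse_cryst1(line)
                if parsed is not None and frame is None:
                    frame = parsed
            elif line.startswith("REMARK 290"):
                remark290.append(line)
            elif line.startswith("REMARK   3"):
                remark3.append(line)
            elif rec == "MODEL ":
                if current:
                    models.append(current)
                    current = []
                in_model = True
            elif rec == "ENDMDL":
                models.append(current)
                current = []
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                current.append(_parse_atom_line(line, len(current) + 1))
            elif rec == "ANISOU":
                serial = int(line[6:11])
                if not current or current[-1].serial != serial:
                    raise ValueError(
                        f"ANISOU record (serial {serial}) without matching ATOM"
                    )
                u11 = float(line[28:35]); u22 = float(line[35:42])
                u33 = float(line[42:49]); u12 = float(line[49:56])
                u13 = float(line[56:63]); u23 = float(line[63:70])
                current[-1].u_aniso = _U_SCALE * np.array(
                    [[u11, u12, u13], [u12, u22, u23], [u13, u23, u33]]
                )
    if current or not models:
        models.append(current)

    if frame is None:
        raise ValueError("no CRYST1 record: cannot compute structure factors")
    ops = _parse_remark290(remark290)
    if ops is not None:
        frame = CrystalFrame(frame.cell, spacegroup=frame.spacegroup, symops=tuple(ops))

    tls_groups, tls_defects = parse_tls_header(remark3)
    header = _parse_header_info(remark3)
    models = [m for m in models if m] or [[]]
    return ModelEnsemble(
        models=models, frame=frame, tls_groups=tls_groups,
        tls_defects=tls_defects, header=header,
    )


# --------------------------------------------------------------------------
# TLS header parsing
# --------------------------------------------------------------------------


def _parse_selection_phenix(text: str):
    """Parse a phenix-style selection: 'chain A and resseq 1:120' with
    'or'-joined alternatives.  Returns ranges or None if unparseable."""
    ranges = []
    for alt in text.lower().split(" or "):
        chain = None
        lo = hi = None
        toks = alt.replace("(", " ").replace(")", " ").split()
        i = 0
        ok = True
        while i < len(toks):
            t = toks[i]
            if t == "chain" and i + 1 < len(toks):
                chain = toks[i + 1].upper()
                i += 2
            elif t in ("resseq", "resid") and i + 1 < len(toks):
                spec = toks[i + 1]
                if ":" in spec:
                    a, _, b = spec.partition(":")
                elif i + 3 < len(toks) and toks[i + 2] == "through":
                    a, b = spec, toks[i + 3]
                    i += 2
                else:
                    a = b = spec
                try:
                    lo, hi = int(a), int(b)
                except ValueError:
                    ok = False
                    break
                i += 2
            elif t == "and":
                i += 1
            elif t == "all":
                chain = "*"
                i += 1
            else:
                ok = False
                break
        if not ok or (chain is None and lo is None):
            return None
        ranges.append((chain or "*", lo, hi))
    return ranges


def _collect_tensor(lines: dict[str, float], labels: tuple[str, ...]):
    vals = []
    for lab in labels:
        if lab not in lines:
            return None
        vals.append(lines[lab])
    return vals


def parse_tls_header(remark3_lines: list[str]):
    """Extract TLS groups from REMARK 3; never raises on malformed records.

    Returns ``(groups, defects)``.  Defect categories follow the common
    failure taxonomy: (a) missing/empty/duplicate/ambiguous/unparseable
    selections, (b) missing or malformed origins, (c) matrix problems.
    A group with any defect is withheld from ``groups``.
    """
    # split into per-group chunks
    chunks: list[tuple[int | None, list[tuple[int, str]]]] = []
    cur: list[tuple[int, str]] | None = None
    cur_id: int | None = None
    for lineno, ln in enumerate(remark3_lines, start=1):
        body = ln[10:].strip() if len(ln) > 10 else ""
        up = body.upper()
        if up.startswith("TLS GROUP"):
            if cur is not None:
                chunks.append((cur_id, cur))
            cur = []
            try:
                cur_id = int(up.split(":")[1])
            except (IndexError, ValueError):
                cur_id = None
        elif cur is not None:
            cur.append((lineno, body))
    if cur is not None:
        chunks.append((cur_id, cur))

    groups: list[TLSGroup] = []
    defects: list[TlsDefect] = []

    for gid, body_lines in chunks:
        dialect = None
        sel_text = None
        ranges = None
        origin = None
        origin_line = None
        tensor_vals: dict[str, float] = {}
        bad_matrix_line = None

        for lineno, body in body_lines:
            up = body.upper()
            if up.startswith("RESIDUE RANGE"):
                dialect = dialect or "refmac"
                parts = body.split(":", 1)[1].split() if ":" in body else []
                if len(parts) >= 4:
                    try:
                        rng = (parts[0].upper(), int(parts[1]), int(parts[3]))
                        ranges = (ranges or []) + [rng]
                        sel_text = (sel_text or "") + " " + body
                    except ValueError:
                        ranges = ranges if ranges else None
                        sel_text = sel_text or body
                else:
                    sel_text = sel_text or body
            elif up.startswith("SELECTION"):
                dialect = dialect or "phenix"
                sel_text = body.split(":", 1)[1].strip() if ":" in body else ""
                ranges = _parse_selection_phenix(sel_text) if sel_text else None
            elif up.startswith("ORIGIN"):
                origin_line = lineno
                tail = body.split(":", 1)[1] if ":" in body else ""
                try:
                    xyz = [float(x) for x in tail.split()[:3]]
                    if len(xyz) == 3:
                        origin = np.array(xyz)
                except ValueError:
                    origin = None
            else:
                # matrix element lines: 'T11:   0.0500 T22:   0.0400'
                toks = body.replace(":", " : ").split()
                i = 0
                while i < len(toks) - 2:
                    lab, colon, val = toks[i], toks[i + 1], toks[i + 2]
                    if colon == ":" and len(lab) == 3 and lab[0] in "TLS":
                        try:
                            tensor_vals[lab.upper()] = float(val)
                        except ValueError:
                            bad_matrix_line = lineno
                        i += 3
                    else:
                        i += 1

        if sel_text is None or ranges is None:
            defects.append(TlsDefect(gid, "a",
                                     "missing or unparseable selection"))
            continue
        if origin is None:
            defects.append(TlsDefect(gid, "b",
                                     "missing or malformed origin", origin_line))
            continue
        t = _collect_tensor(tensor_vals, ("T11", "T22", "T33", "T12", "T13", "T23"))
        l = _collect_tensor(tensor_vals, ("L11", "L22", "L33", "L12", "L13", "L23"))
        s = _collect_tensor(
            tensor_vals,
            ("S11", "S12", "S13", "S21", "S22", "S23", "S31", "S32", "S33"),
        )
        if bad_matrix_line is not None or t is None or l is None or s is None:
            defects.append(TlsDefect(gid, "c",
                                     "missing or malformed T/L/S matrices",
                                     bad_matrix_line))
            continue
        T = np.array([[t[0], t[3], t[4]], [t[3], t[1], t[5]], [t[4], t[5], t[2]]])
        L = np.array([[l[0], l[3], l[4]], [l[3], l[1], l[5]], [l[4], l[5], l[2]]])
        S = np.array(s).reshape(3, 3)
        groups.append(TLSGroup(
            group_id=gid if gid is not None else len(groups) + 1,
            selection_text=sel_text.strip(), ranges=ranges, origin=origin,
            T=T, L=L, S=S, dialect=dialect or "refmac",
        ))

    # overlap check across well-formed groups -> ambiguity, category (a)
    bad_ids = set()
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            if _ranges_overlap(groups[i].ranges, groups[j].ranges):
                bad_ids.update((i, j))
                defects.append(TlsDefect(
                    groups[i].group_id, "a",
                    f"selection overlaps group {groups[j].group_id}",
                ))
    groups = [g for k, g in enumerate(groups) if k not in bad_ids]
    return groups, defects


def _ranges_overlap(r1, r2) -> bool:
    for c1, lo1, hi1 in r1:
        for c2, lo2, hi2 in r2:
            if c1 != c2 and "*" not in (c1, c2):
                continue
            a1, b1 = (-10**9 if lo1 is None else lo1), (10**9 if hi1 is None else hi1)
            a2, b2 = (-10**9 if lo2 is None else lo2), (10**9 if hi2 is None else hi2)
            if a1 <= b2 and a2 <= b1:
                return True
    return False


# --------------------------------------------------------------------------
# writing
# --------------------------------------------------------------------------


def write_pdb(ensemble: ModelEnsemble, stream=None) -> str:
    out = io.StringIO()
    a, b, c, al, be, ga = ensemble.frame.cell
    sg = ensemble.frame.spacegroup
    out.write(
        f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{al:7.2f}{be:7.2f}{ga:7.2f} {sg:<11s}\n"
    )
    multi = ensemble.n_models > 1
    for i, model in enumerate(ensemble.models, start=1):
        if multi:
            out.write(f"MODEL     {i:4d}\n")
        for atom in model:
            rec = "HETATM" if atom.hetero else "ATOM  "
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            out.write(
                f"{rec}{atom.serial:5d} {name:<4s}{atom.altloc or ' ':1s}"
                f"{atom.resname:<3s} {atom.chain:1s}{atom.resseq:4d}"
                f"{atom.icode or ' ':1s}   "
                f"{atom.xyz[0]:8.3f}{atom.xyz[1]:8.3f}{atom.xyz[2]:8.3f}"
                f"{atom.occupancy:6.2f}{atom.b_iso:6.2f}          "
                f"{atom.element:>2s}\n"
            )
            if atom.u_aniso is not None:
                u = np.round(atom.u_aniso / _U_SCALE).astype(int)
                out.write(
                    f"ANISOU{atom.serial:5d} {name:<4s}{atom.altloc or ' ':1s}"
                    f"{atom.resname:<3s} {atom.chain:1s}{atom.resseq:4d}"
                    f"{atom.icode or ' ':1s} "
                    f"{u[0,0]:7d}{u[1,1]:7d}{u[2,2]:7d}"
                    f"{u[0,1]:7d}{u[0,2]:7d}{u[1,2]:7d}  "
                    f"{atom.element:>2s}\n"
                )
        if multi:
            out.write("ENDMDL\n")
    out.write("END\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


# --------------------------------------------------------------------------
# audits
# --------------------------------------------------------------------------


@dataclass
class ModelAudit:
    non_pd_serials: list[int]
    zero_adp_serials: list[int]
    negative_occupancy_serials: list[int]
    unknown_scattering_serials: list[int]
    # (chain, resseq, icode, name) -> occupancy sum over altlocs, only != 1
    altloc_occupancy_anomalies: list[tuple[tuple, float]]
    # H/D exchange pairs: ((serial_H, serial_D), occupancy sum, deficient?)
    hd_exchange_sites: list[tuple[tuple[int, int], float, bool]]
    # multi-model per-site occupancy sums (only for n_models > 1)
    multi_model_site_occupancy: dict[tuple, float]

    @property
    def clean(self) -> bool:
        return not (
            self.non_pd_serials or self.zero_adp_serials
            or self.negative_occupancy_serials or self.unknown_scattering_serials
            or self.altloc_occupancy_anomalies
            or any(d for _, _, d in self.hd_exchange_sites)
        )


OCC_TOL = 1e-3  # PDB occupancies carry two decimals


def audit_model(ensemble: ModelEnsemble) -> ModelAudit:
    from .scattering import XRAY_FORM_FACTORS

    non_pd, zero_adp, neg_occ, unknown = [], [], [], []
    for atom in ensemble.all_atoms():
        if atom.u_aniso is not None and not is_positive_definite(atom.u_aniso):
            non_pd.append(atom.serial)
        if atom.b_iso == 0 and atom.u_aniso is None:
            zero_adp.append(atom.serial)
        if atom.occupancy < 0:
            neg_occ.append(atom.serial)
        if atom.scattering_type.upper() not in XRAY_FORM_FACTORS:
            unknown.append(atom.serial)

    # altloc occupancy sums within one model
    altloc_anom = []
    for model in ensemble.models:
        sums: dict[tuple, float] = {}
        has_alt: dict[tuple, bool] = {}
        for atom in model:
            key = (atom.chain, atom.resseq, atom.icode, atom.name)
            sums[key] = sums.get(key, 0.0) + atom.occupancy
            has_alt[key] = has_alt.get(key, False) or bool(atom.altloc)
        for key, s in sums.items():
            if has_alt[key] and abs(s - 1.0) > OCC_TOL:
                altloc_anom.append((key, s))

    # H/D exchangeable sites: an H and a D at the same position (<= 1e-3 A)
    hd_sites = []
    for model in ensemble.models:
        hs = [a for a in model if a.element.upper() == "H"]
        ds = [a for a in model if a.element.upper() == "D"]
        for h in hs:
            for d in ds:
                if np.linalg.norm(h.xyz - d.xyz) <= 1e-3:
                    s = h.occupancy + d.occupancy
                    hd_sites.append(((h.serial, d.serial), s, s < 1.0 - OCC_TOL))

    multi = {}
    if ensemble.n_models > 1:
        for model in ensemble.models:
            for atom in model:
                key = atom.site_key()
                multi[key] = multi.get(key, 0.0) + atom.occupancy
        multi = {k: round(v, 6) for k, v in multi.items()}

    return ModelAudit(
        non_pd_serials=non_pd,
        zero_adp_serials=zero_adp,
        negative_occupancy_serials=neg_occ,
        unknown_scattering_serials=unknown,
        altloc_occupancy_anomalies=altloc_anom,
        hd_exchange_sites=hd_sites,
        multi_model_site_occupancy=multi,
    )


# --------------------------------------------------------------------------
# hydrogen manipulation
# --------------------------------------------------------------------------

H_BOND_CUTOFF = 1.3  # A: an H belongs to the nearest heavy atom within this


def strip_hydrogens(ensemble: ModelEnsemble) -> ModelEnsemble:
    models = [[a for a in m if not a.is_hydrogen] for m in ensemble.models]
    return replace(ensemble, models=models)


def set_h_adp_from_parent(ensemble: ModelEnsemble) -> ModelEnsemble:
    """Give each H/D the B factor and occupancy of its bonded heavy atom
    (nearest heavy atom within 1.3 A); unmatched hydrogens are left as-is."""
    import warnings

    new_models = []
    for model in ensemble.models:
        heavy = [a for a in model if not a.is_hydrogen]
        hxyz = np.array([a.xyz for a in heavy]).reshape(-1, 3)
        out = []
        for atom in model:
            if atom.is_hydrogen and len(heavy):
                dist = np.linalg.norm(hxyz - atom.xyz, axis=1)
                j = int(np.argmin(dist))
                if dist[j] <= H_BOND_CUTOFF:
                    atom = replace(atom, b_iso=heavy[j].b_iso,
                                   occupancy=heavy[j].occupancy)
                else:
                    warnings.warn(
                        f"H atom serial {atom.serial} has no heavy atom "
                        f"within {H_BOND_CUTOFF} A; left unchanged"
                    )
            out.append(atom)
        new_models.append(out)
    return replace(ensemble, models=new_models)
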