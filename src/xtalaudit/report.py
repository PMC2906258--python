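"""Pipeline orchestration and the four-section report.

``run`` takes model and reflection files and produces a :class:`Report`
with (1) model statistics and audit results, (2) data statistics,
(3) the model-to-data fit and (4) header comparison — reported vs
recomputed R.  Rendering is deterministic: the plain-text view is generated
from the same dictionary the JSON twin serializes, so every printed number
is machine-readable; absent values render as ``n.a.``.

Parse or audit failures of individual components become report entries, not
crashes — the tool is meant to keep running across a large, partly broken
archive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .fitting import CrystalFit
from .maps import (
    estimate_sigma_a,
    granularity_for,
    map_coefficients,
    real_space_cc,
    synthesize_map,
)
from .pdbio import audit_model, parse_pdb
from .reflections import (
    completeness_shells,
    extract_free_flags,
    guess_data_kind,
    merge_to_asu,
    read_reflections,
    to_amplitudes,
    wilson_b,
)

__all__ = ["Report", "run", "render_text", "render_json"]


def _na(x, scale=1.0, nd=4):
    if x is None:
        return "n.a."
    return round(float(x) * scale, nd)


@dataclass
class Report:
    sections: dict

    def to_json(self) -> str:
        return render_json(self)

    def to_text(self) -> str:
        return render_text(self)


def run(model_paths, data_path, *, data_kind: str = "auto",
        free_file=None, data_format: str = "auto", map_type=None,
        cc: str | None = None, twin="auto", scattering: str = "xray",
        map_out=None) -> Report:
    """Execute the full pipeline; see the module docstring."""
    if isinstance(model_paths, (str, bytes)) or hasattr(model_paths, "read"):
        model_paths = [model_paths]
    ensemble = parse_pdb(model_paths[0], model_paths[1:])
    frame = ensemble.frame

    miller, value, sigma, flags = read_reflections(data_path, data_format)

    if data_kind == "auto":
        kind, confidence, ratio = guess_data_kind(miller, value, frame)
    else:
        kind = {"F": "amplitude", "I": "intensity"}.get(data_kind, data_kind)
        confidence, ratio = "declared", float("nan")

    rs, n_redundant = merge_to_asu(miller, value, sigma, frame, kind=kind,
                                   free_flag=flags)
    if free_file is not None:
        fm, _, _, fflags = read_reflections(free_file, "auto")
        if fflags is None:
            # single value column = the flags themselves
            fflags = np.round(np.atleast_1d(np.loadtxt(
                free_file if isinstance(free_file, str) else free_file,
                usecols=(3,)))).astype(int)
        fset, _ = merge_to_asu(fm, fflags.astype(float),
                               np.zeros(len(fm)), frame, kind="amplitude")
        lookup = {tuple(h): int(round(v))
                  for h, v in zip(fset.miller, fset.value)}
        flags = np.array([lookup.get(tuple(h), 0) for h in rs.miller])
        free_mask, convention = extract_free_flags(flags)
    else:
        free_mask, convention = extract_free_flags(
            None if rs.free_flag is None else rs.free_flag.astype(int)
        )
    rs.free_flag = free_mask
    rs = to_amplitudes(rs)

    audit = audit_model(ensemble)
    shells = completeness_shells(rs)
    types = [a.scattering_type for a in ensemble.all_atoms()]
    b_wilson, _ = wilson_b(rs, types)

    fit = CrystalFit(ensemble, rs, mode=scattering, twin=twin).fit()

    atoms = ensemble.all_atoms()
    b_vals = [a.b_iso for a in atoms]
    model_section = {
        "n_models": ensemble.n_models,
        "n_atoms": ensemble.n_atoms,
        "n_hydrogen": sum(a.is_hydrogen for a in atoms),
        "b_iso_min": _na(min(b_vals) if b_vals else None),
        "b_iso_max": _na(max(b_vals) if b_vals else None),
        "b_iso_mean": _na(float(np.mean(b_vals)) if b_vals else None),
        "n_anisotropic": sum(a.u_aniso is not None for a in atoms),
        "audit": {
            "non_positive_definite_adp": audit.non_pd_serials,
            "zero_adp": audit.zero_adp_serials,
            "negative_occupancy": audit.negative_occupancy_serials,
            "unknown_scattering_type": audit.unknown_scattering_serials,
            "altloc_occupancy_anomalies": [
                {"site": list(k), "sum": round(v, 4)}
                for k, v in audit.altloc_occupancy_anomalies
            ],
            "hd_exchange_deficient_sites": [
                {"serials": list(s), "sum": round(v, 4)}
                for s, v, bad in audit.hd_exchange_sites if bad
            ],
            "multi_model_site_occupancy_range": (
                [
                    round(min(audit.multi_model_site_occupancy.values()), 4),
                    round(max(audit.multi_model_site_occupancy.values()), 4),
                ]
                if audit.multi_model_site_occupancy else None
            ),
        },
        "tls_groups": len(ensemble.tls_groups),
        "tls_defects": [
            {"group": d.group_id, "category": d.category, "message": d.message}
            for d in ensemble.tls_defects
        ],
    }

    data_section = {
        "kind": kind,
        "kind_confidence": confidence,
        "moment_ratio": None if np.isnan(ratio) else round(ratio, 3),
        "n_reflections": len(rs),
        "n_redundant_input_rows": n_redundant,
        "d_min": round(float(rs.d.min()), 3),
        "d_max": round(float(rs.d.max()), 3),
        "free_flag_convention": convention,
        "n_free": int(free_mask.sum()) if free_mask is not None else None,
        "wilson_b": _na(b_wilson, nd=2),
        "n_outliers": fit.n_outliers,
        "completeness_shells": [
            {k: (round(v, 4) if isinstance(v, float) else int(v))
             for k, v in row.items()}
            for row in shells.to_dict("records")
        ],
    }

    fit_section = {
        "r_work": _na(fit.r_work),
        "r_free": _na(fit.r_free),
        "n_work": fit.chosen.n_work,
        "n_free": fit.chosen.n_free,
        "adp_convention": fit.adp_convention,
        "adp_variants": {
            k: {"r_work": _na(v.r_work), "r_free": _na(v.r_free)}
            for k, v in fit.variants.items()
        },
        "k_sol": round(fit.scale.k_sol, 3),
        "b_sol": round(fit.scale.b_sol, 2),
        "k_overall": round(fit.scale.k_overall, 5),
        "twin_laws_tested": [
            {"law": law.tolist(), "alpha": round(a, 4), "r_work": _na(r)}
            for law, a, r in fit.twin_results
        ],
        "twin_verdict": (
            None if fit.twin_verdict is None
            else {"law": fit.twin_verdict.law.tolist(),
                  "alpha": round(fit.twin_verdict.fraction, 4)}
        ),
        "header_cutoff_variant": (
            None if fit.cutoff_variant is None else {
                "label": fit.cutoff_variant.label,
                "r_work": _na(fit.cutoff_variant.r_work),
                "r_free": _na(fit.cutoff_variant.r_free),
            }
        ),
    }

    header_section = {
        "reported_r_work": _na(ensemble.header.reported_r_work),
        "reported_r_free": _na(ensemble.header.reported_r_free),
        "recomputed_r_work": _na(fit.r_work),
        "recomputed_r_free": _na(fit.r_free),
        "r_work_difference": (
            _na(fit.r_work - ensemble.header.reported_r_work)
            if fit.r_work is not None
            and ensemble.header.reported_r_work is not None else "n.a."
        ),
        "reported_resolution": [_na(ensemble.header.d_min, nd=2),
                                _na(ensemble.header.d_max, nd=2)],
        "reported_sigma_cutoff": _na(ensemble.header.sigma_cutoff, nd=2),
    }

    sections = {
        "model": model_section,
        "data": data_section,
        "fit": fit_section,
        "header": header_section,
    }

    if map_type is not None:
        fm = fit.f_model()
        sa = estimate_sigma_a(rs, fm)
        h, c = map_coefficients(map_type, rs, fm, sa)
        sections["map"] = {
            "type": map_type,
            "n_coefficients": len(c),
        }
        if map_out is not None:
            write_map_coefficients(map_out, h, c)
            sections["map"]["file"] = str(map_out)

    if cc is not None:
        fm = fit.f_model()
        sa = estimate_sigma_a(rs, fm)
        gran = granularity_for(float(rs.d.min())) if cc == "auto" else cc
        h2, c2 = map_coefficients("2mfo-dfc", rs, fm, sa)
        hf, cf = map_coefficients("fc", rs, fm)
        grid = None
        m_a = synthesize_map(h2, c2, frame, grid)
        m_b = synthesize_map(hf, cf, frame, m_a.values.shape)
        rows = real_space_cc(m_a, m_b, ensemble, gran)
        sections["cc"] = {
            "granularity": gran,
            "units": [
                {"unit": [str(x) for x in r["unit"]],
                 "cc": None if r["cc"] is None else round(r["cc"], 4),
                 "density": round(r["density"], 3)}
                for r in rows
            ],
        }
    return Report(sections=sections)


def write_map_coefficients(path, miller, coeffs) -> None:
    """Plain-column map-coefficient export: h k l amplitude phase_deg."""
    amp = np.abs(coeffs)
    ph = np.degrees(np.angle(coeffs))
    with open(path, "w") as fh:
        for (h, k, l), a, p in zip(miller, amp, ph):
            fh.write(f"{h:5d}{k:5d}{l:5d}{a:12.4f}{p:10.2f}\n")


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------


def render_json(report: Report) -> str:
    return json.dumps(report.sections, indent=1, sort_keys=True)


def _render_dict(d, indent=2):
    lines = []
    for key in d:
        v = d[key]
        pad = " " * indent
        if isinstance(v, dict):
            lines.append(f"{pad}{key}:")
            lines.extend(_render_dict(v, indent + 2))
        elif isinstance(v, list) and v and isinstance(v[0], dict):
            lines.append(f"{pad}{key}:")
            for item in v:
                lines.append(
                    " " * (indent + 2)
                    + "  ".join(f"{k}={item[k]}" for k in item)
                )
        else:
            lines.append(f"{pad}{key}: {'n.a.' if v is None else v}")
    return lines


SECTION_TITLES = {
    "model": "Model information",
    "data": "Data information",
    "fit": "Model-to-data fit",
    "header": "Information from the file header",
    "map": "Map output",
    "cc": "Map correlation",
}


def render_text(report: Report) -> str:
    out = []
    for name in ("model", "data", "fit", "header", "map", "cc"):
        if name not in report.sections:
            continue
        title = SECTION_TITLES[name]
        out.append(title)
        out.append("-" * len(title))
        out.extend(_render_dict(report.sections[name]))
        out.append("")
    return "\n".join(out)
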