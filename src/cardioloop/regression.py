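"""Regression targets: published 1G-supine vs long-term-0G reference values.

Encodes reference hemodynamic changes reported for long-duration (about
five months) spaceflight against a supine 1G baseline — cardiac index
variations, central pressures and waveform-similarity (NSD) values — as
tolerance-checked targets, plus the hard qualitative checks (signs of all
index changes, and the proximal-to-distal growth of waveform alteration
along the arterial tree) that any faithful deconditioning configuration
must reproduce regardless of parameter provenance.

Tolerances come in two tiers: ``tight`` presumes an exact transcription of
the original parameter set; ``loose`` (default) allows for an independent
baseline parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import cardiac_indexes, nsd, beat_statistics, relative_variation

TIERS = {
    "tight": {"variation_pp": 0.5, "nsd": 0.05, "pressure_mmhg": 2.0},
    "loose": {"variation_pp": 2.0, "nsd": 0.10, "pressure_mmhg": 2.0},
}

AORTA_PATH = ["asc_aorta", "thoracic_aorta", "abd_aorta_a", "abd_aorta_e",
              "l_ext_iliac", "l_femoral"]


@dataclass
class PaperTarget:
    """One printed reference value with its comparison rule."""

    id: str
    kind: str            # index_variation | site_mean_p | nsd_p | nsd_q
    name: str            # index field or site id
    printed: float
    tol_class: str       # variation_pp | nsd | pressure_mmhg
    provenance: str


def default_targets() -> list[PaperTarget]:
    """Reference values for the long-term 0G vs 1G supine comparison."""
    t = []
    idxvar = [
        ("sv", -18.32), ("v_lved", -9.30), ("ef", -9.93), ("v_lves", 4.75),
        ("co", -7.58), ("map", -9.92), ("sw_min", -19.29), ("rpp", -1.91),
        ("tti_min", -8.38), ("cvp", -5.08), ("pp_aa", -22.30),
        ("p_aa_syst", -13.39), ("p_aa_dias", -6.90), ("ai_aa", -41.18),
    ]
    for name, val in idxvar:
        t.append(PaperTarget(f"{name}_variation_pct", "index_variation",
                             name, val, "variation_pp",
                             "published cardiac-index variations"))
    for site, val_1g, val_0g in [("asc_aorta", 92.61, 83.19),
                                 ("thoracic_aorta", 92.38, 82.99),
                                 ("l_femoral", 89.47, 80.20)]:
        t.append(PaperTarget(f"{site}_mean_p_1g", "site_mean_p_1g", site,
                             val_1g, "pressure_mmhg",
                             "published beat-averaged pressures"))
        t.append(PaperTarget(f"{site}_mean_p_0g", "site_mean_p_0g", site,
                             val_0g, "pressure_mmhg",
                             "published beat-averaged pressures"))
    for site, val in [("asc_aorta", 0.19), ("thoracic_aorta", 0.24),
                      ("abd_aorta_a", 0.31), ("abd_aorta_e", 0.33),
                      ("l_ext_iliac", 0.34), ("l_femoral", 0.37)]:
        t.append(PaperTarget(f"{site}_nsd_p", "nsd_p", site, val, "nsd",
                             "published pressure-waveform NSD values"))
    for site, val in [("asc_aorta", 0.28), ("l_femoral", 0.56)]:
        t.append(PaperTarget(f"{site}_nsd_q", "nsd_q", site, val, "nsd",
                             "published flow-waveform NSD values"))
    return t


def _computed_value(target: PaperTarget, ctx: dict) -> float:
    if target.kind == "index_variation":
        a = ctx["idx_1g"][target.name]
        b = ctx["idx_0g"][target.name]
        if a == 0 or not np.isfinite(a) or not np.isfinite(b):
            return float("nan")
        return relative_variation(a, b)
    if target.kind == "site_mean_p_1g":
        b = ctx["run_1g"].last_beat(f"{target.name}:P")
        return beat_statistics(b, b.rr)["mean"]
    if target.kind == "site_mean_p_0g":
        b = ctx["run_0g"].last_beat(f"{target.name}:P")
        return beat_statistics(b, b.rr)["mean"]
    if target.kind in ("nsd_p", "nsd_q"):
        var = "P" if target.kind == "nsd_p" else "Q"
        return nsd(ctx["run_1g"].last_beat(f"{target.name}:{var}"),
                   ctx["run_0g"].last_beat(f"{target.name}:{var}"))
    raise ValueError(f"unknown target kind {target.kind}")


def evaluate_targets(run_1g, run_0g, target_set=None,
                     tier: str = "loose") -> pd.DataFrame:
    """Per-target residuals (computed - printed) and pass flags.

    Both runs must be converged steady-state stores recording the target
    sites; a missing quantity raises KeyError naming it.
    """
    targets = target_set if target_set is not None else default_targets()
    tols = TIERS[tier]
    ctx = {
        "run_1g": run_1g, "run_0g": run_0g,
        "idx_1g": cardiac_indexes(run_1g).as_dict(),
        "idx_0g": cardiac_indexes(run_0g).as_dict(),
    }
    rows = []
    for t in targets:
        computed = _computed_value(t, ctx)
        resid = computed - t.printed
        tol = tols[t.tol_class]
        rows.append({
            "target": t.id, "printed": t.printed, "computed": computed,
            "residual": resid, "tolerance": tol, "tier": tier,
            "passed": bool(np.isfinite(resid) and abs(resid) <= tol),
            "provenance": t.provenance,
        })
    return pd.DataFrame(rows).set_index("target")


# ---------------------------------------------------------------------------
# Hard qualitative checks


def direction_checks(run_1g, run_0g) -> dict[str, bool]:
    """Signs of the deconditioning response that must hold regardless of
    magnitude tolerances: contractility, work, oxygen-consumption
    surrogates and central pressures all fall; end-systolic LV volume and
    pulmonary blood volumes rise."""
    a = cardiac_indexes(run_1g).as_dict()
    b = cardiac_indexes(run_0g).as_dict()
    out = {}
    for name in ("sv", "ef", "co", "map", "pp_aa", "sw_min", "tti_min",
                 "rpp", "cvp"):
        out[f"{name}_decreases"] = b[name] < a[name]
    out["v_lves_increases"] = b["v_lves"] > a["v_lves"]
    for cid, label in (("pulm_art", "pulmonary_artery"),
                       ("pulm_vein", "pulmonary_vein")):
        key = f"{cid}:V"
        if key in run_1g.signals and key in run_0g.signals:
            va = beat_statistics(run_1g.last_beat(key))["mean"]
            vb = beat_statistics(run_0g.last_beat(key))["mean"]
            out[f"{label}_volume_increases"] = vb > va
    return out


def nsd_pattern_checks(run_1g, run_0g,
                       aorta_path: list[str] | None = None,
                       arterial_sites: list[str] | None = None) -> dict:
    """Spatial waveform-alteration pattern along the arterial tree.

    Returns the NSD profile along the proximal-to-distal aortic pathway
    plus two summary checks: NSD grows from proximal to distal (distal at
    least doubles the proximal value for pressure), and flow waveforms are
    at least as altered as pressure waveforms at most arterial sites.
    """
    path = aorta_path or AORTA_PATH
    prof_p, prof_q = [], []
    for site in path:
        prof_p.append(nsd(run_1g.last_beat(f"{site}:P"),
                          run_0g.last_beat(f"{site}:P")))
        prof_q.append(nsd(run_1g.last_beat(f"{site}:Q"),
                          run_0g.last_beat(f"{site}:Q")))
    sites = arterial_sites
    if sites is None:
        sites = [k.split(":")[0] for k in run_1g.signals
                 if k.endswith(":P") and not k.startswith(("baro", "LV", "LA",
                                                           "RV", "RA"))
                 and f"{k.split(':')[0]}:Q" in run_1g.signals]
    n_q_ge_p = 0
    for site in sites:
        np_ = nsd(run_1g.last_beat(f"{site}:P"),
                  run_0g.last_beat(f"{site}:P"))
        nq = nsd(run_1g.last_beat(f"{site}:Q"),
                 run_0g.last_beat(f"{site}:Q"))
        n_q_ge_p += nq >= np_
    frac = n_q_ge_p / max(1, len(sites))
    return {
        "path_sites": list(path),
        "nsd_p_profile": prof_p,
        "nsd_q_profile": prof_q,
        "distal_exceeds_proximal_p": prof_p[-1] > prof_p[0],
        "distal_at_least_doubles_p": prof_p[-1] >= 2.0 * prof_p[0],
        "q_ge_p_fraction": frac,
        "q_more_altered_than_p_at_most_sites": frac >= 0.5,
    }
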