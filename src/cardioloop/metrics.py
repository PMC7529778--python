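"""Beat-level hemodynamic analysis.

Beat statistics are quadrature means over one steady beat; cardiac indexes
(SV, EF, CO, SW/min, TTI/min, RPP, CVP, MAP, AI, PP) follow their textbook
definitions; waveform similarity between two configurations is quantified
by the normalized signal difference

    NSD = integral_0^1 | y'_ref(t') - y'_alt(t') | dt'     in [0, 2],

where t' = t/RR and y' = (y - mu)/sigma is the amplitude- and
time-normalized beat.  NSD = 0 means identical waveform shapes; the upper
bound 2 is attained only by complementary step functions centred at
t' = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter


class MetricsError(ValueError):
    """Invalid input to a beat-level metric."""


NORM_GRID = 1000   # samples per beat on the common t' grid


@dataclass
class BeatSeries:
    """One steady beat of one signal, re-indexed to t in [0, RR]."""

    site: str
    kind: str                 # variable kind: P, Q, V, opening, ...
    t: np.ndarray             # s, starting at 0
    y: np.ndarray
    rr: float                 # s
    stale: bool = False       # run had not converged when extracted


@dataclass
class CardiacIndexes:
    """Beat-level cardiac summary (units as printed in clinical tables)."""

    v_lves: float          # ml
    v_lved: float          # ml
    sv: float              # ml
    ef: float              # %
    hr: float              # bpm
    co: float              # l/min
    sw_min: float          # mmHg ml / min
    tti_min: float         # mmHg s / min
    rpp: float             # mmHg bpm
    cvp: float             # mmHg
    map: float             # mmHg
    p_aa_syst: float       # mmHg
    p_aa_dias: float       # mmHg
    pp_aa: float           # mmHg
    ai_aa: float           # %

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _t_y(series):
    """Accept a BeatSeries-like object or a (t, y) pair."""
    if hasattr(series, "t"):
        return np.asarray(series.t, float), np.asarray(series.y, float), \
            getattr(series, "rr", None)
    t, y = series
    return np.asarray(t, float), np.asarray(y, float), None


def beat_statistics(series, rr: float | None = None) -> dict:
    """Quadrature mean, max, min and pulse (max - min) over one beat."""
    t, y, rr_s = _t_y(series)
    rr = rr if rr is not None else rr_s
    if rr is None:
        rr = t[-1] - t[0]
    span = t[-1] - t[0]
    if span < 0.98 * rr:
        raise MetricsError(
            f"incomplete beat: samples span {span:g} s of RR={rr:g} s")
    mean = float(np.trapezoid(y, t) / span)
    return {"mean": mean, "max": float(y.max()), "min": float(y.min()),
            "pulse": float(y.max() - y.min())}


def normalize_waveform(series, n: int = NORM_GRID):
    """Resample one beat to the dimensionless grid t' in [0, 1] and map it
    to zero quadrature mean and unit standard deviation.

    Invariant under any positive affine transform of the input; a constant
    signal (sigma = 0) is rejected.
    """
    t, y, _ = _t_y(series)
    tp = np.linspace(0.0, 1.0, n)
    yy = np.interp(tp, (t - t[0]) / (t[-1] - t[0]), y)
    mu = np.trapezoid(yy, tp)
    var = np.trapezoid((yy - mu) ** 2, tp)
    if var <= 0 or not np.isfinite(var):
        raise MetricsError("cannot normalize a constant signal (sigma = 0)")
    return tp, (yy - mu) / np.sqrt(var)


def nsd(series_ref, series_alt) -> float:
    """Normalized signal difference between two beats.

    Symmetric in its arguments, bounded in [0, 2], and (by
    Cauchy--Schwarz) no larger than sqrt(2 (1 - rho)) where rho is the
    Pearson correlation of the two normalized beats.
    """
    tp, a = normalize_waveform(series_ref)
    _, b = normalize_waveform(series_alt)
    return float(np.trapezoid(np.abs(a - b), tp))


def relative_variation(x_ref, x_alt) -> float:
    """100 (x_alt - x_ref) / x_ref [%]; undefined for a zero baseline."""
    if x_ref == 0:
        raise MetricsError("relative variation undefined for zero baseline")
    return 100.0 * (x_alt - x_ref) / x_ref


def pv_loop_work(p, v) -> float:
    """Area of the closed pressure--volume loop [mmHg ml] (stroke work per
    beat), from the time-ordered samples of one beat."""
    p = np.asarray(p, float)
    v = np.asarray(v, float)
    # close the loop and integrate -oint P dV (ejection at high P makes
    # the time-ordered integral negative for a pumping chamber)
    pc = np.r_[p, p[0]]
    vc = np.r_[v, v[0]]
    return float(-np.trapezoid(pc, vc))


def augmentation_index(t, p, rr: float) -> float:
    """Augmentation index [%] of a central aortic beat.

    The systolic upstroke is smoothed with a low-order polynomial filter;
    the inflection point is the second-derivative zero crossing nearest to
    the systolic peak, and AI = 100 (P_syst - P_inflection) / PP.  The
    window and smoothing length are heuristic (the inflection-point
    decomposition has no unique algorithm); NaN when no inflection exists.
    """
    t = np.asarray(t, float)
    p = np.asarray(p, float)
    n = t.size
    if n < 20:
        return float("nan")
    i_foot = int(np.argmin(p[: max(4, n // 3)]))
    i_peak = i_foot + int(np.argmax(p[i_foot:]))
    i_end = min(n - 1, i_foot + int(0.40 * n))
    win = max(5, (n // 20) | 1)
    ps = savgol_filter(p, win, 3)
    d2 = np.gradient(np.gradient(ps, t), t)
    seg = slice(i_foot + 2, max(i_foot + 4, i_end))
    sign = np.sign(d2[seg])
    cross = np.nonzero(np.diff(sign) != 0)[0]
    if cross.size == 0:
        return float("nan")
    idx = cross + seg.start
    i_inf = idx[np.argmin(np.abs(idx - i_peak))]
    pp = p.max() - p.min()
    if pp <= 0:
        return float("nan")
    return float(100.0 * (p[i_peak] - ps[i_inf]) / pp)


def _beats_from(run_store, keys):
    """Extract last-beat series for the given keys from a run store."""
    if isinstance(run_store, dict):
        missing = [k for k in keys if k not in run_store]
        if missing:
            raise MetricsError(f"missing recorded sites: {missing}")
        return {k: run_store[k] for k in keys}
    out = {}
    for k in keys:
        if k not in run_store.signals:
            raise MetricsError(f"missing recorded site: {k}")
        out[k] = run_store.last_beat(k)
    return out


def cardiac_indexes(run_store, aortic_site: str = "aortic_root",
                    systole_threshold: float = 1e-3) -> CardiacIndexes:
    """All beat-level cardiac indexes from a steady-state run.

    Uses the last full beat.  CVP is the mean of the beat-averaged
    superior and inferior vena cava pressures; TTI integrates ascending
    aortic pressure over the aortic-valve-open window; SW is the LV
    pressure--volume loop area; RPP = HR x systolic aortic pressure.
    """
    keys = ["LV:V", "LV:P", f"{aortic_site}:P", "svc:P", "ivc:P",
            "AV:opening"]
    beats = _beats_from(run_store, keys)
    lv_v = beats["LV:V"]
    rr = lv_v.rr
    hr = 60.0 / rr
    v_lved = float(np.max(lv_v.y))
    v_lves = float(np.min(lv_v.y))
    sv = v_lved - v_lves
    ef = 100.0 * sv / v_lved
    co = sv * hr / 1000.0
    aa = beats[f"{aortic_site}:P"]
    st = beat_statistics(aa, rr)
    p_syst, p_dias, p_map = st["max"], st["min"], st["mean"]
    pp = p_syst - p_dias
    sw_beat = pv_loop_work(beats["LV:P"].y, lv_v.y)
    av = beats["AV:opening"]
    open_mask = np.interp(aa.t, av.t, av.y) > systole_threshold
    tti_beat = float(np.trapezoid(np.where(open_mask, aa.y, 0.0), aa.t))
    cvp = 0.5 * (beat_statistics(beats["svc:P"], rr)["mean"]
                 + beat_statistics(beats["ivc:P"], rr)["mean"])
    ai = augmentation_index(aa.t, aa.y, rr)
    return CardiacIndexes(
        v_lves=v_lves, v_lved=v_lved, sv=sv, ef=ef, hr=hr, co=co,
        sw_min=sw_beat * hr, tti_min=tti_beat * hr, rpp=hr * p_syst,
        cvp=cvp, map=p_map, p_aa_syst=p_syst, p_aa_dias=p_dias, pp_aa=pp,
        ai_aa=ai)


def comparison_report(run_ref, run_alt, site_list: list[str],
                      label_ref: str = "1G", label_alt: str = "0G") -> dict:
    """Machine-readable comparison tables between two steady runs.

    For every site: beat-averaged P and Q with relative variations,
    maximum pressure and pulse pressure with variations, and NSD for the
    normalized P and Q waveforms.  Both runs must record the same sites.
    """
    for site in site_list:
        for run, lbl in ((run_ref, label_ref), (run_alt, label_alt)):
            if f"{site}:P" not in run.signals:
                raise MetricsError(f"site {site} not recorded in {lbl} run")

    rows_mean, rows_ext, rows_nsd = [], [], []
    for site in site_list:
        row_m = {"site": site}
        row_e = {"site": site}
        row_n = {"site": site}
        for var in ("P", "Q"):
            key = f"{site}:{var}"
            has = key in run_ref.signals and key in run_alt.signals
            if not has:
                continue
            b_ref = run_ref.last_beat(key)
            b_alt = run_alt.last_beat(key)
            s_ref = beat_statistics(b_ref, b_ref.rr)
            s_alt = beat_statistics(b_alt, b_alt.rr)
            row_m[f"{var}_{label_ref}"] = s_ref["mean"]
            row_m[f"{var}_{label_alt}"] = s_alt["mean"]
            row_m[f"{var}_variation_pct"] = (
                relative_variation(s_ref["mean"], s_alt["mean"])
                if s_ref["mean"] != 0 else float("nan"))
            if var == "P":
                row_e[f"Pmax_{label_ref}"] = s_ref["max"]
                row_e[f"Pmax_{label_alt}"] = s_alt["max"]
                row_e["Pmax_variation_pct"] = relative_variation(
                    s_ref["max"], s_alt["max"])
                row_e[f"PP_{label_ref}"] = s_ref["pulse"]
                row_e[f"PP_{label_alt}"] = s_alt["pulse"]
                row_e["PP_variation_pct"] = (
                    relative_variation(s_ref["pulse"], s_alt["pulse"])
                    if s_ref["pulse"] != 0 else float("nan"))
            try:
                row_n[f"NSD_{var}"] = nsd(b_ref, b_alt)
            except MetricsError:
                row_n[f"NSD_{var}"] = float("nan")
        rows_mean.append(row_m)
        rows_ext.append(row_e)
        rows_nsd.append(row_n)

    report = {
        "means": pd.DataFrame(rows_mean).set_index("site"),
        "extremes": pd.DataFrame(rows_ext).set_index("site"),
        "nsd": pd.DataFrame(rows_nsd).set_index("site"),
    }
    try:
        idx_ref = cardiac_indexes(run_ref).as_dict()
        idx_alt = cardiac_indexes(run_alt).as_dict()
        rows = []
        for k in idx_ref:
            var = (relative_variation(idx_ref[k], idx_alt[k])
                   if idx_ref[k] not in (0.0,) and np.isfinite(idx_ref[k])
                   else float("nan"))
            rows.append({"index": k, label_ref: idx_ref[k],
                         label_alt: idx_alt[k], "variation_pct": var})
        report["indexes"] = pd.DataFrame(rows).set_index("index")
    except MetricsError:
        pass
    return report


def write_report(report: dict, outdir) -> None:
    import pathlib
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in report.items():
        df.to_csv(out / f"{name}.csv", float_format="%.6g")
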