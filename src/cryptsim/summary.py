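"""Headline metrics computed from scenario results.

These functions condense a scenario's recorders and event log into the
quantities the simulator is validated against: mean cycle durations by
compartment, terminal-division counts, composition drift, dedifferentiation
origins, and injury/recovery magnitudes.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

NICHE_POSITIONS = np.arange(1, 5)


def homeostasis_metrics(result: dict) -> dict:
    """Summary of a homeostasis run (cycle durations, divisions, drift)."""
    cyc = result["cycles"]
    world = result["world"]
    counts = result["counts"]
    t0 = counts["time"].min()

    out = {
        "stem_cycle_h": float(np.mean(cyc.stem_niche)) if cyc.stem_niche else np.nan,
        "stem_cycle_n": len(cyc.stem_niche),
        "ta_cycle_h": float(np.mean(cyc.ta)) if cyc.ta else np.nan,
        "ta_cycle_n": len(cyc.ta),
    }
    tdiv = [d for t, d in world.terminal_divisions if t >= t0]
    out["terminal_divisions_mean"] = float(np.mean(tdiv)) if tdiv else np.nan
    out["terminal_divisions_n"] = len(tdiv)

    drift = {}
    for col in ("stem", "paneth", "absorptive_progenitor",
                "secretory_progenitor", "goblet", "enterocyte",
                "total", "villus"):
        ma = counts[col].rolling(168, min_periods=168).mean().dropna()
        if len(ma) and ma.mean() > 0:
            drift[col] = float((ma.max() - ma.min()) / ma.mean() * 100.0)
    out["drift_pct"] = drift
    out["retro_niche"] = float(result["motion"].retro_fraction())
    return out


def wnt_profile(world, n_bins: int = 12) -> pd.DataFrame:
    """Mean tethered Wnt binned along the crypt axis by position index."""
    from .observers import position_index
    idx, sector, rank = position_index(world)
    df = pd.DataFrame({"pos": rank, "wnt": world.wnt[idx]})
    df["bin"] = np.minimum((df["pos"] - 1) // 3, n_bins - 1)
    return df.groupby("bin")["wnt"].mean().reset_index()


def ablation_metrics(result: dict) -> dict:
    """Summary of a stem-ablation run against its own pre-treatment baseline."""
    counts = result["counts"]
    ts = result["t_start"]
    base = counts[(counts.time >= ts - 24.0) & (counts.time < ts)].mean(
        numeric_only=True)
    ana = result["analysis_counts"]
    ev = result["events"]
    dd = ev[(ev.event == "dedifferentiation") & (ev.time >= ts)]
    n_dd = max(len(dd), 1)
    origin = dd["cell_type"].value_counts()

    treat_rec = counts[counts.time >= ts]
    crypt_min_t = float(treat_rec.loc[treat_rec["total"].idxmin(), "time"] - ts)
    villus_min_t = float(treat_rec.loc[treat_rec["villus"].idxmin(), "time"] - ts)
    recovery = counts[counts.time >= ts + 96.0]

    return {
        "stem_at_analysis": int(ana["stem"]),
        "baseline_paneth": float(base["paneth"]),
        "paneth_reduction_pct": 100.0 * (base["paneth"] - ana["paneth"])
        / max(base["paneth"], 1e-9),
        "baseline_villus": float(base["villus"]),
        "villus_reduction_pct": 100.0 * (base["villus"] - ana["villus"])
        / max(base["villus"], 1e-9),
        "origin_paneth_pct": 100.0 * origin.get("PANETH", 0) / n_dd,
        "origin_absorptive_pct": 100.0 * origin.get("ABSORPTIVE_PROGENITOR", 0) / n_dd,
        "origin_secretory_pct": 100.0 * origin.get("SECRETORY_PROGENITOR", 0) / n_dd,
        "n_dedifferentiation": int(len(dd)),
        "retro_niche_treatment": float(
            result["motion_treatment"].retro_fraction()),
        "baseline_ap": float(base["absorptive_progenitor"]),
        "recovery_ap_max": float(recovery["absorptive_progenitor"].max()),
        "crypt_min_h": crypt_min_t,
        "villus_min_h": villus_min_t,
    }


def pooled(dicts: list[dict], key: str) -> float:
    return float(np.mean([d[key] for d in dicts]))


def fu_metrics(result: dict) -> dict:
    """Summary of a 5-FU run: nadir depression and Ki-67 time course."""
    counts = result["counts"]
    ts = result["t_start"]
    base = counts[(counts.time >= ts - 24.0) & (counts.time < ts)]["total"].mean()
    treat = counts[(counts.time >= ts) & (counts.time <= ts + 96.0)]["total"]
    st = result["staining"]
    ki = st[st.assay == "ki67"].groupby("time").apply(
        lambda g: float((g.fraction * g.n).sum() / g.n.sum()),
        include_groups=False)
    ki.index = np.round(ki.index - ts, 1)
    ev = result["events"]
    return {
        "baseline_total": float(base),
        "nadir_total": float(treat.min()),
        "nadir_depression_pct": 100.0 * (base - treat.min()) / base,
        "ki67_by_time": ki.to_dict(),
        "ki67_baseline": float(ki.get(-1.0, np.nan)),
        "ki67_rebound_max": float(ki[ki.index >= 120.0].max())
        if (ki.index >= 120.0).any() else np.nan,
        "apoptosis_events": int((ev[ev.time >= ts].event == "apoptosis").sum()),
    }
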