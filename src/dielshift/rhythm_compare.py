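"""Rhythm-change classification between conditions, phase shifts, phase enrichment.

Each gene is placed in exactly one category:

* ``WW_only`` / ``DR_only`` -- cycling under a single condition
* ``both_equal``            -- cycling in both, |amplitude difference| below threshold
* ``both_WW_gt_DR`` / ``both_DR_gt_WW`` -- cycling in both with larger amplitude in
  the indicated condition (difference is amplitude_WW - amplitude_DR)
* ``arrhythmic``            -- cycling in neither

Phase shifts are circular distances on the 24-h clock, so they lie in [0, 12].
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core_io import logger

CATEGORIES = (
    "WW_only",
    "DR_only",
    "both_equal",
    "both_WW_gt_DR",
    "both_DR_gt_WW",
    "arrhythmic",
)
TOP_LEVEL = ("WW_only", "DR_only", "both", "arrhythmic")

BOTH_SUBCATEGORIES = ("both_equal", "both_WW_gt_DR", "both_DR_gt_WW")


def circular_phase_shift(phase_a: float, phase_b: float, period: float = 24.0) -> float:
    """Circular distance between two phases, in [0, period/2]."""
    d = abs(phase_a - phase_b) % period
    return min(d, period - d)


def classify_rhythm_change(
    calls_ww: pd.DataFrame,
    calls_dr: pd.DataFrame,
    amp_threshold: float = 3.0,
    phase_threshold: float = 2.0,
) -> pd.DataFrame:
    """Classify every gene's rhythm change between the two conditions.

    ``calls_ww`` / ``calls_dr`` are rhythm-call tables indexed by gene id
    with at least ``cycling``, ``phase`` and ``amplitude`` columns, over the
    same gene universe.  The amplitude threshold is applied to the absolute
    difference; the phase threshold flags ``phase_changed`` for genes cycling
    in both conditions.
    """
    if set(calls_ww.index) != set(calls_dr.index):
        only = set(calls_ww.index) ^ set(calls_dr.index)
        raise ValueError(f"gene universes differ between conditions ({len(only)} genes)")
    dr = calls_dr.loc[calls_ww.index]
    ww = calls_ww

    cyc_ww = ww["cycling"].to_numpy(dtype=bool)
    cyc_dr = dr["cycling"].to_numpy(dtype=bool)
    amp_diff = ww["amplitude"].to_numpy() - dr["amplitude"].to_numpy()

    category = np.where(
        cyc_ww & ~cyc_dr,
        "WW_only",
        np.where(
            ~cyc_ww & cyc_dr,
            "DR_only",
            np.where(~cyc_ww & ~cyc_dr, "arrhythmic", ""),
        ),
    ).astype(object)
    both = cyc_ww & cyc_dr
    category[both & (np.abs(amp_diff) < amp_threshold)] = "both_equal"
    category[both & (np.abs(amp_diff) >= amp_threshold) & (amp_diff > 0)] = "both_WW_gt_DR"
    category[both & (np.abs(amp_diff) >= amp_threshold) & (amp_diff < 0)] = "both_DR_gt_WW"

    shift = np.array(
        [
            circular_phase_shift(a, b)
            for a, b in zip(ww["phase"].to_numpy(), dr["phase"].to_numpy())
        ]
    )
    records = pd.DataFrame(
        {
            "category": category,
            "cycling_ww": cyc_ww,
            "cycling_dr": cyc_dr,
            "amp_diff": np.where(both, amp_diff, np.nan),
            "phase_ww": np.where(cyc_ww, ww["phase"].to_numpy(), np.nan),
            "phase_dr": np.where(cyc_dr, dr["phase"].to_numpy(), np.nan),
            "phase_shift": np.where(both, shift, np.nan),
            "phase_changed": np.where(both, shift >= phase_threshold, False),
        },
        index=ww.index,
    )
    counts = records["category"].value_counts()
    logger.info("classify_rhythm_change: %s", counts.to_dict())
    return records


def tabulate_categories(records: pd.DataFrame) -> pd.DataFrame:
    """Category count table with percentages (1 decimal), Table-1 style.

    The four top-level rows (WW_only, DR_only, both, arrhythmic) partition
    the gene universe; the three ``both_*`` subcategories are reported as
    indented extra rows and sum to the ``both`` row.
    """
    total = len(records)
    cat = records["category"]
    n_both = int(cat.isin(BOTH_SUBCATEGORIES).sum())
    rows = []
    for name in ("WW_only", "DR_only", "both"):
        n = n_both if name == "both" else int((cat == name).sum())
        rows.append((name, n))
        if name == "both":
            for sub in BOTH_SUBCATEGORIES:
                rows.append((sub, int((cat == sub).sum())))
    rows.append(("arrhythmic", int((cat == "arrhythmic").sum())))
    rows.append(("total", total))
    out = pd.DataFrame(rows, columns=["category", "count"]).set_index("category")
    out["percent"] = (100.0 * out["count"] / total).round(1)
    return out


def rhythm_marginals(records: pd.DataFrame) -> dict[str, float]:
    """Per-condition cycling totals and the derived percentages.

    Counts are reconstructed from the category partition alone, so the
    marginals are exactly WW_only + both and DR_only + both.
    """
    tab = tabulate_categories(records)["count"]
    total = int(tab["total"])
    cycling_ww = int(tab["WW_only"] + tab["both"])
    cycling_dr = int(tab["DR_only"] + tab["both"])
    amp_changed = int(tab["both_WW_gt_DR"] + tab["both_DR_gt_WW"])
    out = {
        "total": total,
        "cycling_ww": cycling_ww,
        "cycling_dr": cycling_dr,
        "both": int(tab["both"]),
        "amp_changed": amp_changed,
        "pct_cycling_ww": 100.0 * cycling_ww / total,
        "pct_cycling_dr": 100.0 * cycling_dr / total,
        "pct_both": 100.0 * tab["both"] / total,
        "pct_amp_changed": (100.0 * amp_changed / tab["both"]) if tab["both"] else float("nan"),
    }
    return out


def phase_enrichment(
    phases: pd.Series,
    group: set[str] | list[str],
    background: set[str] | list[str],
    n_phases: int = 24,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-phase over-representation of a gene group (one-sided hypergeometric).

    ``phases`` maps gene id -> integer peak phase (hours); genes without a
    phase (non-cycling) must be excluded beforehand.  Phases are binned on
    the integer hours 0..n_phases-1; p-values are Bonferroni-adjusted by the
    number of phase bins and a bin is enriched when adj_p <= alpha.
    """
    group = set(group)
    background = set(background)
    if not group:
        raise ValueError("empty gene group")
    if not group <= background:
        raise ValueError("group must be a subset of background")
    missing = (group | background) - set(phases.index)
    if missing:
        raise ValueError(f"{len(missing)} genes lack a phase (e.g. {sorted(missing)[:3]})")

    ph = phases.astype(float)
    bins = (np.floor(ph) % n_phases).astype(int)
    n_total = len(background)
    n_group = len(group)
    in_group = bins.index.isin(group)
    in_bg = bins.index.isin(background)
    rows = []
    for h in range(n_phases):
        at_h = bins == h
        k_bg = int((at_h & in_bg).sum())
        k_grp = int((at_h & in_group).sum())
        p = float(hypergeom.sf(k_grp - 1, n_total, k_bg, n_group))
        adj = min(1.0, p * n_phases)
        rows.append((h, k_grp, n_group, k_bg, n_total, p, adj, adj <= alpha))
    return pd.DataFrame(
        rows,
        columns=["phase", "fg_hits", "fg_total", "bg_hits", "bg_total", "p_value", "adj_p", "enriched"],
    ).set_index("phase")
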