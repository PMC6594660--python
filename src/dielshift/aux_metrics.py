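"""Small closed-form assay metrics and gene-family dynamics classification."""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import ttest_ind


def classify_family_dynamics(
    counts: pd.DataFrame,
    totals: Mapping[str, int],
    focal: str,
    contract_ratio: float = 0.2,
    expand_ratio: float = 3.0,
    mode: str = "every",
) -> pd.Series:
    """Classify gene families as contracted/expanded/neither in a focal species.

    ``counts`` is families x species; ``totals`` gives each species' genome
    gene total used for normalization (v = count / total, which makes the
    classification invariant to ploidy-driven rescaling).  A family is
    contracted when the focal species' normalized count is below
    ``contract_ratio`` times that of every other species with a non-zero
    count (``mode="any"`` relaxes "every" to "at least one"), and expanded
    symmetrically above ``expand_ratio``.  Species with zero count for a
    family are excluded from the ratio test.
    """
    if focal not in counts.columns:
        raise ValueError(f"focal species {focal!r} not in count table")
    if mode not in ("every", "any"):
        raise ValueError("mode must be 'every' or 'any'")
    for sp in counts.columns:
        if totals.get(sp, 0) <= 0:
            raise ValueError(f"missing or non-positive genome total for {sp!r}")
        if int(counts[sp].sum()) > totals[sp]:
            raise ValueError(f"family counts for {sp!r} exceed its genome total")
    if (counts < 0).any().any():
        raise ValueError("family counts must be >= 0")

    others = [sp for sp in counts.columns if sp != focal]
    agg = all if mode == "every" else any
    out = {}
    for fam, row in counts.iterrows():
        if row.sum() == 0:
            raise ValueError(f"family {fam!r} absent from every species")
        v_focal = row[focal] / totals[focal]
        ratios = [
            v_focal / (row[sp] / totals[sp]) for sp in others if row[sp] > 0
        ]
        if not ratios:
            out[fam] = "neither"  # family private to the focal species
        elif agg(r < contract_ratio for r in ratios):
            out[fam] = "contracted"
        elif agg(r > expand_ratio for r in ratios):
            out[fam] = "expanded"
        else:
            out[fam] = "neither"
    return pd.Series(out, name="dynamics")


def titratable_acid(naoh_volume_ml: float, fresh_weight_g: float) -> float:
    """Titratable acidity in microequivalents per gram fresh weight.

    volume(0.1 N NaOH, mL) * 0.1 * 1000 / fresh weight (g).
    """
    if fresh_weight_g <= 0:
        raise ValueError("fresh weight must be > 0")
    if naoh_volume_ml < 0:
        raise ValueError("NaOH volume must be >= 0")
    return naoh_volume_ml * 0.1 * 1000.0 / fresh_weight_g


def stomatal_aperture(width: float, length: float) -> float:
    """Stomatal aperture as the width/length ratio (dimensionless)."""
    if length <= 0:
        raise ValueError("stoma length must be > 0")
    return width / length


def compare_apertures(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sample unequal-variance t-test on aperture ratios: (t, p)."""
    t, p = ttest_ind(list(group_a), list(group_b), equal_var=False)
    return float(t), float(p)


def ks_to_time(ks: float, rate: float) -> float:
    """Divergence time in years from synonymous divergence: t = Ks / (2 * rate)."""
    if rate <= 0:
        raise ValueError("substitution rate must be > 0")
    return ks / (2.0 * rate)
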