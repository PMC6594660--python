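"""Nonparametric detection of 24-h rhythmic expression per gene per condition.

The detector matches each (replicate-expanded) timecourse against cosine
reference templates at every grid phase and scores concordance with
Kendall's S.  Two-sided p-values come from the *exact* null distribution of
S given the template's tie structure, computed by integer polynomial
convolution (the inversion generating function of a random multiset
permutation, i.e. the Gaussian multinomial coefficient
``[n]_q! / prod_k [t_k]_q!``).  Ties in the observed data contribute 0 to S;
the null conditions on template ties only.

Per-gene multiplicity over templates uses a Bonferroni factor equal to the
number of distinct templates (toggleable); across genes, cycling is called
at a Bonferroni-adjusted ``p < alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, logger


@dataclass(frozen=True)
class FilterRule:
    """Pre-filter: drop genes with near-zero expression across all samples."""

    min_total_tpm: float = 5.0
    max_zero_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.min_total_tpm < 0 or self.max_zero_fraction < 0:
            raise ValueError("filter thresholds must be >= 0")


def filter_genes(
    matrix: ExpressionMatrix, rule: FilterRule = FilterRule()
) -> tuple[ExpressionMatrix, list[str]]:
    """Partition genes into (kept matrix, removed ids) by the expression filter.

    A gene is kept iff its total TPM over *all* samples (both conditions
    jointly) is >= ``min_total_tpm`` and its fraction of zero cells is
    strictly below ``max_zero_fraction``.
    """
    if matrix.n_genes == 0:
        raise ValueError("empty expression matrix")
    values = matrix.data.to_numpy()
    total = values.sum(axis=1)
    zero_frac = (values == 0).mean(axis=1)
    keep = (total >= rule.min_total_tpm) & (zero_frac < rule.max_zero_fraction)
    kept_ids = [g for g, k in zip(matrix.gene_ids, keep) if k]
    removed = [g for g, k in zip(matrix.gene_ids, keep) if not k]
    if not kept_ids:
        raise ValueError("filter removed every gene")
    logger.info("filter_genes: kept %d / %d genes", len(kept_ids), matrix.n_genes)
    return matrix.subset_genes(kept_ids), removed


# -- exact null distribution of Kendall's S ------------------------------


def _poly_mul_ones(a: list[int], width: int) -> list[int]:
    """Multiply integer polynomial ``a`` by 1 + q + ... + q^(width-1)."""
    out = [0] * (len(a) + width - 1)
    run = 0
    for k in range(len(out)):
        if k < len(a):
            run += a[k]
        if k - width >= 0:
            run -= a[k - width]
        out[k] = run
    return out


def _poly_div_ones(a: list[int], width: int) -> list[int]:
    """Exact division of ``a`` by 1 + q + ... + q^(width-1)."""
    if width == 1:
        return list(a)
    rem = list(a)
    q = [0] * (len(a) - width + 1)
    for i in range(len(q)):
        c = rem[i]
        q[i] = c
        if c:
            for d in range(width):
                rem[i + d] -= c
    if any(rem):
        raise ArithmeticError("polynomial division was not exact")
    return q


@lru_cache(maxsize=256)
def kendall_null_counts(tie_sizes: tuple[int, ...]) -> tuple[int, tuple[int, ...]]:
    """Exact null counts of concordant pairs C for a template with given ties.

    ``tie_sizes`` are the template tie-group sizes (summing to n).  Returns
    ``(M, counts)`` where M is the number of comparable pairs and
    ``counts[c]`` the number of orderings of a tie-free observation vector
    achieving exactly c concordant pairs, c = 0..M.  ``sum(counts)`` equals
    the multinomial ``n! / prod(t_k!)``.
    """
    n = sum(tie_sizes)
    if n < 2:
        raise ValueError("need at least 2 observations")
    poly = [1]
    for i in range(2, n + 1):  # [n]_q!
        poly = _poly_mul_ones(poly, i)
    for t in tie_sizes:  # / prod [t_k]_q!
        for j in range(2, t + 1):
            poly = _poly_div_ones(poly, j)
    m = (n * n - sum(t * t for t in tie_sizes)) // 2
    assert len(poly) == m + 1
    return m, tuple(poly)


@lru_cache(maxsize=256)
def _null_sf(tie_sizes: tuple[int, ...]) -> tuple[int, np.ndarray]:
    """Survival function sf[c] = P(C >= c) for c = 0..M+1 (sf[M+1] = 0)."""
    m, counts = kendall_null_counts(tie_sizes)
    total = sum(counts)
    sf = np.zeros(m + 2)
    acc = 0
    for c in range(m, -1, -1):
        acc += counts[c]
        sf[c] = acc / total
    return m, sf


def kendall_s_pvalue(s: int, tie_sizes: tuple[int, ...]) -> float:
    """Two-sided exact p-value of Kendall's S under the template-tie null."""
    m, sf = _null_sf(tie_sizes)
    s = abs(int(s))
    if s > m:
        raise ValueError(f"|S| = {s} exceeds the maximum {m}")
    c_hi = (s + m + 1) // 2  # C >= ceil((s+M)/2)  <=>  S >= s
    c_lo = (m - s) // 2  # C <= floor((M-s)/2)  <=>  S <= -s
    return float(min(1.0, sf[c_hi] + (1.0 - sf[c_lo + 1])))


# -- template machinery --------------------------------------------------


def _template_values(times: np.ndarray, period: float, lag: float) -> np.ndarray:
    return np.round(np.cos(2 * np.pi * (times - lag) / period), 9)


def _tie_sizes(values: np.ndarray) -> tuple[int, ...]:
    _, counts = np.unique(values, return_counts=True)
    return tuple(sorted(int(c) for c in counts))


def _rank_signature(values: np.ndarray) -> tuple[int, ...]:
    # dense ranks; identifies a template up to monotone transformation
    _, inv = np.unique(values, return_inverse=True)
    return tuple(int(r) for r in inv)


class _TemplateBank:
    """All (period, lag) cosine templates for a fixed sample-time vector."""

    def __init__(self, times: np.ndarray, periods: Sequence[float]):
        times = np.asarray(times, dtype=float)
        if len(np.unique(times)) < 4:
            raise ValueError("need at least 4 distinct timepoints")
        self.times = times
        n = len(times)
        self.iu, self.ju = np.triu_indices(n, 1)
        entries = []  # (period, lag, sign_vector, M, tie_sizes)
        signatures = set()
        for period in periods:
            for lag in sorted(np.unique(times)):
                c = _template_values(times, period, float(lag))
                signatures.add((_rank_signature(c)))
                sign = np.sign(c[self.ju] - c[self.iu]).astype(np.int8)
                entries.append((float(period), float(lag), sign, _tie_sizes(c)))
            # distinct-template count is over unique rank signatures
        self.entries = entries
        self.n_distinct = len(signatures)
        self.sign_matrix = np.stack([e[2] for e in entries])  # L x P


@dataclass(frozen=True)
class JtkResult:
    """Un-adjusted scan result for one series."""

    p_value: float
    period: float
    phase: float
    tau: float
    s: int
    s_max: int
    n_templates: int


def scan_matrix(
    values: np.ndarray,
    times: np.ndarray,
    periods: Sequence[float] = (24.0,),
    per_gene_bonferroni: bool = True,
) -> pd.DataFrame:
    """Vectorised JTK-style scan of many series sharing one time vector.

    Parameters
    ----------
    values:
        (n_genes, n_samples) array; times may repeat for replicates.
    times:
        sample times in hours, aligned with columns of ``values``.

    Returns a DataFrame with columns ``p_value, period, phase, tau, s, s_max``.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if not np.isfinite(values).all():
        raise ValueError("non-finite value in series")
    bank = _TemplateBank(np.asarray(times, float), tuple(periods))

    x_sign = np.sign(values[:, bank.ju] - values[:, bank.iu]).astype(np.float32)
    s_all = x_sign @ bank.sign_matrix.T.astype(np.float32)  # G x L, exact ints
    s_all = np.rint(s_all).astype(np.int64)

    n_genes, n_templates = s_all.shape
    p_all = np.empty_like(s_all, dtype=float)
    for l, (_, _, _, ties) in enumerate(bank.entries):
        m, sf = _null_sf(ties)
        s_abs = np.abs(s_all[:, l])
        c_hi = (s_abs + m + 1) // 2
        c_lo = (m - s_abs) // 2
        p_all[:, l] = np.minimum(1.0, sf[c_hi] + (1.0 - sf[c_lo + 1]))

    # best template: minimal p, then maximal S (puts phase at the peak)
    order = np.lexsort((-s_all, p_all), axis=1)
    best = order[:, 0]
    rows = np.arange(n_genes)
    m_per_template = np.array([np.count_nonzero(e[2]) for e in bank.entries], dtype=float)
    m_best = m_per_template[best]
    s_best = s_all[rows, best]
    p_best = p_all[rows, best]
    factor = bank.n_distinct if per_gene_bonferroni else 1
    p_final = np.minimum(1.0, p_best * factor)

    flat = values.var(axis=1) == 0
    tau = np.where(m_best > 0, s_best / np.maximum(m_best, 1), 0.0)
    p_final = np.where(flat, 1.0, p_final)
    tau = np.where(flat, 0.0, tau)

    return pd.DataFrame(
        {
            "p_value": p_final,
            "period": [bank.entries[l][0] for l in best],
            "phase": [bank.entries[l][1] for l in best],
            "tau": tau,
            "s": s_best,
            "s_max": m_best.astype(int),
        }
    )


def jtk_scan(
    values: Sequence[float],
    times: Sequence[float],
    periods: Sequence[float] = (24.0,),
    per_gene_bonferroni: bool = True,
) -> JtkResult:
    """Scan one series; see :func:`scan_matrix` for the algorithm."""
    df = scan_matrix(np.asarray(values, float)[None, :], times, periods, per_gene_bonferroni)
    row = df.iloc[0]
    bank_distinct = _TemplateBank(np.asarray(times, float), tuple(periods)).n_distinct
    return JtkResult(
        p_value=float(row.p_value),
        period=float(row.period),
        phase=float(row.phase),
        tau=float(row.tau),
        s=int(row.s),
        s_max=int(row.s_max),
        n_templates=bank_distinct,
    )


# -- phase / amplitude ---------------------------------------------------


def estimate_phase_amplitude(
    values: Sequence[float],
    times: Sequence[float],
    period: float,
    phase: float,
) -> tuple[float, float]:
    """Least-squares amplitude of x(t) = m + A cos(2*pi*(t - phase)/period), A >= 0."""
    x = np.asarray(values, dtype=float)
    c = np.cos(2 * np.pi * (np.asarray(times, float) - phase) / period)
    cc = c - c.mean()
    denom = float(cc @ cc)
    if denom == 0:
        return float(phase), 0.0
    amp = float((x - x.mean()) @ cc) / denom
    return float(phase), max(0.0, amp)


def _amplitudes(values: np.ndarray, times: np.ndarray, periods: np.ndarray, phases: np.ndarray) -> np.ndarray:
    out = np.empty(len(values))
    for i in range(len(values)):
        _, out[i] = estimate_phase_amplitude(values[i], times, periods[i], phases[i])
    return out


# -- top level per condition ---------------------------------------------


def call_cycling(calls: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni-adjust p-values across genes and flag cycling (adj_p < alpha)."""
    out = calls.copy()
    n = len(out)
    out["adj_p"] = np.minimum(1.0, out["p_value"] * n)
    out["cycling"] = out["adj_p"] < alpha
    return out


def detect_rhythms(
    matrix: ExpressionMatrix,
    condition: str,
    periods: Sequence[float] = (24.0,),
    alpha: float = 0.05,
    per_gene_bonferroni: bool = True,
    collapse_replicates: bool = False,
) -> pd.DataFrame:
    """Full rhythm-call table for one condition.

    Replicates are expanded against a replicate-expanded template by default;
    ``collapse_replicates=True`` averages them per timepoint first.

    Returns a DataFrame indexed by gene id with columns
    ``condition, p_value, adj_p, cycling, period, phase, amplitude, tau``.
    """
    sub = matrix.subset_condition(condition)
    if collapse_replicates:
        sub = sub.average_replicates().subset_condition(condition)
    order = sorted(range(len(sub.samples)), key=lambda i: (sub.samples[i].zt, sub.samples[i].replicate))
    times = np.array([sub.samples[i].zt for i in order], dtype=float)
    values = sub.data.to_numpy()[:, order]

    calls = scan_matrix(values, times, periods, per_gene_bonferroni)
    calls.index = pd.Index(sub.gene_ids, name="gene_id")
    calls = call_cycling(calls, alpha)
    calls["amplitude"] = _amplitudes(
        values, times, calls["period"].to_numpy(), calls["phase"].to_numpy()
    )
    calls.insert(0, "condition", condition)
    n_cyc = int(calls["cycling"].sum())
    logger.info("detect_rhythms[%s]: %d / %d genes cycling", condition, n_cyc, len(calls))
    return calls[
        ["condition", "p_value", "adj_p", "cycling", "period", "phase", "amplitude", "tau", "s", "s_max"]
    ]
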