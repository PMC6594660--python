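"""Shared data model and I/O: sample keys, expression matrices, gene lists, config.

All tabular output is tab-separated UTF-8 with '.' decimals.  Sample columns
follow the ``<COND>_ZT<tt>_r<k>`` dialect (e.g. ``WW_ZT06_r2``); a custom
regex with named groups ``cond``, ``zt`` and ``rep`` can be supplied to
:func:`parse_sample_key` / :meth:`ExpressionMatrix.from_tsv` for other
dialects.
"""

from __future__ import annotations

import logging
import re
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("dielshift")
if not logger.handlers:  # timestamped stderr logging, once
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

CONDITIONS = ("WW", "DR")

DEFAULT_KEY_PATTERN = r"^(?P<cond>WW|DR)_ZT(?P<zt>\d{1,2})_r(?P<rep>\d+)$"


@dataclass(frozen=True, order=True)
class SampleKey:
    """Identity of one expression sample: condition, zeitgeber time, replicate."""

    condition: str
    zt: int
    replicate: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")
        if not 0 <= self.zt < 24:
            raise ValueError(f"zt must be in [0, 24), got {self.zt}")
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")

    @property
    def label(self) -> str:
        return f"{self.condition}_ZT{self.zt:02d}_r{self.replicate}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_sample_key(label: str, key_pattern: str = DEFAULT_KEY_PATTERN) -> SampleKey:
    """Parse a sample-column label into a :class:`SampleKey`.

    Raises ``ValueError`` naming the offending label when it does not match.
    """
    m = re.match(key_pattern, label)
    if m is None:
        raise ValueError(f"unparseable sample label: {label!r}")
    return SampleKey(m.group("cond"), int(m.group("zt")), int(m.group("rep")))


class ExpressionMatrix:
    """Genes x samples TPM matrix with parsed sample keys.

    Parameters
    ----------
    data:
        DataFrame indexed by gene id with one column per sample.  Values must
        be finite and non-negative (TPM scale).
    samples:
        Sample keys aligned with ``data.columns``.  If omitted, column labels
        are parsed with the default dialect.
    """

    def __init__(self, data: pd.DataFrame, samples: Sequence[SampleKey] | None = None):
        if samples is None:
            samples = [parse_sample_key(str(c)) for c in data.columns]
        samples = list(samples)
        if len(samples) != data.shape[1]:
            raise ValueError("samples must align with data columns")
        if data.index.duplicated().any():
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample keys")
        values = data.to_numpy(dtype=float, copy=False)
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at gene {data.index[i]!r}, sample {samples[j].label}"
            )
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative TPM at gene {data.index[i]!r}, sample {samples[j].label}"
            )
        df = data.astype(float).copy()
        df.columns = [k.label for k in samples]
        df.index = df.index.astype(str)
        df.index.name = "gene_id"
        self.data = df
        self.samples = samples

    # -- basic accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def conditions(self) -> list[str]:
        return sorted({k.condition for k in self.samples}, key=CONDITIONS.index)

    def timepoints(self, condition: str) -> list[int]:
        return sorted({k.zt for k in self.samples if k.condition == condition})

    def subset_condition(self, condition: str) -> "ExpressionMatrix":
        keep = [i for i, k in enumerate(self.samples) if k.condition == condition]
        if not keep:
            raise ValueError(f"no samples for condition {condition!r}")
        return ExpressionMatrix(self.data.iloc[:, keep], [self.samples[i] for i in keep])

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids)], self.samples)

    # -- I/O -------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path, key_pattern: str = DEFAULT_KEY_PATTERN) -> "ExpressionMatrix":
        """Read a gene x sample TSV whose header labels match ``key_pattern``."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        for col in df.columns:
            if not pd.api.types.is_numeric_dtype(df[col]):
                coerced = pd.to_numeric(df[col], errors="coerce")
                bad = df.index[coerced.isna() & df[col].notna()]
                gene = bad[0] if len(bad) else df.index[df[col].isna()][0]
                raise ValueError(f"non-numeric cell at gene {gene!r}, sample {col!r}")
        samples = [parse_sample_key(str(c), key_pattern) for c in df.columns]
        mat = cls(df, samples)
        logger.info("read %s: %d genes, %d samples", path, mat.n_genes, mat.n_samples)
        return mat

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t")

    # -- operations ------------------------------------------------------

    def average_replicates(self) -> "ExpressionMatrix":
        """Average available replicates into one column per (condition, ZT).

        Missing replicates are excluded from the denominator, so a
        (condition, ZT) cell with a single surviving replicate keeps that
        value unchanged.  The result carries replicate 1 as a placeholder key
        and the operation is idempotent.
        """
        groups: dict[tuple[str, int], list[int]] = {}
        for i, k in enumerate(self.samples):
            groups.setdefault((k.condition, k.zt), []).append(i)
        keys = sorted(groups, key=lambda ck: (CONDITIONS.index(ck[0]), ck[1]))
        cols = {}
        out_keys = []
        for cond, zt in keys:
            idx = groups[(cond, zt)]
            if not idx:  # pragma: no cover - cannot happen via construction
                raise ValueError(f"no replicates for ({cond}, ZT{zt})")
            key = SampleKey(cond, zt, 1)
            cols[key.label] = self.data.iloc[:, idx].mean(axis=1)
            out_keys.append(key)
        return ExpressionMatrix(pd.DataFrame(cols, index=self.data.index), out_keys)

    def series(self, gene_id: str, condition: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (times, values) for one gene under one condition, sorted by (zt, rep)."""
        idx = [
            i for i, k in enumerate(self.samples) if k.condition == condition
        ]
        idx.sort(key=lambda i: (self.samples[i].zt, self.samples[i].replicate))
        times = np.array([self.samples[i].zt for i in idx], dtype=float)
        values = self.data.loc[gene_id].to_numpy()[idx]
        return times, values

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"


# -- gene lists ----------------------------------------------------------


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-id-per-line gene list, skipping blank lines."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_gene_list(gene_ids: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in gene_ids))


# -- configuration -------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "filter": {"min_total_tpm": 5.0, "max_zero_fraction": 0.25},
    "rhythm": {"periods": [24.0], "alpha": 0.05, "per_gene_bonferroni": True},
    "compare": {"amp_threshold": 3.0, "phase_threshold": 2.0},
    "elements": {"promoter_length": 2000, "kmin": 3, "kmax": 8, "alpha": 0.05},
    "network": {
        "beta": {"WW": 7, "DR": 10},
        "merge_height": {"WW": 0.01, "DR": 0.15},
        "threshold": {"WW": 0.47, "DR": 0.52},
        "min_module_size": 10,
        "cut_height": 0.6,
        "dpi_tolerance": 0.1,
    },
}


def _deep_update(base: dict, overrides: Mapping) -> dict:
    out = dict(base)
    for k, v in overrides.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load analysis thresholds, overlaying a YAML file onto the defaults."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_update(cfg, user)
    return cfg
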