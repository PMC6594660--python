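"""Ground-truth generators: diel expression matrices, promoters, network samples.

Every downstream stage of the pipeline is exercised against data built here,
where the rhythmic class, phase, amplitude, planted motifs, or planted edges
of every gene are known exactly.  All generators are deterministic given a
seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import CONDITIONS, ExpressionMatrix, SampleKey

RHYTHM_CLASSES = ("WW_only", "DR_only", "both", "arrhythmic")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DielDesign:
    """Sampling design: ZT grid, photoperiod, replication, dropped samples.

    The default mirrors a 24-h course sampled every 2 h under a 12-h
    photoperiod with 3 biological replicates per timepoint and both
    conditions collected in parallel.
    """

    timepoints: tuple[int, ...] = tuple(range(0, 24, 2))
    photoperiod_hours: int = 12
    replicates: int = 3
    conditions: tuple[str, ...] = CONDITIONS
    missing: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        tps = self.timepoints
        if list(tps) != sorted(set(tps)) or any(not 0 <= t < 24 for t in tps):
            raise ValueError("timepoints must be strictly increasing and in [0, 24)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for cond, zt, rep in self.missing:
            if cond not in self.conditions or zt not in tps or not 1 <= rep <= self.replicates:
                raise ValueError(f"missing entry {(cond, zt, rep)} not in design")
        for cond in self.conditions:
            for zt in tps:
                dropped = sum(1 for c, z, _ in self.missing if (c, z) == (cond, zt))
                if dropped >= self.replicates:
                    raise ValueError(f"all replicates of ({cond}, ZT{zt}) dropped")

    def sample_keys(self) -> list[SampleKey]:
        gone = set(self.missing)
        return [
            SampleKey(cond, zt, rep)
            for cond in self.conditions
            for zt in self.timepoints
            for rep in range(1, self.replicates + 1)
            if (cond, zt, rep) not in gone
        ]


def study_design() -> DielDesign:
    """The study layout: WW ZT22 keeps 2 replicates and DR ZT0 keeps 1."""
    return DielDesign(missing=(("WW", 22, 3), ("DR", 0, 2), ("DR", 0, 3)))


@dataclass(frozen=True)
class GeneTruth:
    """True diel parameters of one synthetic gene under both conditions."""

    gene_id: str
    rhythm_class: str
    baseline_ww: float = 10.0
    baseline_dr: float = 10.0
    amplitude_ww: float = 0.0
    amplitude_dr: float = 0.0
    phase_ww: float = 0.0
    phase_dr: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.rhythm_class not in RHYTHM_CLASSES:
            raise ValueError(f"unknown rhythm class {self.rhythm_class!r}")
        for name in ("baseline_ww", "baseline_dr", "amplitude_ww", "amplitude_dr", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rhythm_class in ("DR_only", "arrhythmic") and self.amplitude_ww != 0:
            raise ValueError(f"{self.gene_id}: amplitude_ww must be 0 for class {self.rhythm_class}")
        if self.rhythm_class in ("WW_only", "arrhythmic") and self.amplitude_dr != 0:
            raise ValueError(f"{self.gene_id}: amplitude_dr must be 0 for class {self.rhythm_class}")

    def amplitude(self, condition: str) -> float:
        return self.amplitude_ww if condition == "WW" else self.amplitude_dr

    def baseline(self, condition: str) -> float:
        return self.baseline_ww if condition == "WW" else self.baseline_dr

    def phase(self, condition: str) -> float:
        return self.phase_ww if condition == "WW" else self.phase_dr


def generate_expression(
    design: DielDesign,
    truths: Sequence[GeneTruth],
    seed: int,
    noise: str = "normal",
) -> ExpressionMatrix:
    """Simulate a TPM matrix: baseline + amplitude*cos(2*pi*(t - phase)/24) + noise.

    Noise is additive Gaussian on the TPM scale, drawn independently per
    replicate and truncated at zero; ``noise="lognormal"`` switches to
    multiplicative lognormal noise with matched log-scale sd for
    heavier-tailed data.
    """
    if not truths:
        raise ValueError("truths must be non-empty")
    ids = [t.gene_id for t in truths]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene_ids in truths")
    if noise not in ("normal", "lognormal"):
        raise ValueError(f"unknown noise model {noise!r}")

    rng = np.random.default_rng(seed)
    keys = design.sample_keys()
    values = np.empty((len(truths), len(keys)))
    for i, t in enumerate(truths):
        for j, k in enumerate(keys):
            mean = t.baseline(k.condition) + t.amplitude(k.condition) * np.cos(
                2 * np.pi * (k.zt - t.phase(k.condition)) / 24.0
            )
            if t.noise_sd == 0:
                values[i, j] = max(0.0, mean)
            elif noise == "normal":
                values[i, j] = max(0.0, mean + rng.normal(0.0, t.noise_sd))
            else:
                sigma = np.sqrt(np.log1p((t.noise_sd / max(mean, 1e-9)) ** 2))
                values[i, j] = max(0.0, mean) * rng.lognormal(-sigma**2 / 2, sigma)
    df = pd.DataFrame(values, index=ids, columns=[k.label for k in keys])
    return ExpressionMatrix(df, keys)


# -- truth tables --------------------------------------------------------


def truths_to_frame(truths: Sequence[GeneTruth]) -> pd.DataFrame:
    return pd.DataFrame([vars(t) for t in truths]).set_index("gene_id")


def write_truths(truths: Sequence[GeneTruth], path: str | Path) -> None:
    truths_to_frame(truths).to_csv(path, sep="\t")


def read_truths(path: str | Path) -> list[GeneTruth]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [GeneTruth(gene_id=str(g), **row.to_dict()) for g, row in df.iterrows()]


def benchmark_truths(
    n_ww_only: int = 200,
    n_dr_only: int = 200,
    n_both: int = 300,
    n_shifted: int = 150,
    n_arrhythmic: int = 300,
    amplitude: float = 10.0,
    baseline: float = 20.0,
    noise_ratio: float = 1 / 3,
    seed: int = 0,
) -> list[GeneTruth]:
    """Category-recovery benchmark truth set.

    ``n_shifted`` of the ``n_both`` genes carry a 2-4 h phase shift between
    conditions (drawn on the 2-h grid); all rhythmic genes share one
    amplitude with ``noise_sd = noise_ratio * amplitude``.
    """
    if n_shifted > n_both:
        raise ValueError("n_shifted cannot exceed n_both")
    rng = np.random.default_rng(seed)
    sd = amplitude * noise_ratio
    grid = np.arange(0, 24, 2)
    truths: list[GeneTruth] = []

    def _phase() -> float:
        return float(rng.choice(grid))

    for i in range(n_ww_only):
        truths.append(GeneTruth(f"ww_{i:04d}", "WW_only", baseline, baseline,
                                amplitude, 0.0, _phase(), 0.0, sd))
    for i in range(n_dr_only):
        truths.append(GeneTruth(f"dr_{i:04d}", "DR_only", baseline, baseline,
                                0.0, amplitude, 0.0, _phase(), sd))
    for i in range(n_both):
        ph = _phase()
        shift = float(rng.choice([2, 4])) if i < n_shifted else 0.0
        truths.append(GeneTruth(f"bo_{i:04d}", "both", baseline, baseline,
                                amplitude, amplitude, ph, (ph + shift) % 24, sd))
    for i in range(n_arrhythmic):
        truths.append(GeneTruth(f"ar_{i:04d}", "arrhythmic", baseline, baseline,
                                0.0, 0.0, 0.0, 0.0, sd))
    return truths


# -- promoters -----------------------------------------------------------


@dataclass(frozen=True)
class PromoterTruth:
    """Planted motif layout of one synthetic promoter."""

    gene_id: str
    planted_motifs: tuple[tuple[str, int, str], ...] = ()

    def __post_init__(self) -> None:
        for motif, offset, strand in self.planted_motifs:
            if set(motif) - set("ACGT"):
                raise ValueError(f"motif {motif!r} not over A/C/G/T")
            if offset < 0:
                raise ValueError("motif offset must be >= 0")
            if strand not in "+-":
                raise ValueError(f"strand must be + or -, got {strand!r}")


def generate_promoters(
    truths: Sequence[PromoterTruth],
    length: int,
    gc: float,
    seed: int,
) -> dict[str, str]:
    """Generate promoter sequences with i.i.d. background of given GC content.

    Planted motifs overwrite the background at their stated offsets (reverse
    complemented on the minus strand).  Overlapping plantings that disagree
    on any base are rejected.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    longest = max((len(m) for t in truths for m, _, _ in t.planted_motifs), default=0)
    if length < longest:
        raise ValueError(f"length {length} shorter than longest planted motif ({longest})")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out: dict[str, str] = {}
    for t in truths:
        seq = rng.choice(np.array(list("ACGT")), size=length, p=p)
        placed: dict[int, str] = {}
        for motif, offset, strand in t.planted_motifs:
            if offset + len(motif) > length:
                raise ValueError(f"{t.gene_id}: motif {motif!r} at {offset} exceeds promoter")
            bases = motif if strand == "+" else reverse_complement(motif)
            for i, b in enumerate(bases):
                pos = offset + i
                if placed.get(pos, b) != b:
                    raise ValueError(f"{t.gene_id}: conflicting planted bases at offset {pos}")
                placed[pos] = b
                seq[pos] = b
        out[t.gene_id] = "".join(seq)
    return out


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# -- network-structured samples ------------------------------------------


def generate_network_data(
    n_genes: int,
    planted_edges: Iterable[tuple[str, str] | tuple[str, str, float]],
    n_samples: int,
    seed: int,
    rho: float = 0.9,
) -> pd.DataFrame:
    """Correlated Gaussian samples with planted partner pairs.

    Genes are ``g1 .. g<n>``.  Each planted edge ``(a, b)`` (optionally
    ``(a, b, rho_ab)``) makes the pair correlate at its generating ``rho``
    (``rho=1`` duplicates the partner exactly); correlation propagates along
    edge paths (a chain a-b-c yields corr(a, c) = rho**2), while unconnected
    pairs are independent.  Returns a genes x samples DataFrame.
    """
    if n_samples < 5:
        raise ValueError("n_samples must be >= 5")
    genes = [f"g{i + 1}" for i in range(n_genes)]
    known = set(genes)
    adj: dict[str, list[tuple[str, float]]] = {g: [] for g in genes}
    seen: set[frozenset[str]] = set()
    for edge in planted_edges:
        a, b = edge[0], edge[1]
        r = float(edge[2]) if len(edge) > 2 else rho
        if a not in known or b not in known:
            raise ValueError(f"edge ({a}, {b}) references unknown gene")
        if a == b or frozenset((a, b)) in seen:
            raise ValueError("planted edges must form a simple graph")
        if not -1 <= r <= 1:
            raise ValueError("generating correlation must be in [-1, 1]")
        seen.add(frozenset((a, b)))
        adj[a].append((b, r))
        adj[b].append((a, r))

    rng = np.random.default_rng(seed)
    values: dict[str, np.ndarray] = {}
    for root in genes:  # BFS per component; child = rho*parent + sqrt(1-rho^2)*eps
        if root in values:
            continue
        values[root] = rng.standard_normal(n_samples)
        queue = [root]
        while queue:
            u = queue.pop(0)
            for v, r in adj[u]:
                if v in values:
                    continue
                eps = rng.standard_normal(n_samples)
                values[v] = r * values[u] + np.sqrt(max(0.0, 1 - r * r)) * eps
                queue.append(v)
    return pd.DataFrame({g: values[g] for g in genes}).T.set_axis(genes, axis=0)
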