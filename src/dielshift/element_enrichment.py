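"""Promoter extraction, IUPAC motif scanning, and exhaustive k-mer enrichment.

The enrichment statistic is gene *presence* (does the promoter contain the
element at least once), tested one-sided against the background with the
hypergeometric distribution.  K-mers and their reverse complements are
collapsed to the lexicographically smaller canonical form, so scanning the
forward strand of a promoter covers both strands.  Raw ``p < alpha`` flags
an element enriched (matching ELEMENT-style workflows); Benjamini-Hochberg
q-values over the full tested family are emitted as an extra column.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, hypergeom

from .core_io import logger
from .synthetic_data import reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Known diel / stress cis-element catalog (IUPAC patterns).  The MYC2 site
#: has no unambiguous published consensus in this context; the G-box is used
#: as its default and can be overridden.
DEFAULT_CATALOG: dict[str, str] = {
    "ME": "CCACAC",
    "Gbox": "CACGTG",
    "EE": "AATATCT",
    "GATA": "GGATA",
    "TBX": "AAACCCT",
    "SBX": "AAGCCC",
    "PBX": "ATGGGCC",
    "ABRE": "YACGTGGC",
    "ABRE_like": "BACGTGKM",
    "MYB": "MACCWAMC",
    "MYC2": "CACGTG",
}


def iupac_to_regex(pattern: str) -> str:
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC symbol {ch!r} in pattern {pattern!r}")
        code = IUPAC[ch]
        parts.append(code if len(code) == 1 else f"[{code}]")
    return "".join(parts)


def iupac_reverse_complement(pattern: str) -> str:
    comp = {
        "A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
        "W": "W", "K": "M", "M": "K", "B": "V", "D": "H", "H": "D", "V": "B", "N": "N",
    }
    return "".join(comp[ch] for ch in reversed(pattern.upper()))


# -- promoter extraction -------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model: contig location and strand (0-based half-open)."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"{self.gene_id}: invalid coordinates [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")


def read_bed6(path: str | Path) -> list[GeneModel]:
    models = []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith(("#", "track", "browser")):
            continue
        f = ln.split("\t")
        models.append(GeneModel(f[3], f[0], int(f[1]), int(f[2]), f[5]))
    return models


def read_gff3(path: str | Path, feature: str = "gene") -> list[GeneModel]:
    """Parse gene features from GFF3 (1-based inclusive -> 0-based half-open)."""
    models = []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        f = ln.split("\t")
        if len(f) < 9 or f[2] != feature:
            continue
        attrs = dict(
            kv.split("=", 1) for kv in f[8].strip().split(";") if "=" in kv
        )
        gid = attrs.get("ID") or attrs.get("Name")
        if gid is None:
            raise ValueError(f"GFF3 feature without ID attribute: {ln!r}")
        models.append(GeneModel(gid, f[0], int(f[3]) - 1, int(f[4]), f[6]))
    return models


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def extract_promoters(
    genome: Mapping[str, str] | str | Path,
    models: Sequence[GeneModel],
    length: int = 2000,
) -> dict[str, str]:
    """Extract the ``length`` bases immediately upstream of each gene.

    Plus-strand genes take ``genome[start - length : start)``; minus-strand
    genes take the reverse complement of ``genome[end : end + length)``.
    ``genome`` may be an in-memory mapping contig -> sequence or a FASTA
    path (random access via a pyfaidx index).  Promoters are truncated at
    contig edges (logged); zero-length promoters are skipped with a warning.
    """
    if length not in (500, 1000, 2000):
        logger.warning("non-standard promoter length %d", length)
    if not isinstance(genome, Mapping):
        from pyfaidx import Fasta

        fa = Fasta(str(genome), sequence_always_upper=True)
        genome = {name: fa[name] for name in fa.keys()}
    out: dict[str, str] = {}
    for m in models:
        if m.contig not in genome:
            raise KeyError(f"contig {m.contig!r} for gene {m.gene_id!r} absent from genome")
        contig = genome[m.contig]
        if m.strand == "+":
            lo, hi = max(0, m.start - length), m.start
            seq = str(contig[lo:hi])
        else:
            lo, hi = m.end, min(len(contig), m.end + length)
            seq = reverse_complement(str(contig[lo:hi]))
        if len(seq) == 0:
            logger.warning("zero-length promoter for %s; skipped", m.gene_id)
            continue
        if len(seq) < length:
            logger.info("promoter of %s truncated to %d bp at contig edge", m.gene_id, len(seq))
        out[m.gene_id] = seq.upper()
    return out


# -- motif scanning ------------------------------------------------------


def scan_motif(
    promoters: Mapping[str, str],
    pattern: str,
    both_strands: bool = True,
) -> pd.Series:
    """Count motif sites per promoter (overlapping occurrences included).

    With ``both_strands`` the reverse-complement pattern is scanned too and
    sites are deduplicated by forward-strand position, so a palindromic site
    is counted once.
    """
    fwd = re.compile(f"(?=({iupac_to_regex(pattern)}))")
    patterns = [fwd]
    if both_strands:
        rc = iupac_reverse_complement(pattern)
        if rc != pattern.upper():
            patterns.append(re.compile(f"(?=({iupac_to_regex(rc)}))"))
    counts = {}
    for gene, seq in promoters.items():
        sites: set[int] = set()
        for pat in patterns:
            sites.update(m.start() for m in pat.finditer(seq))
        counts[gene] = len(sites)
    return pd.Series(counts, name=pattern, dtype=int)


def motif_presence(promoters: Mapping[str, str], pattern: str, both_strands: bool = True) -> pd.Series:
    return scan_motif(promoters, pattern, both_strands) >= 1


# -- k-mer enrichment ----------------------------------------------------


def canonical(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def canonical_kmers_present(seq: str, k: int) -> set[str]:
    """Canonical k-mers occurring in a sequence (either strand)."""
    seen: set[str] = set()
    for i in range(len(seq) - k + 1):
        sub = seq[i : i + k]
        if "N" in sub:
            continue
        seen.add(canonical(sub))
    return seen


def _hypergeom_table(
    fg_presence: Mapping[str, int],
    bg_presence: Mapping[str, int],
    fg_total: int,
    bg_total: int,
    alpha: float,
) -> pd.DataFrame:
    elements = sorted(bg_presence)
    rows = []
    for el in elements:
        kb = bg_presence[el]
        kf = fg_presence.get(el, 0)
        p = float(hypergeom.sf(kf - 1, bg_total, kb, fg_total))
        rows.append((el, kf, fg_total, kb, bg_total, p))
    df = pd.DataFrame(
        rows, columns=["element", "fg_hits", "fg_total", "bg_hits", "bg_total", "p_value"]
    ).set_index("element")
    df["q_value"] = false_discovery_control(df["p_value"].to_numpy()) if len(df) else []
    df["enriched"] = df["p_value"] < alpha
    return df.sort_values(["p_value", "element"], kind="stable")


def kmer_enrichment(
    fg: Iterable[str],
    bg: Iterable[str],
    promoters: Mapping[str, str],
    k_range: Sequence[int] = tuple(range(3, 9)),
    alpha: float = 0.05,
    allow_any_k: bool = False,
) -> pd.DataFrame:
    """Exhaustive canonical k-mer over-representation, foreground vs background.

    Tests gene presence with a one-sided hypergeometric per canonical k-mer
    over all k in ``k_range``; elements absent from every background
    promoter are excluded.  The table is sorted by p-value.
    """
    fg = set(fg)
    bg = set(bg)
    if not fg <= bg:
        raise ValueError("foreground must be a subset of background")
    missing = bg - set(promoters)
    if missing:
        raise ValueError(f"{len(missing)} background genes lack promoters")
    if not allow_any_k and any(k < 3 or k > 8 for k in k_range):
        raise ValueError("k must lie in 3..8 (set allow_any_k=True to override)")

    fg_counts: dict[str, int] = {}
    bg_counts: dict[str, int] = {}
    for gene in bg:
        seq = promoters[gene]
        in_fg = gene in fg
        for k in k_range:
            for el in canonical_kmers_present(seq, k):
                bg_counts[el] = bg_counts.get(el, 0) + 1
                if in_fg:
                    fg_counts[el] = fg_counts.get(el, 0) + 1
    return _hypergeom_table(fg_counts, bg_counts, len(fg), len(bg), alpha)


def catalog_enrichment(
    fg: Iterable[str],
    bg: Iterable[str],
    promoters: Mapping[str, str],
    catalog: Mapping[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Presence-based enrichment of the named motif catalog (IUPAC patterns)."""
    catalog = dict(DEFAULT_CATALOG if catalog is None else catalog)
    fg = set(fg)
    bg = set(bg)
    if not fg <= bg:
        raise ValueError("foreground must be a subset of background")
    fg_counts: dict[str, int] = {}
    bg_counts: dict[str, int] = {}
    for name, pattern in catalog.items():
        pres = motif_presence({g: promoters[g] for g in bg}, pattern)
        bg_counts[name] = int(pres.sum())
        fg_counts[name] = int(pres[pres.index.isin(fg)].sum())
    df = _hypergeom_table(fg_counts, bg_counts, len(fg), len(bg), alpha)
    df.insert(0, "pattern", [catalog[name] for name in df.index])
    return df


def category_element_profile(
    records: pd.DataFrame,
    promoters: Mapping[str, str],
    catalog: Mapping[str, str] | None = None,
    k_range: Sequence[int] = tuple(range(3, 9)),
    alpha: float = 0.05,
    min_category_size: int = 10,
) -> dict[str, dict[str, pd.DataFrame]]:
    """Per-category element annotation: k-mer plus catalog enrichment tables.

    ``records`` is the rhythm-change table (``category`` column); background
    is every record gene with a promoter.  Categories smaller than
    ``min_category_size`` are still computed but flagged underpowered in the
    log.
    """
    bg = [g for g in records.index if g in promoters]
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for cat, members in records.groupby("category").groups.items():
        fg = [g for g in members if g in promoters]
        if not fg:
            continue
        if len(fg) < min_category_size:
            logger.warning("category %s has only %d genes; enrichment underpowered", cat, len(fg))
        out[str(cat)] = {
            "kmer": kmer_enrichment(fg, bg, promoters, k_range, alpha),
            "catalog": catalog_enrichment(fg, bg, promoters, catalog, alpha),
        }
    return out


def phase_element_matrix(
    phases: pd.Series,
    promoters: Mapping[str, str],
    elements: Mapping[str, str] | None = None,
    n_phases: int = 24,
) -> pd.DataFrame:
    """-log10 p matrix of element presence enrichment per integer phase bin.

    Foreground at phase h is the set of genes peaking in bin h; background is
    every phased gene with a promoter.
    """
    elements = dict(DEFAULT_CATALOG if elements is None else elements)
    genes = [g for g in phases.index if g in promoters]
    bg = set(genes)
    bins = (np.floor(phases.loc[genes].astype(float)) % n_phases).astype(int)
    presence = {name: motif_presence({g: promoters[g] for g in genes}, pat) for name, pat in elements.items()}
    mat = np.ones((n_phases, len(elements)))
    for j, name in enumerate(elements):
        pres = presence[name]
        kb = int(pres.sum())
        for h in range(n_phases):
            fg = bins.index[bins == h]
            if len(fg) == 0:
                continue
            kf = int(pres.loc[fg].sum())
            mat[h, j] = float(hypergeom.sf(kf - 1, len(bg), kb, len(fg)))
    return pd.DataFrame(
        -np.log10(np.maximum(mat, 1e-300)),
        index=pd.Index(range(n_phases), name="phase"),
        columns=list(elements),
    )
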