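"""Codon-usage bias statistics: counts, RSCU, Wright's Nc, CA, preferred codons.

The stack mirrors the classical CodonW workflow: per-gene codon counts over
the 59 synonymously variable sense codons, relative synonymous codon usage,
Wright's effective number of codons against its GC3-driven null expectation,
a correspondence analysis of relative codon frequencies whose first axis
captures the GC3 gradient, and a preferred-codon (Fop) scan comparing usage
between genes at the two extremes of that axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .composition import gc_by_position
from .seqio import GeneticCode, standard_code

ALL_CODONS = tuple("".join(p) for p in product("TCAG", repeat=3))


def synonymous_families(code: GeneticCode | None = None) -> dict[str, tuple[str, ...]]:
    """Residue -> synonymous codon family, sense codons only."""
    code = code or standard_code()
    fams: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        aa = code.table[codon]
        if aa != "*":
            fams.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(cods)) for aa, cods in fams.items()}


def variable_sense_codons(code: GeneticCode | None = None) -> tuple[str, ...]:
    """The 59 sense codons belonging to families of size >= 2 (no Met/Trp)."""
    fams = synonymous_families(code)
    return tuple(
        c for aa, cods in sorted(fams.items()) if len(cods) > 1 for c in cods
    )


@dataclass(frozen=True)
class CodonCountTable:
    """Genes x 64 codon counts plus per-gene GC3."""

    counts: pd.DataFrame  # index = gene ids, columns = 64 codons
    gc3: pd.Series

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(ALL_CODONS):
            raise ValueError("count table must have the 64 codon columns in order")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative codon counts")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def pooled(self) -> pd.Series:
        return self.counts.sum(axis=0)


def count_codons(
    orfs: Mapping[str, str], code: GeneticCode | None = None
) -> tuple[CodonCountTable, dict[str, list[str]]]:
    """Count codons per in-frame ORF; returns the table and per-gene warnings.

    A terminal stop codon is excluded from the counts; an internal stop is
    skipped with a warning but the gene is retained.  Codons containing an
    ambiguity or gap are skipped and tallied in the warnings.
    """
    code = code or standard_code()
    stops = code.stop_codons
    rows = {}
    gc3 = {}
    warnings: dict[str, list[str]] = {}
    for gene, seq in orfs.items():
        seq = seq.upper()
        if len(seq) == 0:
            raise ValueError(f"gene {gene!r}: empty ORF")
        if len(seq) % 3 != 0:
            raise ValueError(f"gene {gene!r}: length {len(seq)} not divisible by 3")
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if codons and codons[-1] in stops:
            codons = codons[:-1]
        counts = dict.fromkeys(ALL_CODONS, 0)
        notes = []
        for k, c in enumerate(codons):
            if "N" in c or "-" in c:
                notes.append(f"ambiguous codon {c} at codon {k + 1} skipped")
                continue
            if c in stops:
                notes.append(f"internal stop {c} at codon {k + 1} skipped")
                continue
            counts[c] += 1
        rows[gene] = counts
        if notes:
            warnings[gene] = notes
        gc3[gene] = gc_by_position(seq).gc3
    table = pd.DataFrame.from_dict(rows, orient="index", dtype=int)[list(ALL_CODONS)]
    return CodonCountTable(counts=table, gc3=pd.Series(gc3)), warnings


def rscu(
    counts: pd.Series | pd.DataFrame, code: GeneticCode | None = None
) -> pd.Series | pd.DataFrame:
    """Relative synonymous codon usage: count * family size / family total.

    Families with zero total usage give NaN (undefined) rather than zero.
    Accepts a pooled 64-count Series or a genes x 64 DataFrame (row-wise).
    """
    if isinstance(counts, pd.DataFrame):
        return counts.apply(lambda row: rscu(row, code), axis=1)
    fams = synonymous_families(code)
    out = pd.Series(np.nan, index=list(ALL_CODONS))
    for cods in fams.values():
        total = sum(counts[c] for c in cods)
        if total > 0:
            for c in cods:
                out[c] = counts[c] * len(cods) / total
    return out


@dataclass(frozen=True)
class NcResult:
    nc: float | None  # None when undefined
    f_bar: dict[int, float]  # mean homozygosity per degeneracy class


def effective_number_of_codons(
    gene_counts: pd.Series | Mapping[str, int], code: GeneticCode | None = None
) -> NcResult:
    """Wright's effective number of codons for one gene.

    Per family, the codon homozygosity is F = (n*sum(p^2) - 1)/(n - 1) with n
    the family's codon count.  Families with n < 2 or F <= 0 are unusable and
    replaced by their degeneracy class mean; if a whole class has no usable
    family, Nc is undefined.  Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, capped at
    62.
    """
    fams = synonymous_families(code)
    class_f: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    class_sizes = {2: 9, 3: 1, 4: 5, 6: 3}
    n_any = 0
    for aa, cods in fams.items():
        k = len(cods)
        if k == 1:
            n_any += sum(int(gene_counts[c]) for c in cods)
            continue
        ns = np.array([int(gene_counts[c]) for c in cods])
        n = int(ns.sum())
        n_any += n
        if n < 2:
            continue
        p = ns / n
        f_hat = (n * float(p @ p) - 1) / (n - 1)
        if f_hat > 0:
            class_f[k].append(f_hat)
    if n_any == 0:
        raise ValueError("no sense codons in gene")
    f_bar = {}
    for k, fs in class_f.items():
        f_bar[k] = float(np.mean(fs)) if fs else np.nan
    if any(np.isnan(f_bar[k]) for k in class_sizes):
        return NcResult(nc=None, f_bar=f_bar)
    nc = 2 + 9 / f_bar[2] + 1 / f_bar[3] + 5 / f_bar[4] + 3 / f_bar[6]
    return NcResult(nc=min(float(nc), 62.0), f_bar=f_bar)


def nc_table(table: CodonCountTable, code: GeneticCode | None = None) -> pd.DataFrame:
    """Per-gene Nc and GC3 for every gene of a count table."""
    rows = {}
    for gene in table.genes:
        res = effective_number_of_codons(table.counts.loc[gene], code)
        rows[gene] = {"nc": res.nc if res.nc is not None else np.nan,
                      "gc3": float(table.gc3[gene])}
    return pd.DataFrame.from_dict(rows, orient="index")


def expected_nc(s: float) -> float:
    """Null Nc under pure GC3 mutational bias: 2 + s + 29/(s^2 + (1-s)^2)."""
    if not 0.0 < s < 1.0:
        raise ValueError(f"GC3 fraction s={s} must be strictly inside (0, 1)")
    return 2 + s + 29 / (s**2 + (1 - s) ** 2)


@dataclass(frozen=True)
class CAResult:
    """Correspondence analysis of the genes x codons relative-frequency table."""

    gene_coords: pd.DataFrame  # genes x axes
    codon_coords: pd.DataFrame  # codons x axes
    inertia_share: np.ndarray
    axis1_gc3_corr: float


def correspondence_analysis(
    table: CodonCountTable,
    codon_set: Sequence[str] | None = None,
    n_axes: int = 4,
) -> CAResult:
    """CA of codon usage via SVD of the standardized residual matrix.

    Operates on the 59 synonymously variable sense codons by default.  Genes
    and codons are placed in the same space (symmetric principal
    coordinates); axis 1 is oriented so that the gene coordinates correlate
    positively with gene GC3.
    """
    codon_set = tuple(codon_set) if codon_set is not None else variable_sense_codons()
    N = table.counts[list(codon_set)].astype(float)
    N = N.loc[N.sum(axis=1) > 0, N.columns[N.sum(axis=0) > 0]]
    if N.shape[0] < 2 or N.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 codons with nonzero usage")
    P = N.to_numpy() / N.to_numpy().sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sig, Vt = np.linalg.svd(S, full_matrices=False)
    rank = int((sig > 1e-12).sum())
    if rank == 0:
        k = min(n_axes, sig.size)
        zero_g = pd.DataFrame(np.zeros((N.shape[0], k)), index=N.index,
                              columns=[f"axis{i+1}" for i in range(k)])
        zero_c = pd.DataFrame(np.zeros((N.shape[1], k)), index=N.columns,
                              columns=zero_g.columns)
        return CAResult(zero_g, zero_c, np.zeros(k), 0.0)
    k = min(n_axes, rank)
    gene_xy = (U[:, :k] * sig[:k]) / np.sqrt(r)[:, None]
    codon_xy = (Vt.T[:, :k] * sig[:k]) / np.sqrt(c)[:, None]
    inertia = sig**2
    share = inertia[:k] / inertia.sum()
    gc3 = table.gc3.loc[N.index].to_numpy()
    if np.ptp(gc3) > 0 and np.ptp(gene_xy[:, 0]) > 0:
        corr = float(np.corrcoef(gene_xy[:, 0], gc3)[0, 1])
    else:
        corr = 0.0
    if corr < 0:  # orientation rule: high axis-1 end = high-GC3 end
        gene_xy[:, 0] *= -1
        codon_xy[:, 0] *= -1
        corr = -corr
    cols = [f"axis{i+1}" for i in range(k)]
    return CAResult(
        gene_coords=pd.DataFrame(gene_xy, index=N.index, columns=cols),
        codon_coords=pd.DataFrame(codon_xy, index=N.columns, columns=cols),
        inertia_share=share,
        axis1_gc3_corr=corr,
    )


@dataclass(frozen=True)
class FopSet:
    """Preferred codons with their per-codon enrichment test."""

    codons: tuple[str, ...]
    detail: pd.DataFrame  # per-codon usage in high/low sets, chi2, p, preferred
    n_high: int
    n_low: int

    @property
    def gc_ended(self) -> dict[str, bool]:
        return {c: c[2] in "GC" for c in self.codons}


def detect_preferred_codons(
    ca: CAResult,
    table: CodonCountTable,
    extreme_frac: float = 0.10,
    alpha: float = 0.01,
    code: GeneticCode | None = None,
) -> FopSet:
    """Preferred (Fop) codons from the two extremes of CA axis 1.

    Genes are ranked on axis 1 (high end = high-GC3/high-bias end under the
    orientation rule); pooled codon usage of the top ``extreme_frac`` genes
    is compared per codon against the bottom set with a 2x2 chi-square of
    codon-vs-rest-of-family counts.  A codon is preferred when significantly
    enriched in the high-bias set at ``alpha``.  Ranking ties at the extreme
    boundary are broken by gene id order.
    """
    # stable sort on (axis1, gene id) for deterministic boundary ties
    ranked = sorted(ca.gene_coords.index, key=lambda g: (ca.gene_coords.at[g, "axis1"], g))
    n_genes = len(ranked)
    n_ext = max(int(round(extreme_frac * n_genes)), 1)
    if n_ext < 2 or n_genes < 2 * n_ext:
        raise ValueError(f"fewer than 2 genes per extreme ({n_ext} of {n_genes})")
    low = table.counts.loc[ranked[:n_ext]].sum(axis=0)
    high = table.counts.loc[ranked[-n_ext:]].sum(axis=0)
    fams = synonymous_families(code)
    rows = []
    for aa, cods in sorted(fams.items()):
        if len(cods) < 2:
            continue
        fam_high = sum(int(high[c]) for c in cods)
        fam_low = sum(int(low[c]) for c in cods)
        for c in cods:
            h, l = int(high[c]), int(low[c])
            obs = np.array([[h, fam_high - h], [l, fam_low - l]])
            if obs.sum() == 0 or fam_high == 0 or fam_low == 0:
                stat, p = np.nan, np.nan
            elif (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
                stat, p = 0.0, 1.0
            else:
                stat, p, _, _ = chi2_contingency(obs, correction=False)
            enriched = fam_high > 0 and fam_low > 0 and h / fam_high > l / fam_low
            rows.append({
                "codon": c, "aa": aa, "high": h, "low": l,
                "high_frac": h / fam_high if fam_high else np.nan,
                "low_frac": l / fam_low if fam_low else np.nan,
                "chi2": stat, "p": p,
                "preferred": bool(enriched and p == p and p < alpha),
                "gc_ended": c[2] in "GC",
            })
    detail = pd.DataFrame(rows).set_index("codon")
    preferred = tuple(detail.index[detail["preferred"]])
    return FopSet(codons=preferred, detail=detail, n_high=n_ext, n_low=n_ext)
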