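"""Amino-acid composition profiles, hydrophobicity and GC indices.

The indices here are the classical descriptors used to compare proteomes of
thermophilic and mesophilic species: the OMH hydrophobic index W (a
frequency-weighted mean of the Sweet & Eisenberg optimal-matching
hydrophobicity scale), category fractions (charged / polar / hydrophobic,
GARP vs FYMINK, IVYWREL), the E+K/Q+H thermophily ratio, the aliphatic
index, and GC content split by codon position.  Uncertainty on any of them
comes from a codon-column bootstrap over the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .seqio import AMINO_ACIDS, CodonAlignment, ProteinAlignment, SequenceRecord

#: Sweet & Eisenberg OMH hydrophobicity scale (unitless, signed).
OMH_SCALE: dict[str, float] = {
    "D": -1.31, "E": -1.22, "N": -0.92, "Q": -0.91, "G": -0.67,
    "K": -0.67, "H": -0.64, "R": -0.59, "S": -0.55, "P": -0.49,
    "A": -0.40, "T": -0.28, "C": 0.17, "W": 0.50, "V": 0.91,
    "M": 1.02, "L": 1.22, "I": 1.25, "Y": 1.67, "F": 1.92,
}

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class EmptyProfileError(ValueError):
    """No countable residues in the input."""


class UndefinedRatio(Exception):
    """Signalled when a ratio's denominator is zero (not returned as inf)."""


@dataclass(frozen=True)
class ResidueCategories:
    """Named residue sets used by the composition indices.

    The charged/polar/hydrophobic partition is configurable; the default
    puts His with the charged residues and Gly with the polars.  GARP and
    FYMINK are fixed by their codon GC content (GC-rich vs AT-rich codons),
    and IVYWREL is the combination whose total frequency tracks prokaryote
    optimal growth temperature.
    """

    charged: frozenset[str] = frozenset("DEKRH")
    polar: frozenset[str] = frozenset("STNQYCWG")
    hydrophobic: frozenset[str] = frozenset("AVLIMFP")
    garp: frozenset[str] = frozenset("GARP")
    fymink: frozenset[str] = frozenset("FYMINK")
    ivywrel: frozenset[str] = frozenset("IVYWREL")
    ek: frozenset[str] = frozenset("EK")
    qh: frozenset[str] = frozenset("QH")
    #: aliphatic-index coefficients for Val and for Ile+Leu
    aliphatic_a: float = 2.9
    aliphatic_b: float = 3.9

    def __post_init__(self) -> None:
        if self.garp & self.fymink:
            raise ValueError("GARP and FYMINK must be disjoint")
        full = self.charged | self.polar | self.hydrophobic
        if full != frozenset(AMINO_ACIDS):
            raise ValueError("charged/polar/hydrophobic must partition the 20 residues")

    def named(self) -> dict[str, frozenset[str]]:
        return {
            "charged": self.charged, "polar": self.polar,
            "hydrophobic": self.hydrophobic, "garp": self.garp,
            "fymink": self.fymink, "ivywrel": self.ivywrel,
            "ek": self.ek, "qh": self.qh,
        }

    def category_of(self, aa: str) -> str:
        if aa in self.charged:
            return "charged"
        if aa in self.polar:
            return "polar"
        return "hydrophobic"


@dataclass(frozen=True)
class CompositionProfile:
    """Counts and frequencies over the 20 residues (X and gaps excluded)."""

    counts: np.ndarray
    n_sites: int
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (20,) or (counts < 0).any():
            raise ValueError("counts must be 20 nonnegative integers")
        if counts.sum() != self.n_sites:
            raise ValueError("counts must sum to n_sites")
        object.__setattr__(self, "counts", counts)

    @property
    def freqs(self) -> np.ndarray:
        if self.n_sites == 0:
            raise EmptyProfileError("profile has no countable residues")
        return self.counts / self.n_sites

    def freq(self, aa: str) -> float:
        return float(self.freqs[_AA_INDEX[aa]])

    def count(self, aa: str) -> int:
        return int(self.counts[_AA_INDEX[aa]])


@dataclass(frozen=True)
class GCProfile:
    gc12: float
    gc3: float
    gc_total: float
    n_codons: int

    def __post_init__(self) -> None:
        for name in ("gc12", "gc3", "gc_total"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def aa_frequencies(seq: str | SequenceRecord) -> CompositionProfile:
    """Residue counts/frequencies of one protein sequence.

    ``X`` and gaps are excluded from both the counts and the denominator.
    """
    s = seq.seq if isinstance(seq, SequenceRecord) else seq
    counts = np.zeros(20, dtype=int)
    for ch in s:
        idx = _AA_INDEX.get(ch)
        if idx is not None:
            counts[idx] += 1
    n = int(counts.sum())
    if n == 0:
        raise EmptyProfileError("no unambiguous residues in sequence")
    return CompositionProfile(counts=counts, n_sites=n)


def hydrophobic_index(
    profile: CompositionProfile, scale: Mapping[str, float] | None = None
) -> float:
    """OMH hydrophobic index W = sum over residues of freq * weight."""
    scale = OMH_SCALE if scale is None else scale
    weights = np.array([scale[aa] for aa in AMINO_ACIDS])
    return float(profile.freqs @ weights)


def category_fractions(
    profile: CompositionProfile, cats: ResidueCategories | None = None
) -> dict[str, float]:
    """Summed frequency of each named residue set."""
    cats = cats or ResidueCategories()
    freqs = profile.freqs
    return {
        name: float(sum(freqs[_AA_INDEX[aa]] for aa in members))
        for name, members in cats.named().items()
    }


def ekqh_ratio(profile: CompositionProfile) -> float:
    """(E+K)/(Q+H) count ratio; raises :class:`UndefinedRatio` on Q+H = 0."""
    num = profile.count("E") + profile.count("K")
    den = profile.count("Q") + profile.count("H")
    if den == 0:
        raise UndefinedRatio("Q+H count is zero; E+K/Q+H undefined")
    return num / den


def aliphatic_index(
    profile: CompositionProfile, cats: ResidueCategories | None = None
) -> float:
    """Aliphatic index: 100*(X_A + a*X_V + b*(X_I + X_L)), mole fractions."""
    cats = cats or ResidueCategories()
    f = profile.freqs
    return 100.0 * (
        f[_AA_INDEX["A"]]
        + cats.aliphatic_a * f[_AA_INDEX["V"]]
        + cats.aliphatic_b * (f[_AA_INDEX["I"]] + f[_AA_INDEX["L"]])
    )


def gc_by_position(seq: str, stop_codons: frozenset[str] = frozenset({"TAA", "TAG", "TGA"})) -> GCProfile:
    """GC fraction at third vs first+second codon positions of an in-frame ORF.

    Gap codons and stop codons are dropped; ambiguous bases (``N``) are
    excluded from both numerator and denominator position-wise.
    """
    codons = [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
    codons = [c for c in codons if "-" not in c and c not in stop_codons]
    if not codons:
        raise EmptyProfileError("no valid codons for GC computation")
    gc = set("GC")
    n12 = gc12 = n3 = gc3 = 0
    for c in codons:
        for base in c[:2]:
            if base != "N":
                n12 += 1
                gc12 += base in gc
        if c[2] != "N":
            n3 += 1
            gc3 += c[2] in gc
    if n12 == 0 or n3 == 0:
        raise EmptyProfileError("all bases ambiguous")
    return GCProfile(
        gc12=gc12 / n12,
        gc3=gc3 / n3,
        gc_total=(gc12 + gc3) / (n12 + n3),
        n_codons=len(codons),
    )


def bootstrap_sd(
    aln: CodonAlignment | ProteinAlignment,
    statistic: Callable[[CodonAlignment | ProteinAlignment], Mapping[str, float]],
    reps: int = 100,
    seed: int = 0,
    max_skip_frac: float = 0.10,
) -> dict[str, float]:
    """Column-bootstrap standard deviation of a per-taxon statistic.

    Codon (or residue) columns are resampled with replacement alignment-wide,
    so all taxa share each replicate's column draw and stay paired.
    ``statistic`` maps an alignment to ``{taxon: value}``.  Replicates on
    which the statistic fails are skipped and counted; more than
    ``max_skip_frac`` skipped replicates is an error.
    """
    if reps < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    is_codon = isinstance(aln, CodonAlignment)
    if is_codon:
        cols = np.flatnonzero(aln.column_mask)
        unit = 3
    else:
        cols = np.arange(aln.n_sites)
        unit = 1
    if cols.size == 0:
        raise ValueError("alignment has no retained columns")

    values: dict[str, list[float]] = {}
    skipped = 0
    for _ in range(reps):
        draw = rng.choice(cols, size=cols.size, replace=True)
        recs = []
        for rec in aln.records:
            pieces = [rec.seq[unit * k : unit * (k + 1)] for k in draw]
            recs.append(
                SequenceRecord(id=rec.id, species=rec.species,
                               seq="".join(pieces), alphabet=rec.alphabet)
            )
        rep_aln = (
            CodonAlignment(records=tuple(recs)) if is_codon
            else ProteinAlignment(records=tuple(recs))
        )
        try:
            stat = statistic(rep_aln)
        except Exception:
            skipped += 1
            continue
        for taxon, val in stat.items():
            values.setdefault(taxon, []).append(float(val))
    if skipped > max_skip_frac * reps:
        raise RuntimeError(f"{skipped}/{reps} bootstrap replicates failed")
    return {taxon: float(np.std(vals, ddof=1)) for taxon, vals in values.items()}
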