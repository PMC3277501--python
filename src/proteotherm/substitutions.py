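"""Directed amino-acid replacement extraction and directionality tests.

Given pairwise ortholog alignments between a donor species and a focal
species, this module builds the 20x20 table of oriented replacements and runs
three tests: a per-residue one-tailed binomial test of gains vs losses (no
net directional replacement under the null), a comparison of the oriented
replacement distribution against a symmetric neutral expectation derived
from the WAG exchangeability matrix weighted by the observed residue
frequencies, and a z-score outlier scan over the 380 directed replacement
classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest, chi2, norm

from . import _wag
from .composition import aa_frequencies, ekqh_ratio
from .seqio import AMINO_ACIDS, ProteinAlignment

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class DirectedSubstitutionTable:
    """M[i, j] = count of donor residue i replaced by focal residue j."""

    matrix: np.ndarray  # 20x20 int, zero diagonal, indexed by AMINO_ACIDS
    donor: str
    focal: str
    n_sites: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=int)
        if m.shape != (20, 20) or (np.diag(m) != 0).any() or (m < 0).any():
            raise ValueError("matrix must be 20x20, nonnegative, zero diagonal")
        if m.sum() > self.n_sites:
            raise ValueError("more differences than compared sites")
        object.__setattr__(self, "matrix", m)

    @property
    def n_diff(self) -> int:
        return int(self.matrix.sum())

    def count(self, donor_aa: str, focal_aa: str) -> int:
        return int(self.matrix[_AA_INDEX[donor_aa], _AA_INDEX[focal_aa]])

    def transpose(self) -> "DirectedSubstitutionTable":
        return DirectedSubstitutionTable(
            matrix=self.matrix.T.copy(), donor=self.focal, focal=self.donor,
            n_sites=self.n_sites,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(AMINO_ACIDS),
                            columns=list(AMINO_ACIDS))


@dataclass(frozen=True)
class WAGModel:
    """Symmetric exchangeability matrix S and equilibrium frequencies pi."""

    s: np.ndarray
    pi: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        pi = np.asarray(self.pi, dtype=float)
        if s.shape != (20, 20) or not np.allclose(s, s.T):
            raise ValueError("S must be symmetric 20x20")
        if (s < 0).any():
            raise ValueError("S entries must be nonnegative")
        if pi.shape != (20,) or not np.isclose(pi.sum(), 1.0):
            raise ValueError("pi must be 20 frequencies summing to 1")
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "pi", pi)

    @classmethod
    def bundled(cls) -> "WAGModel":
        """The published WAG matrix reordered to this package's residue order."""
        order = [_wag.WAG_ORDER.index(aa) for aa in AMINO_ACIDS]
        s = _wag.exchangeability_matrix()[np.ix_(order, order)]
        pi = _wag.equilibrium_frequencies()[order]
        return cls(s=s, pi=pi)


def extract_directed(
    pairs: Sequence[ProteinAlignment], donor: str, focal: str
) -> DirectedSubstitutionTable:
    """Oriented replacement counts pooled over per-gene pairwise alignments.

    Positions where either residue is a gap or ``X`` are excluded from the
    site count; positions where both are unambiguous and differ increment
    M[donor residue, focal residue].
    """
    m = np.zeros((20, 20), dtype=int)
    n_sites = 0
    for gi, aln in enumerate(pairs):
        try:
            d_rec = aln.by_species(donor)
            f_rec = aln.by_species(focal)
        except KeyError as exc:
            raise KeyError(f"gene {gi + 1}: {exc.args[0]}") from exc
        for a, b in zip(d_rec.seq, f_rec.seq):
            ia = _AA_INDEX.get(a)
            ib = _AA_INDEX.get(b)
            if ia is None or ib is None:
                continue
            n_sites += 1
            if ia != ib:
                m[ia, ib] += 1
    return DirectedSubstitutionTable(matrix=m, donor=donor, focal=focal, n_sites=n_sites)


def protein_divergence(table: DirectedSubstitutionTable) -> float:
    """Percent of compared positions at which the two species differ."""
    if table.n_sites == 0:
        raise ValueError("no compared sites")
    return 100.0 * table.n_diff / table.n_sites


@dataclass(frozen=True)
class BinomialReport:
    table: pd.DataFrame  # per residue: gains, losses, net, p, significant, tested
    alpha: float

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def residue_direction_binomial(
    table: DirectedSubstitutionTable, alpha: float = 0.05
) -> BinomialReport:
    """Per-residue one-tailed binomial test of gains against losses.

    Under no directional replacement each substitution touching residue a is
    equally likely a gain or a loss, so gains ~ Binomial(gains+losses, 1/2).
    The test is one-tailed in the direction of the observed excess; residues
    with no substitutions are reported untested.
    """
    gains = table.matrix.sum(axis=0)
    losses = table.matrix.sum(axis=1)
    rows = {}
    for i, aa in enumerate(AMINO_ACIDS):
        g, l = int(gains[i]), int(losses[i])
        n = g + l
        if n == 0:
            rows[aa] = {"gains": g, "losses": l, "net": 0, "p": np.nan,
                        "direction": "none", "significant": False, "tested": False}
            continue
        direction = "gain" if g >= l else "loss"
        k = max(g, l)
        p = float(binomtest(k, n, 0.5, alternative="greater").pvalue)
        rows[aa] = {"gains": g, "losses": l, "net": g - l, "p": p,
                    "direction": direction, "significant": bool(p < alpha),
                    "tested": True}
    return BinomialReport(
        table=pd.DataFrame.from_dict(rows, orient="index"), alpha=alpha
    )


def wag_expected(
    table: DirectedSubstitutionTable, model: WAGModel | None = None,
    pi: np.ndarray | None = None,
) -> np.ndarray:
    """Neutral expected directed replacement counts from the WAG matrix.

    The unnormalized weight of i -> j is pi_i * S[i, j] * pi_j (symmetric, so
    the null predicts no directional asymmetry); weights are scaled so the
    expected counts sum to the observed number of replacements.  By default
    pi is *not* the WAG equilibrium but the mean of the two species' observed
    residue frequencies implied by the substitution table's margins; pass
    ``pi`` to override.
    """
    model = model or WAGModel.bundled()
    if pi is None:
        pi = observed_pi(table)
    w = np.outer(pi, pi) * model.s
    np.fill_diagonal(w, 0.0)
    total = w.sum()
    if total == 0:
        raise ValueError("degenerate model: all weights zero")
    return w * (table.n_diff / total)


def observed_pi(table: DirectedSubstitutionTable) -> np.ndarray:
    """Mean residue frequencies of the two species from the table margins.

    The substitution table alone does not carry the frequencies of conserved
    residues, so this is only a fallback; prefer passing frequencies computed
    from the alignments via :func:`mean_pi_from_alignments`.
    """
    gains = table.matrix.sum(axis=0)
    losses = table.matrix.sum(axis=1)
    tot = gains + losses
    if tot.sum() == 0:
        return np.full(20, 1 / 20)
    return tot / tot.sum()


def mean_pi_from_alignments(
    pairs: Sequence[ProteinAlignment], donor: str, focal: str
) -> np.ndarray:
    """Unweighted mean of the two species' residue frequencies over all genes."""
    d_counts = np.zeros(20)
    f_counts = np.zeros(20)
    for aln in pairs:
        d_counts += aa_frequencies(aln.by_species(donor)).counts
        f_counts += aa_frequencies(aln.by_species(focal)).counts
    return (d_counts / d_counts.sum() + f_counts / f_counts.sum()) / 2


@dataclass(frozen=True)
class OutlierReport:
    table: pd.DataFrame  # per directed pair: observed, expected, diff, z, flagged
    chi2_stat: float
    chi2_df: int
    chi2_p: float
    threshold: float

    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["flagged"]]


def neutrality_outliers(
    obs: DirectedSubstitutionTable,
    expected: np.ndarray,
    threshold: float = 0.05,
    pool_floor: float = 1.0,
    directed: bool = True,
) -> OutlierReport:
    """Replacement classes departing from the symmetric neutral expectation.

    The differences d = observed - expected over the 380 directed cells (or
    190 unordered cells with ``directed=False``) are standardized by their
    empirical mean and SD; cells with |z| above the two-sided normal quantile
    for ``threshold`` are flagged.  A global chi-square compares observed and
    expected counts, pooling cells with expected < ``pool_floor`` into one
    remainder cell, on pooled-cells - 1 degrees of freedom.
    """
    exp = np.asarray(expected, dtype=float)
    if exp.shape != (20, 20):
        raise ValueError("expected matrix must be 20x20")
    rows = []
    if directed:
        cells = [(i, j) for i in range(20) for j in range(20) if i != j]
        get_obs = lambda i, j: obs.matrix[i, j]
        get_exp = lambda i, j: exp[i, j]
    else:
        cells = [(i, j) for i in range(20) for j in range(i + 1, 20)]
        get_obs = lambda i, j: obs.matrix[i, j] + obs.matrix[j, i]
        get_exp = lambda i, j: exp[i, j] + exp[j, i]
    o = np.array([get_obs(i, j) for i, j in cells], dtype=float)
    e = np.array([get_exp(i, j) for i, j in cells], dtype=float)
    d = o - e
    sd = d.std(ddof=1)
    if sd == 0:
        z = np.zeros_like(d)
    else:
        z = (d - d.mean()) / sd
    crit = norm.ppf(1 - threshold / 2)
    flagged = np.abs(z) > crit if sd > 0 else np.zeros(len(cells), dtype=bool)
    for (i, j), oo, ee, dd, zz, fl in zip(cells, o, e, d, z, flagged):
        pair = f"{AMINO_ACIDS[i]}->{AMINO_ACIDS[j]}" if directed else \
            f"{AMINO_ACIDS[i]}<->{AMINO_ACIDS[j]}"
        rows.append({"pair": pair, "observed": oo, "expected": ee,
                     "difference": dd, "z": zz, "flagged": bool(fl)})
    # global chi-square with pooling of sparse cells
    small = e < pool_floor
    o_used = list(o[~small])
    e_used = list(e[~small])
    if small.any():
        o_used.append(o[small].sum())
        e_used.append(e[small].sum())
    o_used = np.array(o_used)
    e_used = np.array(e_used)
    keep = e_used > 0
    stat = float(((o_used[keep] - e_used[keep]) ** 2 / e_used[keep]).sum())
    df = int(keep.sum()) - 1
    p = float(chi2.sf(stat, df)) if df > 0 else np.nan
    return OutlierReport(
        table=pd.DataFrame(rows).set_index("pair"),
        chi2_stat=stat, chi2_df=df, chi2_p=p, threshold=threshold,
    )


def ekqh_shift(
    pairs: Sequence[ProteinAlignment], donor: str, focal: str
) -> tuple[float, float]:
    """(E+K)/(Q+H) ratio of each species over the same gene set."""
    d_counts = np.zeros(20, dtype=int)
    f_counts = np.zeros(20, dtype=int)
    for aln in pairs:
        d_counts += aa_frequencies(aln.by_species(donor)).counts
        f_counts += aa_frequencies(aln.by_species(focal)).counts
    from .composition import CompositionProfile

    d_ratio = ekqh_ratio(CompositionProfile(counts=d_counts, n_sites=int(d_counts.sum())))
    f_ratio = ekqh_ratio(CompositionProfile(counts=f_counts, n_sites=int(f_counts.sum())))
    return d_ratio, f_ratio
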