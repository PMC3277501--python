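"""Synthetic inputs with known truth for every pipeline stage.

Three generators cover the three input classes the analyses consume:

* ortholog codon-sequence pairs evolved from a common ancestor under a
  WAG-proportional amino-acid Markov process, with a tunable GC3 target for
  codon assignment and a tunable 20x20 directional bias matrix ``beta``
  applied to the focal lineage (so a planted V->A excess can be recovered by
  the directionality tests);
* multi-taxon codon datasets whose amino-acid composition trades GARP for
  FYMINK linearly along a GC3 gradient, optionally with a planted
  Arg/Pro-inflated outlier taxon;
* ideal poly-alanine alpha-helix coordinate models for the ASA stage.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import AMINO_ACIDS, CodonAlignment, SequenceRecord, standard_code
from .structure import ONE_TO_THREE, Residue, AtomRecord, StructureModel, VDW_RADII, write_pdb
from .substitutions import WAGModel

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def _codon_partition() -> dict[str, tuple[list[str], list[str]]]:
    """aa -> (GC-ended synonyms, AT-ended synonyms) under the universal code."""
    code = standard_code()
    out: dict[str, tuple[list[str], list[str]]] = {}
    for codon, aa in code.table.items():
        if aa == "*":
            continue
        gc, at = out.setdefault(aa, ([], []))
        (gc if codon[2] in "GC" else at).append(codon)
    return {aa: (sorted(gc), sorted(at)) for aa, (gc, at) in out.items()}


_PARTITION = _codon_partition()


def _assign_codons(aa_indices: np.ndarray, gc3_target: float,
                   rng: np.random.Generator) -> list[str]:
    """Codon per residue, third position GC with probability ``gc3_target``."""
    use_gc = rng.random(aa_indices.size) < gc3_target
    pick = rng.random(aa_indices.size)
    codons = []
    for idx, g, u in zip(aa_indices, use_gc, pick):
        gc, at = _PARTITION[AMINO_ACIDS[idx]]
        pool = gc if (g and gc) or not at else at
        codons.append(pool[int(u * len(pool))])
    return codons


@dataclass(frozen=True)
class PairSimConfig:
    """Study conditions for one simulated ortholog pair.

    ``length`` is in codons; ``rate`` is the per-site substitution
    probability on each lineage (the default yields an inter-species protein
    divergence of about 7%, the scale observed between closely related
    congeneric species); ``beta[i, j]`` multiplies the i->j replacement rate
    on the focal lineage only.
    """

    length: int = 120
    gc3_target: float = 0.5
    rate: float = 0.036
    beta: np.ndarray | None = None
    seed: int = 0
    donor: str = "donor"
    focal: str = "focal"

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be nonnegative")
        beta = self.beta
        if beta is None:
            beta = np.ones((20, 20))
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (20, 20) or (beta < 0).any():
            raise ValueError("beta must be a nonnegative 20x20 matrix")
        object.__setattr__(self, "beta", beta)


@dataclass(frozen=True)
class TruthRecord:
    """Generator-recorded ground truth for one emitted pair."""

    directed_counts: np.ndarray  # donor residue -> focal residue, 20x20
    n_sites: int
    gc3_donor: float
    gc3_focal: float
    beta: np.ndarray
    seed: int


def _evolve(states: np.ndarray, rate: float, cond: np.ndarray,
            rate_scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One lineage of amino-acid evolution; at most one change per site."""
    out = states.copy()
    p_sub = np.clip(rate * rate_scale[states], 0.0, 1.0)
    hit = rng.random(states.size) < p_sub
    idx = np.flatnonzero(hit)
    if idx.size:
        u = rng.random(idx.size)
        cdf = np.cumsum(cond[states[idx]], axis=1)
        out[idx] = (u[:, None] > cdf).sum(axis=1)
    return out


def simulate_ortholog_pair(cfg: PairSimConfig) -> tuple[CodonAlignment, TruthRecord]:
    """Evolve a donor/focal codon-sequence pair from a common ancestor.

    The ancestor amino-acid sequence is drawn from the WAG equilibrium; each
    lineage substitutes each site independently with probability
    ``cfg.rate`` (scaled on the focal lineage by the relative total outflow
    under ``beta``), targets drawn proportional to S[i, j] * pi_j (times
    beta[i, j] on the focal lineage).  Codons are then assigned to match
    ``gc3_target``, sharing the ancestral codon at sites where a lineage did
    not change.  The truth record holds the realized donor->focal directed
    difference counts, which equal what table extraction recovers from the
    emitted pair.
    """
    rng = np.random.default_rng(cfg.seed)
    model = WAGModel.bundled()
    w_neutral = model.s * model.pi[None, :]
    np.fill_diagonal(w_neutral, 0.0)
    w_focal = w_neutral * cfg.beta
    rows_neutral = w_neutral.sum(axis=1)
    rows_focal = w_focal.sum(axis=1)
    cond_neutral = w_neutral / rows_neutral[:, None]
    cond_focal = w_focal / np.where(rows_focal > 0, rows_focal, 1.0)[:, None]

    anc = rng.choice(20, size=cfg.length, p=model.pi)
    donor = _evolve(anc, cfg.rate, cond_neutral, np.ones(20), rng)
    focal = _evolve(anc, cfg.rate, cond_focal, rows_focal / rows_neutral, rng)

    anc_codons = _assign_codons(anc, cfg.gc3_target, rng)
    donor_codons = list(anc_codons)
    focal_codons = list(anc_codons)
    for k in np.flatnonzero(donor != anc):
        donor_codons[k] = _assign_codons(donor[k : k + 1], cfg.gc3_target, rng)[0]
    for k in np.flatnonzero(focal != anc):
        focal_codons[k] = _assign_codons(focal[k : k + 1], cfg.gc3_target, rng)[0]

    counts = np.zeros((20, 20), dtype=int)
    diff = donor != focal
    np.add.at(counts, (donor[diff], focal[diff]), 1)

    def gc3_of(codons: list[str]) -> float:
        return sum(c[2] in "GC" for c in codons) / len(codons)

    aln = CodonAlignment(records=(
        SequenceRecord(id=cfg.donor, species=cfg.donor,
                       seq="".join(donor_codons), alphabet="nucleotide"),
        SequenceRecord(id=cfg.focal, species=cfg.focal,
                       seq="".join(focal_codons), alphabet="nucleotide"),
    ))
    truth = TruthRecord(directed_counts=counts, n_sites=cfg.length,
                        gc3_donor=gc3_of(donor_codons), gc3_focal=gc3_of(focal_codons),
                        beta=cfg.beta, seed=cfg.seed)
    return aln, truth


def simulate_pair_set(
    n_genes: int = 335,
    total_codons: int = 40338,
    gc3_range: tuple[float, float] = (0.2, 0.8),
    rate: float = 0.036,
    beta: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[list[CodonAlignment], TruthRecord]:
    """A study-scale set of ortholog pairs (defaults: 335 genes, 40338 codons).

    Per-gene GC3 targets are evenly spread over ``gc3_range`` so codon-usage
    analyses see a GC3 gradient across genes.  Returns the per-gene pair
    alignments and the pooled truth record.
    """
    lengths = np.full(n_genes, total_codons // n_genes)
    lengths[: total_codons % n_genes] += 1
    gc3s = np.linspace(gc3_range[0], gc3_range[1], n_genes)
    rng = np.random.default_rng(seed)
    pairs = []
    pooled = np.zeros((20, 20), dtype=int)
    gc_d = gc_f = 0.0
    for g, (length, gc3) in enumerate(zip(lengths, gc3s)):
        cfg = PairSimConfig(length=int(length), gc3_target=float(gc3), rate=rate,
                            beta=beta, seed=int(rng.integers(2**31 - 1)))
        aln, truth = simulate_ortholog_pair(cfg)
        pairs.append(aln)
        pooled += truth.directed_counts
        gc_d += truth.gc3_donor * length
        gc_f += truth.gc3_focal * length
    truth = TruthRecord(directed_counts=pooled, n_sites=int(lengths.sum()),
                        gc3_donor=gc_d / lengths.sum(), gc3_focal=gc_f / lengths.sum(),
                        beta=np.ones((20, 20)) if beta is None else np.asarray(beta),
                        seed=seed)
    return pairs, truth


def bias_matrix(multipliers: dict[tuple[str, str], float]) -> np.ndarray:
    """A beta matrix from {(from_res, to_res): multiplier} (one-letter codes)."""
    beta = np.ones((20, 20))
    for (a, b), m in multipliers.items():
        beta[_AA_INDEX[a], _AA_INDEX[b]] = m
    return beta


#: Directed replacements characteristic of a thermophile-shifted proteome:
#: gains of Ala/Ile/Lys/Tyr/Pro fed by losses of Val, Met, Gly, Gln (and the
#: small polars), the pattern the directionality tests are designed to detect.
THERMOPHILE_SHIFT_PAIRS: tuple[tuple[str, str], ...] = (
    ("V", "A"), ("S", "A"), ("G", "A"), ("T", "A"),
    ("M", "I"), ("V", "I"), ("Q", "K"), ("F", "Y"), ("S", "P"),
)


def thermophile_shift_bias(strength: float = 10.0) -> np.ndarray:
    """Beta matrix planting the thermophile-shifted replacement pattern.

    ``strength`` multiplies each focal-lineage rate in
    :data:`THERMOPHILE_SHIFT_PAIRS`; the default is large enough that a
    single study-scale pair set recovers every planted direction.
    """
    return bias_matrix({pair: strength for pair in THERMOPHILE_SHIFT_PAIRS})


@dataclass(frozen=True)
class TaxonSetTruth:
    gc3: dict[str, float]
    outlier: str | None


def simulate_taxon_compositions(
    n_taxa: int = 11,
    gc3_range: tuple[float, float] = (0.25, 0.75),
    n_codons: int = 5991,
    outlier: bool = False,
    outlier_boost: float = 1.6,
    trade_strength: float = 0.8,
    seed: int = 0,
) -> tuple[dict[str, str], TaxonSetTruth]:
    """Per-taxon codon sequences with a GARP-up / FYMINK-down GC3 gradient.

    Taxa are placed evenly along ``gc3_range``; a taxon's amino-acid
    frequencies are the WAG equilibrium with GARP residues scaled up and
    FYMINK residues scaled down linearly in GC3 (``trade_strength`` sets the
    slope), then renormalized.  With ``outlier=True`` an extra taxon at
    mid-range GC3 has its Arg and Pro frequencies multiplied by
    ``outlier_boost`` — the planted composition outlier the CI-band outlier
    test must recover.  The default sizes match an 11-taxon, 5991-codon
    ribosomal-protein concatenate.
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    rng = np.random.default_rng(seed)
    model = WAGModel.bundled()
    garp = [_AA_INDEX[a] for a in "GARP"]
    fymink = [_AA_INDEX[a] for a in "FYMINK"]
    gc3s = np.linspace(gc3_range[0], gc3_range[1], n_taxa)
    mid = float(np.mean(gc3_range))
    seqs: dict[str, str] = {}
    truth_gc3: dict[str, float] = {}

    def taxon_seq(name: str, gc3: float, boost_rp: float = 1.0) -> None:
        freqs = model.pi.copy()
        delta = trade_strength * (gc3 - mid)
        freqs[garp] *= 1.0 + delta
        freqs[fymink] *= 1.0 - delta
        if boost_rp != 1.0:
            freqs[_AA_INDEX["R"]] *= boost_rp
            freqs[_AA_INDEX["P"]] *= boost_rp
        freqs = np.clip(freqs, 1e-6, None)
        freqs /= freqs.sum()
        aa = rng.choice(20, size=n_codons, p=freqs)
        seqs[name] = "".join(_assign_codons(aa, gc3, rng))
        truth_gc3[name] = gc3

    for t, gc3 in enumerate(gc3s):
        taxon_seq(f"taxon{t + 1:02d}", float(gc3))
    outlier_name = None
    if outlier:
        outlier_name = "outlierRP"
        taxon_seq(outlier_name, mid, boost_rp=outlier_boost)
    return seqs, TaxonSetTruth(gc3=truth_gc3, outlier=outlier_name)


# --- ideal helix ----------------------------------------------------------

_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "CA-CB": 1.521}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7,
          "CA-C-O": 120.8, "N-CA-CB": 110.4}


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D from three reference atoms and internal coordinates."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = bond * np.array([
        -np.cos(angle),
        np.sin(angle) * np.cos(dihedral),
        np.sin(angle) * np.sin(dihedral),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def make_ideal_helix(n_residues: int, residue_type: str = "A",
                     phi: float = -57.0, psi: float = -47.0) -> StructureModel:
    """Poly-residue alpha-helix built at canonical backbone dihedrals.

    Backbone (N, CA, C, O and CB for non-Gly) at ideal bond lengths/angles
    with phi = -57 deg, psi = -47 deg, omega = 180 deg, giving consecutive
    CA-CA distances of ~3.8 Å.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    res3 = ONE_TO_THREE[residue_type] if len(residue_type) == 1 else residue_type
    coords: list[dict[str, np.ndarray]] = []
    # seed residue
    n0 = np.zeros(3)
    ca0 = np.array([_BOND["N-CA"], 0.0, 0.0])
    ang = np.deg2rad(_ANGLE["N-CA-C"])
    c0 = ca0 + _BOND["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n_residues):
        prev = coords[-1]
        n = _nerf(prev["N"], prev["CA"], prev["C"],
                  _BOND["C-N"], _ANGLE["CA-C-N"], psi)
        ca = _nerf(prev["CA"], prev["C"], n,
                   _BOND["N-CA"], _ANGLE["C-N-CA"], 180.0)  # omega
        c = _nerf(prev["C"], n, ca, _BOND["CA-C"], _ANGLE["N-CA-C"], phi)
        coords.append({"N": n, "CA": ca, "C": c})
    # carbonyl O and CB, placed after the chain so every residue has a successor ref
    for i, res in enumerate(coords):
        if i + 1 < len(coords):
            nxt = coords[i + 1]["N"]
            res["O"] = _nerf(nxt, res["CA"], res["C"],
                             _BOND["C-O"], _ANGLE["CA-C-O"], 180.0)
        else:
            res["O"] = _nerf(res["N"], res["CA"], res["C"],
                             _BOND["C-O"], _ANGLE["CA-C-O"], psi + 180.0)
        if res3 != "GLY":
            res["CB"] = _nerf(res["C"], res["N"], res["CA"],
                              _BOND["CA-CB"], _ANGLE["N-CA-CB"], 122.6)
    residues = []
    for i, res in enumerate(coords, start=1):
        atoms = tuple(
            AtomRecord(name=name, element=name[0],
                       coord=xyz, radius=VDW_RADII.get(name[0], 1.70))
            for name, xyz in res.items()
        )
        residues.append(Residue(index=i, name=res3, atoms=atoms, ss="H"))
    return StructureModel(residues=tuple(residues))


# --- fixture bundle -------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_set(outdir: str | Path, seeds: tuple[int, ...] = (1, 2)) -> dict:
    """Emit a small versioned fixture bundle with a checksum manifest.

    Per seed: one ortholog pair (aligned FASTA + truth JSON) and one taxon
    composition FASTA; plus one helix PDB.  The manifest lists every file
    with its sha256, so regeneration with the same seeds is byte-identical
    and deletions are detectable.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def emit(name: str, text: str) -> None:
        p = outdir / name
        p.write_text(text)
        files[name] = _sha256(p)

    for seed in seeds:
        aln, truth = simulate_ortholog_pair(PairSimConfig(length=200, seed=seed))
        fasta = "".join(f">{r.id}\n{r.seq}\n" for r in aln.records)
        emit(f"pair_seed{seed}.fasta", fasta)
        emit(f"pair_seed{seed}_truth.json", json.dumps({
            "directed_counts": truth.directed_counts.tolist(),
            "n_sites": truth.n_sites,
            "gc3_donor": truth.gc3_donor,
            "gc3_focal": truth.gc3_focal,
            "seed": truth.seed,
        }, indent=1))
        taxa, t_truth = simulate_taxon_compositions(n_taxa=6, n_codons=400, seed=seed)
        emit(f"taxa_seed{seed}.fasta",
             "".join(f">{name}\n{seq}\n" for name, seq in taxa.items()))
    helix = make_ideal_helix(20)
    helix_path = outdir / "helix20.pdb"
    write_pdb(helix, helix_path)
    files["helix20.pdb"] = _sha256(helix_path)
    manifest = {"seeds": list(seeds), "files": files}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def validate_manifest(outdir: str | Path) -> bool:
    """True when every manifest entry exists with a matching checksum."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    for name, digest in manifest["files"].items():
        p = outdir / name
        if not p.exists() or _sha256(p) != digest:
            return False
    return True
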