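"""Residue solvent accessibility and structural effect of replacements.

ASA is computed with the Shrake–Rupley sphere-point method on a deterministic
Fibonacci lattice (bit-reproducible for a fixed point count), a 1.4 Å water
probe and a bundled element van-der-Waals radius table.  Residues are binned
into buried (< 20 Å²), intermediate (20–60 Å²) and exposed (>= 60 Å²)
classes, and each inter-species residue replacement is pushed through a rule
cascade that labels it conservative or non-conservative and scores its
expected structural effect (positive / neutral / negative) from the burial
class, residue volume change and hydrogen/electrostatic bond changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import ResidueCategories

#: Element van der Waals radii (Å) for ASA; unlisted elements fall back to 1.70.
VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80,
}
DEFAULT_VDW = 1.70

#: Residue van der Waals volumes (Å^3), standard constants (Zamyatnin).
RESIDUE_VOLUMES: dict[str, float] = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Formal-charge side-chain atoms for salt-bridge detection.
_POSITIVE_ATOMS = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
                   ("HIS", "ND1"), ("HIS", "NE2")}
_NEGATIVE_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}


@dataclass(frozen=True)
class AtomRecord:
    name: str
    element: str
    coord: np.ndarray  # (3,) Å
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"atom {self.name}: nonpositive radius")
        object.__setattr__(self, "coord", np.asarray(self.coord, dtype=float))


@dataclass(frozen=True)
class Residue:
    index: int  # author residue number
    name: str  # three-letter code
    atoms: tuple[AtomRecord, ...]
    ss: str = "C"  # H (helix), E (strand), C (coil)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.name}{self.index} has no atoms")

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclass(frozen=True)
class StructureModel:
    residues: tuple[Residue, ...]
    chain: str = "A"

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing")

    def residue_at(self, index: int) -> Residue:
        for r in self.residues:
            if r.index == index:
                return r
        raise KeyError(f"no residue with index {index}")

    def all_atoms(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_atoms, 3) coordinates and (n_atoms,) radii, model-wide."""
        coords = np.array([a.coord for r in self.residues for a in r.atoms])
        radii = np.array([a.radius for r in self.residues for a in r.atoms])
        return coords, radii


def _element_from_atom_name(name: str) -> str:
    stripped = name.strip()
    return stripped[0] if stripped else "C"


def read_pdb(path: str | Path, chain: str | None = None) -> StructureModel:
    """Read ATOM records (and HELIX/SHEET annotations) from a PDB file.

    Hydrogens are kept if present; HETATM records are ignored.  Secondary
    structure comes from HELIX/SHEET header records when available, else coil.
    """
    helix_ranges: list[tuple[str, int, int]] = []
    sheet_ranges: list[tuple[str, int, int]] = []
    atoms: dict[tuple[str, int], list[AtomRecord]] = {}
    res_names: dict[tuple[str, int], str] = {}
    order: list[tuple[str, int]] = []
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "HELIX ":
                helix_ranges.append((line[19], int(line[21:25]), int(line[33:37])))
            elif rec == "SHEET ":
                sheet_ranges.append((line[21], int(line[22:26]), int(line[33:37])))
            elif rec == "ATOM  ":
                ch = line[21]
                if chain is not None and ch != chain:
                    continue
                key = (ch, int(line[22:26]))
                name = line[12:16].strip()
                element = line[76:78].strip() or _element_from_atom_name(name)
                coord = np.array([float(line[30:38]), float(line[38:46]),
                                  float(line[46:54])])
                radius = VDW_RADII.get(element.upper(), DEFAULT_VDW)
                if key not in atoms:
                    atoms[key] = []
                    order.append(key)
                    res_names[key] = line[17:20].strip()
                atoms[key].append(AtomRecord(name=name, element=element.upper(),
                                             coord=coord, radius=radius))
    if not order:
        raise ValueError(f"no ATOM records read from {path}")
    the_chain = chain if chain is not None else order[0][0]

    def ss_of(ch: str, idx: int) -> str:
        for c, a, b in helix_ranges:
            if c == ch and a <= idx <= b:
                return "H"
        for c, a, b in sheet_ranges:
            if c == ch and a <= idx <= b:
                return "E"
        return "C"

    residues = tuple(
        Residue(index=idx, name=res_names[(ch, idx)], atoms=tuple(atoms[(ch, idx)]),
                ss=ss_of(ch, idx))
        for ch, idx in order if ch == the_chain
    )
    return StructureModel(residues=residues, chain=the_chain)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a minimal valid PDB file (ATOM records, HELIX where annotated)."""
    lines = []
    # merge consecutive helix residues into HELIX records
    run: list[int] = []
    runs: list[tuple[int, int]] = []
    for r in model.residues:
        if r.ss == "H":
            run.append(r.index)
        elif run:
            runs.append((run[0], run[-1]))
            run = []
    if run:
        runs.append((run[0], run[-1]))
    for hi, (a, b) in enumerate(runs, start=1):
        ra = model.residue_at(a).name
        rb = model.residue_at(b).name
        lines.append(
            f"HELIX  {hi:>3} {hi:>3} {ra:>3} {model.chain}{a:>5}  {rb:>3} "
            f"{model.chain}{b:>5}  1{'':>30}{b - a + 1:>5}"
        )
    serial = 1
    for r in model.residues:
        for a in r.atoms:
            name = a.name if len(a.name) == 4 else f" {a.name:<3}"
            lines.append(
                f"ATOM  {serial:>5} {name}{'':1}{r.name:>3} {model.chain}"
                f"{r.index:>4}    {a.coord[0]:8.3f}{a.coord[1]:8.3f}"
                f"{a.coord[2]:8.3f}{1.0:6.2f}{0.0:6.2f}{'':10}{a.element:>2}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform unit-sphere point set (spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


@dataclass(frozen=True)
class ResidueASA:
    index: int
    name: str
    asa: float
    burial: str

    def __post_init__(self) -> None:
        if self.asa < 0:
            raise ValueError("negative ASA")


def burial_class(asa: float) -> str:
    """Burial class from ASA: <20 buried, 20–60 intermediate, >=60 exposed."""
    if asa < 0:
        raise ValueError(f"negative ASA {asa}")
    if asa < 20.0:
        return "buried"
    if asa < 60.0:
        return "intermediate"
    return "exposed"


def shrake_rupley_asa(
    model: StructureModel, probe: float = 1.4, n_points: int = 960
) -> dict[int, ResidueASA]:
    """Per-residue solvent-accessible surface area (Å²).

    Each atom's solvent sphere (radius = vdW + probe) is sampled on a fixed
    Fibonacci lattice of ``n_points`` points; a point is accessible when it
    lies outside every neighbouring atom's solvent sphere.  Atom ASAs are
    summed per residue.
    """
    if n_points < 92:
        raise ValueError("need at least 92 sphere points")
    coords, radii = model.all_atoms()
    ext = radii + probe
    sphere = fibonacci_sphere(n_points)
    n_atoms = coords.shape[0]
    atom_asa = np.zeros(n_atoms)
    # neighbour lists via pairwise distances (models here are small)
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    for i in range(n_atoms):
        cutoff2 = (ext[i] + ext) ** 2
        neigh = np.flatnonzero((d2[i] < cutoff2) & (np.arange(n_atoms) != i))
        pts = coords[i] + ext[i] * sphere
        if neigh.size:
            diff = pts[:, None, :] - coords[neigh][None, :, :]
            inside = (np.sum(diff**2, axis=-1) < ext[neigh][None, :] ** 2).any(axis=1)
            accessible = int(n_points - inside.sum())
        else:
            accessible = n_points
        atom_asa[i] = 4.0 * np.pi * ext[i] ** 2 * accessible / n_points
    out = {}
    k = 0
    for r in model.residues:
        total = float(atom_asa[k : k + len(r.atoms)].sum())
        k += len(r.atoms)
        out[r.index] = ResidueASA(index=r.index, name=r.name, asa=total,
                                  burial=burial_class(total))
    return out


def volume_delta(from_res: str, to_res: str) -> float:
    """Residue volume change (Å^3), to minus from; one-letter codes."""
    try:
        return RESIDUE_VOLUMES[to_res] - RESIDUE_VOLUMES[from_res]
    except KeyError as exc:
        raise KeyError(f"nonstandard residue {exc.args[0]!r}") from exc


def _polar_side_chain_atoms(res: Residue) -> list[AtomRecord]:
    backbone = {"N", "CA", "C", "O", "OXT"}
    return [a for a in res.atoms
            if a.element in ("N", "O") and a.name not in backbone]


def _charge_atoms(model: StructureModel) -> list[tuple[int, int, np.ndarray]]:
    """(residue index, sign, coord) for every formally charged side-chain atom."""
    out = []
    for r in model.residues:
        for a in r.atoms:
            if (r.name, a.name) in _POSITIVE_ATOMS:
                out.append((r.index, +1, a.coord))
            elif (r.name, a.name) in _NEGATIVE_ATOMS:
                out.append((r.index, -1, a.coord))
    return out


def _count_bonds(model: StructureModel, position: int,
                 hbond_cutoff: float, salt_cutoff: float) -> tuple[int, int] | None:
    """(hydrogen bonds, salt bridges) made by the side chain at ``position``.

    Returns None when the residue should have side-chain polar/charged atoms
    but none are present in the model (incomplete side chain).
    """
    res = model.residue_at(position)
    polar_expected = res.one_letter in set("STNQYCHKRDEW")
    donors = _polar_side_chain_atoms(res)
    if polar_expected and not donors:
        return None
    h_bonds = 0
    for a in donors:
        for other in model.residues:
            if other.index == position:
                continue
            for b in other.atoms:
                if b.element in ("N", "O"):
                    if np.linalg.norm(a.coord - b.coord) <= hbond_cutoff:
                        h_bonds += 1
    charges = _charge_atoms(model)
    own = [(s, c) for idx, s, c in charges if idx == position]
    others = [(s, c) for idx, s, c in charges if idx != position]
    salt = 0
    counted: set[tuple[int, int]] = set()
    for i, (s1, c1) in enumerate(own):
        for j, (s2, c2) in enumerate(others):
            if s1 * s2 < 0 and np.linalg.norm(c1 - c2) <= salt_cutoff:
                counted.add(j)
    salt = len(counted)
    return h_bonds, salt


def bond_deltas(
    model_from: StructureModel,
    model_to: StructureModel,
    position: int,
    hbond_cutoff: float = 3.5,
    salt_cutoff: float = 4.0,
) -> tuple[int | None, int | None]:
    """Change in hydrogen-bond and salt-bridge counts at one position.

    Counts donor–acceptor heavy-atom contacts within ``hbond_cutoff`` and
    opposite-formal-charge contacts within ``salt_cutoff`` made by the side
    chain at ``position`` in each model; returns (to - from) for each.  When
    either model lacks the needed side-chain atoms, the corresponding delta
    is ``None`` (unknown) and classification falls back to burial/volume
    logic.
    """
    b_from = _count_bonds(model_from, position, hbond_cutoff, salt_cutoff)
    b_to = _count_bonds(model_to, position, hbond_cutoff, salt_cutoff)
    if b_from is None or b_to is None:
        return None, None
    return b_to[0] - b_from[0], b_to[1] - b_from[1]


@dataclass(frozen=True)
class ReplacementRecord:
    position: int
    from_res: str  # donor species residue, one-letter
    to_res: str  # focal species residue
    burial: str  # class in the donor-species model
    ss: str = "C"
    h_bond_delta: int | None = None
    elec_delta: int | None = None
    volume_delta: float | None = None

    def __post_init__(self) -> None:
        if self.from_res == self.to_res:
            raise ValueError("replacement must change the residue")
        vd = self.volume_delta
        if vd is None:
            object.__setattr__(self, "volume_delta",
                               volume_delta(self.from_res, self.to_res))

    @property
    def bond_delta(self) -> int | None:
        if self.h_bond_delta is None or self.elec_delta is None:
            return None
        return self.h_bond_delta + self.elec_delta


@dataclass(frozen=True)
class EffectClassification:
    record: ReplacementRecord
    conservative: bool
    category_pair: tuple[str, str]
    effect: str  # positive | neutral | negative
    rule: str


def classify_replacement(
    rec: ReplacementRecord,
    cats: ResidueCategories | None = None,
    volume_neutral_threshold: float = 26.0,
) -> EffectClassification:
    """Structural-effect classification of one residue replacement.

    Conservative changes (same category) are scored within-category: apolar
    pairs by the sign of the volume change (|delta| below the glycine-sized
    threshold is neutral), polar and charged pairs by the bond-count change.
    Non-conservative changes are scored by the burial logic: a hydrophobic
    residue introduced at a buried position or a hydrophilic one introduced
    at an exposed position stabilizes (positive), the reverse placements
    destabilize (negative) — except that a buried polar/charged residue
    making a new hydrogen/electrostatic bond is scored positive, and a charge
    introduced at an exposed position is positive (solvation, surface
    interactions).  Exactly one rule fires; its id is recorded.
    """
    cats = cats or ResidueCategories()
    cat_from = cats.category_of(rec.from_res)
    cat_to = cats.category_of(rec.to_res)
    pair = (cat_from, cat_to)
    bond = rec.bond_delta

    def result(conservative: bool, effect: str, rule: str) -> EffectClassification:
        return EffectClassification(record=rec, conservative=conservative,
                                    category_pair=pair, effect=effect, rule=rule)

    if cat_from == cat_to:
        if cat_from == "hydrophobic":
            dv = rec.volume_delta
            if abs(dv) <= volume_neutral_threshold:
                return result(True, "neutral", "C-apolar-volume-neutral")
            return result(True, "positive" if dv > 0 else "negative",
                          "C-apolar-volume-" + ("up" if dv > 0 else "down"))
        # polar or charged pair: bond change decides
        if bond is None or bond == 0:
            return result(True, "neutral", f"C-{cat_from}-no-bond-change")
        return result(True, "positive" if bond > 0 else "negative",
                      f"C-{cat_from}-bond-" + ("added" if bond > 0 else "removed"))

    hydrophobic_in = cat_to == "hydrophobic" and cat_from != "hydrophobic"
    hydrophilic_in = cat_from == "hydrophobic" and cat_to != "hydrophobic"
    charge_in = cat_to == "charged" and cat_from != "charged"

    if rec.burial == "buried":
        if hydrophobic_in:
            return result(False, "positive", "NC-hydrophobic-at-buried")
        # hydrophilic (polar or charged) introduced at a buried position
        if bond is not None and bond > 0:
            return result(False, "positive", "NC-buried-polar-new-bond")
        return result(False, "negative", "NC-hydrophilic-at-buried")
    if rec.burial == "exposed":
        if charge_in:
            return result(False, "positive", "NC-charge-at-exposed")
        if hydrophilic_in:
            return result(False, "positive", "NC-hydrophilic-at-exposed")
        if hydrophobic_in:
            return result(False, "negative", "NC-hydrophobic-at-exposed")
        # polar introduced from charged at the surface: bond change decides
        if bond is not None and bond != 0:
            return result(False, "positive" if bond > 0 else "negative",
                          "NC-exposed-bond-change")
        return result(False, "neutral", "NC-exposed-no-bond-change")
    # intermediate burial: bond information decides, else neutral
    if bond is not None and bond != 0:
        return result(False, "positive" if bond > 0 else "negative",
                      "NC-intermediate-bond-change")
    return result(False, "neutral", "NC-intermediate-no-info")


def summarize_effects(records: Sequence[EffectClassification]) -> dict:
    """Counts by conservative status, category transition and effect.

    Also tallies the net gain of exposed positive charges (Lys/Arg/His
    introduced at exposed positions minus removed) and the secondary
    structure distribution of positive effects.
    """
    if not records:
        raise ValueError("no classifications to summarize")
    counts: dict[str, dict[str, int]] = {}
    for c in records:
        key = ("conservative-" + c.category_pair[0]) if c.conservative else \
            "non-conservative"
        counts.setdefault(key, {"positive": 0, "neutral": 0, "negative": 0})
        counts[key][c.effect] += 1
    positive_charge = set("KRH")
    net_surface_charge = 0
    ss_of_positive: dict[str, int] = {}
    for c in records:
        rec = c.record
        if rec.burial == "exposed":
            net_surface_charge += (rec.to_res in positive_charge) - (
                rec.from_res in positive_charge
            )
        if c.effect == "positive":
            ss_of_positive[rec.ss] = ss_of_positive.get(rec.ss, 0) + 1
    return {
        "counts": counts,
        "total": len(records),
        "n_conservative": sum(1 for c in records if c.conservative),
        "n_non_conservative": sum(1 for c in records if not c.conservative),
        "net_exposed_positive_charge": net_surface_charge,
        "secondary_structure_of_positive": ss_of_positive,
    }


def classification_table(records: Sequence[EffectClassification]) -> pd.DataFrame:
    rows = []
    for c in records:
        r = c.record
        rows.append({
            "position": r.position, "from": r.from_res, "to": r.to_res,
            "burial": r.burial, "ss": r.ss, "volume_delta": r.volume_delta,
            "h_bond_delta": r.h_bond_delta, "elec_delta": r.elec_delta,
            "conservative": c.conservative, "effect": c.effect, "rule": c.rule,
        })
    return pd.DataFrame(rows)
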