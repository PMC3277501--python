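"""Reading, validation and transformation of codon and protein alignments.

All downstream statistics operate on :class:`CodonAlignment` (equal-length,
in-frame nucleotide records with a per-codon-column mask) or its translated
counterpart :class:`ProteinAlignment`.  Parsing of the two supported on-disk
formats (aligned FASTA and relaxed sequential PHYLIP) is delegated to
Biopython's ``AlignIO``; this module adds frame/alphabet validation, codon
masking and per-species concatenation.

Coordinates are 0-based half-open internally; user-facing error messages are
1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDE_CHARS = set("ACGTN-")
PROTEIN_CHARS = set("ACDEFGHIKLMNPQRSTVWYX-")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class AlignmentShapeError(ValueError):
    """Records of unequal length, or a length not compatible with codons."""


class AlphabetError(ValueError):
    """A sequence contains a character outside the declared alphabet."""


class TranslationError(ValueError):
    """An internal stop codon was met in an unmasked column."""


@dataclass(frozen=True)
class GeneticCode:
    """Codon -> one-letter residue map; stop codons map to ``'*'``."""

    table: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(f"genetic code must have 64 entries, got {len(self.table)}")

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.table.items() if aa == "*")

    @property
    def sense_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.table.items() if aa != "*")

    def translate(self, codon: str) -> str:
        """Translate one codon; gaps propagate, any ambiguity gives ``X``."""
        if codon == "---":
            return "-"
        if "N" in codon or "-" in codon:
            return "X"
        return self.table[codon]


def standard_code() -> GeneticCode:
    """The 'universal' genetic code (NCBI translation table 1)."""
    ncbi = CodonTable.unambiguous_dna_by_id[1]
    table = dict(ncbi.forward_table)
    for stop in ncbi.stop_codons:
        table[stop] = "*"
    return GeneticCode(table=table)


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    seq: str
    alphabet: str  # "nucleotide" | "protein"
    species: str = ""

    def __post_init__(self) -> None:
        tag = self.species or self.id
        object.__setattr__(self, "species", tag)
        allowed = NUCLEOTIDE_CHARS if self.alphabet == "nucleotide" else PROTEIN_CHARS
        for pos, ch in enumerate(self.seq):
            if ch not in allowed:
                raise AlphabetError(
                    f"record {self.id!r}: character {ch!r} at position {pos + 1} "
                    f"is not valid for a {self.alphabet} sequence"
                )

    def __len__(self) -> int:
        return len(self.seq)


def _check_equal_lengths(records: Sequence[SequenceRecord]) -> int:
    lengths = {len(r) for r in records}
    if len(lengths) > 1:
        raise AlignmentShapeError(
            "records have unequal lengths: "
            + ", ".join(f"{r.id}={len(r)}" for r in records)
        )
    return lengths.pop() if lengths else 0


@dataclass(frozen=True)
class ProteinAlignment:
    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        _check_equal_lengths(self.records)

    @property
    def n_sites(self) -> int:
        return len(self.records[0]) if self.records else 0

    def by_species(self, tag: str) -> SequenceRecord:
        hits = [r for r in self.records if r.species == tag or r.id == tag]
        if len(hits) != 1:
            raise KeyError(f"species {tag!r} matched {len(hits)} records")
        return hits[0]


@dataclass(frozen=True)
class CodonAlignment:
    """Equal-length in-frame nucleotide records with a per-codon-column mask.

    ``column_mask[k]`` is True when codon column ``k`` is retained for
    analysis.  ``gene_offsets`` records, for concatenations, the codon offset
    at which each source gene starts (plus a terminal sentinel equal to the
    total codon count).
    """

    records: tuple[SequenceRecord, ...]
    column_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    gene_offsets: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        length = _check_equal_lengths(self.records)
        if length % 3 != 0:
            raise AlignmentShapeError(f"alignment length {length} is not divisible by 3")
        mask = self.column_mask
        if mask is None:
            mask = np.ones(length // 3, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (length // 3,):
            raise AlignmentShapeError(
                f"column mask length {mask.shape} does not match {length // 3} codon columns"
            )
        object.__setattr__(self, "column_mask", mask)

    @property
    def n_codon_columns(self) -> int:
        return int(self.column_mask.size)

    @property
    def n_retained_columns(self) -> int:
        return int(self.column_mask.sum())

    def codons(self, record: SequenceRecord, masked: bool = True) -> list[str]:
        """Codon list for one record, restricted to unmasked columns by default."""
        seq = record.seq
        cods = [seq[3 * k : 3 * k + 3] for k in range(self.n_codon_columns)]
        if masked:
            cods = [c for c, keep in zip(cods, self.column_mask) if keep]
        return cods

    def by_species(self, tag: str) -> SequenceRecord:
        hits = [r for r in self.records if r.species == tag or r.id == tag]
        if len(hits) != 1:
            raise KeyError(f"species {tag!r} matched {len(hits)} records")
        return hits[0]


def _detect_alphabet(seqs: Iterable[str]) -> str:
    chars = set("".join(seqs).upper()) - {"-"}
    if chars <= NUCLEOTIDE_CHARS:
        return "nucleotide"
    if chars <= PROTEIN_CHARS:
        return "protein"
    bad = sorted(chars - PROTEIN_CHARS)
    raise AlphabetError(f"unknown sequence characters: {bad}")


def read_alignment(path: str | Path, format: str = "fasta") -> CodonAlignment | ProteinAlignment:
    """Read an aligned FASTA or relaxed PHYLIP file.

    The alphabet is auto-detected: nucleotide inputs whose length is divisible
    by 3 come back as :class:`CodonAlignment`, protein inputs as
    :class:`ProteinAlignment`.
    """
    fmt = {"fasta": "fasta", "phylip": "phylip-relaxed"}.get(format)
    if fmt is None:
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:  # Biopython reports ragged alignments this way
        raise AlignmentShapeError(str(exc)) from exc
    seqs = [str(rec.seq).upper() for rec in msa]
    alphabet = _detect_alphabet(seqs)
    records = tuple(
        SequenceRecord(id=rec.id, seq=seq, alphabet=alphabet)
        for rec, seq in zip(msa, seqs)
    )
    if alphabet == "nucleotide":
        return CodonAlignment(records=records)
    return ProteinAlignment(records=records)


def write_alignment(
    aln: CodonAlignment | ProteinAlignment, path: str | Path, format: str = "fasta"
) -> None:
    """Write an alignment as FASTA or relaxed sequential PHYLIP."""
    fmt = {"fasta": "fasta", "phylip": "phylip-relaxed"}.get(format)
    if fmt is None:
        raise ValueError(f"unsupported format {format!r}")
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(r.seq), id=r.id, description="") for r in aln.records]
    )
    AlignIO.write(msa, str(path), fmt)


def translate_codon_alignment(
    aln: CodonAlignment, code: GeneticCode | None = None
) -> ProteinAlignment:
    """Translate every record codon-by-codon.

    Gap codons ``---`` become ``-``; codons containing ``N`` or a partial gap
    become ``X``.  A stop codon in an *unmasked* column raises
    :class:`TranslationError`; stops in masked columns translate to ``X`` so
    that column indices stay aligned.
    """
    code = code or standard_code()
    out = []
    for rec in aln.records:
        residues = []
        for k in range(aln.n_codon_columns):
            codon = rec.seq[3 * k : 3 * k + 3]
            aa = code.translate(codon)
            if aa == "*":
                if aln.column_mask[k]:
                    raise TranslationError(
                        f"internal stop codon {codon} in record {rec.id!r} "
                        f"at codon column {k + 1}"
                    )
                aa = "X"
            residues.append(aa)
        out.append(SequenceRecord(id=rec.id, species=rec.species,
                                  seq="".join(residues), alphabet="protein"))
    return ProteinAlignment(records=tuple(out))


def drop_unreliable_columns(aln: CodonAlignment) -> CodonAlignment:
    """Mask every codon column containing a gap or ambiguity in any record.

    A column is unreliable when any record has ``-`` or ``N`` anywhere in the
    codon.  Idempotent; an alignment whose columns are all masked is returned
    with a zero mask (callers may warn), not rejected.
    """
    mask = aln.column_mask.copy()
    for k in range(aln.n_codon_columns):
        if not mask[k]:
            continue
        for rec in aln.records:
            codon = rec.seq[3 * k : 3 * k + 3]
            if "-" in codon or "N" in codon:
                mask[k] = False
                break
    return replace(aln, column_mask=mask)


def concatenate(alns: Sequence[CodonAlignment], species: Sequence[str]) -> CodonAlignment:
    """Concatenate per-gene alignments species-wise, recording gene offsets.

    Every input alignment must contain each requested species tag exactly
    once.  Column masks are concatenated along with the sequences.
    """
    if not alns:
        raise ValueError("no alignments to concatenate")
    parts: dict[str, list[str]] = {tag: [] for tag in species}
    masks: list[np.ndarray] = []
    offsets = [0]
    for gi, aln in enumerate(alns):
        for tag in species:
            try:
                rec = aln.by_species(tag)
            except KeyError as exc:
                raise KeyError(f"gene {gi + 1}: {exc.args[0]}") from exc
            parts[tag].append(rec.seq)
        masks.append(aln.column_mask)
        offsets.append(offsets[-1] + aln.n_codon_columns)
    records = tuple(
        SequenceRecord(id=tag, species=tag, seq="".join(parts[tag]), alphabet="nucleotide")
        for tag in species
    )
    return CodonAlignment(
        records=records,
        column_mask=np.concatenate(masks),
        gene_offsets=tuple(offsets),
    )
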