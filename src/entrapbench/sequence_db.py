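"""Protein databases and deterministic in-silico tryptic digestion.

The entrapment workflow starts from a FASTA protein database.  Proteins are
digested with trypsin (cleavage C-terminal of every K and R, *without*
proline suppression, i.e. cleavage also occurs before P), optionally allowing
missed cleavages and a peptide-length window.  Two digestion presets matter:

* peptide-level databases use 1 missed cleavage and lengths 7-35;
* protein-level entrapment construction uses 0 missed cleavages with no
  length filter, so that the fragments concatenate back into the protein.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: residues that terminate a tryptic peptide (no proline suppression)
_CLEAVE_AFTER = frozenset("KR")


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry: accession, free-text description, AA sequence."""

    accession: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.accession!r} has an empty sequence")

    @property
    def has_non_canonical(self) -> bool:
        return not set(self.sequence) <= CANONICAL_AA


@dataclass(frozen=True)
class DigestConfig:
    """Trypsin digestion settings.

    ``missed_cleavages`` is the maximum number of internal uncut K/R sites a
    reported peptide may contain.  When ``apply_length_filter`` is set, only
    peptides with ``min_len <= len <= max_len`` are kept.
    """

    missed_cleavages: int = 1
    min_len: int = 7
    max_len: int = 35
    apply_length_filter: bool = True
    enzyme: str = "trypsin/P-insensitive"

    def __post_init__(self) -> None:
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be non-negative")
        if self.apply_length_filter and self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")


#: preset used for peptide-level entrapment databases
PEPTIDE_LEVEL_DIGEST = DigestConfig(missed_cleavages=1, min_len=7, max_len=35,
                                    apply_length_filter=True)

#: preset used when building protein-level entrapment databases
PROTEIN_LEVEL_DIGEST = DigestConfig(missed_cleavages=0, apply_length_filter=False)


@dataclass
class PeptideSet:
    """Unique peptides with provenance back to their source proteins."""

    peptides: list[str] = field(default_factory=list)
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.peptides)

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.provenance

    def __iter__(self):
        return iter(self.peptides)

    def add(self, peptide: str, accession: str) -> None:
        if peptide not in self.provenance:
            self.peptides.append(peptide)
            self.provenance[peptide] = set()
        self.provenance[peptide].add(accession)

    def to_tsv(self, path: str | Path) -> None:
        """Write as two-column TSV: peptide, semicolon-joined accessions."""
        with open(path, "w") as fh:
            fh.write("peptide\tproteins\n")
            for pep in self.peptides:
                fh.write(f"{pep}\t{';'.join(sorted(self.provenance[pep]))}\n")

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for pep in self.peptides:
                accs = ";".join(sorted(self.provenance[pep]))
                fh.write(f">{pep} {accs}\n{pep}\n")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA protein database, preserving file order.

    Sequences are whitespace-stripped and upper-cased.  Duplicate accessions
    (the first whitespace-delimited token of the header) raise ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = "".join(str(rec.seq).split()).upper()
        if not seq:
            raise ValueError(f"entry {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise ValueError(f"duplicate accession {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, rec.description, seq))
    if not records:
        raise ValueError(f"no FASTA entries found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.accession
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def cleavage_fragments(sequence: str) -> list[str]:
    """Fully tryptic fragments (0 missed cleavages), no length filter.

    Cleaves after every K/R including before proline.  The C-terminal
    fragment is kept whether or not it ends in K/R.  Concatenating the
    returned fragments reproduces ``sequence`` exactly.
    """
    frags: list[str] = []
    start = 0
    for i, aa in enumerate(sequence):
        if aa in _CLEAVE_AFTER:
            frags.append(sequence[start:i + 1])
            start = i + 1
    if start < len(sequence):
        frags.append(sequence[start:])
    return frags


def digest(protein: ProteinRecord | str, config: DigestConfig = PEPTIDE_LEVEL_DIGEST,
           ) -> list[str]:
    """Tryptic peptides of one protein, in N->C order.

    Returns every peptide spanning ``m + 1`` consecutive fully-tryptic
    fragments for ``m = 0 .. missed_cleavages``, subject to the length
    filter.  A sequence repeated at several positions appears once per
    position; deduplication happens at :func:`build_peptide_db` level.
    """
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    frags = cleavage_fragments(seq)
    peptides: list[str] = []
    for m in range(config.missed_cleavages + 1):
        for i in range(len(frags) - m):
            pep = "".join(frags[i:i + m + 1])
            if config.apply_length_filter and not (
                    config.min_len <= len(pep) <= config.max_len):
                continue
            peptides.append(pep)
    return peptides


def build_peptide_db(proteins: Sequence[ProteinRecord],
                     config: DigestConfig = PEPTIDE_LEVEL_DIGEST) -> PeptideSet:
    """Digest a protein collection into a deduplicated peptide database."""
    if not proteins:
        raise ValueError("empty protein collection")
    out = PeptideSet()
    for prot in proteins:
        for pep in digest(prot, config):
            out.add(pep, prot.accession)
    if not out.peptides:
        warnings.warn("no peptides survived digestion and filtering",
                      stacklevel=2)
    return out
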