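"""Construction of paired (shuffled) and foreign entrapment databases.

An entrapment database extends the search space of an MS analysis tool with
sequences known to be absent from the sample, so that entrapment discoveries
flag the tool's false-discovery behaviour.  Two construction modes:

* **shuffled** -- each original target peptide is paired with r shuffled
  copies (C-terminal residue fixed so the tryptic terminus is preserved;
  optionally also the N-terminal residue).  Pairing enables the tighter
  paired/k-matched FDP estimators.
* **foreign** -- sequences are sampled from the proteome of another species;
  no pairing exists, so only the combined/lower-bound/sample estimators
  apply downstream.

At the protein level each original protein is rebuilt from the shuffled
versions of its fully-tryptic fragments, so the entrapment protein has the
same length and the same tryptic boundary structure as the original.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .sequence_db import (
    CANONICAL_AA,
    PEPTIDE_LEVEL_DIGEST,
    ProteinRecord,
    PeptideSet,
    build_peptide_db,
    cleavage_fragments,
)

logger = logging.getLogger(__name__)

#: accession prefix marking entrapment entries in FASTA/report output
ENTRAPMENT_PREFIX = "ENTRAP_"

#: extra shuffle attempts beyond r before giving up on a target peptide
EXTRA_ATTEMPTS = 20


@dataclass(frozen=True)
class ShuffleConfig:
    """Peptide shuffling settings.

    The C-terminal residue is always kept fixed (it carries the tryptic
    K/R); ``fix_n_terminal`` additionally pins the first residue, the
    variant used for small controlled-mixture experiments.  A target for
    which ``max_extra_attempts + r`` shuffles fail to produce r distinct
    entrapments is dropped (peptide level) or falls back (protein level).
    """

    fix_c_terminal: bool = True
    fix_n_terminal: bool = False
    max_extra_attempts: int = EXTRA_ATTEMPTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_extra_attempts < 0:
            raise ValueError("max_extra_attempts must be >= 0")
        if not self.fix_c_terminal:
            raise ValueError("the C-terminal residue is always kept fixed")


@dataclass
class RemovedTarget:
    """A target dropped from the database, with the attempt count spent."""

    peptide: str
    attempts: int
    reason: str = "no distinct shuffle"


@dataclass
class PairedEntrapmentDB:
    """Original targets bound to their entrapment counterparts.

    ``pairs`` maps each surviving original-target identifier (peptide
    sequence at peptide level, protein accession at protein level) to an
    ordered list of exactly ``r`` entrapment sequences.  In foreign mode
    ``pairs`` is empty and ``unpaired_entrapments`` holds the sampled
    foreign entries.
    """

    level: Literal["peptide", "protein"]
    r: float
    mode: Literal["shuffled", "foreign"]
    pairs: dict[str, list[str]] = field(default_factory=dict)
    removed: list[RemovedTarget] = field(default_factory=list)
    unpaired_entrapments: list[str] = field(default_factory=list)
    #: protein level only: per-peptide swap map used to build the proteins
    peptide_pairs: dict[str, list[str]] = field(default_factory=dict)
    #: protein level only: entrapment ProteinRecords (r per original)
    entrapment_proteins: list[ProteinRecord] = field(default_factory=list)
    seed: int | None = None

    @property
    def n_targets(self) -> int:
        return len(self.pairs) if self.mode == "shuffled" else self._n_foreign_targets

    _n_foreign_targets: int = 0

    @property
    def n_entrapments(self) -> int:
        if self.mode == "shuffled":
            return sum(len(v) for v in self.pairs.values())
        return len(self.unpaired_entrapments)

    def effective_ratio(self) -> float:
        """Entrapment-to-surviving-original-target size ratio."""
        n_t = self.n_targets
        if n_t == 0:
            raise ValueError("empty target set: effective ratio undefined")
        return self.n_entrapments / n_t

    # ---- serialisation -------------------------------------------------
    def pair_table(self) -> "pd.DataFrame":  # noqa: F821 (lazy import)
        import pandas as pd

        r = int(self.r)
        rows = [
            {"target": t, **{f"entrapment_{j + 1}": e
                             for j, e in enumerate(ents)}}
            for t, ents in self.pairs.items()
        ]
        cols = ["target"] + [f"entrapment_{j + 1}" for j in range(r)]
        return pd.DataFrame(rows, columns=cols)

    def to_tsv(self, path: str | Path) -> None:
        self.pair_table().to_csv(path, sep="\t", index=False)

    def manifest(self) -> dict:
        return {
            "level": self.level,
            "mode": self.mode,
            "r": self.r,
            "seed": self.seed,
            "n_targets": self.n_targets,
            "n_entrapments": self.n_entrapments,
            "n_removed": len(self.removed),
            "removed": [rm.peptide for rm in self.removed],
            # total-attempt budget reading of the retry rule: 20+r shuffles
            # per target overall, not 20 per entrapment slot
            "attempt_budget": "total (extra+r per target)",
        }


def effective_ratio(db: PairedEntrapmentDB) -> float:
    return db.effective_ratio()


# ---------------------------------------------------------------------------
# shuffling
# ---------------------------------------------------------------------------

def shuffle_peptide(peptide: str, config: ShuffleConfig,
                    rng: np.random.Generator) -> str:
    """Uniform random permutation of the non-fixed positions of a peptide.

    The amino-acid multiset is preserved; the C-terminal (and optionally
    N-terminal) residue stays in place.
    """
    lo = 1 if config.fix_n_terminal else 0
    hi = len(peptide) - 1  # C-terminal always fixed
    if hi - lo < 1:
        raise ValueError(
            f"peptide {peptide!r} too short to permute with the fixed termini")
    mid = list(peptide[lo:hi])
    rng.shuffle(mid)
    return peptide[:lo] + "".join(mid) + peptide[hi:]


def _shufflable(peptide: str, config: ShuffleConfig) -> bool:
    lo = 1 if config.fix_n_terminal else 0
    return len(peptide) - 1 - lo >= 1 and set(peptide) <= CANONICAL_AA


def generate_paired_peptide_db(targets: PeptideSet | Sequence[str], r: int = 1,
                               config: ShuffleConfig | None = None,
                               ) -> PairedEntrapmentDB:
    """Pair every original target peptide with r distinct shuffled entrapments.

    For each target (processed in sorted order for seed-stable output) up to
    ``max_extra_attempts + r`` shuffles are drawn; a candidate is accepted
    only if it differs from *all* original target peptides and from every
    previously accepted entrapment peptide (global distinctness).  Targets
    for which r distinct entrapments cannot be collected are removed and
    recorded, as are peptides that cannot be shuffled at all (too short, or
    containing non-canonical residues, which cannot be safely permuted).
    """
    config = config or ShuffleConfig()
    if r < 1:
        raise ValueError("r must be a positive integer")
    rng = np.random.default_rng(config.seed)
    target_list = sorted(targets.peptides if isinstance(targets, PeptideSet)
                         else targets)
    target_set = set(target_list)
    db = PairedEntrapmentDB(level="peptide", r=r, mode="shuffled",
                            seed=config.seed)
    used: set[str] = set()  # all accepted entrapments, global scope
    budget = config.max_extra_attempts + r
    for pep in target_list:
        if not _shufflable(pep, config):
            db.removed.append(RemovedTarget(pep, 0, "not shufflable"))
            logger.info("target %s cannot be shuffled; removed", pep)
            continue
        got: list[str] = []
        attempts = 0
        while attempts < budget and len(got) < r:
            cand = shuffle_peptide(pep, config, rng)
            attempts += 1
            if cand not in target_set and cand not in used and cand not in got:
                got.append(cand)
        if len(got) < r:
            # roll back: nothing from this target enters the database
            db.removed.append(RemovedTarget(pep, attempts))
        else:
            db.pairs[pep] = got
            used.update(got)
    return db


def generate_paired_protein_db(proteins: Sequence[ProteinRecord], r: int = 1,
                               config: ShuffleConfig | None = None,
                               ) -> PairedEntrapmentDB:
    """Build r paired entrapment proteins per original protein.

    Each protein is digested fully (0 missed cleavages, no length/mass
    filter).  Every distinct fragment peptide is assigned r entrapment
    peptides: up to ``max_extra_attempts + r`` shuffles collect n <= r
    distinct candidates; if 0 < n < r the remaining slots are sampled with
    replacement from the n; if n == 0 all r copies equal the original
    fragment, so no sequence is ever lost.  Entrapment protein j is the
    concatenation of each fragment's j-th entrapment in original order; a
    fragment occurring in several proteins (or several times in one) is
    swapped consistently everywhere.
    """
    config = config or ShuffleConfig()
    if r < 1:
        raise ValueError("r must be a positive integer")
    rng = np.random.default_rng(config.seed)
    # distinct fragments across the whole collection, sorted for determinism
    all_frags: set[str] = set()
    for prot in proteins:
        all_frags.update(cleavage_fragments(prot.sequence))
    db = PairedEntrapmentDB(level="protein", r=r, mode="shuffled",
                            seed=config.seed)
    used: set[str] = set()
    budget = config.max_extra_attempts + r
    for frag in sorted(all_frags):
        got: list[str] = []
        if _shufflable(frag, config):
            attempts = 0
            while attempts < budget and len(got) < r:
                cand = shuffle_peptide(frag, config, rng)
                attempts += 1
                if cand not in all_frags and cand not in used and cand not in got:
                    got.append(cand)
        n = len(got)
        if n == 0:
            assigned = [frag] * r  # unpermutable: entrapment equals target
        elif n < r:
            extra = rng.choice(n, size=r - n, replace=True)
            assigned = got + [got[i] for i in extra]
        else:
            assigned = got
        db.peptide_pairs[frag] = assigned
        used.update(got)
    for prot in proteins:
        frags = cleavage_fragments(prot.sequence)
        ents: list[str] = []
        for j in range(r):
            seq = "".join(db.peptide_pairs[f][j] for f in frags)
            suffix = f"_{j + 1}" if r > 1 else ""
            acc = f"{ENTRAPMENT_PREFIX}{prot.accession}{suffix}"
            db.entrapment_proteins.append(
                ProteinRecord(acc, f"{acc} shuffled entrapment of "
                                   f"{prot.accession}", seq))
            ents.append(seq)
        db.pairs[prot.accession] = ents
    return db


# ---------------------------------------------------------------------------
# foreign entrapment
# ---------------------------------------------------------------------------

def generate_foreign_db(targets: PeptideSet | Sequence[ProteinRecord],
                        foreign: Sequence[ProteinRecord], r: float = 1.0,
                        level: Literal["peptide", "protein"] = "peptide",
                        seed: int = 0) -> PairedEntrapmentDB:
    """Sample a foreign-species entrapment database at ratio r (unpaired).

    Peptide level: both databases are digested with the peptide-level preset
    (1 missed cleavage, lengths 7-35); foreign peptides identical to any
    original target peptide are excluded; the remainder is sampled uniformly
    without replacement to ``round(r * n_targets)`` entries.  Protein level:
    foreign proteins are sampled to ``round(r * n_proteins)``.
    """
    if r <= 0:
        raise ValueError("r must be positive")
    rng = np.random.default_rng(seed)
    db = PairedEntrapmentDB(level=level, r=r, mode="foreign", seed=seed)
    if level == "peptide":
        target_peps = (targets if isinstance(targets, PeptideSet)
                       else build_peptide_db(targets, PEPTIDE_LEVEL_DIGEST))
        target_set = set(target_peps.peptides)
        foreign_peps = build_peptide_db(foreign, PEPTIDE_LEVEL_DIGEST)
        pool = sorted(set(foreign_peps.peptides) - target_set)
        n_targets = len(target_set)
        need = int(round(r * n_targets))
    else:
        if isinstance(targets, PeptideSet):
            raise TypeError("protein-level foreign mode needs ProteinRecords")
        pool = sorted({p.accession for p in foreign})
        n_targets = len(targets)
        need = int(round(r * n_targets))
    if need > len(pool):
        raise ValueError(
            f"foreign pool too small: need {need} entries for r={r}, have "
            f"{len(pool)} (max achievable r = {len(pool) / n_targets:.3f})")
    idx = rng.choice(len(pool), size=need, replace=False)
    db.unpaired_entrapments = [pool[i] for i in sorted(idx)]
    db._n_foreign_targets = n_targets
    return db
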