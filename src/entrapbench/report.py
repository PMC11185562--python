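"""Parsing third-party search-tool reports into discovery tables.

Search engines emit TSV/CSV reports with tool-specific column names; a
:class:`ColumnMap` names the identifier, score, q-value and protein-group
columns and how entrapment entries are marked.  Protein groups follow the
rule that a group containing at least one original-target protein counts as
an original-target discovery; only all-entrapment groups count as
entrapment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .entrapment import ENTRAPMENT_PREFIX
from .estimators import LABEL_ENTRAPMENT, LABEL_ORIGINAL, DiscoveryTable

__all__ = ["ColumnMap", "parse_report", "label_protein_group"]


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from a tool's report columns to the canonical table.

    At least one of ``score_column`` / ``qvalue_column`` must be given.
    ``entrapment_marker`` is an accession prefix tested against the id or
    protein-group members; alternatively ``label_column`` names a column
    already holding original/entrapment labels.  ``pair_column``, when
    present, carries the paired original-target identifier.
    """

    id_column: str = "id"
    score_column: str | None = "score"
    qvalue_column: str | None = "q_value"
    protein_group_column: str | None = None
    entrapment_marker: str = ENTRAPMENT_PREFIX
    label_column: str | None = None
    pair_column: str | None = None
    group_delimiter: str = ";"

    def __post_init__(self) -> None:
        if self.score_column is None and self.qvalue_column is None:
            raise ValueError("need a score column or a q-value column")


#: preset for generic score/q-value tables written by this package
GENERIC_COLUMNS = ColumnMap()


def label_protein_group(group: str, marker: str = ENTRAPMENT_PREFIX,
                        delimiter: str = ";") -> str:
    """Label a delimited protein group: original unless *every* member is marked."""
    members = [m.strip() for m in group.split(delimiter) if m.strip()]
    if not members:
        raise ValueError("empty protein group")
    if all(m.startswith(marker) for m in members):
        return LABEL_ENTRAPMENT
    return LABEL_ORIGINAL


def parse_report(path: str | Path, cmap: ColumnMap = GENERIC_COLUMNS,
                 ) -> DiscoveryTable:
    """Read a TSV/CSV search report into a canonical DiscoveryTable.

    Rows are labeled original/entrapment by the marker rule (or taken from
    ``label_column``); duplicate identifiers collapse to the best row
    (lowest q-value, then highest score).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep)
    needed = [c for c in (cmap.id_column, cmap.score_column,
                          cmap.qvalue_column, cmap.protein_group_column,
                          cmap.label_column, cmap.pair_column)
              if c is not None]
    missing = [c for c in needed if c not in raw.columns]
    if missing:
        raise ValueError(f"report {path} is missing mapped columns: {missing}")

    ids = raw[cmap.id_column].astype(str)
    if cmap.label_column is not None:
        labels = raw[cmap.label_column].astype(str)
    elif cmap.protein_group_column is not None:
        labels = raw[cmap.protein_group_column].astype(str).map(
            lambda g: label_protein_group(g, cmap.entrapment_marker,
                                          cmap.group_delimiter))
    else:
        labels = ids.map(lambda i: LABEL_ENTRAPMENT
                         if i.startswith(cmap.entrapment_marker)
                         else LABEL_ORIGINAL)

    if cmap.qvalue_column is not None:
        q = raw[cmap.qvalue_column].astype(float)
        bad = q[(q < 0) | (q > 1)]
        if not bad.empty:
            raise ValueError(
                f"q-values outside [0, 1] at row(s) {list(bad.index[:5])}")
    else:
        q = pd.Series(np.nan, index=raw.index)
    score = (raw[cmap.score_column].astype(float)
             if cmap.score_column is not None
             else pd.Series(np.nan, index=raw.index))
    pair = (raw[cmap.pair_column] if cmap.pair_column is not None
            else pd.Series(pd.NA, index=raw.index))

    df = pd.DataFrame({"id": ids, "label": labels, "score": score,
                       "q_value": q, "pair_key": pair})
    # collapse duplicates to the best observation of each identifier
    df = (df.sort_values(["q_value", "score"], ascending=[True, False],
                         na_position="last")
            .drop_duplicates("id", keep="first")
            .sort_index(ignore_index=True))
    return DiscoveryTable(df)
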