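"""Multiple-sequence-alignment handling and per-position conservation rates.

The scoring method compares the hydropathy of each residue of a *target*
protein against the residue distribution observed at the corresponding
alignment column of its family ("library").  This module reads a finished
alignment (it never builds one), maps the target's ungapped 1-based residue
numbering onto alignment columns, and tabulates the appearance rate of each
of the 20 standard amino acids at every target position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Align import MultipleSeqAlignment

log = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical by one-letter code.  This is the
#: residue index order used throughout (rows of the conservation matrix).
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

GAP = "-"

#: Ambiguity / non-standard letters folded into the gap bucket for rate
#: purposes (the hydropathy scale is defined only for the 20 standard
#: residues).
NON_STANDARD = set("BZXUOJ*.")


class AlignmentError(ValueError):
    """Raised for malformed alignments or unresolvable targets."""


@dataclass(frozen=True)
class AlignedFamily:
    """An alignment of a protein family with one designated target sequence.

    Parameters
    ----------
    ids :
        Sequence identifiers, in file order.
    rows :
        Aligned residue strings (upper-case), one per id, all the same length.
    target_id :
        Identifier of the target sequence within ``ids``.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    target_id: str

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError("no sequences")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentError("not an alignment: ragged sequence lengths")
        hits = [i for i, x in enumerate(self.ids) if x == self.target_id]
        if len(hits) != 1:
            raise AlignmentError(f"target not found: {self.target_id!r}")
        bad = set("".join(self.rows)) - set(AMINO_ACIDS) - {GAP} - NON_STANDARD
        if bad:
            raise AlignmentError(f"unknown characters in alignment: {sorted(bad)}")

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def target_index(self) -> int:
        return self.ids.index(self.target_id)

    @property
    def target_row(self) -> str:
        return self.rows[self.target_index]

    def column(self, c: int) -> str:
        """Residues of alignment column ``c`` (0-based), over all sequences."""
        return "".join(r[c] for r in self.rows)


@dataclass(frozen=True)
class PositionMap:
    """Maps 1-based target residue positions to 0-based alignment columns."""

    positions: tuple[int, ...]
    columns: tuple[int, ...]
    residues: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.positions)

    def column_of(self, j: int) -> int:
        """Alignment column of target position ``j`` (1-based)."""
        return self.columns[j - 1]

    def residue_of(self, j: int) -> str:
        return self.residues[j - 1]


@dataclass
class ConservationMatrix:
    """Appearance rates (%) of the 20 residues at each target position.

    ``rates`` is a 20 x L DataFrame: rows indexed by one-letter code in
    alphabetical order, columns by 1-based target position.  ``gap_fraction``
    holds, per position, the fraction of family sequences with a gap (or a
    non-standard letter) at that column.  Under the default ``all`` gap mode
    rates are computed over all family sequences, so per position::

        sum_i rates[i, j] + 100 * gap_fraction[j] == 100
    """

    rates: pd.DataFrame
    gap_fraction: pd.Series
    gap_mode: str = "all"
    residue_order: str = AMINO_ACIDS

    def rate(self, residue: str, j: int) -> float:
        return float(self.rates.at[residue, j])

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV: 20 residue rows plus a final ``gap`` row, 2 decimals."""
        out = self.rates.round(2).copy()
        out.loc["gap"] = (100.0 * self.gap_fraction).round(2)
        out.index.name = "residue"
        out.to_csv(path, sep="\t", float_format="%.2f")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConservationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.columns = df.columns.astype(int)
        gap = df.loc["gap"] / 100.0
        rates = df.drop(index="gap")
        return cls(rates=rates, gap_fraction=gap)


def read_alignment(
    path: str | Path,
    fmt: Literal["fasta", "clustal"],
    target_id: str,
) -> AlignedFamily:
    """Read an aligned FASTA or Clustal file into an :class:`AlignedFamily`.

    Sequence order is preserved; letters are upper-cased.  Raises
    :class:`AlignmentError` if the file is empty, ragged, or lacks the target.
    """
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        # Distinguish "nothing there" from "rows of unequal length".
        records = list(SeqIO.parse(str(path), fmt))
        if not records:
            raise AlignmentError("no sequences") from exc
        raise AlignmentError("not an alignment") from exc
    ids = tuple(rec.id for rec in aln)
    rows = tuple(str(rec.seq).upper() for rec in aln)
    return AlignedFamily(ids=ids, rows=rows, target_id=target_id)


def write_alignment(family: AlignedFamily, path: str | Path, fmt: str = "fasta") -> None:
    """Write the family back out (FASTA by default)."""
    records = [
        SeqRecord(Seq(row), id=name, description="")
        for name, row in zip(family.ids, family.rows)
    ]
    AlignIO.write(MultipleSeqAlignment(records), str(path), fmt)


def map_target_positions(family: AlignedFamily) -> PositionMap:
    """One entry per non-gap target character; ``j`` counts from 1."""
    positions, columns, residues = [], [], []
    j = 0
    for c, ch in enumerate(family.target_row):
        if ch == GAP:
            continue
        j += 1
        positions.append(j)
        columns.append(c)
        residues.append(ch)
    if not positions:
        raise AlignmentError("empty target: target sequence is all gaps")
    return PositionMap(tuple(positions), tuple(columns), tuple(residues))


def conservation_rates(
    family: AlignedFamily,
    positions: PositionMap | None = None,
    *,
    gap_mode: Literal["all", "ungapped"] = "all",
    exclude_target: bool = False,
) -> ConservationMatrix:
    """Per-position appearance rates (%) of the 20 residues across the family.

    ``gap_mode='all'`` divides counts by the number of family sequences, so
    gaps dilute the rates (and the consensus hydropathy term downstream is a
    sub-weighted mean).  ``'ungapped'`` renormalises over the sequences that
    actually carry a residue at the column.  ``exclude_target`` drops the
    target's own row from the counts.
    """
    if positions is None:
        positions = map_target_positions(family)

    rows = list(family.rows)
    if exclude_target:
        rows = [r for i, r in enumerate(rows) if i != family.target_index]
        if not rows:
            raise AlignmentError("no sequences left after excluding target")

    arr = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(len(rows), -1)
    cols = np.array(positions.columns)
    sub = arr[:, cols]  # n_seq x L

    nonstd = 0
    counts = np.empty((len(AMINO_ACIDS), len(cols)), dtype=np.int64)
    for i, aa in enumerate(AMINO_ACIDS):
        counts[i] = (sub == ord(aa)).sum(axis=0)
    standard_total = counts.sum(axis=0)
    n_seq = len(rows)
    gap_like = n_seq - standard_total  # gaps plus non-standard letters
    nonstd = int((gap_like - (sub == ord(GAP)).sum(axis=0)).sum())
    if nonstd:
        log.warning(
            "%d non-standard residue letters treated as gaps for rate purposes",
            nonstd,
        )

    if gap_mode == "all":
        denom = np.full(len(cols), n_seq, dtype=float)
    elif gap_mode == "ungapped":
        denom = np.maximum(standard_total, 1).astype(float)
    else:
        raise ValueError(f"unknown gap mode: {gap_mode!r}")

    rates = 100.0 * counts / denom
    idx = pd.Index(list(AMINO_ACIDS), name="residue")
    cols_idx = pd.Index(positions.positions, name="position")
    return ConservationMatrix(
        rates=pd.DataFrame(rates, index=idx, columns=cols_idx),
        gap_fraction=pd.Series(gap_like / n_seq, index=cols_idx, name="gap_fraction"),
        gap_mode=gap_mode,
    )
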