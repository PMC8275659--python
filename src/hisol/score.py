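"""Hydropathy-mismatch (HiSol) scoring of candidate mutation sites.

The score of target position ``j`` is the z-transformed Kyte-Doolittle
hydropathy of the target's own residue minus the conservation-weighted mean
z-hydropathy of the family at that position::

    score(j) = z(target_j) - sum_i z_i * R_cons[i, j] / 100

A large positive score marks a hydrophobic residue where the family conserves
hydrophilic ones (a candidate for replacement by a more hydrophilic residue);
a large negative score marks the opposite mismatch.  Candidate sites are the
positions with the largest absolute scores, and the proposed substitution at
each site is the non-wild-type residue with the highest conservation rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .msa import AMINO_ACIDS, AlignedFamily, ConservationMatrix, PositionMap
from .msa import conservation_rates, map_target_positions

log = logging.getLogger(__name__)

#: Kyte-Doolittle (1982) hydropathy indices; positive = hydrophobic.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}


@dataclass(frozen=True)
class HydropathyScale:
    """A 20-residue hydropathy scale together with its z-transform."""

    raw: dict[str, float]
    z: dict[str, float]
    mu: float
    sigma: float

    def z_vector(self) -> np.ndarray:
        """z-values in alphabetical one-letter order (the residue index order)."""
        return np.array([self.z[a] for a in AMINO_ACIDS])


def z_transform_scale(
    raw: dict[str, float] | None = None,
    *,
    mode: Literal["population", "sample"] = "population",
) -> HydropathyScale:
    """Standardise a 20-residue scale to mean 0 and standard deviation 1.

    The default divisor is the population standard deviation (ddof=0): the 20
    amino acids are the complete alphabet, not a sample from one.  ``sample``
    (ddof=1) is available for sensitivity checks.
    """
    raw = dict(KYTE_DOOLITTLE if raw is None else raw)
    if set(raw) != set(AMINO_ACIDS):
        raise ValueError("scale must be defined for exactly the 20 standard residues")
    values = np.array([raw[a] for a in AMINO_ACIDS], dtype=float)
    mu = float(values.mean())
    sigma = float(values.std(ddof=0 if mode == "population" else 1))
    if sigma == 0:
        raise ValueError("degenerate scale: zero standard deviation")
    z = {a: (raw[a] - mu) / sigma for a in AMINO_ACIDS}
    return HydropathyScale(raw=raw, z=z, mu=mu, sigma=sigma)


@dataclass(frozen=True)
class MutationCandidate:
    """A ranked mutation site with its proposed substitution."""

    position: int
    wild_type: str
    proposed: str | None
    score: float
    direction: str  # "to-hydrophilic" (score > 0) or "to-hydrophobic"
    proposal_rate_pct: float
    ss_element: str | None = None
    reason: str | None = None  # set when no proposal exists

    @property
    def mutation(self) -> str | None:
        if self.proposed is None:
            return None
        return f"{self.wild_type}{self.position}{self.proposed}"


def hisol_score(
    j: int,
    scale: HydropathyScale,
    cons: ConservationMatrix,
    positions: PositionMap,
) -> float:
    """Literal single-position evaluation of the score formula.

    Kept deliberately as an explicit loop over the 20 residues: it is the
    reference form the vectorised table is tested against.
    """
    wt = positions.residue_of(j)
    if wt not in scale.z:
        raise ValueError(f"unscored position {j}: non-standard residue {wt!r}")
    consensus = 0.0
    for aa in AMINO_ACIDS:
        consensus += scale.z[aa] * cons.rate(aa, j) / 100.0
    return scale.z[wt] - consensus


def hisol_table(
    family: AlignedFamily | None = None,
    *,
    cons: ConservationMatrix | None = None,
    positions: PositionMap | None = None,
    scale: HydropathyScale | None = None,
    gap_mode: Literal["all", "ungapped"] = "all",
    exclude_target: bool = False,
) -> pd.DataFrame:
    """Vectorised per-position score table.

    Either pass a family (rates are computed in-line) or a precomputed
    conservation matrix plus position map.  Returns a DataFrame indexed by
    1-based target position with columns ``wt``, ``consensus_hydropathy``,
    ``score``, ``rank_abs``, ``sign``, ``proposal``, ``proposal_rate_pct``.
    Positions whose target residue is non-standard get NaN scores and are
    excluded from ranking.
    """
    if scale is None:
        scale = z_transform_scale()
    if cons is None or positions is None:
        if family is None:
            raise ValueError("need either a family or (cons, positions)")
        positions = map_target_positions(family)
        cons = conservation_rates(
            family, positions, gap_mode=gap_mode, exclude_target=exclude_target
        )

    zvec = scale.z_vector()
    consensus = zvec @ (cons.rates.to_numpy() / 100.0)
    wt = np.array(list(positions.residues))
    z_wt = np.array([scale.z.get(a, np.nan) for a in wt])
    score = z_wt - consensus

    df = pd.DataFrame(
        {
            "wt": wt,
            "consensus_hydropathy": consensus,
            "score": score,
        },
        index=pd.Index(positions.positions, name="position"),
    )
    scored = df["score"].notna()
    ranks = (-df.loc[scored, "score"].abs()).rank(method="first").astype(int)
    df["rank_abs"] = ranks.reindex(df.index)
    df["sign"] = np.where(df["score"] > 0, "+", "-")
    df.loc[~scored, "sign"] = ""

    # Highest-conserved non-wild-type residue per position.
    rates = cons.rates.to_numpy().copy()
    aa_idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    for k, a in enumerate(wt):
        if a in aa_idx:
            rates[aa_idx[a], k] = -np.inf
    best = rates.argmax(axis=0)
    best_rate = rates.max(axis=0)
    # argmax takes the first (alphabetically smallest) index on ties.
    df["proposal"] = [AMINO_ACIDS[b] if r > 0 else "" for b, r in zip(best, best_rate)]
    df["proposal_rate_pct"] = np.where(best_rate > 0, best_rate, 0.0)
    return df


def rank_candidates(
    table: pd.DataFrame,
    n_positive: int = 10,
    n_negative: int = 10,
) -> list[MutationCandidate]:
    """The ``n_positive`` largest positive and ``n_negative`` most negative
    scores, each group ordered by descending absolute score.

    Fewer candidates are returned (with a logged warning) when a sign class
    has fewer positions than requested.
    """
    scored = table[table["score"].notna()]
    pos = scored[scored["score"] > 0].nlargest(n_positive, "score")
    neg = scored[scored["score"] < 0].nsmallest(n_negative, "score")
    if len(pos) < n_positive:
        log.warning("only %d positive-score positions available", len(pos))
    if len(neg) < n_negative:
        log.warning("only %d negative-score positions available", len(neg))

    out: list[MutationCandidate] = []
    for block in (pos, neg):
        for j, row in block.iterrows():
            out.append(_candidate_from_row(int(j), row))
    return out


def _candidate_from_row(j: int, row: pd.Series) -> MutationCandidate:
    proposed = row["proposal"] or None
    return MutationCandidate(
        position=j,
        wild_type=row["wt"],
        proposed=proposed,
        score=float(row["score"]),
        direction="to-hydrophilic" if row["score"] > 0 else "to-hydrophobic",
        proposal_rate_pct=float(row["proposal_rate_pct"]),
        ss_element=row.get("ss") or None,
        reason=None if proposed else "no family support",
    )


def propose_substitution(
    j: int, cons: ConservationMatrix, table: pd.DataFrame
) -> MutationCandidate:
    """Proposal for one position: the non-wild-type residue with the highest
    conservation rate; ties break alphabetically by one-letter code."""
    return _candidate_from_row(j, table.loc[j])


def read_ss2(path: str | Path) -> pd.DataFrame:
    """Parse a PSIPRED ``.ss2`` file.

    Standard VFORMAT columns: residue index, residue letter, predicted state
    (H helix / E strand / C coil), and three per-state confidences.  Header
    and comment lines are skipped.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if len(parts) < 3 or parts[0].startswith("#") or not parts[0].isdigit():
            continue
        rows.append((int(parts[0]), parts[1], parts[2]))
    df = pd.DataFrame(rows, columns=["position", "residue", "state"])
    bad = set(df["state"]) - {"H", "E", "C"}
    if bad:
        raise ValueError(f"unknown secondary-structure states: {sorted(bad)}")
    return df.set_index("position")


def annotate_secondary_structure(
    table: pd.DataFrame, ss2: pd.DataFrame | None
) -> pd.DataFrame:
    """Attach per-position H/E/C secondary-structure states to a score table.

    With ``ss2=None`` the table is returned unchanged (no ``ss`` column).
    Raises on length mismatch between the prediction and the target.
    """
    if ss2 is None or ss2.empty:
        return table
    if len(ss2) != len(table):
        raise ValueError(
            f"annotation length mismatch: ss2 has {len(ss2)} residues, "
            f"target has {len(table)}"
        )
    out = table.copy()
    out["ss"] = ss2["state"].reindex(out.index)
    return out


def ss_summary(candidates: Sequence[MutationCandidate]) -> dict[str, float]:
    """Percentage of candidates per secondary-structure class.

    Returns ``{"helix_pct": ..., "strand_pct": ..., "coil_pct": ...}`` over
    the candidates that carry an annotation.
    """
    states = [c.ss_element for c in candidates if c.ss_element]
    n = len(states)
    if n == 0:
        return {}
    return {
        "helix_pct": 100.0 * states.count("H") / n,
        "strand_pct": 100.0 * states.count("E") / n,
        "coil_pct": 100.0 * states.count("C") / n,
    }


def candidates_frame(candidates: Sequence[MutationCandidate]) -> pd.DataFrame:
    """Candidate list as a DataFrame (for TSV/JSON reports)."""
    return pd.DataFrame(
        {
            "position": [c.position for c in candidates],
            "wt": [c.wild_type for c in candidates],
            "score": [c.score for c in candidates],
            "sign": ["+" if c.score > 0 else "-" for c in candidates],
            "direction": [c.direction for c in candidates],
            "proposal": [c.proposed or "" for c in candidates],
            "proposal_rate_pct": [c.proposal_rate_pct for c in candidates],
            "mutation": [c.mutation or "" for c in candidates],
            "ss": [c.ss_element or "" for c in candidates],
        }
    )
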