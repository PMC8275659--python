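"""Seeded synthetic inputs with known ground truth.

Two generators make every other module testable without external data:

* :func:`generate_family` samples an aligned protein family column-wise from
  per-position residue distributions, so conservation rates and hydropathy-
  mismatch scores have an exact known target.  Columns are independent — no
  phylogenetic correlation, no indels beyond per-column gap sampling — which
  matches how the score itself treats columns and is a deliberate
  simplification.

* :func:`generate_spectrum` builds centroided ESI peak lists of an apo/holo
  protein mixture at a known holo fraction: for each charge z, peaks at
  (M + z * m_H+) / z for both species, Gaussian-envelope intensities across
  charges, multiplicative intensity noise, optional m/z jitter.  Denatured
  mode emits the apoprotein only, over a wider charge range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .msa import AMINO_ACIDS, AlignedFamily
from .native_ms import PROTON, PeakList

log = logging.getLogger(__name__)


@dataclass
class FamilySpec:
    """Recipe for a synthetic aligned family.

    Per position, the residue distribution is either a consensus residue held
    at probability ``conservation`` with the remainder spread uniformly over
    the other 19 residues, or an explicit 20-vector in alphabetical residue
    order (``profiles`` overrides consensus/conservation where given).
    """

    target_sequence: str
    n_sequences: int = 50
    conservation: float | Sequence[float] = 0.7
    consensus: str | None = None  # defaults to the target sequence itself
    profiles: dict[int, Sequence[float]] | None = None  # 1-based position -> 20-vector
    gap_rate: float | Sequence[float] = 0.0
    seed: int = 0
    target_id: str = "target"

    def __post_init__(self) -> None:
        L = len(self.target_sequence)
        if not L:
            raise ValueError("bad spec: empty target sequence")
        if set(self.target_sequence) - set(AMINO_ACIDS):
            raise ValueError("bad spec: target must use the 20 standard residues")
        if self.consensus is not None and len(self.consensus) != L:
            raise ValueError("bad spec: consensus length mismatch")
        self._p_cons = np.broadcast_to(
            np.asarray(self.conservation, dtype=float), (L,)
        ).copy()
        self._p_gap = np.broadcast_to(np.asarray(self.gap_rate, dtype=float), (L,)).copy()
        if np.any((self._p_cons < 0) | (self._p_cons > 1)):
            raise ValueError("bad spec: conservation must be in [0, 1]")
        if np.any((self._p_gap < 0) | (self._p_gap >= 1)):
            raise ValueError("bad spec: gap_rate must be in [0, 1)")

    def probabilities(self) -> np.ndarray:
        """L x 20 residue probabilities per position (excluding gaps)."""
        L = len(self.target_sequence)
        consensus = self.consensus or self.target_sequence
        probs = np.empty((L, len(AMINO_ACIDS)))
        for k in range(L):
            if self.profiles and (k + 1) in self.profiles:
                p = np.asarray(self.profiles[k + 1], dtype=float)
                if p.shape != (20,) or p.min() < 0 or not np.isclose(p.sum(), 1.0):
                    raise ValueError(f"bad spec: profile at position {k + 1}")
                probs[k] = p
            else:
                pc = self._p_cons[k]
                probs[k] = (1.0 - pc) / 19.0
                probs[k, AMINO_ACIDS.index(consensus[k])] = pc
        return probs


def generate_family(spec: FamilySpec) -> AlignedFamily:
    """Sample a family; the target is included verbatim as its own row.

    Deterministic under a fixed seed.  Homolog rows are drawn column-wise
    i.i.d.: first a gap/no-gap Bernoulli draw, then a residue from the
    position's categorical distribution.
    """
    rng = np.random.default_rng(spec.seed)
    L = len(spec.target_sequence)
    probs = spec.probabilities()
    n_homologs = spec.n_sequences - 1
    if n_homologs < 0:
        raise ValueError("bad spec: need n_sequences >= 1")
    letters = np.array(list(AMINO_ACIDS))
    rows = []
    for _ in range(n_homologs):
        chars = np.empty(L, dtype="<U1")
        for k in range(L):
            if spec._p_gap[k] and rng.random() < spec._p_gap[k]:
                chars[k] = "-"
            else:
                chars[k] = letters[rng.choice(20, p=probs[k])]
        rows.append("".join(chars))
    ids = (spec.target_id,) + tuple(f"homolog_{i + 1}" for i in range(n_homologs))
    return AlignedFamily(ids=ids, rows=(spec.target_sequence, *rows),
                         target_id=spec.target_id)


def random_target(length: int, seed: int) -> str:
    """A uniformly random standard-residue sequence (handy for tests)."""
    rng = np.random.default_rng(seed)
    return "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, size=length)])


@dataclass
class SpectrumSpec:
    """Recipe for a synthetic centroided ESI spectrum of an apo/holo mixture."""

    protein_mass: float = 41216.78
    cofactor_mass: float = 616.5
    holo_fraction: float = 0.7
    charge_range: tuple[int, int] = (10, 15)
    peak_width: float = 0.5  # Th; used only for the resolution warning
    intensity_envelope: Sequence[float] | None = None  # per charge, low z first
    noise_cv: float = 0.0
    mz_jitter: float = 0.0  # Th, uniform half-width
    condition: str = "native"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.holo_fraction <= 1.0):
            raise ValueError("bad spec: holo_fraction must be in [0, 1]")
        if self.charge_range[0] < 1 or self.charge_range[0] > self.charge_range[1]:
            raise ValueError("bad spec: invalid charge range")
        if self.peak_width <= 0:
            raise ValueError("bad spec: peak width must be positive")

    def charges(self) -> np.ndarray:
        return np.arange(self.charge_range[0], self.charge_range[1] + 1)

    def envelope(self) -> np.ndarray:
        """Per-charge relative intensities; default: Gaussian over the window."""
        z = self.charges().astype(float)
        if self.intensity_envelope is not None:
            env = np.asarray(self.intensity_envelope, dtype=float)
            if env.shape != z.shape:
                raise ValueError("bad spec: envelope length != number of charges")
            return env
        centre = z.mean()
        width = max((z[-1] - z[0]) / 3.0, 1.0)
        return np.exp(-0.5 * ((z - centre) / width) ** 2)


def generate_spectrum(spec: SpectrumSpec) -> PeakList:
    """Centroid peaks of the apo (and, natively, holo) charge-state envelopes.

    Intensities are envelope x {1 - f, f} x (1 + noise) with multiplicative
    Gaussian noise of coefficient of variation ``noise_cv`` (clipped so
    intensities stay non-negative).  In denatured mode only the bare protein
    envelope is emitted, over a charge window widened by 50%.
    """
    rng = np.random.default_rng(spec.seed)
    denatured = spec.condition == "denatured"
    if denatured:
        z_lo, z_hi = spec.charge_range
        extra = max(1, (z_hi - z_lo + 1) // 2)
        charges = np.arange(z_lo, z_hi + extra + 1).astype(float)
        centre, width = charges.mean(), max((charges[-1] - charges[0]) / 3.0, 1.0)
        env = np.exp(-0.5 * ((charges - centre) / width) ** 2)
        fractions = {"apo": 1.0}
    else:
        charges = spec.charges().astype(float)
        env = spec.envelope()
        fractions = {"apo": 1.0 - spec.holo_fraction, "holo": spec.holo_fraction}

    min_gap = min(spec.cofactor_mass / z for z in charges)
    if not denatured and 0 < spec.holo_fraction < 1 and min_gap < spec.peak_width:
        log.warning(
            "unresolved pair: apo/holo spacing %.2f Th below peak width %.2f Th",
            min_gap, spec.peak_width,
        )

    mzs, ints = [], []
    for z, e in zip(charges, env):
        for species, frac in fractions.items():
            if frac <= 0:
                continue
            mass = spec.protein_mass + (spec.cofactor_mass if species == "holo" else 0)
            mz = (mass + z * PROTON) / z
            if spec.mz_jitter:
                mz += rng.uniform(-spec.mz_jitter, spec.mz_jitter)
            intensity = e * frac
            if spec.noise_cv:
                intensity *= max(1.0 + rng.normal(0.0, spec.noise_cv), 0.0)
            mzs.append(mz)
            ints.append(intensity)
    order = np.argsort(mzs)
    return PeakList(
        np.asarray(mzs)[order], np.asarray(ints)[order],
        condition=spec.condition,
        label=f"synthetic seed={spec.seed}",
    )
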