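"""Native ESI-MS: charge-state deconvolution and heme-occupancy estimation.

Electrospray ionisation of a folded protein produces a short series of peaks
at consecutive charges z, at m/z = (M + z * m_H+) / z.  Deconvolution inverts
this: among all assignments of consecutive charges to the observed peaks
(highest charge on the lowest m/z peak), the one whose per-peak neutral-mass
estimates are most self-consistent — minimal standard deviation — wins.

A heme protein appears as two interleaved envelopes, apoprotein (cofactor-
free) and holoprotein, whose neutral masses differ by the cofactor mass
(heme b, ~616 Da average).  Pairing the two species and comparing apo vs holo
peak intensities charge-by-charge yields a relative cofactor-occupancy
estimate, assuming the cofactor does not change ionisation efficiency.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass

#: Proton mass (Da); the adduct per charge for [M + zH]z+ positive-mode ESI.
PROTON = 1.007276

ELECTRON = 0.000548579909

#: Elemental composition of protoheme IX (heme b), the iron-protoporphyrin IX
#: cofactor of aldoxime dehydratases.
HEME_B_FORMULA = "C34H32FeN4O4"

#: Average mass of heme b; the default expected apo/holo native mass shift.
HEME_B_AVERAGE_MASS = 616.5


class DeconvolutionError(ValueError):
    """Raised when no consistent charge assignment (or pairing) exists."""


@dataclass
class PeakList:
    """A centroided peak list (m/z ascending, intensities >= 0)."""

    mz: np.ndarray
    intensity: np.ndarray
    condition: str = "native"  # "native" or "denatured"
    label: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have the same length")
        if len(self.mz) and np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.mz)

    def subset(self, indices: np.ndarray) -> "PeakList":
        indices = np.sort(np.asarray(indices))
        return PeakList(self.mz[indices], self.intensity[indices],
                        self.condition, self.label)


def read_peaklist(path: str | Path) -> PeakList:
    """Read a 2-column TSV (mz, intensity); ``# condition: ...`` header
    comments set the measurement condition."""
    condition, label = "native", Path(path).stem
    mzs, ints = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("condition:"):
                condition = body.split(":", 1)[1].strip()
            continue
        parts = line.replace(",", "\t").split()
        if parts[0].lower() in ("mz", "m/z"):
            continue
        mzs.append(float(parts[0]))
        ints.append(float(parts[1]))
    order = np.argsort(mzs)
    return PeakList(np.array(mzs)[order], np.array(ints)[order],
                    condition=condition, label=label)


def write_peaklist(peaks: PeakList, path: str | Path, header: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"# condition: {peaks.condition}\n")
        if header:
            fh.write(f"# {header}\n")
        fh.write("mz\tintensity\n")
        for m, i in zip(peaks.mz, peaks.intensity):
            fh.write(f"{m:.6f}\t{i:.6f}\n")


def read_mzml_centroided(path: str | Path, index: int = 0,
                         condition: str = "native") -> PeakList:
    """Read one centroided spectrum from an mzML file.

    Profile-mode spectra are rejected: baseline subtraction / smoothing /
    centroiding are upstream vendor-software steps, out of scope here.
    """
    from pyteomics import mzml

    with mzml.read(str(path)) as reader:
        spectrum = next(itertools.islice(reader, index, None))
    if "profile spectrum" in spectrum:
        raise ValueError("profile-mode spectrum: supply centroided data")
    order = np.argsort(spectrum["m/z array"])
    return PeakList(spectrum["m/z array"][order],
                    spectrum["intensity array"][order],
                    condition=condition, label=spectrum.get("id", ""))


def cofactor_monoisotopic_mz(
    formula: str, charge: int = 1, *, subtract_electron: bool = False
) -> float:
    """Theoretical m/z of a cofactor ion from its elemental composition.

    Neutral monoisotopic mass divided by charge; the electron mass is
    neglected by default (for heme b this matches the conventional
    theoretical value to ~0.1 mmu) but can be subtracted.
    """
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    try:
        m = _ptmass.calculate_mass(formula=formula)
    except Exception as exc:  # unknown element symbol
        raise ValueError(f"no mass for element in formula {formula!r}") from exc
    if subtract_electron:
        m -= charge * ELECTRON
    return m / charge


def cofactor_average_mass(formula: str = HEME_B_FORMULA) -> float:
    """Isotope-abundance-weighted (average) mass of a formula."""
    return _ptmass.calculate_mass(formula=formula, average=True)


@dataclass
class MassSpeciesEstimate:
    """A deconvoluted protein species: mass +/- sd with per-charge evidence."""

    mass: float
    sd: float
    charge_range: tuple[int, int]
    per_charge_intensity: dict[int, float]
    per_peak_mass: dict[int, float] = field(default_factory=dict)

    @property
    def charges(self) -> list[int]:
        return sorted(self.per_charge_intensity)

    def predicted_mz(self, z: int, adduct: float = PROTON) -> float:
        return (self.mass + z * adduct) / z


def _series_masses(mz: np.ndarray, charges: np.ndarray,
                   adduct: float) -> np.ndarray:
    return charges * (mz - adduct)


def deconvolute(
    peaks: PeakList,
    z_min: int,
    z_max: int,
    min_peaks: int = 2,
    *,
    adduct: float = PROTON,
    sd_bound: float = 200.0,
) -> MassSpeciesEstimate:
    """Assign consecutive charges to ALL peaks and estimate the neutral mass.

    Every assignment of consecutive charges within ``[z_min, z_max]`` —
    highest charge on the lowest-m/z peak, descending as m/z ascends — is
    scored by the standard deviation of the per-peak mass estimates
    ``z_k * (mz_k - adduct)``; the minimal-sd assignment wins.  Assignments
    whose best sd exceeds ``sd_bound`` are rejected as inconsistent.
    """
    n = len(peaks)
    if n < min_peaks:
        raise DeconvolutionError(f"insufficient peaks: {n} < {min_peaks}")
    if not (1 <= z_min < z_max):
        raise ValueError("need 1 <= z_min < z_max")
    if z_max - z_min + 1 < n:
        raise DeconvolutionError(
            f"charge window [{z_min}, {z_max}] narrower than peak count {n}"
        )

    best = None
    for z_top in range(z_max, z_min + n - 2, -1):
        charges = np.arange(z_top, z_top - n, -1)
        if charges[-1] < z_min:
            continue
        masses = _series_masses(peaks.mz, charges, adduct)
        sd = float(masses.std())
        if best is None or sd < best[0]:
            best = (sd, charges, masses)
    if best is None or best[0] > sd_bound:
        raise DeconvolutionError("no consistent charge series")
    sd, charges, masses = best
    return MassSpeciesEstimate(
        mass=float(masses.mean()),
        sd=sd,
        charge_range=(int(charges.min()), int(charges.max())),
        per_charge_intensity={int(z): float(i)
                              for z, i in zip(charges, peaks.intensity)},
        per_peak_mass={int(z): float(m) for z, m in zip(charges, masses)},
    )


def find_species(
    peaks: PeakList,
    z_min: int,
    z_max: int,
    *,
    n_species: int = 2,
    min_peaks: int = 2,
    mz_tol: float = 2.0,
    adduct: float = PROTON,
    sd_bound: float = 200.0,
) -> list[MassSpeciesEstimate]:
    """Extract up to ``n_species`` charge series from a mixed peak list.

    Seed-and-extend: each (peak, charge) hypothesis implies a neutral mass;
    the series is grown by looking for a peak within ``mz_tol`` of the
    predicted m/z at every other charge in the window, keeping the maximal
    consecutive run through the seed.  The longest series wins (ties: lowest
    mass sd, then highest summed intensity); its peaks are removed and the
    search repeats.  Heavier-species results are returned sorted by mass.
    """
    remaining = np.arange(len(peaks))
    species: list[MassSpeciesEstimate] = []
    while len(remaining) >= min_peaks and len(species) < n_species:
        sub = peaks.subset(remaining)
        found = _best_series(sub, z_min, z_max, min_peaks, mz_tol, adduct, sd_bound)
        if found is None:
            break
        est, used_local = found
        species.append(est)
        remaining = np.delete(remaining, used_local)
    if not species:
        raise DeconvolutionError("no consistent charge series")
    return sorted(species, key=lambda s: s.mass)


def _best_series(peaks, z_min, z_max, min_peaks, mz_tol, adduct, sd_bound):
    best = None
    mz = peaks.mz
    for seed in range(len(mz)):
        for z_seed in range(z_min, z_max + 1):
            m_hat = z_seed * (mz[seed] - adduct)
            if m_hat <= 0:
                continue
            matched: dict[int, int] = {}
            for z in range(z_min, z_max + 1):
                pred = (m_hat + z * adduct) / z
                k = int(np.argmin(np.abs(mz - pred)))
                if abs(mz[k] - pred) <= mz_tol:
                    matched[z] = k
            if z_seed not in matched:
                continue
            run = _consecutive_run(sorted(matched), z_seed)
            if len(run) < min_peaks:
                continue
            idx = np.array([matched[z] for z in run])
            if len(set(idx.tolist())) != len(idx):
                continue
            charges = np.array(run, dtype=float)
            masses = charges * (mz[idx] - adduct)
            sd = float(masses.std())
            if sd > sd_bound:
                continue
            total = float(peaks.intensity[idx].sum())
            key = (-len(run), sd, -total)
            if best is None or key < best[0]:
                est = MassSpeciesEstimate(
                    mass=float(masses.mean()),
                    sd=sd,
                    charge_range=(min(run), max(run)),
                    per_charge_intensity={
                        int(z): float(peaks.intensity[k])
                        for z, k in zip(run, idx)
                    },
                    per_peak_mass={int(z): float(m)
                                   for z, m in zip(run, masses)},
                )
                best = (key, est, idx)
    if best is None:
        return None
    return best[1], best[2]


def _consecutive_run(charges: list[int], anchor: int) -> list[int]:
    """Maximal run of consecutive integers in ``charges`` containing
    ``anchor``."""
    s = set(charges)
    lo = hi = anchor
    while lo - 1 in s:
        lo -= 1
    while hi + 1 in s:
        hi += 1
    return list(range(lo, hi + 1))


@dataclass
class ApoHoloResult:
    """A matched apo/holo species pair with its occupancy estimate."""

    apo: MassSpeciesEstimate
    holo: MassSpeciesEstimate
    shift: float
    heme_fraction: float
    per_charge_fraction: dict[int, float]

    @property
    def matched_charges(self) -> list[int]:
        return sorted(self.per_charge_fraction)


def pair_apo_holo(
    species: list[MassSpeciesEstimate],
    expected_shift: float = HEME_B_AVERAGE_MASS,
    window: float = 40.0,
) -> ApoHoloResult:
    """Pair the two species whose mass difference best matches the cofactor.

    Among all pairs, the one with mass difference closest to
    ``expected_shift`` and within ``+/- window`` of it is selected; the
    lighter species is the apoprotein, the heavier the holoprotein.
    """
    if len(species) < 2:
        raise DeconvolutionError("no apo/holo pair: need at least 2 species")
    best = None
    for a, b in itertools.combinations(species, 2):
        lo, hi = (a, b) if a.mass <= b.mass else (b, a)
        shift = hi.mass - lo.mass
        miss = abs(shift - expected_shift)
        if miss > window:
            continue
        if best is None or miss < best[0]:
            best = (miss, lo, hi, shift)
    if best is None:
        raise DeconvolutionError(
            f"no apo/holo pair within {expected_shift} +/- {window} Da"
        )
    _, apo, holo, shift = best
    common = sorted(set(apo.per_charge_intensity) & set(holo.per_charge_intensity))
    per_charge = {}
    apo_total = holo_total = 0.0
    for z in common:
        ia, ih = apo.per_charge_intensity[z], holo.per_charge_intensity[z]
        apo_total += ia
        holo_total += ih
        if ia + ih > 0:
            per_charge[z] = ih / (ia + ih)
    total = apo_total + holo_total
    fraction = holo_total / total if total > 0 else float("nan")
    return ApoHoloResult(apo=apo, holo=holo, shift=shift,
                         heme_fraction=fraction, per_charge_fraction=per_charge)


def heme_content(result: ApoHoloResult) -> float:
    """Aggregate holo fraction over matched charge states, in [0, 1].

    The underlying assumption is equal ionisation efficiency of apo and holo
    forms, so peak-intensity integrals are proportional to solution amounts.
    """
    if not np.isfinite(result.heme_fraction):
        raise DeconvolutionError("empty envelope: zero total intensity")
    if not result.per_charge_fraction:
        raise DeconvolutionError("no matched charge states in pairing")
    return result.heme_fraction


def estimate_heme_fraction(
    peaks: PeakList,
    z_min: int,
    z_max: int,
    *,
    expected_shift: float = HEME_B_AVERAGE_MASS,
    window: float = 40.0,
    **find_kwargs,
) -> ApoHoloResult:
    """End-to-end pipeline: species extraction -> pairing -> occupancy."""
    species = find_species(peaks, z_min, z_max, n_species=2, **find_kwargs)
    result = pair_apo_holo(species, expected_shift=expected_shift, window=window)
    heme_content(result)  # validates
    return result


def overlay_report(
    native: ApoHoloResult,
    denatured: MassSpeciesEstimate,
    *,
    adduct: float = PROTON,
) -> pd.DataFrame:
    """Overlay table of native apo/holo vs denatured species.

    One row per charge state present in any species, giving predicted m/z
    positions, plus the native-minus-denatured mass differences.  When the
    heavy-native-minus-denatured difference deviates from the native
    apo/holo shift by more than the pooled mass sds, the row comment flags
    it (typical causes: salt adducts, incomplete desolvation).
    """
    charges = sorted(
        set(native.apo.charges) | set(native.holo.charges) | set(denatured.charges)
    )
    rows = []
    for z in charges:
        rows.append(
            {
                "charge": z,
                "mz_apo": native.apo.predicted_mz(z, adduct),
                "mz_holo": native.holo.predicted_mz(z, adduct),
                "mz_denatured": denatured.predicted_mz(z, adduct),
            }
        )
    df = pd.DataFrame(rows).set_index("charge")
    df.attrs["delta_holo_minus_denatured"] = native.holo.mass - denatured.mass
    df.attrs["delta_apo_minus_denatured"] = native.apo.mass - denatured.mass
    df.attrs["apo_holo_shift"] = native.shift
    tol = native.holo.sd + denatured.sd + native.apo.sd
    mismatch = abs(
        df.attrs["delta_holo_minus_denatured"] - native.shift
    )
    df.attrs["flag"] = (
        "delta(native holo - denatured) differs from the apo/holo shift by "
        f"{mismatch:.1f} Da (pooled sd {tol:.1f} Da); possible salt adducts"
        if mismatch > max(tol, 1.0)
        else ""
    )
    return df


def result_to_json(result: ApoHoloResult) -> str:
    """Serialise an apo/holo analysis as the JSON report format."""
    payload = {
        "species": [
            {
                "role": role,
                "mass_da": est.mass,
                "sd_da": est.sd,
                "charge_range": list(est.charge_range),
                "per_charge_intensity": {str(z): i for z, i
                                         in est.per_charge_intensity.items()},
            }
            for role, est in (("apo", result.apo), ("holo", result.holo))
        ],
        "shift_da": result.shift,
        "heme_fraction": result.heme_fraction,
        "per_charge_fraction": {str(z): f for z, f
                                in result.per_charge_fraction.items()},
    }
    return json.dumps(payload, indent=2)
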