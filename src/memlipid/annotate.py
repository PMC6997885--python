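"""Peak-list annotation: match observed m/z against a species database.

Matching is a plain ppm-window search: a peak is assigned to every
database entry whose adduct m/z lies within ``tol_ppm`` (inclusive, the
window is closed at the boundary).  Peaks matching more than one entry
are flagged ambiguous and retained — downstream quantification splits
their intensity equally among the isobars unless MS2 evidence resolves
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .species import LipidSpecies, species_mz

__all__ = [
    "Peak",
    "MatchConfig",
    "PeakAssignment",
    "DEFAULT_ADDUCTS",
    "match_peaks",
    "read_peaks",
    "write_peaks",
    "assignments_frame",
]


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("m/z must be positive")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


#: default ionization per class: protonation for choline lipids, ammonium
#: adducts for neutral/storage lipids, deprotonation for everything measured
#: in negative mode.
DEFAULT_ADDUCTS: dict[str, dict[str, str]] = {
    "positive": {
        **{c: "[M+H]+" for c in ("PC", "LPC")},
        **{c: "[M+NH4]+" for c in ("DG", "TG", "EE")},
    },
    "negative": {
        c: "[M-H]-"
        for c in (
            "PE", "PI", "PS", "PA", "PG", "CL",
            "LPE", "LPI", "LPS", "Cer", "IPC", "MIPC",
        )
    },
}


@dataclass(frozen=True)
class MatchConfig:
    tol_ppm: float = 3.0
    polarity: str = "negative"
    adducts: dict | None = None  # class -> adduct, overrides the default

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")

    def adduct_for(self, lipid_class: str) -> str | None:
        if self.adducts and lipid_class in self.adducts:
            return self.adducts[lipid_class]
        return DEFAULT_ADDUCTS[self.polarity].get(lipid_class)


@dataclass(frozen=True)
class PeakAssignment:
    peak: Peak
    species: LipidSpecies
    adduct: str
    mz_theoretical: float
    ppm_error: float
    ambiguous: bool = False
    n_candidates: int = 1

    @property
    def split_intensity(self) -> float:
        """Peak intensity apportioned equally among isobaric candidates."""
        return self.peak.intensity / self.n_candidates


def match_peaks(
    peaks: Iterable[Peak],
    database: Sequence[LipidSpecies],
    config: MatchConfig = MatchConfig(),
) -> list[PeakAssignment]:
    """Assign peaks to database species within the ppm tolerance.

    Every candidate within tolerance is reported; a peak with more than
    one candidate yields one flagged assignment per candidate.  Classes
    without an adduct for the configured polarity are skipped.
    """
    entries = []
    for sp in database:
        adduct = config.adduct_for(sp.lipid_class)
        if adduct is None:
            continue
        entries.append((species_mz(sp, adduct), sp, adduct))
    if not entries:
        return []
    entries.sort(key=lambda e: e[0])
    theo = np.array([e[0] for e in entries])

    out: list[PeakAssignment] = []
    for peak in peaks:
        half = peak.mz * config.tol_ppm * 1e-6
        lo = np.searchsorted(theo, peak.mz - half, side="left")
        hi = np.searchsorted(theo, peak.mz + half, side="right")
        hits = [
            (mz_t, sp, adduct)
            for mz_t, sp, adduct in entries[lo:hi]
            if abs(peak.mz - mz_t) / mz_t * 1e6 <= config.tol_ppm
        ]
        for mz_t, sp, adduct in hits:
            out.append(
                PeakAssignment(
                    peak=peak,
                    species=sp,
                    adduct=adduct,
                    mz_theoretical=mz_t,
                    ppm_error=(peak.mz - mz_t) / mz_t * 1e6,
                    ambiguous=len(hits) > 1,
                    n_candidates=len(hits),
                )
            )
    return out


def read_peaks(path: str | Path) -> list[Peak]:
    """Read a TSV/CSV peak list with columns ``mz`` and ``intensity``."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    return [Peak(float(r.mz), float(r.intensity)) for r in df.itertuples()]


def write_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    pd.DataFrame([(p.mz, p.intensity) for p in peaks], columns=["mz", "intensity"]).to_csv(
        path, sep="\t", index=False
    )


def assignments_frame(assignments: Iterable[PeakAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": a.species.label,
            "lipid_class": a.species.lipid_class,
            "adduct": a.adduct,
            "mz_observed": a.peak.mz,
            "mz_theoretical": a.mz_theoretical,
            "ppm_error": a.ppm_error,
            "intensity": a.peak.intensity,
            "ambiguous": a.ambiguous,
        }
        for a in assignments
    )
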