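"""Internal-standard quantification and mol%-of-polar-lipids profiles.

One spiked standard per lipid class; assuming unit response factors the
molar amount of a species is its intensity relative to the class
standard times the spiked amount.  Mol% is expressed over polar lipids
only (glycerophospholipids + sphingolipids); storage lipids are
quantified in pmol but excluded from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .annotate import PeakAssignment
from .species import LipidSpecies, POLAR_CLASSES

__all__ = ["InternalStandard", "QuantRecord", "quantify_species", "class_profiles"]


@dataclass(frozen=True)
class InternalStandard:
    lipid_class: str
    label: str  # species label of the spiked standard, e.g. "PC d31-16:0/18:1"
    spiked_pmol: float

    def __post_init__(self) -> None:
        if self.spiked_pmol <= 0:
            raise ValueError("spiked amount must be positive")


@dataclass(frozen=True)
class QuantRecord:
    species: LipidSpecies
    amount_pmol: float
    mol_percent_polar: float


def quantify_species(
    assignments: Sequence[PeakAssignment],
    standards: Sequence[InternalStandard],
) -> list[QuantRecord]:
    """Quantify assigned species against per-class internal standards.

    amount(species) = intensity(species) / intensity(class standard)
                      x spiked_pmol(class standard)

    Ambiguous (isobaric) assignments contribute their equally split
    intensity.  Raises ``ValueError`` naming the class when a class
    lacks a standard or its standard peak is missing/zero.
    """
    std_by_class = {s.lipid_class: s for s in standards}
    std_labels = {s.label for s in standards}

    # intensity per species label (isobar-split), standards separated out
    intensity: dict[str, float] = {}
    species_by_label: dict[str, LipidSpecies] = {}
    std_intensity: dict[str, float] = {}
    for a in assignments:
        lbl = a.species.label
        if lbl in std_labels:
            std_intensity[lbl] = std_intensity.get(lbl, 0.0) + a.split_intensity
        else:
            intensity[lbl] = intensity.get(lbl, 0.0) + a.split_intensity
            species_by_label[lbl] = a.species

    amounts: dict[str, float] = {}
    for lbl, inten in intensity.items():
        cls = species_by_label[lbl].lipid_class
        std = std_by_class.get(cls)
        if std is None:
            raise ValueError(f"no internal standard for class {cls}")
        ref = std_intensity.get(std.label, 0.0)
        if ref <= 0:
            raise ValueError(f"missing or zero-intensity standard peak for class {cls}")
        amounts[lbl] = inten / ref * std.spiked_pmol

    polar_total = sum(
        amt
        for lbl, amt in amounts.items()
        if species_by_label[lbl].lipid_class in POLAR_CLASSES
    )
    records = []
    for lbl, amt in amounts.items():
        sp = species_by_label[lbl]
        molpct = (
            100.0 * amt / polar_total
            if sp.lipid_class in POLAR_CLASSES and polar_total > 0
            else 0.0
        )
        records.append(QuantRecord(sp, amt, molpct))
    records.sort(key=lambda r: (r.species.lipid_class, r.species.label))
    return records


def class_profiles(records: Iterable[QuantRecord]) -> tuple[pd.Series, pd.DataFrame]:
    """Per-class mol% (over polar classes) and within-class species mol%.

    Returns ``(class_molpct, species_table)``; ``class_molpct`` sums to
    100 over polar classes, and within each class the species fractions
    sum to 100.
    """
    rows = [
        (r.species.lipid_class, r.species.label, r.amount_pmol)
        for r in records
        if r.species.lipid_class in POLAR_CLASSES
    ]
    if not rows:
        raise ValueError("no polar-lipid quantities")
    df = pd.DataFrame(rows, columns=["lipid_class", "label", "amount_pmol"])
    total = df["amount_pmol"].sum()
    if total <= 0:
        raise ValueError("all polar-lipid amounts are zero")
    class_molpct = df.groupby("lipid_class")["amount_pmol"].sum() / total * 100.0
    df["within_class_pct"] = df.groupby("lipid_class")["amount_pmol"].transform(
        lambda s: s / s.sum() * 100.0
    )
    df["mol_percent_polar"] = df["amount_pmol"] / total * 100.0
    return class_molpct, df
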