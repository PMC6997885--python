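"""Lipid species model: classes, acyl chains, naming and exact masses.

Species are annotated at two levels, following shotgun-lipidomics
convention: *sum* composition (``PC 34:1`` — total acyl carbons : total
double bonds, chains unresolved) and *sn-resolved* composition
(``PI 18:0/10:0`` — sn-1 chain / sn-2 chain).  Sphingolipid sum
compositions carry a third number counting hydroxyl groups
(``Cer 44:0:4``).

The per-class head-group/backbone atom table below is the package's own;
each species formula is assembled as

    head-group alcohol + sum of fatty-acid formulas - one water per ester

and, for sphingolipids, from the long-chain-base + amide-linked fatty
acid arithmetic.  The table is validated against an independently coded
atomic-summation oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .chemistry import ElementalComposition, WATER, adduct_mz, monoisotopic_mass

__all__ = [
    "AcylChain",
    "LipidSpecies",
    "GLYCEROPHOSPHOLIPID_CLASSES",
    "SPHINGOLIPID_CLASSES",
    "NEUTRAL_CLASSES",
    "POLAR_CLASSES",
    "LIPID_CLASSES",
    "N_CHAINS",
    "build_species_database",
    "elemental_composition",
    "species_mass",
    "species_mz",
    "parse_label",
]


@dataclass(frozen=True, order=True)
class AcylChain:
    """A fatty-acyl chain (or, at sum level, the total over all chains).

    ``deuteriums`` supports deuterated internal standards such as the
    d31-palmitoyl chain of the spiked PC standard.
    """

    carbons: int
    double_bonds: int = 0
    hydroxyls: int = 0
    deuteriums: int = 0

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError("acyl chain needs at least 2 carbons")
        if not 0 <= self.double_bonds <= self.carbons // 2:
            raise ValueError("double bond count out of range")
        if self.hydroxyls < 0 or self.deuteriums < 0:
            raise ValueError("hydroxyl/deuterium counts must be >= 0")

    @property
    def label(self) -> str:
        core = f"{self.carbons}:{self.double_bonds}"
        if self.hydroxyls:
            core += f":{self.hydroxyls}"
        if self.deuteriums:
            core = f"d{self.deuteriums}-{core}"
        return core

    def acid_composition(self) -> ElementalComposition:
        """Elemental composition of the free fatty acid CnH(2n-2d)O2."""
        h = 2 * self.carbons - 2 * self.double_bonds - self.deuteriums
        if h < 0:
            raise ValueError("more deuteriums than hydrogens")
        comp = ElementalComposition(
            {"C": self.carbons, "H": h, "O": 2 + self.hydroxyls}
        )
        if self.deuteriums:
            comp["H[2]"] = self.deuteriums
        if comp["H"] == 0:
            del comp["H"]
        return comp


# Head-group alcohol compositions (glycerophospho-X for GPLs, glycerol for
# glycerolipids, ergosterol for steryl esters).  Species formula =
# head + sum(FA) - n_chains * H2O.
_HEAD: dict[str, ElementalComposition] = {
    "PC": ElementalComposition({"C": 8, "H": 20, "N": 1, "O": 6, "P": 1}),
    "PE": ElementalComposition({"C": 5, "H": 14, "N": 1, "O": 6, "P": 1}),
    "PI": ElementalComposition({"C": 9, "H": 19, "O": 11, "P": 1}),
    "PS": ElementalComposition({"C": 6, "H": 14, "N": 1, "O": 8, "P": 1}),
    "PA": ElementalComposition({"C": 3, "H": 9, "O": 6, "P": 1}),
    "PG": ElementalComposition({"C": 6, "H": 15, "O": 8, "P": 1}),
    "CL": ElementalComposition({"C": 9, "H": 22, "O": 13, "P": 2}),
    "DG": ElementalComposition({"C": 3, "H": 8, "O": 3}),
    "TG": ElementalComposition({"C": 3, "H": 8, "O": 3}),
    "EE": ElementalComposition({"C": 28, "H": 44, "O": 1}),
}
_HEAD["LPC"] = _HEAD["PC"]
_HEAD["LPE"] = _HEAD["PE"]
_HEAD["LPI"] = _HEAD["PI"]
_HEAD["LPS"] = _HEAD["PS"]

# Sphingolipid head additions on top of the ceramide formula.
_SPHINGO_HEAD: dict[str, ElementalComposition] = {
    "Cer": ElementalComposition(),
    # + inositol phosphate, condensed (C6H13O9P - H2O)
    "IPC": ElementalComposition({"C": 6, "H": 11, "O": 8, "P": 1}),
    # + mannose, condensed (C6H12O6 - H2O)
    "MIPC": ElementalComposition({"C": 12, "H": 21, "O": 13, "P": 1}),
}

GLYCEROPHOSPHOLIPID_CLASSES = frozenset(
    {"PC", "PE", "PI", "PS", "PA", "PG", "CL", "LPC", "LPE", "LPI", "LPS"}
)
SPHINGOLIPID_CLASSES = frozenset({"Cer", "IPC", "MIPC"})
NEUTRAL_CLASSES = frozenset({"DG", "TG", "EE"})
#: classes entering the mol%-of-polar-lipids denominator (GPLs + sphingolipids)
POLAR_CLASSES = GLYCEROPHOSPHOLIPID_CLASSES | SPHINGOLIPID_CLASSES
LIPID_CLASSES = POLAR_CLASSES | NEUTRAL_CLASSES

#: number of resolved chains per class (sphingolipids: base + amide FA)
N_CHAINS: dict[str, int] = {
    **{c: 2 for c in ("PC", "PE", "PI", "PS", "PA", "PG", "DG")},
    **{c: 1 for c in ("LPC", "LPE", "LPI", "LPS", "EE")},
    "TG": 3,
    "CL": 4,
    "Cer": 2,
    "IPC": 2,
    "MIPC": 2,
}


@dataclass(frozen=True)
class LipidSpecies:
    lipid_class: str
    level: str  # "sum" | "sn_resolved"
    chains: tuple[AcylChain, ...]

    def __post_init__(self) -> None:
        if self.lipid_class not in LIPID_CLASSES:
            raise ValueError(f"unknown lipid class {self.lipid_class!r}")
        if self.level not in ("sum", "sn_resolved"):
            raise ValueError("level must be 'sum' or 'sn_resolved'")
        object.__setattr__(self, "chains", tuple(self.chains))
        if self.level == "sum":
            if len(self.chains) != 1:
                raise ValueError("sum-level species holds one pseudo-chain")
        elif len(self.chains) != N_CHAINS[self.lipid_class]:
            raise ValueError(
                f"{self.lipid_class} requires {N_CHAINS[self.lipid_class]} chains"
            )

    @property
    def total_carbons(self) -> int:
        return sum(c.carbons for c in self.chains)

    @property
    def total_double_bonds(self) -> int:
        return sum(c.double_bonds for c in self.chains)

    @property
    def total_hydroxyls(self) -> int:
        return sum(c.hydroxyls for c in self.chains)

    @property
    def label(self) -> str:
        if self.level == "sum":
            return f"{self.lipid_class} {self.chains[0].label}"
        return f"{self.lipid_class} " + "/".join(c.label for c in self.chains)

    def to_sum(self) -> "LipidSpecies":
        """Collapse to sum composition (no-op on sum-level species)."""
        if self.level == "sum":
            return self
        pseudo = AcylChain(
            self.total_carbons,
            self.total_double_bonds,
            self.total_hydroxyls,
            sum(c.deuteriums for c in self.chains),
        )
        return LipidSpecies(self.lipid_class, "sum", (pseudo,))


def _sum_chain(species: LipidSpecies) -> AcylChain:
    return species.to_sum().chains[0]


def elemental_composition(species: LipidSpecies) -> ElementalComposition:
    """Neutral elemental composition of a lipid species.

    Sum-level and sn-resolved species of the same totals yield the same
    composition (esterification arithmetic depends only on totals).
    """
    cls = species.lipid_class
    if cls in SPHINGOLIPID_CLASSES:
        tot = _sum_chain(species)
        c, d, h = tot.carbons, tot.double_bonds, tot.hydroxyls
        # ceramide = long-chain base + amide-linked FA: C_c H_(2c+1-2d) N O_(h+1)
        comp = ElementalComposition(
            {"C": c, "H": 2 * c + 1 - 2 * d - tot.deuteriums, "N": 1, "O": h + 1}
        )
        if tot.deuteriums:
            comp["H[2]"] = tot.deuteriums
        return comp + _SPHINGO_HEAD[cls]
    if cls not in _HEAD:
        raise ValueError(f"no composition rule for class {cls!r}")
    n_esters = N_CHAINS[cls]
    comp = ElementalComposition(_HEAD[cls])
    if species.level == "sn_resolved":
        for chain in species.chains:
            comp = comp + chain.acid_composition()
    else:
        comp = comp + _sum_chain(species).acid_composition()
        # sum pseudo-chain carries one carboxyl; add the remaining ones
        comp = comp + ElementalComposition({"O": 2 * (n_esters - 1)})
        comp["H"] += 0  # H count already totals 2C-2D across chains
    return comp - n_esters * WATER


def species_mass(species: LipidSpecies) -> float:
    """Neutral monoisotopic mass in Da."""
    return monoisotopic_mass(elemental_composition(species))


def species_mz(species: LipidSpecies, adduct: str) -> float:
    return adduct_mz(species_mass(species), adduct)


def _parse_chain(token: str) -> AcylChain:
    deut = 0
    if token.startswith("d") and "-" in token:
        dpart, token = token.split("-", 1)
        deut = int(dpart[1:])
    parts = [int(p) for p in token.split(":")]
    if len(parts) == 2:
        c, d = parts
        h = 0
    elif len(parts) == 3:
        c, d, h = parts
    else:
        raise ValueError(f"cannot parse chain token {token!r}")
    return AcylChain(c, d, h, deut)


def parse_label(label: str) -> LipidSpecies:
    """Inverse of :attr:`LipidSpecies.label` (round-trip guaranteed)."""
    try:
        cls, rest = label.split(" ", 1)
    except ValueError:
        raise ValueError(f"cannot parse label {label!r}") from None
    chains = tuple(_parse_chain(tok) for tok in rest.split("/"))
    level = "sn_resolved" if "/" in rest else "sum"
    return LipidSpecies(cls, level, chains)


def build_species_database(
    classes: Iterable[str],
    carbon_range: Sequence[int],
    db_range: Sequence[int],
    hydroxyls: int = 0,
) -> list[LipidSpecies]:
    """Enumerate sum-composition species over (class, total C, total DB).

    ``carbon_range`` and ``db_range`` are inclusive ``(lo, hi)`` integer
    intervals; ``hydroxyls`` applies to sphingolipid classes only.  One
    species per combination, unique labels by construction.
    """
    classes = list(classes)
    if not classes:
        raise ValueError("no classes")
    c_lo, c_hi = min(carbon_range), max(carbon_range)
    d_lo, d_hi = min(db_range), max(db_range)
    if c_lo > c_hi or d_lo > d_hi:
        raise ValueError("empty carbon or double-bond range")
    out = []
    for cls in classes:
        if cls not in LIPID_CLASSES:
            raise ValueError(f"unknown lipid class {cls!r}")
        h = hydroxyls if cls in SPHINGOLIPID_CLASSES else 0
        for c in range(c_lo, c_hi + 1):
            for d in range(d_lo, d_hi + 1):
                if d > c // 2:
                    continue
                out.append(
                    LipidSpecies(cls, "sum", (AcylChain(c, d, h),))
                )
    return out
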