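"""sn-regiochemistry from MS2, in-silico PLA2 digestion, acyl summaries.

Glycerophospholipid regiochemistry is read off negative-mode MS2 via the
'intensity rule': neutral losses of the fatty acid (as free acid
[M-H-RCOOH]- or ketene [M-H-R'CH=C=O]-) are more abundant from the sn-2
than from the sn-1 position.  Both loss channels are summed per chain;
the chain with the larger summed loss intensity is called sn-2, and the
call is confident when the sn-2/sn-1 ratio reaches ``min_ratio``
(default 7, the empirical floor for this rule in fission-yeast
lipidomes; inclusive boundary).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotate import Peak
from .chemistry import PROTON_MASS, WATER, monoisotopic_mass
from .species import (
    AcylChain,
    GLYCEROPHOSPHOLIPID_CLASSES,
    LipidSpecies,
    species_mass,
)

__all__ = [
    "Ms2Spectrum",
    "SnAssignment",
    "DigestProduct",
    "diagnostic_fragments",
    "assign_sn_positions",
    "pla2_digest",
    "asymmetry_metrics",
    "acyl_summaries",
    "ASYMMETRY_THRESHOLD",
]

#: chains differing by at least this many carbons count as asymmetrical
#: (covers the 6-8 carbon difference characteristic of C10:0-at-sn-2 lipids)
ASYMMETRY_THRESHOLD = 6

_WATER_MASS = monoisotopic_mass(WATER)

#: diacyl classes digestible by PLA2 into an annotated lyso class
_LYSO_OF = {"PC": "LPC", "PE": "LPE", "PI": "LPI", "PS": "LPS"}


@dataclass(frozen=True)
class Ms2Spectrum:
    precursor_mz: float
    fragments: tuple[Peak, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "fragments", tuple(self.fragments))
        if any(f.mz > self.precursor_mz + 0.5 for f in self.fragments):
            raise ValueError("fragment m/z above precursor")

    def scaled(self, factor: float) -> "Ms2Spectrum":
        return Ms2Spectrum(
            self.precursor_mz,
            tuple(Peak(f.mz, f.intensity * factor) for f in self.fragments),
        )


@dataclass(frozen=True)
class SnAssignment:
    species: LipidSpecies  # sn_resolved, chains ordered (sn-1, sn-2)
    sn2_over_sn1_ratio: float
    confidence: str  # "assigned" | "ambiguous"


@dataclass(frozen=True)
class DigestProduct:
    lyso: LipidSpecies  # sn-1 chain retained
    free_fatty_acid: AcylChain  # released sn-2 chain


def diagnostic_fragments(
    species: LipidSpecies, polarity: str = "negative"
) -> dict[int, dict[str, float]]:
    """Expected diagnostic fragment m/z per chain of an sn-resolved GPL.

    Returns ``{chain_index: {"carboxylate", "acid_loss", "ketene_loss"}}``
    for the deprotonated precursor: the fatty-acid carboxylate anion
    RCOO-, the acid neutral loss [M-H-RCOOH]- and the ketene neutral
    loss [M-H-(RCOOH-H2O)]-.
    """
    if polarity != "negative":
        raise ValueError("diagnostic fragments implemented for negative mode")
    if species.level != "sn_resolved":
        raise ValueError("resolve chains first")
    mh = species_mass(species) - PROTON_MASS
    out: dict[int, dict[str, float]] = {}
    for i, chain in enumerate(species.chains):
        acid = monoisotopic_mass(chain.acid_composition())
        out[i] = {
            "carboxylate": acid - PROTON_MASS,
            "acid_loss": mh - acid,
            "ketene_loss": mh - (acid - _WATER_MASS),
        }
    return out


def _decompositions(
    total_c: int, total_d: int, chain_carbons: range, chain_dbs: range
) -> list[tuple[AcylChain, AcylChain]]:
    pairs = []
    for c1 in chain_carbons:
        c2 = total_c - c1
        if c2 < c1 or c2 not in chain_carbons:
            continue
        for d1 in chain_dbs:
            d2 = total_d - d1
            if d2 < 0 or d2 not in chain_dbs:
                continue
            if c1 == c2 and d2 < d1:
                continue  # unordered pair already seen
            try:
                pairs.append((AcylChain(c1, d1), AcylChain(c2, d2)))
            except ValueError:
                continue
    return pairs


def _matched_intensity(spectrum: Ms2Spectrum, mz: float, tol_mz: float) -> float:
    return sum(f.intensity for f in spectrum.fragments if abs(f.mz - mz) <= tol_mz)


def assign_sn_positions(
    ms2: Ms2Spectrum,
    candidate: LipidSpecies,
    min_ratio: float = 7.0,
    tol_mz: float = 0.01,
    chain_carbons: range = range(4, 27),
    chain_dbs: range = range(0, 5),
) -> SnAssignment:
    """Assign sn-1/sn-2 chains of a sum-composition GPL from MS2.

    Every two-chain decomposition consistent with the candidate's total
    C:DB is scored by its total matched diagnostic-fragment intensity;
    for the best-supported decomposition the chain with the larger
    summed neutral-loss (acid + ketene) intensity is placed at sn-2.
    ``confidence`` is "assigned" when the sn-2/sn-1 loss ratio is at
    least ``min_ratio`` (inclusive), else "ambiguous".
    """
    if min_ratio <= 1:
        raise ValueError("min_ratio must exceed 1")
    total = candidate.to_sum().chains[0]
    best = None
    for ch_a, ch_b in _decompositions(
        total.carbons, total.double_bonds, chain_carbons, chain_dbs
    ):
        sp = LipidSpecies(candidate.lipid_class, "sn_resolved", (ch_a, ch_b))
        frags = diagnostic_fragments(sp)
        loss = []
        support = 0.0
        for i in (0, 1):
            li = _matched_intensity(ms2, frags[i]["acid_loss"], tol_mz)
            li += _matched_intensity(ms2, frags[i]["ketene_loss"], tol_mz)
            support += li + _matched_intensity(ms2, frags[i]["carboxylate"], tol_mz)
            loss.append(li)
        if ch_a == ch_b:
            # identical chains share the same fragments; split evenly
            loss = [loss[0] / 2, loss[1] / 2]
        if min(loss) <= 0:
            continue
        if best is None or support > best[0]:
            best = (support, (ch_a, ch_b), loss)
    if best is None:
        raise ValueError("uninformative spectrum: no diagnostic fragments matched")
    _, (ch_a, ch_b), loss = best
    if loss[1] >= loss[0]:
        sn1, sn2, (l1, l2) = ch_a, ch_b, loss
    else:
        sn1, sn2, (l2, l1) = ch_b, ch_a, loss
    ratio = l2 / l1 if l1 > 0 else float("inf")
    species = LipidSpecies(candidate.lipid_class, "sn_resolved", (sn1, sn2))
    confidence = "assigned" if ratio >= min_ratio else "ambiguous"
    return SnAssignment(species, ratio, confidence)


def pla2_digest(
    species_table: Sequence[LipidSpecies | tuple[LipidSpecies, float]],
) -> tuple[list[DigestProduct], pd.Series]:
    """In-silico PLA2 digestion of sn-resolved diacyl GPLs.

    PLA2 hydrolyzes the sn-2 ester specifically: each species yields its
    sn-1 lyso-lipid plus the free sn-2 fatty acid.  Returns the products
    and the lipid-bound ("recovered") fatty-acid profile, which by
    construction contains only sn-1 chains.  Lyso- and sphingolipid
    inputs, and classes without an annotated lyso form, are skipped with
    a warning.  Entries may carry an abundance weight (default 1).
    """
    products: list[DigestProduct] = []
    profile: dict[str, float] = {}
    for entry in species_table:
        sp, weight = entry if isinstance(entry, tuple) else (entry, 1.0)
        if sp.level != "sn_resolved" or sp.lipid_class not in _LYSO_OF:
            warnings.warn(f"skipping non-digestible species {sp.label}")
            continue
        sn1, sn2 = sp.chains
        lyso = LipidSpecies(_LYSO_OF[sp.lipid_class], "sn_resolved", (sn1,))
        products.append(DigestProduct(lyso, sn2))
        profile[sn1.label] = profile.get(sn1.label, 0.0) + weight
    return products, pd.Series(profile, name="recovered_fa").sort_index()


def asymmetry_metrics(
    species: LipidSpecies,
    sn2_chain: AcylChain | None = None,
    threshold: int = ASYMMETRY_THRESHOLD,
) -> dict:
    """Chain-length difference and asymmetry call for a two-chain lipid.

    Either pass an sn-resolved species, or a sum-composition species
    together with a known sn-2 chain (e.g. the class-wide C10:0-at-sn-2
    result established by PLA2 digestion).
    """
    if species.level == "sn_resolved" and len(species.chains) == 2:
        c1, c2 = (c.carbons for c in species.chains)
    elif sn2_chain is not None:
        c2 = sn2_chain.carbons
        c1 = species.total_carbons - c2
        if c1 < 2:
            raise ValueError("implied sn-1 chain shorter than 2 carbons")
    else:
        raise ValueError("chain lengths not determinable")
    diff = abs(c1 - c2)
    return {"chain_diff": diff, "is_asymmetrical": diff >= threshold}


def acyl_summaries(
    quant_records: Iterable,
    assume_sn2: Mapping[str, AcylChain] | None = None,
    threshold: int = ASYMMETRY_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class acyl summaries from quantification records.

    Returns ``(summary, db_distribution)``: the summary holds the
    mol%-weighted average combined fatty-acid length and the
    asymmetrical fraction (percent of class mol% with chain-length
    difference >= ``threshold``, over species whose chains are
    determinable); the distribution table gives the double-bond-count
    spectrum per class in percent.

    ``assume_sn2`` optionally maps a lipid class to a chain taken to sit
    at sn-2 class-wide, promoting sum-level species for the asymmetry
    call (documented assumption flag).
    """
    rows = []
    for r in quant_records:
        sp = r.species
        weight = r.mol_percent_polar
        asym = None
        sn2 = (assume_sn2 or {}).get(sp.lipid_class)
        try:
            asym = asymmetry_metrics(sp, sn2_chain=sn2, threshold=threshold)[
                "is_asymmetrical"
            ]
        except ValueError:
            pass
        rows.append(
            (
                sp.lipid_class,
                sp.total_carbons,
                sp.total_double_bonds,
                weight,
                asym,
            )
        )
    df = pd.DataFrame(
        rows, columns=["lipid_class", "carbons", "double_bonds", "molpct", "asym"]
    )
    df = df[df["molpct"] > 0]
    if df.empty:
        raise ValueError("no quantified species")

    def _summarize(g: pd.DataFrame) -> pd.Series:
        w = g["molpct"].sum()
        known = g.dropna(subset=["asym"])
        asym_pct = (
            100.0 * known.loc[known["asym"].astype(bool), "molpct"].sum()
            / known["molpct"].sum()
            if known["molpct"].sum() > 0
            else float("nan")
        )
        return pd.Series(
            {
                "avg_combined_length": (g["carbons"] * g["molpct"]).sum() / w,
                "asymmetrical_pct": asym_pct,
                "molpct_total": w,
            }
        )

    summary = df.groupby("lipid_class").apply(_summarize, include_groups=False)
    db_dist = (
        df.groupby(["lipid_class", "double_bonds"])["molpct"].sum()
        / df.groupby("lipid_class")["molpct"].sum()
        * 100.0
    ).rename("pct").reset_index()
    return summary, db_dist
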