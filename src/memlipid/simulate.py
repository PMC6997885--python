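"""Seeded synthetic-data generators with machine-readable ground truth.

Each generator emulates the statistical structure one pipeline stage
assumes, so the full analysis chain is testable without instrument data:

* :func:`gen_lipidome` — a fission-yeast-style polar lipidome whose
  defaults mirror a C10:0-rich species (abundant 26:0/28:0 sum species,
  per-class asymmetric fractions reaching 0.9 for PI), rendered as
  positive/negative-mode peak lists with deuterated class standards,
  log-normal intensity noise and Gaussian ppm jitter.
* :func:`gen_ms2` — negative-mode MS2 spectra obeying the sn-2 > sn-1
  neutral-loss intensity rule with a tunable sn-2/sn-1 factor.
* :func:`gen_guv_contours` — thermally fluctuating quasi-spherical
  equatorial contours drawn mode-by-mode from the Helfrich spectrum
  (independent complex Gaussian coefficients per frame; quasi-static
  approximation, no temporal correlation).
* :func:`gen_mids` — isotopologue vectors from a binomial mixture of
  tracer-labeled and unlabeled molecules with multinomial counting
  noise.
* :func:`gen_ortholog_proteomes` — four-species 1:1:1:1 ortholog cohorts
  with planted, species-specific TMH length distributions, optional
  median shifts, helix dropout and residue-composition enrichment.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .annotate import DEFAULT_ADDUCTS, Peak
from .chemistry import adduct_mz
from .flicker import ContourSeries, helfrich_variance
from .isotope import IsotopologueVector, P_NATURAL_13C
from .quantify import InternalStandard
from .species import AcylChain, LipidSpecies, species_mass, species_mz
from .structure import Ms2Spectrum, diagnostic_fragments

__all__ = [
    "LipidomeConfig",
    "LipidomeSample",
    "gen_lipidome",
    "gen_ms2",
    "GuvConfig",
    "gen_guv_contours",
    "MidConfig",
    "gen_mids",
    "ProteomeConfig",
    "ProteomeSample",
    "gen_ortholog_proteomes",
]


# --------------------------------------------------------------------------
# lipidome

#: sn-resolved palettes: asymmetric species carry C10:0 at sn-2 with a
#: long saturated or mono-unsaturated chain at sn-1; symmetric species
#: are the conventional 32-36 carbon combinations.
_ASYM_PALETTE = (
    (AcylChain(16, 0), AcylChain(10, 0)),  # 26:0
    (AcylChain(18, 0), AcylChain(10, 0)),  # 28:0
    (AcylChain(18, 1), AcylChain(10, 0)),  # 28:1
)
_SYM_PALETTE = (
    (AcylChain(16, 0), AcylChain(16, 0)),  # 32:0
    (AcylChain(16, 0), AcylChain(18, 1)),  # 34:1
    (AcylChain(18, 1), AcylChain(18, 1)),  # 36:2
)

#: spiked internal-standard mix (pmol) and standard species per class
_STANDARD_MIX: dict[str, tuple[float, LipidSpecies]] = {
    "PC": (71.0, LipidSpecies("PC", "sn_resolved",
                              (AcylChain(16, 0, deuteriums=31), AcylChain(18, 1)))),
    "PE": (50.0, LipidSpecies("PE", "sn_resolved",
                              (AcylChain(16, 0, deuteriums=31), AcylChain(18, 1)))),
    "PI": (43.0, LipidSpecies("PI", "sn_resolved",
                              (AcylChain(16, 0, deuteriums=31), AcylChain(18, 1)))),
    "PS": (24.0, LipidSpecies("PS", "sn_resolved",
                              (AcylChain(16, 0, deuteriums=31), AcylChain(18, 1)))),
}


@dataclass
class LipidomeConfig:
    """Ground-truth lipidome composition and measurement noise.

    Class weights and per-class asymmetric fractions default to a
    C10:0-producing fission-yeast profile (asymmetric fraction highest,
    0.9, for PI).
    """

    class_weights: Mapping[str, float] = field(
        default_factory=lambda: {"PC": 0.38, "PE": 0.22, "PI": 0.28, "PS": 0.12}
    )
    asym_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"PC": 0.45, "PE": 0.55, "PI": 0.90, "PS": 0.50}
    )
    total_pmol: float = 200.0
    standard_intensity: float = 1.0e6
    intensity_cv: float = 0.0  # log-normal sigma on every analyte peak
    ppm_jitter: float = 0.0  # Gaussian sigma on observed m/z, ppm
    seed: int = 0


@dataclass
class LipidomeSample:
    truth: pd.DataFrame  # label, class, molpct, is_asymmetric, sn1/sn2
    peaks: dict[str, list[Peak]]  # polarity -> peak list (standards included)
    standards: list[InternalStandard]
    standard_species: list[LipidSpecies]
    database: list[LipidSpecies]  # sum-level analyte species + standards


def gen_lipidome(config: LipidomeConfig = LipidomeConfig()) -> LipidomeSample:
    """Generate a ground-truth lipidome and its shotgun peak lists.

    Species mol% is deterministic (class weight split over the
    asymmetric/symmetric palettes by the class asymmetric fraction);
    only peak intensities and m/z carry noise.
    """
    weights = dict(config.class_weights)
    if not weights:
        raise ValueError("empty class palette")
    wsum = sum(weights.values())
    if wsum <= 0:
        raise ValueError("class weights not normalizable")
    rng = np.random.default_rng(config.seed)

    rows = []
    for cls, w in weights.items():
        f = config.asym_fraction.get(cls, 0.0)
        for pool, pool_weight in ((_ASYM_PALETTE, f), (_SYM_PALETTE, 1.0 - f)):
            for sn1, sn2 in pool:
                sp = LipidSpecies(cls, "sn_resolved", (sn1, sn2))
                rows.append(
                    {
                        "label": sp.to_sum().label,
                        "lipid_class": cls,
                        "sn1": sn1.label,
                        "sn2": sn2.label,
                        "molpct": 100.0 * (w / wsum) * pool_weight / len(pool),
                        "is_asymmetric": abs(sn1.carbons - sn2.carbons) >= 6,
                    }
                )
    truth = pd.DataFrame(rows)

    standards = [
        InternalStandard(cls, sp.label, pmol)
        for cls, (pmol, sp) in _STANDARD_MIX.items()
        if cls in weights
    ]
    standard_species = [
        _STANDARD_MIX[cls][1] for cls in weights if cls in _STANDARD_MIX
    ]
    missing = [c for c in weights if c not in _STANDARD_MIX]
    if missing:
        raise ValueError(f"no standard defined for classes {missing}")

    peaks: dict[str, list[Peak]] = {"positive": [], "negative": []}
    database: list[LipidSpecies] = []

    def _emit(sp_sum: LipidSpecies, intensity: float) -> None:
        for polarity in ("positive", "negative"):
            adduct = DEFAULT_ADDUCTS[polarity].get(sp_sum.lipid_class)
            if adduct is None:
                continue
            mz = species_mz(sp_sum, adduct)
            if config.ppm_jitter > 0:
                mz *= 1.0 + rng.normal(0.0, config.ppm_jitter) * 1e-6
            inten = intensity
            if config.intensity_cv > 0:
                inten *= rng.lognormal(0.0, config.intensity_cv)
            peaks[polarity].append(Peak(mz, inten))

    for cls, (pmol, std_sp) in _STANDARD_MIX.items():
        if cls not in weights:
            continue
        database.append(std_sp)
        _emit(std_sp, config.standard_intensity)

    for row in truth.itertuples():
        sp_sum = LipidSpecies(
            row.lipid_class, "sum",
            (AcylChain(*map(int, row.label.split(" ")[1].split(":"))),),
        )
        if sp_sum not in database:
            database.append(sp_sum)
        std_pmol = _STANDARD_MIX[row.lipid_class][0]
        amount = row.molpct / 100.0 * config.total_pmol
        _emit(sp_sum, amount / std_pmol * config.standard_intensity)

    # sum species appearing twice in truth (asym + sym can share totals)
    truth = (
        truth.groupby(["label", "lipid_class"], as_index=False)
        .agg(
            molpct=("molpct", "sum"),
            asym_molpct=("molpct",
                         lambda s: 0.0),  # placeholder, filled below
            sn1=("sn1", "first"),
            sn2=("sn2", "first"),
        )
    )
    asym = pd.DataFrame(rows)
    asym_tot = (
        asym[asym["is_asymmetric"]]
        .groupby(["label", "lipid_class"])["molpct"]
        .sum()
    )
    truth["asym_molpct"] = [
        float(asym_tot.get((r.label, r.lipid_class), 0.0))
        for r in truth.itertuples()
    ]
    truth["is_asymmetric"] = truth["asym_molpct"] > truth["molpct"] / 2
    return LipidomeSample(truth, peaks, standards, standard_species, database)


# --------------------------------------------------------------------------
# MS2

def gen_ms2(
    species: LipidSpecies,
    sn2_factor: float = 8.0,
    noise: float = 0.0,
    seed: int = 0,
    base_loss_intensity: float = 1000.0,
    carboxylate_intensity: float = 5000.0,
) -> Ms2Spectrum:
    """Negative-mode MS2 spectrum of an sn-resolved GPL.

    Both neutral-loss channels (acid and ketene) of the sn-2 chain are
    ``sn2_factor`` times more intense than the sn-1 ones before noise
    (multiplicative log-normal of sigma ``noise``).
    """
    if sn2_factor <= 0:
        raise ValueError("sn2_factor must be positive")
    rng = np.random.default_rng(seed)
    frags = diagnostic_fragments(species)
    precursor = species_mass(species) - 1.00727646688
    fragments = []
    for i, chain_frags in frags.items():
        loss_scale = base_loss_intensity * (sn2_factor if i == 1 else 1.0)
        for kind, mz in chain_frags.items():
            inten = carboxylate_intensity if kind == "carboxylate" else loss_scale
            if noise > 0:
                inten *= rng.lognormal(0.0, noise)
            fragments.append(Peak(mz, inten))
    return Ms2Spectrum(precursor, tuple(fragments))


# --------------------------------------------------------------------------
# GUV contours

@dataclass
class GuvConfig:
    kappa: float = 20.0  # kB T
    sigma_bar: float = 10.0
    radius_um: float = 15.0
    temperature: float = 295.0
    n_frames: int = 4000
    n_points: int = 512
    q_max: int = 40
    l_max: int = 100
    pixel_noise_um: float = 0.0
    seed: int = 0


def gen_guv_contours(config: GuvConfig = GuvConfig()) -> ContourSeries:
    """Simulate equatorial contours of a fluctuating quasi-spherical GUV.

    Per frame, independent complex Gaussian mode amplitudes u_q with
    variance from :func:`helfrich_variance` are superposed on a circle
    of radius R: r(phi) = R [1 + sum_q 2 Re(u_q e^{i q phi})].
    """
    if config.kappa <= 0:
        raise ValueError("kappa must be positive")
    if config.n_points < 128:
        raise ValueError("need at least 128 contour points")
    rng = np.random.default_rng(config.seed)
    qs = np.arange(2, config.q_max + 1)
    var = helfrich_variance(qs, config.kappa, config.sigma_bar, config.l_max)
    scale = np.sqrt(var / 2.0)
    n, npts = config.n_frames, config.n_points
    coef = np.zeros((n, npts // 2 + 1), dtype=complex)
    coef[:, qs] = rng.normal(0.0, scale, (n, len(qs))) + 1j * rng.normal(
        0.0, scale, (n, len(qs))
    )
    u = np.fft.irfft(coef * npts, n=npts, axis=1)
    phi = np.linspace(0.0, 2.0 * np.pi, npts, endpoint=False)
    r = config.radius_um * (1.0 + u)
    xy = np.stack([r * np.cos(phi), r * np.sin(phi)], axis=-1)
    if config.pixel_noise_um > 0:
        xy += rng.normal(0.0, config.pixel_noise_um, xy.shape)
    return ContourSeries(list(xy), pixel_size=1.0, temperature=config.temperature)


# --------------------------------------------------------------------------
# isotopologues

@dataclass
class MidConfig:
    metabolite: str = "C10:0"
    n_carbons: int = 10
    labeled_fraction: float = 0.4
    tracer_purity: float = 0.99
    p_natural: float = P_NATURAL_13C
    derivatization_carbons: int = 1  # FAME methyl carbon
    depth: int = 100_000  # total counts; 0 = noiseless expectation
    seed: int = 0


def gen_mids(config: MidConfig = MidConfig()) -> tuple[IsotopologueVector, float]:
    """Isotopologue vector of a binomially mixed labeled/unlabeled pool.

    Labeled molecules carry tracer 13C on every skeleton carbon with
    probability ``tracer_purity``; all non-tracer carbons (including
    derivatization carbons) pick up natural 13C.  Counting noise is
    multinomial at ``depth`` total counts.  Returns the vector and the
    planted labeled fraction.
    """
    f = config.labeled_fraction
    if not 0.0 <= f <= 1.0:
        raise ValueError("labeled_fraction must lie in [0, 1]")
    n, nd = config.n_carbons, config.derivatization_carbons
    shifts = np.arange(n + nd + 1)
    lab = np.convolve(
        binom.pmf(np.arange(n + 1), n, config.tracer_purity),
        binom.pmf(np.arange(nd + 1), nd, config.p_natural),
    )
    unlab = binom.pmf(shifts, n + nd, config.p_natural)
    mix = f * lab + (1.0 - f) * unlab
    probs = mix[: n + 1]
    probs = probs / probs.sum()  # measurement window M+0..M+n
    if config.depth > 0:
        rng = np.random.default_rng(config.seed)
        counts = rng.multinomial(config.depth, probs).astype(float)
    else:
        counts = probs
    return IsotopologueVector(config.metabolite, n, tuple(counts)), f


# --------------------------------------------------------------------------
# ortholog proteomes

_BACKGROUND_RESIDUES = np.array(list("DEKRNQSTPGHY"))
_TMH_RESIDUES = np.array(list("LIVFMAGS"))
_TMH_WEIGHTS = np.array([0.28, 0.18, 0.18, 0.10, 0.06, 0.10, 0.05, 0.05])


@dataclass
class ProteomeConfig:
    n_groups: int = 200
    species: tuple[str, ...] = ("pombe", "japonicus", "octosporus", "cryophilus")
    reference: str = "pombe"
    tmh_length_median: Mapping[str, int] = field(
        default_factory=lambda: {"pombe": 23, "japonicus": 23,
                                 "octosporus": 23, "cryophilus": 23}
    )
    length_shift: Mapping[str, int] = field(default_factory=dict)  # e.g. {"japonicus": -4}
    length_sd: float = 2.0
    single_span_fraction: float = 1.0  # remainder get two helices
    helix_dropout: Mapping[str, float] = field(default_factory=dict)
    small_enrich: Mapping[str, float] = field(default_factory=dict)  # G/A/S factor
    background_length: int = 60  # flank length on each side of a helix
    seed: int = 0


@dataclass
class ProteomeSample:
    sequences: dict[str, str]  # protein id -> sequence
    groups: list  # OrthologGroup-compatible (constructed lazily to avoid cycle)
    truth: pd.DataFrame  # group, species, protein, planted segments/lengths

    def fasta(self, species: str) -> str:
        out = []
        for pid, seq in self.sequences.items():
            if pid.startswith(species + "|"):
                out.append(f">{pid}\n{seq}")
        return "\n".join(out) + "\n"


def gen_ortholog_proteomes(config: ProteomeConfig = ProteomeConfig()) -> ProteomeSample:
    """Four-species ortholog cohort with planted hydrophobic helices.

    Backgrounds are hydrophilic; each planted helix is a run of
    hydrophobic residues of species-specific length (discretized normal
    around the species median plus any planted shift).  ``helix_dropout``
    removes a protein's helix with the given probability;
    ``small_enrich`` multiplies the G/A/S sampling weight inside helices
    of one species.
    """
    from .tmh import OrthologGroup  # local import: tmh does not know simulate

    for sp, med in config.tmh_length_median.items():
        if med < 8:
            raise ValueError(f"implausible TMH median for {sp}")
    rng = np.random.default_rng(config.seed)
    sequences: dict[str, str] = {}
    groups = []
    rows = []
    for gi in range(config.n_groups):
        gid = f"OG{gi:05d}"
        n_helices_ref = 1 if rng.random() < config.single_span_fraction else 2
        members = {}
        for sp in config.species:
            pid = f"{sp}|P{gi:05d}"
            members[sp] = pid
            weights = _TMH_WEIGHTS.copy()
            enrich = config.small_enrich.get(sp, 1.0)
            if enrich != 1.0:
                for r in "GAS":
                    weights[list(_TMH_RESIDUES).index(r)] *= enrich
            weights = weights / weights.sum()
            n_helices = n_helices_ref
            if rng.random() < config.helix_dropout.get(sp, 0.0):
                n_helices = max(0, n_helices - 1)
            median = config.tmh_length_median[sp] + config.length_shift.get(sp, 0)
            parts = []
            segments = []
            pos = 0
            for _ in range(max(n_helices, 0) or 0):
                flank = "".join(rng.choice(_BACKGROUND_RESIDUES, config.background_length))
                length = int(np.clip(round(rng.normal(median, config.length_sd)), 12, 40))
                helix = "".join(rng.choice(_TMH_RESIDUES, length, p=weights))
                parts.extend([flank, helix])
                pos += len(flank)
                segments.append((pos + 1, pos + length))
                pos += length
            parts.append("".join(rng.choice(_BACKGROUND_RESIDUES, config.background_length)))
            if n_helices == 0:
                # still emit a realistic-length hydrophilic protein
                parts.append("".join(rng.choice(_BACKGROUND_RESIDUES, config.background_length)))
            seq = "".join(parts)
            sequences[pid] = seq
            rows.append(
                {
                    "group_id": gid,
                    "species": sp,
                    "protein_id": pid,
                    "n_helices": n_helices,
                    "segments": tuple(segments),
                    "lengths": tuple(e - s + 1 for s, e in segments),
                }
            )
        groups.append(OrthologGroup(gid, members))
    return ProteomeSample(sequences, groups, pd.DataFrame(rows))
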