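"""Comparative transmembrane-helix (TMH) statistics across ortholog groups.

The analysis chain: predict (or load) TMH segments per protein, pool all
segment lengths and discard predictions deviating from the pooled median
by at least half of it, keep 1:1:1:1 ortholog groups whose
reference-species member is single-span, then compare per-species helix
lengths (two-sided Wilcoxon rank-sum), per-group helix-count differences
against the reference, and residue-class composition inside kept
helices.

The built-in predictor is a deliberately simple sliding-window
hydropathy scorer (Kyte-Doolittle scale, window 19, threshold 1.6) so
synthetic cohorts need no external tool; annotations from a real
predictor can be supplied through the same TSV interface (1-based
inclusive residue coordinates).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE
from scipy import stats

__all__ = [
    "TmhAnnotation",
    "OrthologGroup",
    "FilterConfig",
    "RESIDUE_CLASSES",
    "predict_tmh_hydropathy",
    "filter_by_median",
    "median_filter_cutoff",
    "single_span_orthologs",
    "rank_sum_test",
    "length_comparison",
    "count_difference_distribution",
    "residue_class_composition",
]


@dataclass(frozen=True)
class TmhAnnotation:
    protein_id: str
    species: str
    segments: tuple[tuple[int, int], ...]  # 1-based inclusive (start, end)

    def __post_init__(self) -> None:
        segs = tuple(sorted(tuple(s) for s in self.segments))
        for start, end in segs:
            if not 1 <= start <= end:
                raise ValueError("segments need 1 <= start <= end")
        for (_, e1), (s2, _) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise ValueError("segments must be non-overlapping and sorted")
        object.__setattr__(self, "segments", segs)

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(end - start + 1 for start, end in self.segments)


@dataclass(frozen=True)
class OrthologGroup:
    group_id: str
    members: Mapping[str, str]  # species -> protein id (1:1:1:1)

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", dict(self.members))
        if len(self.members) != 4:
            raise ValueError("ortholog group needs exactly one member per 4 species")


@dataclass(frozen=True)
class FilterConfig:
    median_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.median_fraction < 1.0:
            raise ValueError("median_fraction must lie in (0, 1)")


def predict_tmh_hydropathy(
    sequence: str,
    protein_id: str = "",
    species: str = "",
    window: int = 19,
    threshold: float = 1.6,
    merge_gap: int = 3,
) -> TmhAnnotation:
    """Sliding-window hydropathy TMH prediction.

    Positions are the window centres of maximal runs where the windowed
    mean Kyte-Doolittle hydropathy reaches ``threshold``; runs separated
    by fewer than ``merge_gap`` residues are merged.  Deterministic.
    """
    seq = sequence.upper()
    bad = set(seq) - set(KYTE_DOOLITTLE)
    if bad:
        raise ValueError(f"non-amino-acid characters: {sorted(bad)}")
    if len(seq) < window:
        return TmhAnnotation(protein_id, species, ())
    values = np.array([KYTE_DOOLITTLE[a] for a in seq])
    means = np.convolve(values, np.ones(window) / window, mode="valid")
    half = window // 2
    hot = means >= threshold  # index i covers residues i..i+window-1
    runs: list[tuple[int, int]] = []
    i = 0
    while i < len(hot):
        if hot[i]:
            j = i
            while j + 1 < len(hot) and hot[j + 1]:
                j += 1
            # report the span of window centres, 1-based
            runs.append((i + half + 1, j + half + 1))
            i = j + 1
        else:
            i += 1
    merged: list[tuple[int, int]] = []
    for start, end in runs:
        if merged and start - merged[-1][1] - 1 < merge_gap:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return TmhAnnotation(protein_id, species, tuple(merged))


def median_filter_cutoff(lengths: Sequence[int], config: FilterConfig = FilterConfig()) -> tuple[float, int]:
    """Pooled median and the integer discard cutoff ceil(fraction x median)."""
    if not lengths:
        raise ValueError("no segments")
    med = float(np.median(list(lengths)))
    return med, math.ceil(config.median_fraction * med)


def filter_by_median(
    annotations: Iterable[TmhAnnotation],
    config: FilterConfig = FilterConfig(),
) -> tuple[list[TmhAnnotation], float, int]:
    """Drop segments deviating from the pooled median length by >= cutoff.

    The median is computed over all predicted segments pooled across
    species, cutoff = ceil(median_fraction x median), and the discard
    boundary is inclusive (deviation == cutoff is discarded).  Returns
    the filtered annotations plus (median, cutoff).  Idempotent when the
    pooled median is unchanged by filtering.
    """
    anns = list(annotations)
    lengths = [ln for a in anns for ln in a.lengths]
    med, cutoff = median_filter_cutoff(lengths, config)
    out = []
    for a in anns:
        kept = tuple(
            seg
            for seg, ln in zip(a.segments, a.lengths)
            if abs(ln - med) < cutoff
        )
        out.append(TmhAnnotation(a.protein_id, a.species, kept))
    return out, med, cutoff


def single_span_orthologs(
    groups: Iterable[OrthologGroup],
    annotations: Mapping[str, TmhAnnotation],
    reference_species: str,
) -> list[OrthologGroup]:
    """Groups whose reference-species member has exactly one kept TMH."""
    kept = []
    for g in groups:
        pid = g.members.get(reference_species)
        ann = annotations.get(pid) if pid is not None else None
        if ann is None:
            warnings.warn(f"group {g.group_id}: missing annotation, skipped")
            continue
        if len(ann.segments) == 1:
            kept.append(g)
    return kept


def _exact_rank_sum_p(ranks2: np.ndarray, n_a: int, observed2: float) -> float:
    """Exact two-sided rank-sum p over all C(N, n_a) group assignments.

    ``ranks2`` are midranks doubled so ties become integers.  The null is
    enumerated by dynamic programming over (subset size, subset sum);
    two-sided means distance of the rank sum from its permutation mean.
    """
    ranks2 = np.rint(ranks2).astype(int)
    total = int(ranks2.sum())
    # f[k][s]: number of size-k subsets with doubled-rank sum s
    f = np.zeros((n_a + 1, total + 1), dtype=float)
    f[0, 0] = 1.0
    for r in ranks2:
        f[1 : n_a + 1, r:] += f[0:n_a, 0 : total + 1 - r]
    counts = f[n_a]
    mean2 = total * n_a / ranks2.size
    dev = np.abs(np.arange(total + 1) - mean2)
    threshold = abs(observed2 - mean2) - 1e-9
    return float(counts[dev >= threshold].sum() / counts.sum())


def rank_sum_test(
    a: Sequence[float], b: Sequence[float], exact_max_n: int = 25
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (statistic, p).

    The statistic is the Mann-Whitney U of the first sample.  For
    combined n <= ``exact_max_n`` the null is enumerated exactly over
    all assignments of the pooled values to groups (tie-safe, two-sided
    by distance of the rank sum from its permutation mean); larger
    samples use the tie-corrected normal approximation without
    continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per sample")
    u_stat = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                      method="asymptotic").statistic)
    if np.ptp(np.concatenate([a, b])) == 0:
        return u_stat, 1.0  # all pooled values tied: no evidence either way
    if a.size + b.size <= exact_max_n:
        ranks = stats.rankdata(np.concatenate([a, b]))
        observed2 = 2.0 * ranks[: a.size].sum()
        return u_stat, _exact_rank_sum_p(2.0 * ranks, a.size, observed2)
    p = float(
        stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        ).pvalue
    )
    return u_stat, p


def length_comparison(
    groups: Iterable[OrthologGroup],
    annotations: Mapping[str, TmhAnnotation],
    species_a: str,
    species_b: str,
) -> dict:
    """Wilcoxon rank-sum comparison of kept single-span TMH lengths."""
    lengths: dict[str, list[int]] = {species_a: [], species_b: []}
    for g in groups:
        for sp in (species_a, species_b):
            ann = annotations.get(g.members.get(sp, ""))
            if ann is not None and len(ann.segments) == 1:
                lengths[sp].append(ann.lengths[0])
    if not lengths[species_a] or not lengths[species_b]:
        raise ValueError("empty length sample")
    stat, p = rank_sum_test(lengths[species_a], lengths[species_b])
    return {
        "statistic": stat,
        "p_value": p,
        "n_a": len(lengths[species_a]),
        "n_b": len(lengths[species_b]),
        "median_a": float(np.median(lengths[species_a])),
        "median_b": float(np.median(lengths[species_b])),
    }


def count_difference_distribution(
    groups: Iterable[OrthologGroup],
    annotations: Mapping[str, TmhAnnotation],
    reference_species: str,
) -> pd.DataFrame:
    """Per-group signed TMH-count differences against the reference.

    One row per (group, non-reference species) with the difference
    count(species) - count(reference), computed on kept segments.
    """
    rows = []
    for g in groups:
        ref_ann = annotations.get(g.members.get(reference_species, ""))
        if ref_ann is None:
            warnings.warn(f"group {g.group_id}: missing reference annotation")
            continue
        ref_n = len(ref_ann.segments)
        for sp, pid in g.members.items():
            if sp == reference_species:
                continue
            ann = annotations.get(pid)
            if ann is None:
                warnings.warn(f"group {g.group_id}: missing annotation for {sp}")
                continue
            rows.append((g.group_id, sp, len(ann.segments) - ref_n))
    return pd.DataFrame(rows, columns=["group_id", "species", "count_difference"])


#: default residue classes; the membership table is configurable because
#: "small" vs "large" non-polar is a convention, not a measurement
RESIDUE_CLASSES: dict[str, str] = {
    **{r: "small_nonpolar" for r in "GASCP"},
    **{r: "large_nonpolar" for r in "VLIMFWY"},
    **{r: "polar" for r in "TNQH"},
    **{r: "charged" for r in "DEKR"},
}


def residue_class_composition(
    annotations: Iterable[TmhAnnotation],
    sequences: Mapping[str, str],
    class_table: Mapping[str, str] = RESIDUE_CLASSES,
) -> pd.DataFrame:
    """Fraction of each residue class inside kept TMHs, per species.

    Fractions sum to 1 per species.  A residue missing from the class
    table raises ``ValueError``.
    """
    counts: dict[tuple[str, str], int] = {}
    for ann in annotations:
        seq = sequences[ann.protein_id]
        for start, end in ann.segments:
            for res in seq[start - 1 : end].upper():
                if res not in class_table:
                    raise ValueError(f"residue {res!r} absent from class table")
                key = (ann.species, class_table[res])
                counts[key] = counts.get(key, 0) + 1
    if not counts:
        raise ValueError("no TMH residues to classify")
    df = pd.DataFrame(
        [(sp, cls, n) for (sp, cls), n in counts.items()],
        columns=["species", "residue_class", "count"],
    )
    df["fraction"] = df.groupby("species")["count"].transform(lambda s: s / s.sum())
    return df.sort_values(["species", "residue_class"]).reset_index(drop=True)
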