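"""Overlap and read-density statistics against external feature sets.

Clusters are compared with published interval sets (dsRNA loci, antisense
TSS positions, overlapping-operon regions): simple overlap counts, overlap
fractions per abundance decile, TSS proximity, and read-density (RPKM)
comparisons between interval groups with length-matched random control sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignedRead
from .clusters import Cluster
from .features import FeatureSet


def overlap_count(
    clusters: Sequence[Cluster],
    features: FeatureSet,
    min_overlap: int = 1,
) -> tuple[int, list[str]]:
    """Clusters sharing >= ``min_overlap`` bases with any feature (strand
    ignored). Returns (count, cluster ids)."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    feat_chroms = {c for c, *_ in features.intervals}
    clu_chroms = {c.chrom for c in clusters}
    if clusters and features.intervals and not (feat_chroms & clu_chroms):
        raise ValueError(
            f"feature chroms {sorted(feat_chroms)} do not match cluster "
            f"chroms {sorted(clu_chroms)}"
        )
    ids = []
    for c in clusters:
        for chrom, fs, fe, _ in features.intervals:
            if chrom == c.chrom and min(c.end, fe) - max(c.start, fs) >= min_overlap:
                ids.append(c.id)
                break
    return len(ids), ids


def decile_overlap(
    clusters: Sequence[Cluster],
    decile_map: dict[str, int],
    features: FeatureSet,
    min_overlap: int = 1,
) -> dict[int, float | None]:
    """Fraction of clusters overlapping the features, per abundance decile.

    Deciles with no clusters report ``None`` rather than 0.
    """
    _, overlapping = overlap_count(clusters, features, min_overlap)
    overlapping_set = set(overlapping)
    totals = {d: 0 for d in range(1, 11)}
    hits = {d: 0 for d in range(1, 11)}
    for c in clusters:
        d = decile_map[c.id]
        totals[d] += 1
        if c.id in overlapping_set:
            hits[d] += 1
    return {
        d: (hits[d] / totals[d] if totals[d] else None) for d in range(1, 11)
    }


def tss_proximity(
    clusters: Sequence[Cluster],
    tss: FeatureSet,
    flank: int = 50,
) -> tuple[int, list[str]]:
    """Clusters with a TSS within ``flank`` nt of the cluster on either side.

    A cluster counts iff some TSS position t satisfies
    ``start - flank <= t < end + flank`` (strand ignored).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if tss.kind != "point":
        raise ValueError("tss feature set must be of kind 'point'")
    ids = []
    for c in clusters:
        for chrom, ts, _te, _ in tss.intervals:
            if chrom == c.chrom and c.start - flank <= ts < c.end + flank:
                ids.append(c.id)
                break
    return len(ids), ids


@dataclass
class DensityComparison:
    """RPKM comparison between two interval groups plus matched controls."""

    group5_rpkm: list[float]
    group3_rpkm: list[float]
    fold_change: float  # arithmetic-mean ratio, inf -> math.inf
    fold_change_geometric: float
    mannwhitney_p: float
    empirical_p_group5: float
    empirical_p_group3: float
    n_control_sets: int
    seed: int


def _rpkm(
    five_prime_ends: np.ndarray,
    counts: np.ndarray,
    intervals: Sequence[tuple[str, int, int, str | None]],
    chrom_of: np.ndarray,
    library_size: int,
) -> list[float]:
    out = []
    for chrom, start, end, _ in intervals:
        inside = (chrom_of == chrom) & (five_prime_ends >= start) & (five_prime_ends < end)
        reads = counts[inside].sum()
        out.append(float(reads) * 1e9 / (library_size * (end - start)))
    return out


def region_density_compare(
    alignments: Sequence[AlignedRead],
    group5: FeatureSet,
    group3: FeatureSet,
    library_size: int,
    genome_lengths: dict[str, int],
    n_control_sets: int = 100,
    seed: int = 0,
) -> DensityComparison:
    """Compare read density (RPKM by 5'-end containment) between two interval
    groups, against length-matched uniformly placed random control sets.

    ``fold_change`` is mean RPKM(group5) / mean RPKM(group3) on arithmetic
    means (geometric also reported, with a half-minimum pseudocount for
    zeros). The two groups are compared with a two-sided Mann-Whitney U test;
    each group additionally gets an empirical one-sided p-value versus
    ``n_control_sets`` random interval sets with the identical length
    multiset: p = (1 + #controls with mean >= observed) / (n + 1).
    """
    if not group5.intervals or not group3.intervals:
        raise ValueError("both interval groups must be non-empty")
    for fs in (group5, group3):
        for chrom, start, end, _ in fs.intervals:
            if chrom not in genome_lengths or end > genome_lengths[chrom]:
                raise ValueError(f"interval [{start},{end}) exceeds {chrom} bounds")
    ends5 = np.array([a.five_prime for a in alignments])
    counts = np.array([a.count for a in alignments])
    chrom_of = np.array([a.chrom for a in alignments])

    rpkm5 = _rpkm(ends5, counts, group5.intervals, chrom_of, library_size)
    rpkm3 = _rpkm(ends5, counts, group3.intervals, chrom_of, library_size)
    mean5, mean3 = float(np.mean(rpkm5)), float(np.mean(rpkm3))
    fold = mean5 / mean3 if mean3 > 0 else float("inf")

    pooled = np.array(rpkm5 + rpkm3)
    positive = pooled[pooled > 0]
    pseudo = positive.min() / 2 if positive.size else 1.0
    geo5 = float(np.exp(np.mean(np.log(np.array(rpkm5) + pseudo))))
    geo3 = float(np.exp(np.mean(np.log(np.array(rpkm3) + pseudo))))
    fold_geo = geo5 / geo3

    if np.ptp(pooled) == 0:
        mw_p = 1.0
    else:
        mw_p = float(
            stats.mannwhitneyu(rpkm5, rpkm3, alternative="two-sided").pvalue
        )

    rng = np.random.default_rng(seed)
    emp_p = {}
    for label, fs, observed in (("g5", group5, mean5), ("g3", group3, mean3)):
        exceed = 0
        for _ in range(n_control_sets):
            ctrl = []
            for chrom, start, end, strand in fs.intervals:
                length = end - start
                glen = genome_lengths[chrom]
                if length > glen:
                    raise ValueError("control interval longer than reference")
                s = int(rng.integers(0, glen - length + 1))
                ctrl.append((chrom, s, s + length, strand))
            m = float(
                np.mean(_rpkm(ends5, counts, ctrl, chrom_of, library_size))
            )
            if m >= observed:
                exceed += 1
        emp_p[label] = (1 + exceed) / (n_control_sets + 1)

    return DensityComparison(
        group5_rpkm=rpkm5,
        group3_rpkm=rpkm3,
        fold_change=fold,
        fold_change_geometric=fold_geo,
        mannwhitney_p=mw_p,
        empirical_p_group5=emp_p["g5"],
        empirical_p_group3=emp_p["g3"],
        n_control_sets=n_control_sets,
        seed=seed,
    )


def export_decile_overlap(
    fractions: dict[int, float | None], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "decile": list(fractions),
            "fraction_overlapping": [
                "NA" if v is None else v for v in fractions.values()
            ],
        }
    ).to_csv(path, sep="\t", index=False)


def export_density_comparison(dc: DensityComparison, path: str | Path) -> None:
    payload = {
        "fold_change": dc.fold_change if np.isfinite(dc.fold_change) else "inf",
        "fold_change_geometric": dc.fold_change_geometric,
        "mannwhitney_p": dc.mannwhitney_p,
        "empirical_p_group5": dc.empirical_p_group5,
        "empirical_p_group3": dc.empirical_p_group3,
        "n_control_sets": dc.n_control_sets,
        "seed": dc.seed,
        "group5_rpkm": dc.group5_rpkm,
        "group3_rpkm": dc.group3_rpkm,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
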