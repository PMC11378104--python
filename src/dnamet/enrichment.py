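"""Characterisation of the CpGs a surrogate model selects.

Covers CpG-island-centric genomic context (island / shore / shelf /
open sea, with shores 2 kb from an island edge and shelves 2-4 kb),
Fisher's exact enrichment of a CpG selection against annotation sets or
a trait catalogue with BH correction, genes in cis within a fixed
distance, pairwise model overlap, and CpGs recurring across models.

Coordinate conventions: CpG positions are 1-based; region intervals are
half-open [start, end) on the same 1-based axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coxph import bh_adjust

CGI_CONTEXTS = ("island", "shore", "shelf", "open_sea")


def _merge_intervals(intervals: np.ndarray) -> np.ndarray:
    if len(intervals) == 0:
        return intervals
    iv = intervals[np.argsort(intervals[:, 0])]
    merged = [iv[0].tolist()]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged)


def annotate_cgi_context(cpg_positions: pd.DataFrame, islands: pd.DataFrame,
                         shore_bp: int = 2000, shelf_bp: int = 2000) -> pd.Series:
    """Classify each CpG relative to the nearest CpG island.

    ``cpg_positions``: frame with columns chrom, pos (1-based), indexed
    by CpG id.  ``islands``: BED-like frame with chrom, start, end
    (half-open).  A CpG inside an island is ``island``; within
    ``shore_bp`` of an island edge, ``shore``; within a further
    ``shelf_bp``, ``shelf``; otherwise ``open_sea``.  CpGs on
    chromosomes without any island are open sea (with a warning).
    """
    by_chrom = {}
    for chrom, grp in islands.groupby("chrom"):
        by_chrom[chrom] = _merge_intervals(grp[["start", "end"]].to_numpy(int))
    labels = np.full(len(cpg_positions), "open_sea", dtype=object)
    warned = set()
    for chrom, grp in cpg_positions.groupby("chrom"):
        iv = by_chrom.get(chrom)
        idx = cpg_positions.index.get_indexer(grp.index)
        if iv is None or len(iv) == 0:
            if chrom not in warned:
                warnings.warn(f"no islands on chromosome {chrom}; CpGs set to open_sea")
                warned.add(chrom)
            continue
        pos = grp["pos"].to_numpy(int)
        starts, ends = iv[:, 0], iv[:, 1]
        # nearest interval by insertion point
        right = np.searchsorted(starts, pos, side="right")
        dist = np.full(len(pos), np.iinfo(np.int64).max, dtype=np.int64)
        inside = np.zeros(len(pos), bool)
        prev = right - 1
        has_prev = prev >= 0
        p_in = has_prev & (pos < ends[np.clip(prev, 0, None)]) & (pos >= starts[np.clip(prev, 0, None)])
        inside |= p_in
        # distance to previous interval's right edge (last covered base end-1)
        d_prev = np.where(has_prev, pos - (ends[np.clip(prev, 0, None)] - 1), np.iinfo(np.int64).max)
        has_next = right < len(starts)
        d_next = np.where(has_next, starts[np.clip(right, None, len(starts) - 1)] - pos,
                          np.iinfo(np.int64).max)
        dist = np.minimum(np.abs(d_prev), np.abs(d_next))
        lab = np.where(inside, "island",
                       np.where(dist <= shore_bp, "shore",
                                np.where(dist <= shore_bp + shelf_bp, "shelf", "open_sea")))
        labels[idx] = lab
    return pd.Series(labels, index=cpg_positions.index, name="cgi_context")


@dataclass
class EnrichmentRow:
    label: str
    a: int  # selected & annotated
    b: int  # selected & not annotated
    c: int  # annotated & not selected
    d: int  # neither
    odds_ratio: float
    p: float
    p_adj: float = float("nan")


def fisher_enrichment(selected: set, universe: set,
                      annotation_sets: dict[str, set]) -> pd.DataFrame:
    """Two-sided Fisher enrichment of ``selected`` within ``universe``.

    Per label the 2x2 table is (selected & annotated, selected only,
    annotated only, rest); the odds ratio is ad/bc with a
    Haldane-Anscombe 0.5 correction applied when any cell is zero.
    BH adjustment runs across labels; ``significant`` flags FDR < 0.05.
    """
    selected = set(selected)
    universe = set(universe)
    if not selected:
        raise ValueError("empty selected set")
    if not selected <= universe:
        raise ValueError("selected CpGs must be a subset of the universe")
    rows = []
    for label, members in annotation_sets.items():
        members = set(members) & universe
        a = len(selected & members)
        b = len(selected) - a
        c = len(members) - a
        d = len(universe) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if min(a, b, c, d) == 0:
            orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
        else:
            orr = a * d / (b * c)
        rows.append({"label": label, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": float(orr), "p": float(p)})
    out = pd.DataFrame(rows).set_index("label")
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p_adj"] < 0.05
    return out


def load_trait_catalog(catalog: pd.DataFrame, array_size: int = 480_000,
                       alpha: float = 0.05) -> dict[str, set]:
    """Trait -> CpG sets, keeping associations past a Bonferroni threshold.

    The per-association threshold is alpha / array_size, the catalogue
    convention for array-wide significance.
    """
    thr = alpha / array_size
    kept = catalog[catalog["p"] < thr]
    return {trait: set(grp["cpg"]) for trait, grp in kept.groupby("trait")}


def genes_in_cis(cpg_positions: pd.DataFrame, genes: pd.DataFrame,
                 max_dist: int = 100_000) -> dict[str, set]:
    """CpG -> set of genes whose interval lies within ``max_dist`` bp (inclusive).

    ``genes``: frame with chrom, start, end (half-open), name.  Distance
    is 0 inside the gene body.
    """
    if (genes["start"] > genes["end"]).any():
        bad = genes[genes["start"] > genes["end"]].iloc[0]
        raise ValueError(f"malformed gene interval {bad['name']}: start > end")
    out: dict[str, set] = {cpg: set() for cpg in cpg_positions.index}
    for chrom, grp in cpg_positions.groupby("chrom"):
        g = genes[genes["chrom"] == chrom]
        if g.empty:
            continue
        pos = grp["pos"].to_numpy(int)
        for start, end, name in zip(g["start"].to_numpy(int), g["end"].to_numpy(int),
                                    g["name"]):
            hit = (pos >= start - max_dist) & (pos <= end - 1 + max_dist)
            for cpg in grp.index[hit]:
                out[cpg].add(name)
    return out


def model_overlap(models: list, metric: str = "min") -> pd.DataFrame:
    """Pairwise overlap of nonzero-weight CpG sets.

    ``min`` normalises the intersection by the smaller set ("overlap
    coefficient"); ``jaccard`` by the union.  Empty-weight models
    overlap 0 with everything (warning), diagonal is 1.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    sets = {m.target: set(m.weights) for m in models}
    names = [m.target for m in models]
    for name, s in sets.items():
        if not s:
            warnings.warn(f"model {name} has no nonzero weights; overlap set to 0")
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, ni in enumerate(names):
        for j in range(i + 1, len(names)):
            nj = names[j]
            si, sj = sets[ni], sets[nj]
            if not si or not sj:
                val = 0.0
            elif metric == "min":
                val = len(si & sj) / min(len(si), len(sj))
            elif metric == "jaccard":
                val = len(si & sj) / len(si | sj)
            else:
                raise ValueError("metric must be 'min' or 'jaccard'")
            out.iloc[i, j] = out.iloc[j, i] = val
    return out


def recurrent_cpgs(models: list, min_models: int = 2) -> pd.DataFrame:
    """CpGs selected (nonzero weight) in strictly more than ``min_models`` models.

    For each such CpG the table reports the model count, the fraction of
    models sharing the majority coefficient sign, and the median rank of
    its |weight| within each selecting model (rank 1 = largest).
    The boundary is strict: a CpG in exactly ``min_models`` models is
    not reported.
    """
    if min_models < 2:
        raise ValueError("min_models must be >= 2")
    counts: dict[str, int] = {}
    signs: dict[str, list[float]] = {}
    ranks: dict[str, list[float]] = {}
    for m in models:
        if not m.weights:
            continue
        mags = pd.Series({c: abs(w) for c, w in m.weights.items()})
        rank = mags.rank(ascending=False)
        for cpg, w in m.weights.items():
            counts[cpg] = counts.get(cpg, 0) + 1
            signs.setdefault(cpg, []).append(np.sign(w))
            ranks.setdefault(cpg, []).append(float(rank[cpg]))
    rows = []
    for cpg, n in counts.items():
        if n <= min_models:
            continue
        s = np.array(signs[cpg])
        agreement = max((s > 0).mean(), (s < 0).mean())
        rows.append({"cpg": cpg, "n_models": n, "sign_agreement": float(agreement),
                     "median_weight_rank": float(np.median(ranks[cpg]))})
    out = pd.DataFrame(rows, columns=["cpg", "n_models", "sign_agreement",
                                      "median_weight_rank"])
    if len(out):
        out = out.sort_values(["n_models", "sign_agreement"],
                              ascending=False).reset_index(drop=True)
    return out
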