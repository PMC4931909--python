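"""Super-enhancer calling by rank-score tangent threshold.

Procedure: peaks on the same chromosome separated by no more than a stitching
distance (default 12,500 bp) are merged transitively into regions; regions
are ranked by total normalized tag count in the condition of interest; the
ascending rank-score curve is min-max normalized on both axes, and the
threshold is the point at which the tangent to the curve reaches slope one —
regions past that point are super-enhancers.

Numerically, the tangent point is found as the (last) global minimum of
y - x on the curve with both axes min-max normalized to [0, 1]: that is the
rank at which a line of slope one touches the curve from below, i.e. where
the discrete tangent crosses one on a convex curve. The global-minimum
formulation is deliberately used instead of a local slope scan because
single-step slopes are noisy — a tied pair of scores inside the
super-enhancer block, or one large order-statistic gap in the background
tail, flips a local rule by many ranks while leaving the global contact
point unchanged. A perfectly linear curve has y - x = 0 everywhere and
yields zero super-enhancers by the last-minimum tie-break.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .containers import GeneAnnotation, PeakSet, SECallResult, StitchedRegion
from .enhancers import nearest_tss

__all__ = [
    "stitch_peaks",
    "find_se_threshold",
    "call_super_enhancers",
    "compare_se_sets",
    "se_group_gain",
]

log = logging.getLogger(__name__)

DEFAULT_STITCH_DISTANCE = 12_500


def stitch_peaks(peaks: PeakSet, stitch_distance: int = DEFAULT_STITCH_DISTANCE
                 ) -> List[StitchedRegion]:
    """Merge peaks within ``stitch_distance`` bp (gap <= distance, inclusive)
    transitively into regions; tags are summed per condition.

    Regions never span chromosomes. The result is sorted by (chrom, start).
    Stitching is idempotent: regions produced here are separated by gaps
    larger than the stitch distance.
    """
    regions: List[StitchedRegion] = []
    df = peaks.df.sort_values(["chrom", "start", "end"], kind="mergesort")
    for chrom, sub in df.groupby("chrom", sort=True):
        cur_start = cur_end = None
        cur_ids: List[str] = []
        cur_tags = {c: 0.0 for c in peaks.conditions}

        def _flush():
            if cur_ids:
                regions.append(StitchedRegion(
                    chrom=chrom, start=int(cur_start), end=int(cur_end),
                    constituent_peak_ids=tuple(cur_ids),
                    total_tags=dict(cur_tags),
                ))

        for _, r in sub.iterrows():
            s, e = int(r["start"]), int(r["end"])
            if cur_end is None or s - cur_end > stitch_distance:
                _flush()
                cur_start, cur_end = s, e
                cur_ids = [str(r["peak_id"])]
                cur_tags = {c: float(r[c]) for c in peaks.conditions}
            else:
                cur_end = max(cur_end, e)
                cur_ids.append(str(r["peak_id"]))
                for c in peaks.conditions:
                    cur_tags[c] += float(r[c])
        _flush()
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    return regions


def find_se_threshold(region_scores: Sequence[float]) -> Tuple[int, float]:
    """Tangent-slope-one threshold on a rank-score curve.

    ``region_scores`` may arrive in any order; they are sorted ascending and
    both axes min-max normalized to [0, 1]. Returns ``(threshold_rank,
    threshold_score)`` where ``threshold_rank`` counts the regions past the
    threshold (the super-enhancers: the top ``threshold_rank`` scores, every
    one >= ``threshold_score``). All-equal scores yield zero supers with a
    warning.
    """
    scores = np.sort(np.asarray(list(region_scores), dtype=float))
    n = len(scores)
    if n < 3:
        raise ValueError("need at least 3 regions")
    if (scores < 0).any():
        raise ValueError("scores must be non-negative")
    span = scores[-1] - scores[0]
    if span == 0.0:
        log.warning("all region scores equal; zero super-enhancers called")
        return 0, float(scores[-1])
    y = (scores - scores[0]) / span
    x = np.arange(n) / (n - 1)
    d = y - x
    # tangent contact of the slope-1 line: (last) global minimum of y - x;
    # everything past it rises faster than the diagonal in aggregate
    t = int(np.flatnonzero(d == d.min())[-1]) + 1
    threshold_rank = n - t
    threshold_score = float(scores[t]) if t < n else float(scores[-1])
    return threshold_rank, threshold_score


def call_super_enhancers(
    peaks: PeakSet,
    condition: str,
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    exclude_tss_window: int = 0,
    genes: Optional[GeneAnnotation] = None,
) -> SECallResult:
    """Stitch, rank by total tags, threshold, and flag super-enhancers.

    With ``exclude_tss_window`` > 0 (and a gene annotation), peaks whose
    midpoint lies within that distance of an annotated TSS are removed before
    stitching — the optional promoter-exclusion variant. Ranks are descending
    by total tag count (ties broken by region coordinates, so the call is
    deterministic); ``is_super`` iff rank <= threshold_rank.
    """
    if condition not in peaks.conditions:
        raise KeyError(f"unknown condition {condition!r}")
    work = peaks
    if exclude_tss_window > 0:
        if genes is None:
            raise ValueError("exclude_tss_window requires a gene annotation")
        mids = ((peaks.df["start"] + peaks.df["end"]) // 2).to_numpy()
        keep = np.ones(len(peaks.df), dtype=bool)
        tss_by_chrom = {c: np.sort(sub["tss"].to_numpy())
                        for c, sub in genes.df.groupby("chrom")}
        for i, (chrom, mid) in enumerate(zip(peaks.df["chrom"], mids)):
            tss = tss_by_chrom.get(chrom)
            if tss is None or len(tss) == 0:
                continue
            j = np.searchsorted(tss, mid)
            d = min(abs(int(tss[k]) - int(mid)) for k in (j - 1, j)
                    if 0 <= k < len(tss))
            keep[i] = d > exclude_tss_window
        work = PeakSet(peaks.df[keep].reset_index(drop=True), list(peaks.conditions))

    regions = stitch_peaks(work, stitch_distance)
    params: Dict[str, object] = {
        "condition": condition,
        "stitch_distance": stitch_distance,
        "exclude_tss_window": exclude_tss_window,
    }
    if not regions:
        return SECallResult(regions=[], threshold_rank=0, threshold_score=0.0,
                            n_super=0, parameters=params)
    regions.sort(key=lambda r: (-r.total_tags[condition], r.chrom, r.start))
    for rank, region in enumerate(regions, start=1):
        region.rank = rank
    if len(regions) < 3:
        threshold_rank, threshold_score = 0, float(regions[0].total_tags[condition])
    else:
        threshold_rank, threshold_score = find_se_threshold(
            [r.total_tags[condition] for r in regions]
        )
    for region in regions:
        region.is_super = region.rank <= threshold_rank
    return SECallResult(
        regions=regions,
        threshold_rank=threshold_rank,
        threshold_score=threshold_score,
        n_super=threshold_rank,
        parameters=params,
    )


def compare_se_sets(call_a: SECallResult, call_b: SECallResult) -> Dict[str, object]:
    """Shared vs condition-exclusive super-enhancers between two calls.

    A super region of one call is *shared* if it overlaps (>= 1 bp) any super
    region of the other call. Counts are reported from each side (the two
    shared counts can differ when regions split or merge between conditions).
    """
    def _tree(call: SECallResult) -> Dict[str, IntervalTree]:
        trees: Dict[str, IntervalTree] = {}
        for r in call.super_regions:
            trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
        return trees

    trees_a, trees_b = _tree(call_a), _tree(call_b)

    def _split(call: SECallResult, other_trees) -> Tuple[List[StitchedRegion], List[StitchedRegion]]:
        shared, only = [], []
        for r in call.super_regions:
            tree = other_trees.get(r.chrom)
            (shared if tree is not None and tree.overlaps(r.start, r.end) else only).append(r)
        return shared, only

    shared_a, a_only = _split(call_a, trees_b)
    shared_b, b_only = _split(call_b, trees_a)
    return {
        "shared_a": shared_a, "shared_b": shared_b,
        "a_only": a_only, "b_only": b_only,
        "counts": {
            "a_super": len(call_a.super_regions),
            "b_super": len(call_b.super_regions),
            "shared_from_a": len(shared_a),
            "shared_from_b": len(shared_b),
            "a_only": len(a_only),
            "b_only": len(b_only),
        },
    }


def se_group_gain(
    shared_regions: Sequence[StitchedRegion],
    genes: GeneAnnotation,
    signature_genes: Iterable[str],
    condition_a: str,
    condition_b: str,
) -> Dict[str, object]:
    """Tag gain of shared super-enhancers, split by signature proximity.

    Each region is assigned to its nearest gene (TSS distance from the region
    midpoint); regions whose nearest gene is in the signature set form one
    split, the rest the other. Per-region gain = tags_b - tags_a. The splits
    are compared with a two-sided Welch t test when both have >= 2 regions;
    with a singleton split the comparison is refused (t and p are None) but
    the gains are still reported. An empty split is an error.
    """
    from scipy import stats

    regions = list(shared_regions)
    if not regions:
        raise ValueError("no shared regions")
    df = pd.DataFrame({
        "chrom": [r.chrom for r in regions],
        "start": [r.start for r in regions],
        "end": [r.end for r in regions],
        "peak_id": [r.region_id for r in regions],
        "_a": [r.total_tags[condition_a] for r in regions],
        "_b": [r.total_tags[condition_b] for r in regions],
    })
    pseudo = PeakSet(df, ["_a", "_b"])
    nearest = nearest_tss(pseudo, genes)
    sig = set(signature_genes)
    near_sig = nearest.isin(sig).to_numpy()
    gains = (df["_b"] - df["_a"]).to_numpy()
    sig_gains = gains[near_sig]
    other_gains = gains[~near_sig]
    if len(sig_gains) == 0 or len(other_gains) == 0:
        raise ValueError("one proximity split is empty; cannot compare")
    if len(sig_gains) < 2 or len(other_gains) < 2:
        t = p = None
        log.warning("a split has a single region; comparison refused")
    elif np.allclose(gains, gains[0]):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(sig_gains, other_gains, equal_var=False)
        t, p = float(t), float(p)
    return {
        "signature_gains": sig_gains,
        "other_gains": other_gains,
        "mean_gain_signature": float(sig_gains.mean()),
        "mean_gain_other": float(other_gains.mean()),
        "t": t, "p": p,
        "nearest_gene": nearest,
    }
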