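"""Peak-level enhancer analytics.

Thresholding by normalized tag count, pairwise peak-overlap tables,
activation fold-change classification, tag aggregation around binding sites,
the H3K4me2 gene-body/promoter spreading ratio, promoter-window binding
frequency, expression stratification, nearest-gene proximity enrichment, and
digital-vs-analog response classification.

House rules (documented once, applied everywhere): intervals are 0-based
half-open; two intervals overlap iff they share >= 1 bp; promoter and
gene-body windows are strand-aware; peaks are assigned to the gene with the
nearest TSS measured from the peak midpoint, ties going to the smaller
coordinate.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .containers import CoverageTrack, ExpressionMatrix, GeneAnnotation, PeakSet, TagProfile

__all__ = [
    "threshold_peaks",
    "overlap_table",
    "classify_fold_change",
    "aggregate_tags_at_sites",
    "spreading_ratio",
    "promoter_binding_frequency",
    "stratify_by_expression",
    "proximity_enrichment",
    "classify_digital_analog",
    "nearest_tss",
    "chi_squared_2x2",
]

log = logging.getLogger(__name__)


def threshold_peaks(peaks: PeakSet, condition: str, min_tags: float = 40.0) -> PeakSet:
    """Keep peaks with at least ``min_tags`` normalized tags in ``condition``
    (inclusive boundary: a peak with exactly ``min_tags`` is kept)."""
    tags = peaks.tags(condition)
    return PeakSet(peaks.df[tags >= min_tags].reset_index(drop=True),
                   list(peaks.conditions))


def _trees(peaks: PeakSet) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for chrom, sub in peaks.df.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"].astype(int), sub["end"].astype(int))
        )
    return trees


def overlap_table(
    peak_sets: Sequence[PeakSet],
    conditions: Optional[Sequence[str]] = None,
    min_tags: float = 40.0,
    labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Pairwise peak-overlap count matrix across an ordered list of peak sets.

    Each set is first thresholded at ``min_tags`` in its own condition
    (``conditions[i]``, default the set's first condition). Entry (i, j) for
    i != j counts set-i peaks overlapping >= 1 bp of at least one set-j peak
    (each peak counted at most once); the diagonal holds the thresholded peak
    count of each set, mirroring the published pairwise-overlap table layout.
    The count matrix is directional: (i, j) and (j, i) answer "how many of
    set i land in set j" and vice versa.
    """
    if len(peak_sets) < 1:
        raise ValueError("need at least one peak set")
    conds = list(conditions) if conditions else [ps.conditions[0] for ps in peak_sets]
    names = list(labels) if labels else conds
    thresholded = [threshold_peaks(ps, c, min_tags) for ps, c in zip(peak_sets, conds)]
    trees = [_trees(ps) for ps in thresholded]
    n = len(thresholded)
    out = np.zeros((n, n), dtype=int)
    for i, ps in enumerate(thresholded):
        out[i, i] = len(ps)
        for j in range(n):
            if i == j:
                continue
            count = 0
            for _, r in ps.df.iterrows():
                tree = trees[j].get(r["chrom"])
                if tree is not None and tree.overlaps(int(r["start"]), int(r["end"])):
                    count += 1
            out[i, j] = count
    return pd.DataFrame(out, index=names, columns=names)


def classify_fold_change(
    peaks: PeakSet,
    condition_a: str,
    condition_b: str,
    fold: float = 2.0,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Label each peak up/down/unchanged by its tag ratio between conditions.

    ``up`` iff (tags_b + pc) / (tags_a + pc) > fold (strict, per "more than
    x-fold"); ``down`` mirrored; otherwise ``unchanged``. The pseudocount
    keeps zero-tag denominators finite.
    """
    a = peaks.tags(condition_a).to_numpy(dtype=float) + pseudocount
    b = peaks.tags(condition_b).to_numpy(dtype=float) + pseudocount
    labels = np.where(b / a > fold, "up", np.where(a / b > fold, "down", "unchanged"))
    return pd.Series(labels, index=peaks.df["peak_id"].to_numpy(), name="label")


def aggregate_tags_at_sites(
    site_set: PeakSet,
    tag_libraries: Mapping[str, CoverageTrack],
    window_bp: int = 1000,
) -> Dict[str, object]:
    """Aggregate tag coverage in +-``window_bp`` around each site center.

    Returns, per condition, the total tag count over all site windows, the
    per-site mean, and the site-aligned mean per-base profile; plus the site
    count. Windows are clipped at chromosome boundaries.
    """
    if len(site_set) == 0:
        raise ValueError("empty site set")
    centers = ((site_set.df["start"] + site_set.df["end"]) // 2).astype(int)
    chroms = site_set.df["chrom"]
    width = 2 * window_bp
    totals: Dict[str, float] = {}
    means: Dict[str, float] = {}
    profiles: Dict[str, np.ndarray] = {}
    for cond, track in tag_libraries.items():
        profile = np.zeros(width)
        total = 0.0
        for chrom, center in zip(chroms, centers):
            arr = track.coverage[chrom]
            lo, hi = center - window_bp, center + window_bp
            clo, chi = max(0, lo), min(len(arr), hi)
            if chi > clo:
                seg = arr[clo:chi]
                profile[clo - lo:clo - lo + len(seg)] += seg
                total += float(seg.sum())
        totals[cond] = total
        means[cond] = total / len(site_set)
        profiles[cond] = profile / len(site_set)
    return {"totals": totals, "per_site_means": means, "profiles": profiles,
            "n_sites": len(site_set), "window_bp": window_bp}


def spreading_ratio(
    source,
    gene=None,
    promoter_halfwidth: int = 1000,
    body_span: Tuple[int, int] = (1000, 4000),
) -> float:
    """Gene-body over promoter tag-density ratio (the histone-mark spreading
    statistic).

    promoter = TSS +- ``promoter_halfwidth``; body = the strand-aware window
    ``body_span`` bp downstream of the TSS (default the first 1000-4000 bp of
    the gene). Both are converted to per-bp densities, so the ratio is
    invariant to uniform coverage scaling; uniform coverage gives exactly 1.

    ``source`` is either a :class:`TagProfile` (TSS-anchored, strand already
    applied; ``gene`` ignored) or a :class:`CoverageTrack` with ``gene`` a row
    of a :class:`GeneAnnotation`. For a genomic gene shorter than the body
    window the body is truncated at the gene end (with a warning); an empty
    promoter gets pseudo-density 1e-6 and a warning.
    """
    lo, hi = body_span
    if not (0 <= lo < hi):
        raise ValueError("body_span must be increasing and non-negative")
    if isinstance(source, TagProfile):
        prom = source.window_sum(-promoter_halfwidth, promoter_halfwidth)
        prom_bp = 2 * promoter_halfwidth
        body = source.window_sum(lo, hi)
        body_bp = hi - lo
    elif isinstance(source, CoverageTrack):
        if gene is None:
            raise ValueError("a gene annotation row is required with a CoverageTrack")
        tss, strand = int(gene["tss"]), gene["strand"]
        chrom = gene["chrom"]
        prom = source.window_sum(chrom, tss - promoter_halfwidth, tss + promoter_halfwidth)
        prom_bp = 2 * promoter_halfwidth
        if strand == "+":
            b_lo, b_hi = tss + lo, tss + hi
            gene_limit = int(gene["end"])
            if b_hi > gene_limit:
                log.warning("gene %s shorter than body window; truncated",
                            gene.get("gene_id", "?"))
                b_hi = max(gene_limit, b_lo + 1)
        else:
            b_lo, b_hi = tss - hi, tss - lo
            gene_limit = int(gene["start"])
            if b_lo < gene_limit:
                log.warning("gene %s shorter than body window; truncated",
                            gene.get("gene_id", "?"))
                b_lo = min(gene_limit, b_hi - 1)
        body = source.window_sum(chrom, b_lo, b_hi)
        body_bp = b_hi - b_lo
    else:
        raise TypeError("source must be a TagProfile or CoverageTrack")
    prom_density = prom / prom_bp
    body_density = body / body_bp
    if prom_density == 0.0:
        log.warning("empty promoter window; pseudo-density applied")
        prom_density = 1e-6
    return float(body_density / prom_density)


def promoter_binding_frequency(
    site_sets: Mapping[str, PeakSet],
    genes: GeneAnnotation,
    gene_groups: Mapping[str, Iterable[str]],
    window: int = 1000,
    statistic: str = "frequency",
) -> pd.DataFrame:
    """Fraction of group genes with a binding site in the promoter window.

    For each transcription-factor site set and gene group, counts the genes
    with >= 1 site overlapping TSS +- ``window`` (or, with
    ``statistic="mean_sites"``, the mean number of in-window sites per gene).
    A ``pooled`` row reports the union over all factors. Empty groups are an
    error.
    """
    if statistic not in ("frequency", "mean_sites"):
        raise ValueError(f"unknown statistic {statistic!r}")
    trees = {name: _trees(ps) for name, ps in site_sets.items()}
    gdf = genes.df.set_index("gene_id")
    rows = []
    for gname, members in gene_groups.items():
        members = list(dict.fromkeys(members))
        if not members:
            raise ValueError(f"empty gene group {gname!r}")
        missing = [g for g in members if g not in gdf.index]
        if missing:
            raise KeyError(f"genes without annotation: {missing[:5]}")
        per_factor_counts: Dict[str, List[int]] = {f: [] for f in site_sets}
        pooled_counts: List[int] = []
        for g in members:
            rec = gdf.loc[g]
            lo, hi = int(rec["tss"]) - window, int(rec["tss"]) + window
            pooled = 0
            for fname in site_sets:
                tree = trees[fname].get(rec["chrom"])
                hits = len(tree.overlap(lo, hi)) if tree is not None else 0
                per_factor_counts[fname].append(hits)
                pooled += hits
            pooled_counts.append(pooled)
        for fname in site_sets:
            counts = np.array(per_factor_counts[fname])
            value = float((counts > 0).mean()) if statistic == "frequency" \
                else float(counts.mean())
            rows.append({"group": gname, "factor": fname, "n_genes": len(members),
                         "value": value})
        counts = np.array(pooled_counts)
        value = float((counts > 0).mean()) if statistic == "frequency" \
            else float(counts.mean())
        rows.append({"group": gname, "factor": "pooled", "n_genes": len(members),
                     "value": value})
    return pd.DataFrame(rows)


def stratify_by_expression(
    gene_group: Iterable[str],
    matrix: ExpressionMatrix,
    bin_edges: Sequence[float],
) -> Dict[str, List[str]]:
    """Partition a gene group into RPKM strata by mean expression.

    Bins are ``[edge_i, edge_{i+1})`` over the gene's mean RPKM across all
    samples; edges must be strictly increasing (use ``np.inf`` for an open
    top bin). Genes missing from the matrix are dropped with a warning.
    """
    edges = [float(e) for e in bin_edges]
    if len(edges) < 2 or any(y <= x for x, y in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing with >= 2 values")
    group = list(dict.fromkeys(gene_group))
    present = [g for g in group if g in matrix.values.index]
    if len(present) < len(group):
        log.warning("%d group genes missing from matrix; dropped",
                    len(group) - len(present))
    means = matrix.values.loc[present].mean(axis=1)
    out: Dict[str, List[str]] = {}
    for lo, hi in zip(edges, edges[1:]):
        label = f"[{lo:g}, {hi:g})"
        out[label] = [g for g in present if lo <= means[g] < hi]
    return out


def nearest_tss(peaks: PeakSet, genes: GeneAnnotation) -> pd.Series:
    """Assign each peak to the gene with the nearest TSS.

    Distance is measured from the peak midpoint; equidistant ties go to the
    gene with the smaller TSS coordinate (then lexicographic gene id). Peaks
    on chromosomes without any annotated gene are an error.
    """
    by_chrom: Dict[str, pd.DataFrame] = {}
    for chrom, sub in genes.df.groupby("chrom"):
        by_chrom[chrom] = sub.sort_values(["tss", "gene_id"]).reset_index(drop=True)
    assigned = []
    for _, r in peaks.df.iterrows():
        sub = by_chrom.get(r["chrom"])
        if sub is None:
            raise ValueError(f"no gene annotation on chromosome {r['chrom']!r}")
        mid = (int(r["start"]) + int(r["end"])) // 2
        tss = sub["tss"].to_numpy()
        i = int(np.searchsorted(tss, mid))
        candidates = [j for j in (i - 1, i) if 0 <= j < len(sub)]
        best = min(candidates, key=lambda j: (abs(int(tss[j]) - mid), int(tss[j]),
                                              sub["gene_id"].iloc[j]))
        assigned.append(sub["gene_id"].iloc[best])
    return pd.Series(assigned, index=peaks.df["peak_id"].to_numpy(), name="nearest_gene")


def chi_squared_2x2(table) -> Tuple[float, float]:
    """Pearson chi-squared (df=1, no continuity correction) on a 2x2 table."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if tab.sum() == 0:
        raise ValueError("empty table")
    expected = stats.contingency.expected_freq(tab)
    if (expected < 1.0).any():
        raise ValueError(
            "expected cell count < 1; use an exact test (out of scope here)"
        )
    if (expected == tab).all():
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), float(p)


def proximity_enrichment(
    peak_subset: PeakSet,
    all_peaks: PeakSet,
    signature_genes: Iterable[str],
    genes: GeneAnnotation,
) -> Dict[str, object]:
    """Chi-squared test: is the peak subset enriched near signature genes?

    Every peak in ``all_peaks`` is assigned to its nearest TSS; the 2x2 table
    crosses (peak in subset?) x (nearest gene in signature set?) and is
    tested with Pearson's chi-squared (df=1, no continuity correction). The
    table is returned with the statistic.
    """
    sig = set(signature_genes)
    assignment = nearest_tss(all_peaks, genes)
    subset_ids = set(peak_subset.df["peak_id"])
    in_subset = assignment.index.to_series().isin(subset_ids).to_numpy()
    near_sig = assignment.isin(sig).to_numpy()
    table = np.array([
        [int((in_subset & near_sig).sum()), int((in_subset & ~near_sig).sum())],
        [int((~in_subset & near_sig).sum()), int((~in_subset & ~near_sig).sum())],
    ])
    chi2, p = chi_squared_2x2(table)
    return {"chi2": chi2, "p": p, "df": 1, "table": table,
            "nearest_gene": assignment}


def classify_digital_analog(
    matrix: ExpressionMatrix,
    reference_condition: Optional[str] = None,
    induction_fold: float = 4.0,
    max_treated_cv: float = 0.15,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Label each gene's response across treated conditions as digital,
    analog, or other.

    With condition means (reference = first condition unless given) and
    treated = all later conditions in order:

    * ``digital``: min treated mean >= ``induction_fold`` x reference mean
      (reference floored at ``pseudocount`` when zero) AND the coefficient of
      variation across treated means <= ``max_treated_cv`` — induced once,
      then flat.
    * ``analog``: treated means strictly monotone in condition order with a
      max/min fold >= 2 — graded with signal strength.
    * ``other``: everything else. Digital takes precedence.

    The returned frame also carries ``digital_rank_score`` =
    induction fold x (1 - treated CV), the documented ranking used to pick a
    "top N most highly induced / most consistently expressed" digital
    cluster. The 4-fold and 0.15-CV defaults are this package's own
    thresholds for an otherwise qualitative published description.
    """
    means = matrix.condition_means()
    ref = reference_condition or matrix.condition_order[0]
    if ref not in means.columns:
        raise KeyError(f"reference condition {ref!r} has no samples")
    treated_conds = [c for c in means.columns if c != ref]
    if len(treated_conds) < 2:
        raise ValueError("need at least 2 treated conditions")
    treated = means[treated_conds].to_numpy()
    ref_vals = means[ref].to_numpy()
    ref_floor = np.where(ref_vals > 0, ref_vals, pseudocount)

    t_mean = treated.mean(axis=1)
    t_cv = np.divide(treated.std(axis=1, ddof=0), t_mean,
                     out=np.zeros(len(t_mean)), where=t_mean > 0)
    induction = treated.min(axis=1) / ref_floor
    digital = (induction >= induction_fold) & (t_cv <= max_treated_cv)

    diffs = np.diff(treated, axis=1)
    monotone = (diffs > 0).all(axis=1) | (diffs < 0).all(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        total_fold = np.where(treated.min(axis=1) > 0,
                              treated.max(axis=1) / treated.min(axis=1), np.inf)
    analog = monotone & (total_fold >= 2.0) & ~digital

    label = np.where(digital, "digital", np.where(analog, "analog", "other"))
    rank_score = (treated.min(axis=1) / ref_floor) * (1.0 - t_cv)
    return pd.DataFrame({
        "gene_id": means.index,
        "label": label,
        "induction_fold": induction,
        "treated_cv": t_cv,
        "digital_rank_score": rank_score,
    }).set_index("gene_id")
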