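"""Activation scoring of arbitrary samples and gene-group trend statistics.

The activation score of a sample is the dot product of the signature model's
PC1 loadings with the sample's mean-centered expression over the signature
genes, scaled by the maximum absolute score so the most extreme sample in the
scored set is at +-1. The score ranks samples *within* an experiment; it is
deliberately not comparable across experiments, because the centering is
taken over the samples being scored.

The trend test asks whether a gene group's mean expression change between two
conditions is larger than expected for a random group of the same size: the
null is built by redrawing gene groups (without replacement) from the full
matrix universe, a normal distribution is fitted to the null statistics, and
a two-tailed p-value is read off the fitted normal (the empirical permutation
rank is reported alongside).
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ActivationScoreResult, ExpressionMatrix, PermutationTestResult, SignatureModel

__all__ = [
    "score_samples",
    "rank_experiment_groups",
    "permutation_trend_test",
    "compare_group_expression",
]

log = logging.getLogger(__name__)


def score_samples(
    model: SignatureModel,
    matrix: ExpressionMatrix,
    center: str = "scored",
) -> ActivationScoreResult:
    """Score every sample of ``matrix`` with the signature model.

    ``center`` controls the gene-wise mean subtracted before the dot product:
    ``"scored"`` (default) uses the mean over the samples being scored — the
    right choice when scoring external datasets whose absolute levels are not
    comparable to the training data; ``"model"`` uses the model's stored
    training means; ``"none"`` skips centering (the caller supplies an
    already-centered matrix).

    Signature genes missing from the matrix are dropped (never imputed); if
    fewer than 50% of the model's genes are present this is an error.
    """
    if center not in ("scored", "model", "none"):
        raise ValueError(f"unknown centering mode {center!r}")
    present = [g for g in model.gene_ids if g in matrix.values.index]
    missing = [g for g in model.gene_ids if g not in matrix.values.index]
    if len(model.gene_ids) == 0:
        raise ValueError("signature model has no genes")
    frac_missing = len(missing) / len(model.gene_ids)
    if frac_missing > 0.5:
        raise ValueError(
            f"matrix shares only {1 - frac_missing:.0%} of the model's genes "
            f"({len(missing)} of {len(model.gene_ids)} missing)"
        )
    X = matrix.values.loc[present]  # genes x samples
    if center == "scored":
        Xc = X.sub(X.mean(axis=1), axis=0)
    elif center == "model":
        Xc = X.sub(model.gene_means.loc[present], axis=0)
    else:
        Xc = X
    # axis-reduction rather than BLAS matmul: identical samples must receive
    # bit-identical scores (matmul blocking breaks exact ties)
    load = model.loadings.loc[present].to_numpy()
    raw = (Xc.to_numpy() * load[:, None]).sum(axis=0)
    raw = pd.Series(raw, index=matrix.sample_ids)
    peak = float(np.abs(raw).max())
    if peak == 0.0:
        log.warning("all raw scores are zero; scaled scores reported as 0")
        scaled = raw.copy()
    else:
        scaled = raw / peak
    return ActivationScoreResult(
        sample_ids=list(matrix.sample_ids),
        raw_score=raw,
        scaled_score=scaled,
        n_genes_used=len(present),
        genes_missing=missing,
    )


def rank_experiment_groups(
    result: ActivationScoreResult,
    group_labels: Mapping[str, str],
) -> pd.DataFrame:
    """Per-group mean scaled score, ordered from most to least activated.

    Every scored sample must be labeled. Groups are ranked by mean scaled
    score; exact ties share the ``tied`` flag. Cross-experiment comparison is
    out of scope by construction — call once per experiment.
    """
    unlabeled = [s for s in result.sample_ids if s not in group_labels]
    if unlabeled:
        raise KeyError(f"samples without a group label: {unlabeled}")
    rows = {}
    for s in result.sample_ids:
        rows.setdefault(group_labels[s], []).append(result.scaled_score[s])
    out = pd.DataFrame(
        {"group": list(rows), "n": [len(v) for v in rows.values()],
         "mean_scaled_score": [float(np.mean(v)) for v in rows.values()]}
    ).sort_values(["mean_scaled_score", "group"], ascending=[False, True]).reset_index(drop=True)
    out["tied"] = out["mean_scaled_score"].duplicated(keep=False)
    return out


def _condition_diff(matrix: ExpressionMatrix, condition_a: str, condition_b: str) -> pd.Series:
    means = matrix.condition_means()
    for cond in (condition_a, condition_b):
        if cond not in means.columns:
            raise KeyError(f"condition {cond!r} has no samples")
    return means[condition_b] - means[condition_a]


def permutation_trend_test(
    matrix: ExpressionMatrix,
    gene_group: Iterable[str],
    condition_a: str,
    condition_b: str,
    n_permutations: int = 10000,
    seed: Optional[int] = None,
) -> PermutationTestResult:
    """Test a gene group's mean expression change against a random-group null.

    observed = mean over the group of (mean expression in ``condition_b`` -
    mean expression in ``condition_a``). The null redraws
    ``n_permutations`` random gene groups of the same size (without
    replacement) from the full gene universe and computes the same statistic;
    a normal is fitted to the null and the two-tailed p-value is
    ``2 * Phi(-|z|)``, floored at machine precision. The empirical
    permutation rank p-value is reported alongside. Deterministic per seed.
    """
    group = list(dict.fromkeys(gene_group))
    if len(group) < 2:
        raise ValueError("gene group must contain at least 2 genes")
    missing = [g for g in group if g not in matrix.values.index]
    if missing:
        raise KeyError(f"genes not in matrix: {missing[:5]}")
    diffs = _condition_diff(matrix, condition_a, condition_b)
    observed = float(diffs.loc[group].mean())

    universe = diffs.to_numpy()
    n, k = len(universe), len(group)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = universe[rng.choice(n, size=k, replace=False)].mean()
    null_mean = float(null.mean())
    null_std = float(null.std(ddof=1))
    if null_std <= 1e-12 * max(abs(null_mean), 1.0):
        if np.isclose(observed, null_mean):
            z, p = 0.0, 1.0
        else:
            raise ValueError("degenerate null: permutation statistics have zero spread")
    else:
        z = (observed - null_mean) / null_std
        p = max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny)
    p_emp = float(
        (1 + np.sum(np.abs(null - null_mean) >= abs(observed - null_mean)))
        / (n_permutations + 1)
    )
    return PermutationTestResult(
        observed_statistic=observed,
        null_mean=null_mean,
        null_std=null_std,
        n_permutations=n_permutations,
        z=float(z),
        p_two_tailed=float(p),
        p_empirical=p_emp,
        seed=seed,
    )


def compare_group_expression(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    gene_group: Iterable[str],
    strata_by_rpkm: Optional[Sequence[float]] = None,
) -> Dict[str, object]:
    """Paired per-gene comparison of a gene group between two datasets.

    For each group gene, the per-gene value is its mean expression over all
    samples of each matrix; the statistic is the paired two-sided Student's t
    test on (b - a) with the group mean difference reported. With
    ``strata_by_rpkm`` (increasing bin edges on the matrix_a mean RPKM) the
    comparison is repeated within each stratum; empty strata are skipped with
    a warning.

    Returns a dict with keys ``per_gene`` (DataFrame: gene, mean_a, mean_b,
    diff), ``mean_difference``, ``t``, ``p``, and ``strata`` (list of per-
    stratum summaries, empty if no edges given).
    """
    group = [g for g in dict.fromkeys(gene_group)]
    shared = [g for g in group
              if g in matrix_a.values.index and g in matrix_b.values.index]
    dropped = [g for g in group if g not in shared]
    if dropped:
        log.warning("%d group genes absent from one of the matrices; dropped",
                    len(dropped))
    if len(shared) < 2:
        raise ValueError("need at least 2 shared group genes")
    a = matrix_a.values.loc[shared].mean(axis=1)
    b = matrix_b.values.loc[shared].mean(axis=1)
    per_gene = pd.DataFrame({"gene": shared, "mean_a": a.to_numpy(),
                             "mean_b": b.to_numpy(),
                             "diff": (b - a).to_numpy()})

    def _summary(sub: pd.DataFrame) -> Tuple[float, float, float]:
        d = sub["diff"].to_numpy()
        if np.allclose(d, 0.0):
            return 0.0, 0.0, 1.0
        t, p = stats.ttest_rel(sub["mean_b"], sub["mean_a"])
        return float(d.mean()), float(t), float(p)

    mean_diff, t, p = _summary(per_gene)
    strata: List[Dict[str, object]] = []
    if strata_by_rpkm is not None:
        edges = list(strata_by_rpkm)
        if any(y <= x for x, y in zip(edges, edges[1:])):
            raise ValueError("stratum edges must be strictly increasing")
        for lo, hi in zip(edges, edges[1:]):
            sub = per_gene[(per_gene["mean_a"] >= lo) & (per_gene["mean_a"] < hi)]
            if len(sub) < 2:
                log.warning("stratum [%s, %s) has <2 genes; skipped", lo, hi)
                continue
            sd, st, sp = _summary(sub)
            strata.append({"lo": lo, "hi": hi, "n": len(sub),
                           "mean_difference": sd, "t": st, "p": sp})
    return {"per_gene": per_gene, "mean_difference": mean_diff, "t": t, "p": p,
            "n_genes": len(shared), "strata": strata}
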