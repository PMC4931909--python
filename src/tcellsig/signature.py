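"""Derivation of the activation signature: variable-gene filtering, the
principal axis of the stimulation series, and replicate-consistent signature
gene sets.

The model: over an ordered series of stimulation conditions, the dominant
axis of gene-expression variation (PC1 of the gene-wise mean-centered RPKM
matrix, samples as observations) orders samples by activation state. Genes
with the most positive PC1 loadings increase with signal strength ("activation
signature genes"); the most negative decrease. The signature is made
replicate-robust by fitting the axis separately per replicate dataset and on
the combined dataset, dropping genes that are weakly or inconsistently
expressed in the reference (unstimulated) condition, and intersecting the
extreme-decile sets across all fits.

PCA is computed on untransformed RPKM after gene-wise mean-centering and no
unit-variance scaling (a ``scale`` switch is provided); high-expression genes
therefore dominate the axis, which is what makes the RPKM-floor filter in
:func:`derive_signature` meaningful.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SignatureModel

__all__ = [
    "filter_variable_genes",
    "fit_pc1",
    "extract_deciles",
    "derive_signature",
]

log = logging.getLogger(__name__)


def filter_variable_genes(
    matrix: ExpressionMatrix,
    min_rpkm: float = 10.0,
    min_fold: float = 2.0,
    pseudocount: float = 1.0,
) -> List[str]:
    """Genes expressed above ``min_rpkm`` and >= ``min_fold`` different
    between some pair of conditions.

    Replicates are collapsed to condition means first. A gene is kept iff its
    maximum condition mean exceeds ``min_rpkm`` (strictly) and
    ``max_mean / (min_mean + pseudocount) >= min_fold``. The pseudocount
    (default 1 RPKM, below the expression floor) keeps zero-mean genes finite.
    Returns gene ids in matrix order; an empty result is a warning, not an
    error.
    """
    means = matrix.condition_means()
    if means.shape[1] < 2:
        raise ValueError("need >= 2 conditions with samples")
    mx = means.max(axis=1)
    mn = means.min(axis=1)
    keep = (mx > min_rpkm) & (mx / (mn + pseudocount) >= min_fold)
    genes = list(means.index[keep])
    if not genes:
        log.warning("variable-gene filter retained no genes")
    return genes


def fit_pc1(
    matrix: ExpressionMatrix,
    gene_set: Optional[Iterable[str]] = None,
    scale: bool = False,
    reference_condition: Optional[str] = None,
) -> SignatureModel:
    """Fit the first principal axis over the given genes.

    Samples are the observations and genes the features: the loadings are the
    first right-singular direction of the gene-wise mean-centered (optionally
    unit-variance scaled) matrix, unit-norm; ``sample_scores`` are the
    projections of the centered samples onto that direction, and
    ``variance_explained`` the PC1 share of total variance.

    Sign convention: the mean score of the reference-condition samples (first
    condition in ``condition_order`` unless given) must not exceed the mean
    score of the highest-signal condition's samples, so scores increase with
    activation. If both conditions score identically the sign is fixed by
    making the largest-magnitude loading positive.
    """
    genes = list(gene_set) if gene_set is not None else matrix.gene_ids
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to fit a principal axis")
    if len(matrix.sample_ids) < 2:
        raise ValueError("need at least 2 samples to fit a principal axis")
    X = matrix.values.loc[genes].T.to_numpy(dtype=float)  # samples x genes
    gene_means = X.mean(axis=0)
    Xc = X - gene_means
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    total_var = float((Xc ** 2).sum())
    if total_var == 0.0:
        raise ValueError("no principal axis: matrix has zero variance")
    _, svals, vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = vt[0]
    variance_explained = float(svals[0] ** 2 / (svals ** 2).sum())
    # axis-reduction, not matmul: identical samples get bit-identical scores
    scores = (Xc * loadings).sum(axis=1)

    ref = reference_condition or matrix.condition_order[0]
    high = matrix.condition_order[-1]
    ref_samples = matrix.samples_of(ref)
    high_samples = matrix.samples_of(high)
    sample_index = {s: i for i, s in enumerate(matrix.sample_ids)}
    ref_mean = float(np.mean([scores[sample_index[s]] for s in ref_samples])) if ref_samples else 0.0
    high_mean = float(np.mean([scores[sample_index[s]] for s in high_samples])) if high_samples else 0.0
    if ref_mean > high_mean:
        loadings, scores = -loadings, -scores
    elif ref_mean == high_mean and loadings[np.argmax(np.abs(loadings))] < 0:
        loadings, scores = -loadings, -scores

    return SignatureModel(
        gene_ids=genes,
        loadings=pd.Series(loadings, index=genes),
        gene_means=pd.Series(gene_means, index=genes),
        variance_explained=variance_explained,
        sample_scores=pd.Series(scores, index=matrix.sample_ids),
        reference_condition=ref,
    )


def extract_deciles(
    model: SignatureModel, fraction: float = 0.10
) -> Tuple[List[str], List[str]]:
    """Extreme-loading gene sets: the top and bottom ``fraction`` of genes.

    Genes are sorted by loading (ties broken by lexicographic gene id, so the
    extraction is fully deterministic); each set has
    ``min(ceil(fraction * n), n // 2)`` genes — the cap guarantees the two
    sets are disjoint for any fraction <= 0.5.
    """
    if not (0.0 < fraction <= 0.5):
        raise ValueError("fraction must be in (0, 0.5]")
    n = len(model.gene_ids)
    k = min(math.ceil(fraction * n), n // 2)
    order = sorted(model.gene_ids, key=lambda g: (-model.loadings[g], g))
    top = order[:k]
    order_low = sorted(model.gene_ids, key=lambda g: (model.loadings[g], g))
    bottom = order_low[:k]
    return top, bottom


def derive_signature(
    replicate_matrices: Sequence[ExpressionMatrix],
    combined_matrix: ExpressionMatrix,
    reference_condition: Optional[str] = None,
    min_ref_rpkm: float = 100.0,
    max_ref_cv: float = 0.20,
    fraction: float = 0.10,
    gene_set: Optional[Iterable[str]] = None,
    scale: bool = False,
) -> SignatureModel:
    """Derive replicate-consistent activation-signature gene sets.

    Procedure:

    1. Fit PC1 separately on each replicate matrix and on the combined matrix
       (over ``gene_set`` if given, else the shared gene universe).
    2. Drop genes whose reference-condition expression in the combined matrix
       is below ``min_ref_rpkm``, or whose reference-condition level varies
       across the replicate datasets with std > ``max_ref_cv`` x the
       reference level (the cross-replicate consistency filter).
    3. Take the top and bottom ``fraction`` of the *remaining* genes in every
       fit, and intersect across all k+1 fits (each replicate plus the
       combined dataset).

    Returns the combined-matrix model restricted to the surviving genes, with
    ``top_set``/``bottom_set`` filled in (sorted by combined loading,
    descending for the top set, ascending for the bottom). An empty
    intersection is a warning, not an error.
    """
    if len(replicate_matrices) < 1:
        raise ValueError("need at least one replicate matrix")
    ref = reference_condition or combined_matrix.condition_order[0]

    universe = set(combined_matrix.gene_ids)
    for m in replicate_matrices:
        universe &= set(m.gene_ids)
    genes = [g for g in combined_matrix.gene_ids if g in universe]
    if gene_set is not None:
        wanted = set(gene_set)
        genes = [g for g in genes if g in wanted]

    fits = [fit_pc1(m, genes, scale=scale, reference_condition=ref)
            for m in replicate_matrices]
    combined_fit = fit_pc1(combined_matrix, genes, scale=scale,
                           reference_condition=ref)

    # reference-condition expression filter
    ref_combined = combined_matrix.condition_means()[ref].loc[genes]
    ref_by_rep = pd.DataFrame(
        {i: m.condition_means()[ref].loc[genes] for i, m in enumerate(replicate_matrices)}
    )
    ref_std = ref_by_rep.std(axis=1, ddof=1) if len(replicate_matrices) > 1 else pd.Series(0.0, index=genes)
    ok = (ref_combined >= min_ref_rpkm) & (ref_std <= max_ref_cv * ref_combined)
    surviving = [g for g in genes if ok[g]]
    if not surviving:
        log.warning("reference-condition filters removed every gene")

    top: Optional[Set[str]] = None
    bottom: Optional[Set[str]] = None
    for fit in fits + [combined_fit]:
        t, b = extract_deciles(fit.restrict(surviving), fraction)
        top = set(t) if top is None else top & set(t)
        bottom = set(b) if bottom is None else bottom & set(b)
    if not top or not bottom:
        log.warning("decile intersection is empty for %s set(s)",
                    "top" if not top else "bottom")

    model = combined_fit.restrict(surviving)
    model.top_set = sorted(top or (), key=lambda g: (-model.loadings[g], g))
    model.bottom_set = sorted(bottom or (), key=lambda g: (model.loadings[g], g))
    return model
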