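"""Synthetic expression matrices and peak landscapes with full ground truth.

The generators emulate the statistical structure of a five-condition T-cell
stimulation series so that every downstream stage (signature derivation,
scoring, trend testing, enhancer analytics, super-enhancer calling) can be
tested without any sequencing data:

* ``generate_expression`` plants four gene classes — *analog_up* (mean
  increasing linearly with per-condition signal strength), *analog_down*
  (mirrored decreasing), *digital* (at baseline in the reference condition and
  uniformly induced in every treated condition), and *null* (flat) — under
  multiplicative log-normal noise with a stated coefficient of variation.
* ``generate_peaks`` plants a background enhancer landscape plus fold-gained
  peaks and clustered high-tag super-enhancer regions.
* ``generate_tag_profile`` produces TSS-anchored coverage shapes (focal
  promoter peak, gene-body spreading, uniform) for the spreading-ratio
  statistic.

All generators are pure functions of (parameters, seed): one
``numpy.random.default_rng`` stream per call, no global state.
"""

from __future__ import annotations

import math
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    PeakSet,
    PlantedEnhancerTruth,
    SyntheticTruth,
    TagProfile,
)

__all__ = ["generate_expression", "generate_peaks", "generate_tag_profile",
           "DEFAULT_CONDITIONS", "DEFAULT_SIGNAL_STRENGTHS", "DEFAULT_PROPORTIONS"]

#: Condition labels of the five-condition stimulation series, ordered by
#: increasing nominal TCR signal strength.
DEFAULT_CONDITIONS = ("no_peptide", "K99A_10uM", "K99A_100uM", "PCC_0.1uM", "PCC_10uM")

#: Per-condition signal strengths in [0, 1]. The middle two conditions are
#: deliberately close (0.55 vs 0.60) to mimic the near-tie between the
#: high-dose low-affinity and low-dose high-affinity stimulations.
DEFAULT_SIGNAL_STRENGTHS = (0.0, 0.45, 0.55, 0.60, 1.0)

DEFAULT_PROPORTIONS = {"analog_up": 0.10, "analog_down": 0.10,
                       "digital": 0.05, "null": 0.75}


def _class_counts(n_genes: int, proportions: Mapping[str, float]) -> Dict[str, int]:
    """Largest-remainder apportionment of genes to classes."""
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class proportions sum to {total!r}, not 1")
    raw = {k: proportions[k] * n_genes for k in proportions}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n_genes - sum(counts.values())
    for k in sorted(raw, key=lambda k: (raw[k] - counts[k]), reverse=True)[:short]:
        counts[k] += 1
    return counts


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(() if shape is None else shape)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=shape)


def generate_expression(
    n_genes: int = 3000,
    class_proportions: Optional[Mapping[str, float]] = None,
    signal_strengths: Sequence[float] = DEFAULT_SIGNAL_STRENGTHS,
    effect_size_range: Tuple[float, float] = (2.0, 8.0),
    noise_cv: float = 0.10,
    n_replicates: int = 2,
    baseline_range: Tuple[float, float] = (100.0, 1000.0),
    digital_baseline_range: Tuple[float, float] = (5.0, 50.0),
    condition_names: Optional[Sequence[str]] = None,
    seed: int = 0,
) -> Tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a genes x (conditions x replicates) RPKM matrix with ground truth.

    Mean structure (noise_cv=0 reproduces it exactly), with per-gene baseline
    ``b`` and effect size ``e``:

    * analog_up:    mean_c = b * (1 + (e - 1) * s_c)
    * analog_down:  mean_c = b * (1 + (e - 1) * (1 - s_c))   (mirrored)
    * digital:      b in the reference (first) condition, b * e in all others
    * null:         b in every condition

    where ``s_c`` is the condition's signal strength. Baselines are
    log-uniform over ``baseline_range`` except for digital genes, which draw
    from the lower ``digital_baseline_range`` (digital-response genes start
    from a low, off-like level in the unstimulated control). Replicate
    columns are independent noise draws.
    """
    strengths = [float(s) for s in signal_strengths]
    if len(strengths) < 2:
        raise ValueError("need at least 2 conditions")
    if any(b <= a for a, b in zip(strengths, strengths[1:])):
        raise ValueError("signal_strengths must be strictly increasing")
    props = dict(class_proportions or DEFAULT_PROPORTIONS)
    counts = _class_counts(n_genes, props)
    lo, hi = effect_size_range
    if not (hi >= lo > 1.0):
        raise ValueError("effect sizes must be > 1 for non-null genes")

    if condition_names is None:
        if len(strengths) == len(DEFAULT_CONDITIONS):
            condition_names = list(DEFAULT_CONDITIONS)
        else:
            condition_names = [f"cond{i}" for i in range(len(strengths))]
    condition_names = list(condition_names)

    rng = np.random.default_rng(seed)
    width = len(str(max(n_genes - 1, 1)))
    gene_ids = [f"g{i:0{width}d}" for i in range(n_genes)]
    classes = np.concatenate([np.repeat(k, counts[k]) for k in sorted(counts)])
    rng.shuffle(classes)

    baseline = np.exp(rng.uniform(math.log(baseline_range[0]),
                                  math.log(baseline_range[1]), n_genes))
    dlo, dhi = digital_baseline_range
    digital_mask = classes == "digital"
    baseline[digital_mask] = np.exp(
        rng.uniform(math.log(dlo), math.log(dhi), int(digital_mask.sum()))
    )
    effect = np.exp(rng.uniform(math.log(lo), math.log(hi), n_genes))
    effect[classes == "null"] = 1.0

    s = np.asarray(strengths)
    n_cond = len(s)
    means = np.empty((n_genes, n_cond))
    for i in range(n_genes):
        b, e = baseline[i], effect[i]
        if classes[i] == "analog_up":
            means[i] = b * (1.0 + (e - 1.0) * s)
        elif classes[i] == "analog_down":
            means[i] = b * (1.0 + (e - 1.0) * (1.0 - s))
        elif classes[i] == "digital":
            means[i] = np.full(n_cond, b * e)
            means[i, 0] = b
        else:
            means[i] = b

    sample_ids, cond_of, rep_of, cols = [], {}, {}, []
    for r in range(1, n_replicates + 1):
        for c, cond in enumerate(condition_names):
            sid = f"{cond}_rep{r}"
            sample_ids.append(sid)
            cond_of[sid] = cond
            rep_of[sid] = f"rep{r}"
            noise = _lognormal_noise(rng, noise_cv, n_genes)
            cols.append(means[:, c] * noise)
    values = pd.DataFrame(np.column_stack(cols), index=gene_ids, columns=sample_ids)

    matrix = ExpressionMatrix(values, cond_of, condition_names, rep_of)
    truth = SyntheticTruth(
        gene_class=dict(zip(gene_ids, classes)),
        signal_strength=dict(zip(condition_names, strengths)),
        effect_size=dict(zip(gene_ids, effect)),
        baseline=dict(zip(gene_ids, baseline)),
        noise_cv=noise_cv,
        seed=seed,
    )
    return matrix, truth


def generate_peaks(
    n_background: int = 2000,
    n_gain: int = 100,
    gain_fold: float = 3.0,
    n_superenhancers: int = 20,
    peaks_per_se: int = 10,
    genome_spec: Optional[Mapping[str, int]] = None,
    conditions: Sequence[str] = ("unstimulated", "stimulated"),
    tag_noise_cv: float = 0.05,
    se_span: int = 8000,
    background_tag_cap: float = 120.0,
    seed: int = 0,
) -> Tuple[PeakSet, PlantedEnhancerTruth]:
    """Generate a two-condition peak landscape with planted events.

    Background peaks share tag counts across conditions up to multiplicative
    noise; ``n_gain`` peaks have their stimulated-condition tags multiplied by
    ``gain_fold`` (> 2 required); ``n_superenhancers`` regions each receive
    ``peaks_per_se`` clustered high-tag peaks within an ``se_span`` bp window
    (smaller than the default 12,500 bp stitching distance, so each planted
    region stitches into exactly one region).

    Peaks are laid out on a 30 kb grid so that distinct planted elements never
    overlap and background peaks never stitch together. Background tag counts
    are log-normal, clipped at ``background_tag_cap``: the clip keeps the
    upper tail of the background rank-score curve below unit slope, so the
    planted regions are the only tangent-threshold crossings. (An unbounded
    heavy tail is itself steep enough near its maximum to be called
    super-enhancer — a real feature of tag landscapes, but fatal for a
    planted-truth test bed.)
    """
    if gain_fold <= 2.0:
        raise ValueError("gain_fold must be strictly > 2")
    if len(conditions) != 2:
        raise ValueError("generate_peaks plants a two-condition landscape")
    genome = dict(genome_spec or {"chr1": 60_000_000, "chr2": 60_000_000,
                                  "chr3": 60_000_000})
    slot_size = 30_000
    slots = [(chrom, i * slot_size)
             for chrom in sorted(genome)
             for i in range(int(genome[chrom]) // slot_size)]
    n_elements = n_background + n_gain + n_superenhancers
    if n_elements > len(slots):
        raise ValueError(
            f"genome too small to place {n_elements} non-overlapping elements"
        )
    if se_span >= slot_size - 1000:
        raise ValueError("se_span must fit inside a placement slot")

    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(slots), size=n_elements, replace=False)
    cond_a, cond_b = conditions

    rows = []
    gain_ids = []
    se_regions = []
    k = 0
    bg_params = {"tag_log_mean": math.log(60.0), "tag_log_sigma": 0.4,
                 "tag_cap": background_tag_cap,
                 "se_tag_log_mean": math.log(250.0), "se_tag_log_sigma": 0.3,
                 "tag_noise_cv": tag_noise_cv}

    def _noisy(base: float) -> float:
        return float(base * _lognormal_noise(rng, tag_noise_cv, None))

    # keep every element >12.5 kb from its slot edges' neighbours so that
    # background peaks never stitch together (a stitched background pair
    # would double its tags and leak past the background cap)
    margin = 13_000
    for i in range(n_background + n_gain):
        chrom, slot_start = slots[chosen[k]]; k += 1
        width = int(rng.integers(500, 2000))
        start = slot_start + int(rng.integers(0, slot_size - width - margin))
        base = min(float(rng.lognormal(bg_params["tag_log_mean"],
                                       bg_params["tag_log_sigma"])),
                   background_tag_cap)
        is_gain = i >= n_background
        pid = f"gain{i - n_background:04d}" if is_gain else f"bg{i:05d}"
        # the cap is a hard ceiling (applied to the base level and again
        # after noise): background tags are clipped log-normal, so the
        # background rank curve ends in a flat shelf well below any planted
        # region; gain peaks multiply the capped base by gain_fold
        tag_a = min(_noisy(base), background_tag_cap)
        tag_b = _noisy(base * gain_fold) if is_gain \
            else min(_noisy(base), background_tag_cap)
        if is_gain:
            gain_ids.append(pid)
        rows.append((chrom, start, start + width, pid, tag_a, tag_b))

    for j in range(n_superenhancers):
        chrom, slot_start = slots[chosen[k]]; k += 1
        region_start = slot_start + 500
        spacing = se_span // peaks_per_se
        ends = []
        for p in range(peaks_per_se):
            width = int(rng.integers(300, min(600, spacing)))
            start = region_start + p * spacing
            base = float(rng.lognormal(bg_params["se_tag_log_mean"],
                                       bg_params["se_tag_log_sigma"]))
            pid = f"se{j:02d}_p{p:02d}"
            rows.append((chrom, start, start + width, pid, _noisy(base), _noisy(base)))
            ends.append(start + width)
        se_regions.append((chrom, region_start, max(ends)))

    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_id",
                                     cond_a, cond_b])
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    peaks = PeakSet(df, [cond_a, cond_b])
    truth = PlantedEnhancerTruth(
        planted_gain_peaks=gain_ids,
        planted_superenhancer_regions=se_regions,
        background_params=bg_params,
        seed=seed,
    )
    return peaks, truth


def generate_tag_profile(
    shape: str,
    window_bp: int = 10000,
    depth: float = 1.0,
    seed: int = 0,
) -> TagProfile:
    """Generate a TSS-anchored per-base tag coverage vector.

    The profile spans offsets [-window_bp//2, window_bp//2) around the anchor
    (offset 0 = TSS, positive offsets downstream). All shapes carry the same
    expected total of ``depth * window_bp`` tags; per-base counts are Poisson
    draws around the shape's rate:

    * ``uniform``: flat rate ``depth`` at every base.
    * ``focal_tss``: Gaussian rate with sd 250 bp centered on the TSS, which
      puts >95% of the expected tags within +-500 bp.
    * ``spread_body``: uniform rate over the first 4000 bp downstream of the
      TSS (offsets [0, 4000)), zero elsewhere.
    """
    if window_bp < 4000:
        raise ValueError("window_bp must be >= 4000")
    if shape not in ("focal_tss", "spread_body", "uniform"):
        raise ValueError(f"unknown profile shape {shape!r}")
    half = window_bp // 2
    offsets = np.arange(-half, -half + window_bp)
    total = depth * window_bp
    if shape == "uniform":
        rate = np.full(window_bp, depth, dtype=float)
    elif shape == "focal_tss":
        sd = 250.0
        dens = np.exp(-0.5 * (offsets / sd) ** 2)
        rate = total * dens / dens.sum()
    else:  # spread_body
        body = (offsets >= 0) & (offsets < 4000)
        rate = np.where(body, total / body.sum(), 0.0)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate).astype(float)
    return TagProfile(offset_start=-half, coverage=counts)
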