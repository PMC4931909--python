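"""Core in-memory containers shared across the pipeline.

Conventions used throughout the package:

* Genomic coordinates are 0-based, half-open (BED arithmetic), everywhere.
* Expression values are gene-level RPKM (reads per kilobase of transcript per
  million mapped reads), non-negative and finite.
* Peak tag counts are sequencing-depth-normalized ("normalized tags"); the
  package never re-normalizes them (see :func:`tcellsig.io_formats.rescale_tags`
  for an explicit helper).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneAnnotation",
    "PeakSet",
    "CoverageTrack",
    "TagProfile",
    "SignatureModel",
    "ActivationScoreResult",
    "PermutationTestResult",
    "StitchedRegion",
    "SECallResult",
    "SyntheticTruth",
    "PlantedEnhancerTruth",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples RPKM matrix with ordered condition labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample.
    condition_of_sample
        Maps every sample id to a condition label.
    condition_order
        Condition labels ordered by increasing nominal signal strength.
    replicate_of_sample
        Optional replicate-group label per sample.
    """

    values: pd.DataFrame
    condition_of_sample: Dict[str, str]
    condition_order: List[str]
    replicate_of_sample: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.condition_order = list(self.condition_order)
        self.validate()

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression matrix contains non-finite values")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative expression value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        for sample in self.values.columns:
            cond = self.condition_of_sample.get(sample)
            if cond is None:
                raise KeyError(f"sample {sample!r} missing from condition map")
            if cond not in self.condition_order:
                raise ValueError(
                    f"sample {sample!r} maps to unknown condition {cond!r}"
                )

    @property
    def gene_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.columns)

    def samples_of(self, condition: str) -> List[str]:
        return [s for s in self.values.columns if self.condition_of_sample[s] == condition]

    def condition_means(self) -> pd.DataFrame:
        """Collapse replicates: per-gene mean over the samples of each condition.

        Only conditions that actually have samples appear as columns.
        """
        cols = {}
        for cond in self.condition_order:
            samples = self.samples_of(cond)
            if samples:
                cols[cond] = self.values[samples].mean(axis=1)
        return pd.DataFrame(cols)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(
            self.values.loc[genes].copy(),
            dict(self.condition_of_sample),
            list(self.condition_order),
            dict(self.replicate_of_sample),
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(samples)].copy(),
            {s: self.condition_of_sample[s] for s in samples},
            list(self.condition_order),
            {s: r for s, r in self.replicate_of_sample.items() if s in samples},
        )


@dataclass
class GeneAnnotation:
    """Gene annotation table: gene_id, chrom, start, end, strand, tss.

    Coordinates are 0-based half-open; ``tss`` is the base position of the
    transcription start site and must satisfy start <= tss <= end. Strand is
    required ('+' or '-') because promoter and gene-body windows are
    strand-aware.
    """

    df: pd.DataFrame

    REQUIRED = ("gene_id", "chrom", "start", "end", "strand", "tss")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"gene annotation missing columns {missing}")
        df = self.df
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene id {dup!r}")
        bad = df["start"] >= df["end"]
        if bad.any():
            g = df.loc[bad, "gene_id"].iloc[0]
            raise ValueError(f"gene {g!r} has start >= end")
        if not df["strand"].isin(["+", "-"]).all():
            raise ValueError("gene strand must be '+' or '-'")
        out = (df["tss"] < df["start"]) | (df["tss"] > df["end"])
        if out.any():
            g = df.loc[out, "gene_id"].iloc[0]
            raise ValueError(f"gene {g!r} has TSS outside the gene body")

    def __len__(self) -> int:
        return len(self.df)

    def row(self, gene_id: str) -> pd.Series:
        hit = self.df[self.df["gene_id"] == gene_id]
        if hit.empty:
            raise KeyError(gene_id)
        return hit.iloc[0]


@dataclass
class PeakSet:
    """Genomic intervals with per-condition normalized tag counts.

    ``df`` columns: chrom, start, end, peak_id, then one float column per
    condition in ``conditions``. Intervals are 0-based half-open.
    """

    df: pd.DataFrame
    conditions: List[str]

    def __post_init__(self) -> None:
        self.conditions = list(self.conditions)
        for col in ("chrom", "start", "end", "peak_id"):
            if col not in self.df.columns:
                raise ValueError(f"peak table missing column {col!r}")
        for cond in self.conditions:
            if cond not in self.df.columns:
                raise ValueError(f"tag column for condition {cond!r} missing")
            if (self.df[cond] < 0).any():
                raise ValueError(f"negative tag count in condition {cond!r}")
        if (self.df["start"] >= self.df["end"]).any():
            bad = self.df[self.df["start"] >= self.df["end"]].iloc[0]
            raise ValueError(
                f"interval start >= end for peak {bad['peak_id']!r}"
            )
        if self.df["peak_id"].duplicated().any():
            dup = self.df.loc[self.df["peak_id"].duplicated(), "peak_id"].iloc[0]
            raise ValueError(f"duplicate peak id {dup!r}")

    def __len__(self) -> int:
        return len(self.df)

    def tags(self, condition: str) -> pd.Series:
        if condition not in self.conditions:
            raise KeyError(f"unknown condition {condition!r}")
        return self.df[condition]


@dataclass
class CoverageTrack:
    """Dense per-base tag coverage, one non-negative float array per chromosome."""

    coverage: Dict[str, np.ndarray]

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Total tags in [start, end), clipped to the chromosome."""
        arr = self.coverage[chrom]
        lo, hi = max(0, start), min(len(arr), end)
        if hi <= lo:
            return 0.0
        return float(arr[lo:hi].sum())


@dataclass
class TagProfile:
    """Tag coverage anchored at a position (offset 0 = the anchor, e.g. a TSS).

    Offsets run from ``offset_start`` to ``offset_start + len(coverage)``;
    strand orientation is already applied (positive offsets point downstream).
    """

    offset_start: int
    coverage: np.ndarray

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(self.offset_start, self.offset_start + len(self.coverage))

    def window_sum(self, lo: int, hi: int) -> float:
        """Total tags for offsets in [lo, hi), clipped to the profile extent."""
        i = max(0, lo - self.offset_start)
        j = min(len(self.coverage), hi - self.offset_start)
        if j <= i:
            return 0.0
        return float(self.coverage[i:j].sum())


@dataclass
class SignatureModel:
    """The fitted principal-axis model of the activation response.

    ``loadings`` is the unit-norm first right-singular direction of the
    gene-wise mean-centered matrix (samples as observations); the sign is
    fixed so that the mean sample score of the reference condition is <= the
    mean score of the highest-signal condition.
    """

    gene_ids: List[str]
    loadings: pd.Series
    gene_means: pd.Series
    variance_explained: float
    sample_scores: pd.Series
    reference_condition: str
    top_set: List[str] = field(default_factory=list)
    bottom_set: List[str] = field(default_factory=list)

    def restrict(self, genes: Iterable[str]) -> "SignatureModel":
        keep = [g for g in self.gene_ids if g in set(genes)]
        return SignatureModel(
            gene_ids=keep,
            loadings=self.loadings.loc[keep],
            gene_means=self.gene_means.loc[keep],
            variance_explained=self.variance_explained,
            sample_scores=self.sample_scores,
            reference_condition=self.reference_condition,
            top_set=[g for g in self.top_set if g in set(keep)],
            bottom_set=[g for g in self.bottom_set if g in set(keep)],
        )

    def to_dict(self) -> dict:
        return {
            "gene_ids": list(self.gene_ids),
            "loadings": {g: float(v) for g, v in self.loadings.items()},
            "gene_means": {g: float(v) for g, v in self.gene_means.items()},
            "variance_explained": float(self.variance_explained),
            "sample_scores": {s: float(v) for s, v in self.sample_scores.items()},
            "reference_condition": self.reference_condition,
            "top_set": list(self.top_set),
            "bottom_set": list(self.bottom_set),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SignatureModel":
        return cls(
            gene_ids=list(d["gene_ids"]),
            loadings=pd.Series(d["loadings"]).loc[list(d["gene_ids"])],
            gene_means=pd.Series(d["gene_means"]).loc[list(d["gene_ids"])],
            variance_explained=float(d["variance_explained"]),
            sample_scores=pd.Series(d["sample_scores"]),
            reference_condition=d["reference_condition"],
            top_set=list(d["top_set"]),
            bottom_set=list(d["bottom_set"]),
        )

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ActivationScoreResult:
    """Per-sample activation scores: raw dot products and max-scaled values."""

    sample_ids: List[str]
    raw_score: pd.Series
    scaled_score: pd.Series
    n_genes_used: int
    genes_missing: List[str]

    def ranking(self) -> pd.DataFrame:
        """Samples ordered by decreasing scaled score (ties by sample id)."""
        out = pd.DataFrame(
            {"sample": self.sample_ids,
             "raw": [self.raw_score[s] for s in self.sample_ids],
             "scaled": [self.scaled_score[s] for s in self.sample_ids]}
        )
        out = out.sort_values(["scaled", "sample"], ascending=[False, True])
        out["rank"] = np.arange(1, len(out) + 1)
        return out.reset_index(drop=True)


@dataclass
class PermutationTestResult:
    """Trend-test result: observed group statistic against a permutation null."""

    observed_statistic: float
    null_mean: float
    null_std: float
    n_permutations: int
    z: float
    p_two_tailed: float
    p_empirical: float
    seed: Optional[int]


@dataclass
class StitchedRegion:
    """A merged peak region with per-condition total tags and (optional) rank."""

    chrom: str
    start: int
    end: int
    constituent_peak_ids: Tuple[str, ...]
    total_tags: Dict[str, float]
    rank: Optional[int] = None
    is_super: bool = False

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class SECallResult:
    """Super-enhancer call: ranked stitched regions plus the tangent threshold."""

    regions: List[StitchedRegion]
    threshold_rank: int
    threshold_score: float
    n_super: int
    parameters: Dict[str, object]

    @property
    def super_regions(self) -> List[StitchedRegion]:
        return [r for r in self.regions if r.is_super]

    def rank_curve(self) -> pd.DataFrame:
        """Ascending rank-score curve (the one the threshold is found on)."""
        scores = sorted(r.total_tags[self.parameters["condition"]] for r in self.regions)
        return pd.DataFrame({"ascending_rank": np.arange(len(scores)), "score": scores})


@dataclass
class SyntheticTruth:
    """Ground truth for a generated expression matrix."""

    gene_class: Dict[str, str]
    signal_strength: Dict[str, float]
    effect_size: Dict[str, float]
    baseline: Dict[str, float]
    noise_cv: float
    seed: int

    def genes_of(self, cls: str) -> List[str]:
        return [g for g, c in self.gene_class.items() if c == cls]


@dataclass
class PlantedEnhancerTruth:
    """Ground truth for a generated peak landscape."""

    planted_gain_peaks: List[str]
    planted_superenhancer_regions: List[Tuple[str, int, int]]
    background_params: Dict[str, float]
    seed: int
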