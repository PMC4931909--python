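"""Readers and writers for the pipeline's external text formats.

Formats handled: tab-separated expression matrices (RPKM), BED5/BED6 interval
tables, headered multi-condition peak tables, gene-annotation tables,
bedGraph-style coverage tracks, and JSON run manifests. All genomic
coordinates are 0-based half-open. Parsing is locale-independent (decimal
point only). Numbers are written back in a canonical form (integers without a
decimal point, floats via ``repr``) so that read -> write round-trips are
byte-identical.
"""

from __future__ import annotations

import json
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import CoverageTrack, ExpressionMatrix, GeneAnnotation, PeakSet

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_interval_table",
    "write_interval_table",
    "read_peak_table",
    "write_peak_table",
    "read_gene_table",
    "write_gene_table",
    "read_bedgraph",
    "write_bedgraph",
    "read_sample_table",
    "write_sample_table",
    "write_manifest",
    "rescale_tags",
]


def _fmt(x) -> str:
    """Canonical numeric formatting: ints bare, floats via repr (round-trip safe)."""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    xf = float(x)
    if xf.is_integer() and abs(xf) < 1e16:
        return str(int(xf))
    return repr(xf)


def _parse_float(token: str, where: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ValueError(f"non-numeric value {token!r} at {where}") from None


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_table(
    path,
    condition_map: Mapping[str, str],
    condition_order: Optional[Sequence[str]] = None,
    replicate_map: Optional[Mapping[str, str]] = None,
) -> ExpressionMatrix:
    """Read a TSV expression matrix (header = sample ids, first column = gene ids).

    Every sample in the file must appear in ``condition_map``. If
    ``condition_order`` is omitted it is taken from the order in which
    conditions first appear across the file's samples.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        samples = header[1:]
        for s in samples:
            if s not in condition_map:
                raise KeyError(f"sample {s!r} absent from condition map")
        gene_ids: List[str] = []
        seen = set()
        rows: List[List[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(samples) + 1:
                raise ValueError(f"{path}: line {lineno} has {len(parts)} fields, "
                                 f"expected {len(samples) + 1}")
            gid = parts[0]
            if gid in seen:
                raise ValueError(f"duplicate gene id {gid!r} (line {lineno})")
            seen.add(gid)
            vals = []
            for col, tok in zip(samples, parts[1:]):
                v = _parse_float(tok, f"row {gid!r}, column {col!r}")
                if v < 0:
                    raise ValueError(
                        f"negative expression value at (row {gid!r}, column {col!r})"
                    )
                vals.append(v)
            gene_ids.append(gid)
            rows.append(vals)
    values = pd.DataFrame(rows, index=gene_ids, columns=samples, dtype=float)
    if condition_order is None:
        condition_order = list(dict.fromkeys(condition_map[s] for s in samples))
    return ExpressionMatrix(
        values=values,
        condition_of_sample={s: condition_map[s] for s in samples},
        condition_order=list(condition_order),
        replicate_of_sample=dict(replicate_map or {}),
    )


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for gid, row in matrix.values.iterrows():
            fh.write(gid + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# BED-style interval tables
# ---------------------------------------------------------------------------

def read_interval_table(path, schema: str = "peaks", condition: str = "tags"):
    """Read a BED5/BED6 file.

    schema="peaks": columns chrom, start, end, name, score(=normalized tags),
    strand(optional, ignored); returns a single-condition :class:`PeakSet`
    whose tag column is named ``condition``.

    schema="genes": BED6 with strand required; returns :class:`GeneAnnotation`
    with the TSS at the 5' end of the interval (start for '+', end-1 for '-').
    """
    if schema not in ("peaks", "genes"):
        raise ValueError(f"unknown schema {schema!r}")
    recs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}: malformed line {lineno} (need >=5 fields)")
            chrom, start_s, end_s, name = parts[0], parts[1], parts[2], parts[3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path}: malformed coordinates on line {lineno}") from None
            if start >= end:
                raise ValueError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            score = _parse_float(parts[4], f"line {lineno}, score column")
            strand = parts[5] if len(parts) > 5 else "+"
            recs.append((chrom, start, end, name, score, strand))
    if schema == "peaks":
        df = pd.DataFrame(recs, columns=["chrom", "start", "end", "peak_id",
                                         condition, "strand"])
        return PeakSet(df.drop(columns=["strand"]), [condition])
    df = pd.DataFrame(recs, columns=["chrom", "start", "end", "gene_id",
                                     "score", "strand"])
    if len(df) and not df["strand"].isin(["+", "-"]).all():
        raise ValueError("gene BED requires explicit strand '+' or '-'")
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return GeneAnnotation(df[["gene_id", "chrom", "start", "end", "strand", "tss"]])


def write_interval_table(obj, path, condition: Optional[str] = None) -> None:
    """Write a PeakSet (BED5) or GeneAnnotation (BED6, score 0) back to disk."""
    with open(path, "w") as fh:
        if isinstance(obj, PeakSet):
            cond = condition or obj.conditions[0]
            for _, r in obj.df.iterrows():
                fh.write("\t".join([r["chrom"], str(int(r["start"])), str(int(r["end"])),
                                    str(r["peak_id"]), _fmt(r[cond])]) + "\n")
        elif isinstance(obj, GeneAnnotation):
            for _, r in obj.df.iterrows():
                fh.write("\t".join([r["chrom"], str(int(r["start"])), str(int(r["end"])),
                                    str(r["gene_id"]), "0", r["strand"]]) + "\n")
        else:
            raise TypeError(f"cannot write {type(obj).__name__} as interval table")


# ---------------------------------------------------------------------------
# headered multi-condition peak tables and gene tables
# ---------------------------------------------------------------------------

def read_peak_table(path) -> PeakSet:
    """Read a headered TSV: chrom, start, end, peak_id, then one tag column
    per condition (column names are the condition labels)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "peak_id": str})
    required = ["chrom", "start", "end", "peak_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    conditions = [c for c in df.columns if c not in required]
    df[conditions] = df[conditions].astype(float)
    return PeakSet(df, conditions)


def write_peak_table(peaks: PeakSet, path) -> None:
    cols = ["chrom", "start", "end", "peak_id"] + peaks.conditions
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for _, r in peaks.df.iterrows():
            out = [r["chrom"], str(int(r["start"])), str(int(r["end"])), str(r["peak_id"])]
            out += [_fmt(r[c]) for c in peaks.conditions]
            fh.write("\t".join(out) + "\n")


def read_gene_table(path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    return GeneAnnotation(df[list(GeneAnnotation.REQUIRED)])


def write_gene_table(genes: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GeneAnnotation.REQUIRED) + "\n")
        for _, r in genes.df.iterrows():
            fh.write("\t".join([str(r["gene_id"]), r["chrom"], str(int(r["start"])),
                                str(int(r["end"])), r["strand"], str(int(r["tss"]))]) + "\n")


# ---------------------------------------------------------------------------
# coverage tracks (bedGraph-like)
# ---------------------------------------------------------------------------

def read_bedgraph(path, chrom_sizes: Optional[Mapping[str, int]] = None) -> CoverageTrack:
    """Read chrom/start/end/value rows into dense per-base coverage arrays.

    Without ``chrom_sizes`` each chromosome's array extends to the largest
    end coordinate seen.
    """
    spans: Dict[str, List] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: malformed line {lineno}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}: line {lineno}: start >= end")
            value = _parse_float(parts[3], f"line {lineno}, value column")
            spans.setdefault(chrom, []).append((start, end, value))
    cov: Dict[str, np.ndarray] = {}
    for chrom, rows in spans.items():
        size = chrom_sizes[chrom] if chrom_sizes else max(e for _, e, _ in rows)
        arr = np.zeros(size, dtype=float)
        for start, end, value in rows:
            arr[start:min(end, size)] += value
        cov[chrom] = arr
    return CoverageTrack(cov)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a coverage track as run-length-encoded chrom/start/end/value rows."""
    with open(path, "w") as fh:
        for chrom in sorted(track.coverage):
            arr = track.coverage[chrom]
            if len(arr) == 0:
                continue
            boundaries = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [len(arr)]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{_fmt(v)}\n")


# ---------------------------------------------------------------------------
# sample tables, manifests, helpers
# ---------------------------------------------------------------------------

def read_sample_table(path):
    """Read a TSV with columns sample, condition[, replicate].

    Returns (condition_map, condition_order, replicate_map); condition order
    follows first appearance.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns or "condition" not in df.columns:
        raise ValueError(f"{path}: need 'sample' and 'condition' columns")
    condition_map = dict(zip(df["sample"], df["condition"]))
    condition_order = list(dict.fromkeys(df["condition"]))
    replicate_map = (
        dict(zip(df["sample"], df["replicate"])) if "replicate" in df.columns else {}
    )
    return condition_map, condition_order, replicate_map


def write_sample_table(matrix: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tcondition\treplicate\n")
        for s in matrix.sample_ids:
            rep = matrix.replicate_of_sample.get(s, "")
            fh.write(f"{s}\t{matrix.condition_of_sample[s]}\t{rep}\n")


def write_manifest(path, command: str, parameters: Mapping, seed=None) -> None:
    """JSON run manifest: command, parameters, seed, package/library versions.

    Deliberately excludes timestamps so reruns are byte-identical.
    """
    from . import __version__

    doc = {
        "command": command,
        "parameters": {k: parameters[k] for k in sorted(parameters)},
        "seed": seed,
        "versions": {
            "tcellsig": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")


def rescale_tags(peaks: PeakSet, library_sizes: Mapping[str, float],
                 per: float = 1e7) -> PeakSet:
    """Rescale raw per-condition tag counts to tags per ``per`` (default 1e7) reads.

    The pipeline otherwise treats incoming tag counts as already
    depth-normalized; this helper is the one explicit place raw counts can be
    brought onto that scale.
    """
    df = peaks.df.copy()
    for cond in peaks.conditions:
        if cond not in library_sizes:
            raise KeyError(f"library size missing for condition {cond!r}")
        df[cond] = df[cond] * (per / float(library_sizes[cond]))
    return PeakSet(df, list(peaks.conditions))
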