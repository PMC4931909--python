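"""Shared fixtures and independent brute-force oracles.

The oracle functions here are deliberately written as plain O(n*m) loops over
every pair — slow, obvious, and independent of the interval engines they
check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tcellsig.containers import ExpressionMatrix, GeneAnnotation, PeakSet


def make_matrix(values, sample_conditions, condition_order=None,
                replicates=None, gene_ids=None) -> ExpressionMatrix:
    """Build an ExpressionMatrix from a 2-D array and sample->condition pairs."""
    values = np.asarray(values, dtype=float)
    sample_conditions = list(sample_conditions)
    samples = [s for s, _ in sample_conditions]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(values.shape[0])]
    cond_map = dict(sample_conditions)
    order = condition_order or list(dict.fromkeys(cond_map.values()))
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=samples),
        cond_map, order, dict(replicates or {}),
    )


def make_peaks(rows, conditions) -> PeakSet:
    """rows: (chrom, start, end, peak_id, *tags)."""
    cols = ["chrom", "start", "end", "peak_id"] + list(conditions)
    return PeakSet(pd.DataFrame(rows, columns=cols), list(conditions))


def make_genes(rows) -> GeneAnnotation:
    """rows: (gene_id, chrom, start, end, strand, tss)."""
    return GeneAnnotation(pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "tss"]))


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def intervals_overlap(a, b):
    """(chrom, start, end) half-open overlap by >= 1 bp."""
    return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]


def brute_overlap_count(a_rows, b_rows) -> int:
    """Number of intervals in a overlapping at least one interval in b."""
    return sum(1 for a in a_rows if any(intervals_overlap(a, b) for b in b_rows))


def brute_stitch(rows, distance):
    """Transitive merge of (chrom, start, end) with gap <= distance.

    Returns sorted (chrom, start, end) tuples, merged by repeated pairwise
    passes until a fixed point.
    """
    regions = [list(r) for r in rows]
    changed = True
    while changed:
        changed = False
        out = []
        for r in regions:
            merged = False
            for o in out:
                if o[0] == r[0] and r[1] - o[2] <= distance and o[1] - r[2] <= distance:
                    o[1], o[2] = min(o[1], r[1]), max(o[2], r[2])
                    merged = changed = True
                    break
            if not merged:
                out.append(list(r))
        regions = out
    return sorted(tuple(r) for r in regions)


def brute_nearest_tss(peak_rows, gene_rows):
    """Nearest-TSS assignment from peak midpoints; ties to the smaller TSS."""
    out = []
    for chrom, start, end in peak_rows:
        mid = (start + end) // 2
        best = min(
            (g for g in gene_rows if g[1] == chrom),
            key=lambda g: (abs(g[2] - mid), g[2], g[0]),  # (gene_id, chrom, tss)
        )
        out.append(best[0])
    return out


def random_intervals(rng, n, chroms=("chr1", "chr2", "chr3"), span=1_000_000):
    rows = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span))
        width = int(rng.integers(1, 5000))
        rows.append((chrom, start, start + width))
    return rows


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


# ---------------------------------------------------------------------------
# CLI workspace shared by the determinism checks
# ---------------------------------------------------------------------------

def run_cli(args):
    from click.testing import CliRunner
    from tcellsig.cli import main
    result = CliRunner().invoke(main, args, catch_exceptions=False)
    assert result.exit_code == 0, result.output
    return result


def build_cli_workspace(ws):
    """Populate a directory with simulated inputs for every CLI subcommand."""
    sim = ws / "sim"
    run_cli(["--out-dir", str(sim), "--seed", "7", "simulate", "expression",
             "--n-genes", "300"])
    run_cli(["--out-dir", str(sim), "--seed", "7", "simulate", "peaks",
             "--n-background", "200", "--n-gain", "20",
             "--n-superenhancers", "5"])
    run_cli(["--out-dir", str(sim), "signature", "derive",
             "--replicates", str(sim / "expr_rep1.tsv"),
             "--replicates", str(sim / "expr_rep2.tsv"),
             "--combined", str(sim / "expr_combined.tsv"),
             "--samples", str(sim / "samples.tsv")])
    genes = [line.split("\t")[0] for line in
             (sim / "expr_combined.tsv").read_text().splitlines()[1:6]]
    (ws / "group.txt").write_text("\n".join(genes) + "\n")
    (ws / "genes.tsv").write_text(
        "gene_id\tchrom\tstart\tend\tstrand\ttss\n"
        "gA\tchr1\t100000\t150000\t+\t100000\n"
        "gB\tchr1\t900000\t950000\t-\t950000\n"
        "gC\tchr2\t500000\t550000\t+\t500000\n"
        "gD\tchr3\t700000\t760000\t+\t700000\n")
    (ws / "sig_genes.txt").write_text("gA\ngB\n")
    peaks = (ws / "sim" / "peaks.tsv").read_text().splitlines()
    subset = [line.split("\t")[3] for line in peaks[1:40]]
    (ws / "subset_ids.txt").write_text("\n".join(subset) + "\n")
    (ws / "sites.bed").write_text(
        "chr1\t99500\t99700\ts1\t10\nchr1\t400000\t400100\ts2\t5\n")
    (ws / "cov.bedgraph").write_text(
        "chr1\t0\t2000000\t2\nchr2\t0\t600000\t1\nchr3\t0\t800000\t1\n")
    (ws / "groups.tsv").write_text(
        "sample\tgroup\n" + "\n".join(
            f"{line.split()[0]}\t{line.split()[1]}"
            for line in (sim / "samples.tsv").read_text().splitlines()[1:]) + "\n")
    return ws


CLI_SUBCOMMANDS = [
    ("simulate_expression",
     lambda ws: ["--seed", "11", "simulate", "expression", "--n-genes", "120"]),
    ("simulate_peaks",
     lambda ws: ["--seed", "11", "simulate", "peaks", "--n-background", "80",
                 "--n-superenhancers", "3"]),
    ("signature_derive",
     lambda ws: ["signature", "derive",
                 "--replicates", str(ws / "sim/expr_rep1.tsv"),
                 "--replicates", str(ws / "sim/expr_rep2.tsv"),
                 "--combined", str(ws / "sim/expr_combined.tsv"),
                 "--samples", str(ws / "sim/samples.tsv")]),
    ("signature_score",
     lambda ws: ["signature", "score", "--model", str(ws / "sim/model.json"),
                 "--matrix", str(ws / "sim/expr_combined.tsv"),
                 "--samples", str(ws / "sim/samples.tsv"),
                 "--groups", str(ws / "groups.tsv")]),
    ("trend_test",
     lambda ws: ["--seed", "3", "trend", "test",
                 "--matrix", str(ws / "sim/expr_combined.tsv"),
                 "--samples", str(ws / "sim/samples.tsv"),
                 "--group", str(ws / "group.txt"),
                 "--a", "no_peptide", "--b", "PCC_10uM", "--n-perm", "400"]),
    ("enhancer_overlap",
     lambda ws: ["enhancer", "overlap", "--peaks", str(ws / "sim/peaks.tsv")]),
    ("enhancer_foldchange",
     lambda ws: ["enhancer", "foldchange", "--peaks", str(ws / "sim/peaks.tsv"),
                 "--a", "unstimulated", "--b", "stimulated"]),
    ("enhancer_aggregate",
     lambda ws: ["enhancer", "aggregate", "--sites", str(ws / "sites.bed"),
                 "--track", f"basal={ws / 'cov.bedgraph'}"]),
    ("enhancer_spreading",
     lambda ws: ["enhancer", "spreading", "--track", str(ws / "cov.bedgraph"),
                 "--genes", str(ws / "genes.tsv")]),
    ("enhancer_proximity",
     lambda ws: ["enhancer", "proximity", "--peaks", str(ws / "sim/peaks.tsv"),
                 "--subset-ids", str(ws / "subset_ids.txt"),
                 "--genes", str(ws / "genes.tsv"),
                 "--signature-genes", str(ws / "sig_genes.txt")]),
    ("se_call",
     lambda ws: ["se", "call", "--peaks", str(ws / "sim/peaks.tsv"),
                 "--condition", "stimulated"]),
]
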