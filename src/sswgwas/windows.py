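"""Sliding-window variance decomposition and reporting.

The genetic value of a window of ``w`` adjacent SNPs is the sum of its
members' centred genotypes times their back-solved effects; the window's
contribution is the sample variance of that value across genotyped
individuals, expressed as a percentage of the total additive genetic
variance (VE%).  Windows slide one SNP at a time within a chromosome by
default.  Reporting operations: the >= 0.5% informative-window filter,
region aggregation, gene annotation from a coordinate table, and
Manhattan-ready track export.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import GenotypeSet
from .genomic import centered_z

__all__ = [
    "window_variance",
    "informative_windows",
    "collapse_overlapping",
    "aggregate_region",
    "annotate_windows",
    "manhattan_export",
]

logger = logging.getLogger(__name__)

WINDOW_COLUMNS = ["window_id", "chromosome", "start_bp", "end_bp", "ve_percent"]


def window_variance(
    g: GenotypeSet,
    u_hat: np.ndarray,
    sigma2_a: float,
    p: np.ndarray,
    window_size: int = 5,
    step: int = 1,
) -> pd.DataFrame:
    """VE% of every sliding window of ``window_size`` consecutive SNPs.

    ``window_id`` is the genome-order index of the window's first SNP;
    start/end bp span the first and last member.  A chromosome with
    fewer SNPs than the window size contributes no windows.
    """
    u_hat = np.asarray(u_hat, dtype=float)
    if u_hat.shape[0] != g.n_markers:
        raise ValueError("effect vector length does not match marker count")
    if sigma2_a <= 0:
        raise ValueError("sigma2_a must be positive")
    Z = centered_z(g, p)
    chroms = g.markers["chromosome"].to_numpy()
    pos = g.markers["position_bp"].to_numpy()

    rows = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        if idx.size < window_size:
            logger.info("chromosome %s has %d SNPs < window size %d; skipped",
                        chrom, idx.size, window_size)
            continue
        for s in range(0, idx.size - window_size + 1, step):
            members = idx[s:s + window_size]
            a_i = Z[:, members] @ u_hat[members]
            ve = float(np.var(a_i, ddof=1)) / sigma2_a * 100.0
            rows.append((int(members[0]), chrom, int(pos[members[0]]),
                         int(pos[members[-1]]), ve))
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def informative_windows(wt: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Windows explaining no less than ``threshold`` percent of the
    genetic variance (inclusive boundary)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return wt[wt["ve_percent"] >= threshold].reset_index(drop=True)


def collapse_overlapping(wt: pd.DataFrame) -> pd.DataFrame:
    """Collapse each run of bp-overlapping windows on a chromosome to its
    maximal-VE representative (non-overlap report mode)."""
    out = []
    for _, sub in wt.groupby("chromosome", sort=False):
        sub = sub.sort_values("start_bp")
        run: list[pd.Series] = []
        run_end = -1
        for _, row in sub.iterrows():
            if run and row["start_bp"] > run_end:
                out.append(max(run, key=lambda r: r["ve_percent"]))
                run = []
            run.append(row)
            run_end = max(run_end, int(row["end_bp"]))
        if run:
            out.append(max(run, key=lambda r: r["ve_percent"]))
    return pd.DataFrame(out).reset_index(drop=True)[list(wt.columns)]


def aggregate_region(
    wt: pd.DataFrame, chromosome, bp_lo: int, bp_hi: int
) -> tuple[int, float]:
    """Count and summed VE% of windows starting within [bp_lo, bp_hi] on
    the given chromosome (selection by window start coordinate)."""
    if bp_lo > bp_hi:
        raise ValueError("bp_lo must be <= bp_hi")
    sel = wt[
        (wt["chromosome"].astype(str) == str(chromosome))
        & (wt["start_bp"] >= bp_lo)
        & (wt["start_bp"] <= bp_hi)
    ]
    return len(sel), float(sel["ve_percent"].sum())


def annotate_windows(
    wt: pd.DataFrame, genes: pd.DataFrame, max_distance_bp: int = 1_000_000
) -> pd.DataFrame:
    """Assign genes to windows from a 1-based inclusive coordinate table.

    Genes overlapping a window are reported with ``distance_bp`` 0 and
    the overlap length; a window with no overlap gets its nearest gene
    within ``max_distance_bp``, with a signed distance (negative when the
    gene lies upstream of the window start).
    """
    rows = []
    for _, win in wt.iterrows():
        sub = genes[genes["chromosome"].astype(str) == str(win["chromosome"])]
        if sub.empty:
            continue
        ov_lo = np.maximum(sub["start_bp"].to_numpy(), win["start_bp"])
        ov_hi = np.minimum(sub["end_bp"].to_numpy(), win["end_bp"])
        overlap = np.maximum(ov_hi - ov_lo + 1, 0)
        hit = overlap > 0
        if hit.any():
            for gid, ob in zip(sub["gene_id"].to_numpy()[hit], overlap[hit]):
                rows.append((int(win["window_id"]), win["chromosome"], gid, int(ob), 0))
        else:
            after = sub["start_bp"].to_numpy() - int(win["end_bp"])  # gene downstream
            before = sub["end_bp"].to_numpy() - int(win["start_bp"])  # gene upstream (neg)
            dist = np.where(after > 0, after, before)
            j = int(np.argmin(np.abs(dist)))
            if abs(int(dist[j])) <= max_distance_bp:
                rows.append((int(win["window_id"]), win["chromosome"],
                             sub["gene_id"].iloc[j], 0, int(dist[j])))
    return pd.DataFrame(
        rows, columns=["window_id", "chromosome", "gene_id", "overlap_bp", "distance_bp"]
    )


def _cumulative_offsets(chroms: pd.Series, pos: pd.Series) -> np.ndarray:
    """Genome-cumulative coordinates, chromosomes laid out in order of
    first appearance."""
    offsets = {}
    running = 0
    for chrom in pd.unique(chroms):
        offsets[chrom] = running
        running += int(pos[chroms == chrom].max()) + 1
    return pos.to_numpy() + np.array([offsets[c] for c in chroms])


def manhattan_export(
    snp_table: pd.DataFrame,
    window_table: pd.DataFrame,
    out_dir,
    threshold_minus_log10_p: float | None = None,
    ve_threshold: float | None = None,
) -> tuple[Path, Path]:
    """Write per-SNP (-log10 P) and per-window (VE%) Manhattan tracks.

    Both tracks carry a genome-cumulative coordinate; rerunning on the
    same input produces byte-identical files.  Returns the two paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    snp = snp_table.copy()
    snp["cumulative_bp"] = _cumulative_offsets(snp["chromosome"], snp["position_bp"])
    if threshold_minus_log10_p is not None:
        snp["threshold_minus_log10_p"] = threshold_minus_log10_p
    snp_path = out_dir / "snp_track.tsv"
    snp.to_csv(snp_path, sep="\t", index=False, float_format="%.10g")

    win = window_table.copy()
    win["cumulative_bp"] = _cumulative_offsets(win["chromosome"], win["start_bp"])
    if ve_threshold is not None:
        win["ve_threshold"] = ve_threshold
    win_path = out_dir / "window_track.tsv"
    win.to_csv(win_path, sep="\t", index=False, float_format="%.10g")
    return snp_path, win_path
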