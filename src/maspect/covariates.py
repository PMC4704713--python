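"""Binned relative-rate analyses: local G/C content, replication time, expression.

Each covariate partitions the analyzed genome into bins (1% G/C windows,
1-minute replication-time intervals, 0.25 log10-FPKM expression intervals).
A bin's relative rate is its per-bp SNM rate over the genome-wide per-bp
rate.  Bins are merged, in covariate order, into a small number of groups
holding roughly equal SNM counts; group summaries are bp-weighted means with
a bp-weighted SE, so the overall bp-weighted mean across groups is exactly 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GCWindowTable, ReferenceGenome

__all__ = [
    "BinnedRateTable",
    "bin_by_gc",
    "bin_by_replication_time",
    "bin_by_expression",
    "group_difference_z",
]


@dataclass
class BinnedRateTable:
    covariate: str
    bins: pd.DataFrame      # bin, bp, snms, relative_rate, group
    groups: pd.DataFrame    # group, bins, bp, snms, weighted_rate, weighted_se
    total_snms: int
    total_bp: float
    unassigned_snms: int = 0
    unassigned_bp: float = 0.0

    @property
    def weighted_mean(self) -> float:
        g = self.groups
        return float((g["weighted_rate"] * g["bp"]).sum() / g["bp"].sum())


def _greedy_groups(snms_per_bin: np.ndarray, n_groups: int) -> np.ndarray:
    """Assign bins (already in covariate order) to groups of roughly equal
    SNM content: accumulate until a group reaches total/n_groups, then start
    the next; ties stay in the earlier group; the last group absorbs the rest."""
    total = snms_per_bin.sum()
    target = total / n_groups
    assign = np.zeros(len(snms_per_bin), dtype=int)
    group, acc = 0, 0.0
    for i, s in enumerate(snms_per_bin):
        assign[i] = group
        acc += s
        if acc >= target and group < n_groups - 1:
            group += 1
            acc = 0.0
    return assign


def _build_table(covariate, bin_labels, bp, snms, n_groups,
                 unassigned_snms=0, unassigned_bp=0.0) -> BinnedRateTable:
    bp = np.asarray(bp, dtype=float)
    snms = np.asarray(snms, dtype=float)
    keep = bp > 0
    bin_labels = [b for b, k in zip(bin_labels, keep) if k]
    bp, snms = bp[keep], snms[keep]
    total_bp, total_snms = bp.sum(), snms.sum()
    overall = total_snms / total_bp if total_bp else float("nan")
    rel = (snms / bp) / overall if overall > 0 else np.full_like(bp, np.nan)
    assign = _greedy_groups(snms, n_groups)
    bins = pd.DataFrame(
        {"bin": bin_labels, "bp": bp, "snms": snms.astype(int),
         "relative_rate": rel, "group": assign}
    )
    grows = []
    for g in range(assign.max() + 1):
        sel = assign == g
        w, r = bp[sel], rel[sel]
        wsum = w.sum()
        wmean = (w * r).sum() / wsum
        if sel.sum() > 1:
            wvar = (w * (r - wmean) ** 2).sum() / wsum
            n_eff = wsum**2 / (w**2).sum()
            wse = math.sqrt(wvar / n_eff)
        else:
            wse = float("nan")
        grows.append(
            {"group": g, "bins": list(np.array(bin_labels, dtype=object)[sel]),
             "bp": wsum, "snms": int(snms[sel].sum()),
             "weighted_rate": wmean, "weighted_se": wse}
        )
    return BinnedRateTable(
        covariate=covariate,
        bins=bins,
        groups=pd.DataFrame(grows),
        total_snms=int(total_snms),
        total_bp=float(total_bp),
        unassigned_snms=unassigned_snms,
        unassigned_bp=unassigned_bp,
    )


def group_difference_z(table: BinnedRateTable, a: int = 0, b: int = -1):
    """Two-sample z on the weighted means of two groups (default first vs last)."""
    g = table.groups
    ra, sa = g.iloc[a][["weighted_rate", "weighted_se"]]
    rb, sb = g.iloc[b][["weighted_rate", "weighted_se"]]
    z = (ra - rb) / math.sqrt(sa**2 + sb**2)
    return float(z), float(2 * stats.norm.sf(abs(z)))


# ----------------------------------------------------------------------------
# G/C content
# ----------------------------------------------------------------------------


def _snm_positions(events):
    for e in events:
        if e.event_class == "SNM":
            v = e.member_variants[0]
            yield v.chromosome, v.position, v.ref_allele


def bin_by_gc(windows: GCWindowTable, events, n_groups: int = 2,
              base_subset: str | None = None) -> BinnedRateTable:
    """SNM rate by 1%-binned window G/C content.

    ``base_subset`` of 'AT' or 'GC' restricts both numerator (SNMs whose
    reference base is in the subset) and denominator (per-window A/T or G/C
    base tallies).  SNMs in flagged short windows are excluded and reported
    in the remainder fields.
    """
    win = windows.windows
    full = win[~win["short"]].reset_index(drop=True)
    bp_col = {"AT": "at_bp", "GC": "gc_bp", None: "included_bp"}[base_subset]
    by_bin = full.groupby("gc_bin")[bp_col].sum()
    snm_counts = {b: 0 for b in by_bin.index}
    unassigned = 0
    lookup = {
        (r.chrom, (r.start - 1) // windows.window_bp): (r.gc_bin, r.short)
        for r in win.itertuples()
    }
    for chrom, pos, ref in _snm_positions(events):
        if base_subset == "AT" and ref not in "AT":
            continue
        if base_subset == "GC" and ref not in "GC":
            continue
        gc_bin, short = lookup[(chrom, (pos - 1) // windows.window_bp)]
        if short or gc_bin not in snm_counts:
            unassigned += 1
            continue
        snm_counts[gc_bin] += 1
    labels = sorted(by_bin.index)
    name = "gc_content" + (f"_{base_subset.lower()}" if base_subset else "")
    return _build_table(
        name, labels, [by_bin[b] for b in labels],
        [snm_counts[b] for b in labels], n_groups,
        unassigned_snms=unassigned,
        unassigned_bp=float(win.loc[win["short"], bp_col].sum()),
    )


# ----------------------------------------------------------------------------
# replication time
# ----------------------------------------------------------------------------


def replication_time_map(genome: ReferenceGenome, ori_table: pd.DataFrame):
    """Per-position firing minute of the nearest origin (same chromosome).

    Equidistant ties go to the earlier-firing origin.  Chromosomes with no
    origin are left unassigned (minute -1).
    """
    out = {}
    for chrom in genome.names:
        n = len(genome.seqs[chrom])
        minutes = np.full(n, -1, dtype=np.int16)
        oris = ori_table[ori_table["chrom"] == chrom].sort_values("position")
        if len(oris):
            pos = oris["position"].to_numpy()
            mins = oris["minute"].to_numpy()
            coords = np.arange(1, n + 1)
            right = np.searchsorted(pos, coords)  # index of first ori >= coord
            left = np.clip(right - 1, 0, len(pos) - 1)
            right = np.clip(right, 0, len(pos) - 1)
            dl = np.abs(coords - pos[left])
            dr = np.abs(coords - pos[right])
            pick_left = (dl < dr) | ((dl == dr) & (mins[left] <= mins[right]))
            minutes[:] = np.where(pick_left, mins[left], mins[right])
        out[chrom] = minutes
    return out


def bin_by_replication_time(
    genome: ReferenceGenome, events, ori_table: pd.DataFrame, n_groups: int = 3
) -> BinnedRateTable:
    """SNM rate by 1-minute replication-time bins (nearest-origin assignment)."""
    if ori_table.empty:
        raise ValueError("ori table is empty")
    time_map = replication_time_map(genome, ori_table)
    bp_per_min: dict[int, float] = {}
    unassigned_bp = 0.0
    for chrom in genome.names:
        minutes = time_map[chrom][genome.mask[chrom]]
        counts = np.bincount(minutes[minutes >= 0])
        unassigned_bp += float((minutes < 0).sum())
        for m in np.nonzero(counts)[0]:
            bp_per_min[m] = bp_per_min.get(m, 0.0) + float(counts[m])
    snm_counts = {m: 0 for m in bp_per_min}
    unassigned_snms = 0
    for chrom, pos, _ in _snm_positions(events):
        m = int(time_map[chrom][pos - 1])
        if m < 0:
            unassigned_snms += 1
        else:
            snm_counts[m] += 1
    labels = sorted(bp_per_min)
    return _build_table(
        "replication_time", labels, [bp_per_min[m] for m in labels],
        [snm_counts[m] for m in labels], n_groups,
        unassigned_snms=unassigned_snms, unassigned_bp=unassigned_bp,
    )


# ----------------------------------------------------------------------------
# expression
# ----------------------------------------------------------------------------

EXPRESSION_BIN_WIDTH = 0.25
EXPRESSION_MAX = 3.5
N_EXPRESSION_BINS = 15  # zero bin + 14 quarter-log intervals


def expression_bin_of(value: float) -> int:
    """Bin 0 for zero expression; otherwise (0,0.25]->1 ... (3.25,3.5]->14,
    clamped into the top bin above 3.5."""
    if value < 0:
        raise ValueError("negative FPKM")
    if value == 0:
        return 0
    return min(int(math.ceil(value / EXPRESSION_BIN_WIDTH)), N_EXPRESSION_BINS - 1)


def bin_by_expression(
    genome: ReferenceGenome, events, expression_table: pd.DataFrame,
    n_groups: int = 2,
) -> BinnedRateTable:
    """SNM rate by transcript-abundance bins.

    ``expression_table`` needs columns chrom, start, end and either a
    ``log10_fpkm`` column or replicate columns ``log10_fpkm_*`` whose
    per-transcript median is used.  Positions outside any transcript carry
    expression 0 (bin 0).
    """
    rep_cols = [c for c in expression_table.columns if c.startswith("log10_fpkm")]
    if not rep_cols:
        raise ValueError("expression table lacks log10_fpkm columns")
    values = expression_table[rep_cols].median(axis=1)
    if (values < 0).any():
        raise ValueError("negative FPKM in expression table")
    bin_map = {c: np.zeros(len(genome.seqs[c]), dtype=np.int8) for c in genome.names}
    for (_, row), val in zip(expression_table.iterrows(), values):
        b = expression_bin_of(float(val))
        bin_map[row["chrom"]][int(row["start"]) - 1 : int(row["end"])] = b
    bp_per_bin = np.zeros(N_EXPRESSION_BINS)
    for chrom in genome.names:
        bins = bin_map[chrom][genome.mask[chrom]]
        bp_per_bin += np.bincount(bins, minlength=N_EXPRESSION_BINS)
    snms = np.zeros(N_EXPRESSION_BINS)
    for chrom, pos, _ in _snm_positions(events):
        snms[bin_map[chrom][pos - 1]] += 1
    labels = list(range(N_EXPRESSION_BINS))
    return _build_table("expression", labels, bp_per_bin, snms, n_groups)
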