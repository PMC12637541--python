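"""Molecule quality control and transcript-to-cell assignment.

Decoded blank barcodes estimate the false-discovery process: no blank is
ever planted (or probed), so blank detections calibrate filtering.  The
misidentification rate is normalized per barcode,

    MIR = (N_blank / B_blank) / (N_total / B_total),

where ``N`` counts decoded molecules and ``B`` counts codebook entries —
the raw blank fraction would depend on panel composition.  Filtering
removes 3D-histogram bins (pixel count x mean brightness x min barcode
distance) in ascending gene-to-blank ratio order until the MIR reaches
the target (5% by default).

Per-molecule quality scores combine three metrics by Fisher's method
against their empirical distributions; a low score is good, and a
threshold separating the gene-score and blank-score populations is
chosen at the valley of a kernel-density estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .codebook import Codebook

__all__ = [
    "fisher_scores",
    "choose_score_threshold",
    "adaptive_bin_filter",
    "misidentification_rate",
    "MisidentificationReport",
    "assign_to_cells",
    "cell_by_gene_matrix",
]

TARGET_MISID = 0.05

# (column, direction): +1 means high values are good, -1 means low values are
FISHER_METRICS = [
    ("mean_brightness", +1),
    ("min_distance", -1),
    ("spread", -1),
]


def _empirical_tail_p(values: np.ndarray, direction: int) -> np.ndarray:
    """P(metric at least as bad as this molecule's) over the table.

    For a good-is-high metric (``direction=+1``) this is the fraction
    with value <= x, so the best molecule gets p = 1 and only the worst
    approaches 0; symmetric for good-is-low.  Floored at 1/(n+1) so a
    log never diverges.
    """
    n = len(values)
    sorted_vals = np.sort(values)
    if direction > 0:
        counts = np.searchsorted(sorted_vals, values, side="right")  # <= x
    else:
        counts = n - np.searchsorted(sorted_vals, values, side="left")  # >= x
    p = counts / n
    return np.maximum(p, 1.0 / (n + 1))


def fisher_scores(molecules: pd.DataFrame) -> pd.DataFrame:
    """Fisher-combined quality score per molecule (low = good).

    For each of the three metrics (mean brightness — higher is better;
    minimum barcode distance and spatial spread — lower is better) the
    empirical probability p_i of a molecule doing at least as badly is
    computed over all decoded molecules, and the combined score is
    ``S = -2 * sum_i ln(p_i)``.  The best molecule scores 0 (p = 1 on
    every metric) and low-quality molecules score high; under
    independent uniform metrics S follows chi-squared with 6 degrees of
    freedom.
    """
    if len(molecules) < 2:
        raise ValueError("need at least 2 molecules to form score distributions")
    out = molecules.copy()
    total = np.zeros(len(out))
    for col, direction in FISHER_METRICS:
        values = out[col].to_numpy(dtype=float)
        if np.allclose(values, values[0]):
            warnings.warn(f"metric {col!r} is constant; contributes uniformly")
            p = np.full(len(values), 0.5)
        else:
            p = _empirical_tail_p(values, direction)
        total += -2.0 * np.log(p)
    out["score"] = total
    return out


def choose_score_threshold(
    gene_scores: np.ndarray,
    blank_scores: np.ndarray,
    *,
    fallback_blank_quantile: float = 0.25,
) -> float:
    """Score cutoff separating the gene and blank score populations.

    The pooled score distribution is smoothed with a Gaussian KDE
    (Silverman bandwidth) and the threshold is placed at the density
    minimum between the gene mode and the blank mode.  If the pooled
    density has no interior valley (unimodal or degenerate), the
    ``fallback_blank_quantile`` of the blank scores is used and a
    warning is emitted.  Molecules with score above the threshold (the
    blank side — low scores are good) should be removed.
    """
    gene_scores = np.asarray(gene_scores, dtype=float)
    blank_scores = np.asarray(blank_scores, dtype=float)
    if len(gene_scores) == 0 or len(blank_scores) == 0:
        raise ValueError("gene and blank score sets must both be nonempty")
    pooled = np.concatenate([gene_scores, blank_scores])
    fallback = float(np.quantile(blank_scores, fallback_blank_quantile))
    if np.allclose(pooled, pooled[0]):
        warnings.warn("degenerate score distribution; falling back to blank quantile")
        return fallback
    kde = gaussian_kde(pooled, bw_method="silverman")
    grid = np.linspace(pooled.min(), pooled.max(), 512)
    dens = kde(grid)
    gene_mode = grid[np.argmin(np.abs(grid - np.median(gene_scores)))]
    blank_mode = grid[np.argmin(np.abs(grid - np.median(blank_scores)))]
    lo, hi = sorted((gene_mode, blank_mode))
    inside = (grid >= lo) & (grid <= hi)
    if inside.sum() < 3:
        warnings.warn("gene and blank modes coincide; falling back to blank quantile")
        return fallback
    seg, seg_dens = grid[inside], dens[inside]
    k = int(np.argmin(seg_dens))
    if k == 0 or k == len(seg) - 1:
        warnings.warn("pooled score density has no interior valley; "
                      "falling back to blank quantile")
        return fallback
    return float(seg[k])


@dataclass
class MisidentificationReport:
    """Audit trail of the adaptive bin filter."""

    initial_rate: float
    final_rate: float
    target: float
    n_blank_barcodes: int
    n_total_barcodes: int
    bins_removed: list[tuple] = field(default_factory=list)
    target_reached: bool = True


def misidentification_rate(
    n_blank: int, n_total: int, b_blank: int, b_total: int
) -> float:
    """Per-barcode-normalized blank rate: (N_blank/B_blank)/(N_total/B_total)."""
    if b_blank == 0:
        raise ValueError("codebook has no blank barcodes")
    if n_total == 0:
        return 0.0
    return (n_blank / b_blank) / (n_total / b_total)


def _quantile_edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-occupancy bin edges, robust to heavily tied data.

    When the data hold no more distinct values than requested bins, each
    distinct value gets its own bin (edges at midpoints); otherwise
    deduplicated quantile edges are used.
    """
    uniq = np.unique(values)
    if len(uniq) == 1:
        return np.array([uniq[0] - 0.5, uniq[0] + 0.5])
    if len(uniq) <= n_bins:
        mids = (uniq[:-1] + uniq[1:]) / 2
        return np.concatenate([[uniq[0] - 0.5], mids, [uniq[-1] + 0.5]])
    edges = np.unique(np.quantile(values, np.linspace(0, 1, n_bins + 1)))
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    return edges


def adaptive_bin_filter(
    molecules: pd.DataFrame,
    codebook: Codebook,
    n_bins_per_axis: int = 10,
    target_misid: float = TARGET_MISID,
) -> tuple[pd.DataFrame, MisidentificationReport]:
    """Blank-driven adaptive filtering to a target misidentification rate.

    A 3D histogram over (pixel count, mean brightness, min barcode
    distance) with equal-occupancy edges is built; bins are removed in
    ascending gene-to-blank ratio order, recomputing the MIR after each
    removal, until the MIR is at or below the target.  If every removable
    bin is exhausted first, the best achievable state is returned with
    ``target_reached=False``.
    """
    b_blank = codebook.n_blanks
    b_total = len(codebook)
    if b_blank == 0:
        raise ValueError("codebook has no blank barcodes")
    mols = molecules.reset_index(drop=True)
    axes = ["n_pixels", "mean_brightness", "min_distance"]
    values = [mols[a].to_numpy(dtype=float) for a in axes]
    edges = [_quantile_edges(v, n_bins_per_axis) for v in values]
    bin_idx = np.stack(
        [np.clip(np.digitize(v, e) - 1, 0, len(e) - 2) for v, e in zip(values, edges)],
        axis=1,
    )
    is_blank = mols["is_blank"].to_numpy(dtype=bool)

    keys = [tuple(r) for r in bin_idx]
    bins: dict[tuple, list[int]] = {}
    for i, k in enumerate(keys):
        bins.setdefault(k, []).append(i)

    def counts(selected: dict[tuple, list[int]]) -> tuple[int, int]:
        idx = [i for members in selected.values() for i in members]
        if not idx:
            return 0, 0
        nb = int(is_blank[idx].sum())
        return nb, len(idx)

    n_blank, n_total = counts(bins)
    initial = misidentification_rate(n_blank, n_total, b_blank, b_total)
    report = MisidentificationReport(
        initial_rate=initial,
        final_rate=initial,
        target=target_misid,
        n_blank_barcodes=b_blank,
        n_total_barcodes=b_total,
    )
    # bins sorted by ascending gene-to-blank ratio (blank-free bins last)
    def ratio(k: tuple) -> float:
        members = bins[k]
        nb = int(is_blank[members].sum())
        ng = len(members) - nb
        return ng / nb if nb else np.inf

    order = sorted(bins, key=lambda k: (ratio(k), k))
    rate = initial
    removed: set[tuple] = set()
    for k in order:
        if rate <= target_misid:
            break
        removed.add(k)
        remaining = {kk: v for kk, v in bins.items() if kk not in removed}
        n_blank, n_total = counts(remaining)
        rate = misidentification_rate(n_blank, n_total, b_blank, b_total)
        report.bins_removed.append(k)
    report.final_rate = rate
    report.target_reached = rate <= target_misid
    keep_mask = np.array([k not in removed for k in keys], dtype=bool)
    return mols[keep_mask].reset_index(drop=True), report


def _round_half_away(values: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (documented rule)."""
    return np.sign(values) * np.floor(np.abs(values) + 0.5)


def assign_to_cells(
    molecules: pd.DataFrame,
    label_mask: np.ndarray,
    drift: tuple[int, int, int] = (0, 0, 0),
) -> pd.DataFrame:
    """Look up each molecule's cell id in a segmentation label mask.

    Coordinates are adjusted by the drift between the segmentation and
    RNA imaging rounds, rounded to the nearest integer (halves away from
    zero), and indexed into the mask; label 0 is background and
    out-of-bounds positions stay unassigned (cell_id 0).
    """
    label_mask = np.asarray(label_mask)
    out = molecules.copy()
    coords = out[["z", "y", "x"]].to_numpy(dtype=float) + np.asarray(drift, dtype=float)
    idx = _round_half_away(coords).astype(int)
    shape = np.asarray(label_mask.shape)
    inside = ((idx >= 0) & (idx < shape)).all(axis=1)
    cell_ids = np.zeros(len(out), dtype=label_mask.dtype)
    if inside.any():
        ii = idx[inside]
        cell_ids[inside] = label_mask[ii[:, 0], ii[:, 1], ii[:, 2]]
    out["cell_id"] = cell_ids
    return out


def cell_by_gene_matrix(molecules: pd.DataFrame) -> pd.DataFrame:
    """Cell-by-gene count matrix from assigned molecules (cell_id > 0)."""
    assigned = molecules[molecules["cell_id"] > 0]
    return (
        assigned.pivot_table(
            index="cell_id", columns="gene", values="x", aggfunc="count", fill_value=0
        )
        .rename_axis(index="cell_id", columns="gene")
        .astype(int)
    )
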