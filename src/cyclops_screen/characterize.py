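"""Candidate-gene characterization and SCNA-burden arithmetic.

Expression uniformity (variance normalized to expression level), the
copy-number -> expression response (percent decrease upon loss and the
per-gene copy-number/expression correlation), fraction-of-genome-lost and
event-size accounting over segment profiles, hypergeometric gene-set
enrichment, and the categorical tests (Fisher mutual exclusivity, binomial
overlap proportions).

All interval arithmetic is 0-based half-open: the length of [a, b) is b-a.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cyclops import STATE_LOSS, STATE_NEUTRAL
from .stats import bh_adjust, binomial_tail, fisher_exact, hypergeom_test


def normalized_expression_variance(expr: pd.DataFrame, strategy: str = "cv2") -> pd.Series:
    """Per-gene expression variance normalized to expression level.

    strategy 'cv2': squared coefficient of variation (variance / mean^2) on
    the linear scale; 'variance_of_log': variance of log expression. Genes
    with zero mean (cv2) or fewer than 3 samples get NA.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    x = expr.to_numpy(dtype=float)
    if strategy == "cv2":
        mean = np.nanmean(x, axis=1)
        var = np.nanvar(x, axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            stat = np.where(mean > 0, var / mean ** 2, np.nan)
    elif strategy == "variance_of_log":
        with np.errstate(invalid="ignore", divide="ignore"):
            stat = np.nanvar(np.log(np.where(x > 0, x, np.nan)), axis=1, ddof=1)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return pd.Series(stat, index=expr.index, name=strategy)


def cn_expression_response(expr: pd.DataFrame, states: pd.DataFrame,
                           cn: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-gene expression response to copy-loss.

    states holds {loss, neutral, gain}/None per gene x sample (same layout
    as expr). Returns percent_decrease = 100*(1 - mean_loss/mean_neutral)
    (NA unless >= 2 loss and >= 2 neutral samples and mean_neutral > 0) and,
    when cn is given, the per-gene Pearson r between continuous copy number
    and expression.
    """
    samples = expr.columns
    st = states.reindex(index=expr.index, columns=samples).to_numpy(dtype=object)
    x = expr.to_numpy(dtype=float)
    loss = (st == STATE_LOSS) & np.isfinite(x)
    neut = (st == STATE_NEUTRAL) & np.isfinite(x)
    nl = loss.sum(axis=1)
    nn = neut.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_loss = np.where(loss, x, 0.0).sum(axis=1) / np.maximum(nl, 1)
        mean_neut = np.where(neut, x, 0.0).sum(axis=1) / np.maximum(nn, 1)
        pct = 100.0 * (1.0 - mean_loss / mean_neut)
    pct = np.where((nl >= 2) & (nn >= 2) & (mean_neut > 0), pct, np.nan)
    out = pd.DataFrame({"percent_decrease": pct,
                        "n_loss": nl, "n_neutral": nn}, index=expr.index)
    if cn is not None:
        c = cn.reindex(index=expr.index, columns=samples).to_numpy(dtype=float)
        ok = np.isfinite(c) & np.isfinite(x)
        c0 = np.where(ok, c, 0.0)
        x0 = np.where(ok, x, 0.0)
        n = ok.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            sx, sy = c0.sum(1), x0.sum(1)
            cov = n * (c0 * x0).sum(1) - sx * sy
            var1 = n * (c0 ** 2).sum(1) - sx ** 2
            var2 = n * (x0 ** 2).sum(1) - sy ** 2
            r = cov / np.sqrt(var1 * var2)
        out["r_cn_expression"] = np.where(n >= 3, r, np.nan)
    return out


# ---------------------------------------------------------------------------
# segment (SCNA burden) arithmetic


def _check_chromosomes(seg: pd.DataFrame, lengths: pd.Series) -> None:
    unknown = set(seg["chromosome"]) - set(lengths.index)
    if unknown:
        raise ValueError(f"unknown chromosomes in segment profile: {sorted(unknown)}")


def fraction_genome_lost(seg: pd.DataFrame, chromosome_lengths: pd.Series,
                         loss_threshold: float = -0.35) -> pd.Series:
    """Per-sample fraction of the genome in segments at or below the loss
    threshold (half-open lengths)."""
    _check_chromosomes(seg, chromosome_lengths)
    genome = float(chromosome_lengths.sum())
    lost = seg[seg["log2"] <= loss_threshold]
    lens = (lost["end"] - lost["start"]).groupby(lost["sample"]).sum()
    return (lens / genome).reindex(seg["sample"].unique(), fill_value=0.0)


def event_size_profile(seg: pd.DataFrame, arm_table: pd.DataFrame,
                       loss_threshold: float = -0.35,
                       bins=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Loss-event sizes relative to the containing chromosome arm.

    Each loss segment's size is its length divided by the length of the arm
    containing its start; a segment spanning the centromere exceeds 1 and a
    whole chromosome scores 2. Returns (sizes, histogram, bin edges).
    """
    arms = arm_table.sort_values(["chromosome", "start"])
    lost = seg[seg["log2"] <= loss_threshold]
    sizes = []
    for _, row in lost.iterrows():
        sub = arms[arms["chromosome"] == row["chromosome"]]
        if sub.empty:
            raise ValueError(f"chromosome {row['chromosome']!r} not in arm table")
        containing = sub[(sub["start"] <= row["start"]) & (row["start"] < sub["end"])]
        arm_len = float(containing.iloc[0]["end"] - containing.iloc[0]["start"])
        sizes.append((row["end"] - row["start"]) / arm_len)
    sizes = np.asarray(sizes, dtype=float)
    if bins is None:
        bins = np.linspace(0.0, 2.0, 21)
    hist, edges = np.histogram(sizes, bins=bins)
    return sizes, hist, edges


def count_genes_lost(seg_one_sample: pd.DataFrame, genes: pd.DataFrame,
                     loss_threshold: float = -0.35,
                     overlap_fraction: float = 0.5) -> int:
    """Genes covered by loss segments over >= overlap_fraction of their length."""
    lost = seg_one_sample[seg_one_sample["log2"] <= loss_threshold]
    count = 0
    for _, g in genes.iterrows():
        sub = lost[lost["chromosome"] == g["chromosome"]]
        ov = np.clip(np.minimum(sub["end"].to_numpy(), g["end"])
                     - np.maximum(sub["start"].to_numpy(), g["start"]), 0, None).sum()
        if ov / (g["end"] - g["start"]) >= overlap_fraction:
            count += 1
    return count


def genes_lost_per_sample(seg: pd.DataFrame, genes: pd.DataFrame,
                          loss_threshold: float = -0.35,
                          overlap_fraction: float = 0.5) -> pd.Series:
    """count_genes_lost applied per sample."""
    return pd.Series({
        sample: count_genes_lost(grp, genes, loss_threshold, overlap_fraction)
        for sample, grp in seg.groupby("sample", sort=False)
    })


# ---------------------------------------------------------------------------
# categorical tests


def set_enrichment(query: set[str], universe: set[str],
                   gene_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of query within each gene set,
    BH-adjusted across sets. Sets are intersected with the universe."""
    if not universe:
        raise ValueError("universe must be non-empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    rows = []
    for name, members in gene_sets.items():
        mem = members & universe
        if not mem:
            continue
        k = len(query & mem)
        rows.append({
            "set_name": name, "overlap": k, "set_size": len(mem),
            "query_size": len(query), "universe_size": len(universe),
            "p": hypergeom_test(k, len(mem), len(query), len(universe)),
        })
    out = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size",
                                      "query_size", "universe_size", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


def mutual_exclusivity(event_a, event_b) -> dict:
    """Two-sided Fisher exact test of co-occurrence of two binary events.

    Returns the 2x2 table (rows: A yes/no, columns: B yes/no), odds ratio
    and p. An all-zero margin gives p = 1.
    """
    a = np.asarray(event_a, dtype=bool)
    b = np.asarray(event_b, dtype=bool)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("events must be equal-length, non-empty binary vectors")
    table = np.array([
        [int((a & b).sum()), int((a & ~b).sum())],
        [int((~a & b).sum()), int((~a & ~b).sum())],
    ])
    odds, p = fisher_exact(table)
    return {"table": table, "odds_ratio": odds, "p": p}


def overlap_proportion_test(k: int, n: int, p0: float) -> float:
    """One-sided exact binomial proportion test: P(X >= k), X~Bin(n, p0)."""
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    return binomial_tail(k, n, p0)
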