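"""Genome-wide copy-number x dependency association screen.

All-pairs Pearson correlation between the copy number of each gene and the
dependency score of each gene, computed on pairwise-complete samples with a
vectorized masked formulation; p-values from the two-sided t reference with
n-2 degrees of freedom; one joint Benjamini-Hochberg family over all
non-missing pairs. Significant associations driven by one large copy-number
event are collapsed into a single independently-significant interaction per
genomic region, with a nominated source gene (self > paralog > most
significant).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

RELATION_CIS = "cis"
RELATION_TRANS = "trans"
DIR_LOSS = "loss_associated"
DIR_GAIN = "gain_associated"


def count_association_space(cn: pd.DataFrame, dep: pd.DataFrame) -> int:
    """Number of candidate (copy-number gene, dependency gene) pairings."""
    if cn.empty or dep.empty:
        raise ValueError("matrices must be non-empty")
    return cn.shape[0] * dep.shape[0]


def cyclops_family_share(cn: pd.DataFrame, dep: pd.DataFrame) -> float:
    """Share (percent) of the association space that is the cis same-gene
    (CYCLOPS) hypothesis family: one own-copy-number test per dependency
    gene, over all pairings."""
    return 100.0 * dep.shape[0] / count_association_space(cn, dep)


def correlate_all_pairs(cn: pd.DataFrame, dep: pd.DataFrame,
                        min_pairwise_samples: int = 20) -> pd.DataFrame:
    """All-pairs Pearson r and two-sided p on pairwise-complete samples.

    Returns a long table (cn_gene, dep_gene, r, n_used, p). Pairs with
    fewer than min_pairwise_samples complete samples or a zero-variance
    vector get NA r/p (and are later excluded from the FDR family).
    """
    shared = cn.columns.intersection(dep.columns)
    if len(shared) == 0:
        raise ValueError("no shared sample columns between matrices")
    X = cn[shared].to_numpy(dtype=float)  # (ncn, s)
    Y = dep[shared].to_numpy(dtype=float)  # (ndep, s)
    Mx = np.isfinite(X)
    My = np.isfinite(Y)
    X0 = np.where(Mx, X, 0.0)
    Y0 = np.where(My, Y, 0.0)
    MxF = Mx.astype(float)
    MyF = My.astype(float)

    n = MxF @ MyF.T
    sx = X0 @ MyF.T
    sy = MxF @ Y0.T
    sxy = X0 @ Y0.T
    sxx = (X0 ** 2) @ MyF.T
    syy = MxF @ (Y0 ** 2).T

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx ** 2
        vary = n * syy - sy ** 2
        r = cov / np.sqrt(varx * vary)
        # guard tiny negative variance from cancellation
        degenerate = (varx <= 1e-12 * np.maximum(1.0, sxx * n)) | \
                     (vary <= 1e-12 * np.maximum(1.0, syy * n))
        r = np.where(degenerate, np.nan, np.clip(r, -1.0, 1.0))
        r = np.where(n >= min_pairwise_samples, r, np.nan)
        df = n - 2
        t = r * np.sqrt(df / np.maximum(1.0 - r ** 2, 1e-300))
        p = 2.0 * sps.t.sf(np.abs(t), np.maximum(df, 1))
        p = np.where(np.isfinite(r), np.minimum(p, 1.0), np.nan)

    out = pd.DataFrame({
        "cn_gene": np.repeat(cn.index.to_numpy(), dep.shape[0]),
        "dep_gene": np.tile(dep.index.to_numpy(), cn.shape[0]),
        "r": r.ravel(),
        "n_used": n.ravel().astype(int),
        "p": p.ravel(),
    })
    return out


def classify_interactions(records: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Add relation (cis = same chromosome) and direction columns.

    Direction follows the correlation sign: r > 0 means lower copy number
    goes with a lower (more dependent) score, i.e. loss_associated; r < 0
    is gain_associated.
    """
    chrom = annotation.set_index("gene_id")["chromosome"]
    for col in ("cn_gene", "dep_gene"):
        missing = set(records[col]) - set(chrom.index)
        if missing:
            raise ValueError(f"unannotated genes in {col}: {sorted(missing)[:5]}")
    out = records.copy()
    same = chrom[out["cn_gene"]].to_numpy() == chrom[out["dep_gene"]].to_numpy()
    out["relation"] = np.where(same, RELATION_CIS, RELATION_TRANS)
    out["direction"] = np.where(out["r"] > 0, DIR_LOSS,
                                np.where(out["r"] < 0, DIR_GAIN, "NA"))
    return out


def add_fdr(records: pd.DataFrame) -> pd.DataFrame:
    """BH q-values over all non-NA pairs as one family."""
    out = records.copy()
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def collapse_independent(significant: pd.DataFrame, cn: pd.DataFrame,
                         annotation: pd.DataFrame, paralogs: dict[str, set[str]],
                         collapse_r_min: float = 0.9) -> pd.DataFrame:
    """Collapse each dependency gene's significant copy-number genes into
    independently significant region-level interactions.

    Genes on the same chromosome are linked transitively when genomically
    adjacent significant members have copy-number profiles correlating at
    least collapse_r_min, so one arm-level event yields one region.
    Nomination priority: the dependency gene itself within the region, then
    a paralog of it, then the member with the smallest q.
    """
    cols = ["dep_gene", "region_chromosome", "region_start", "region_end",
            "member_cn_genes", "nominated_gene", "nomination_basis",
            "best_q", "relation", "direction"]
    if significant.empty:
        return pd.DataFrame(columns=cols)
    ann = annotation.set_index("gene_id")
    rows = []
    for dep_gene, grp in significant.groupby("dep_gene", sort=True):
        for chrom, cgrp in grp.groupby(
                ann.loc[grp["cn_gene"], "chromosome"].to_numpy(), sort=True):
            cgrp = cgrp.assign(_start=ann.loc[cgrp["cn_gene"], "start"].to_numpy())
            cgrp = cgrp.sort_values("_start", kind="stable")
            members = cgrp["cn_gene"].tolist()
            # split where adjacent profiles decorrelate
            regions, current = [], [0]
            for i in range(1, len(members)):
                a = cn.loc[members[i - 1]].to_numpy(dtype=float)
                b = cn.loc[members[i]].to_numpy(dtype=float)
                ok = np.isfinite(a) & np.isfinite(b)
                rr = np.corrcoef(a[ok], b[ok])[0, 1] if ok.sum() >= 3 else 0.0
                if rr >= collapse_r_min:
                    current.append(i)
                else:
                    regions.append(current)
                    current = [i]
            regions.append(current)
            for idx in regions:
                sub = cgrp.iloc[idx]
                mem = sub["cn_gene"].tolist()
                if dep_gene in mem:
                    nominated, basis = dep_gene, "self"
                else:
                    pals = paralogs.get(dep_gene, set()) & set(mem)
                    if pals:
                        nominated, basis = sorted(pals)[0], "paralog"
                    else:
                        nominated = sub.loc[sub["q"].idxmin(), "cn_gene"]
                        basis = "top_significant"
                best = sub.loc[sub["q"].idxmin()]
                rows.append({
                    "dep_gene": dep_gene,
                    "region_chromosome": chrom,
                    "region_start": int(ann.loc[mem, "start"].min()),
                    "region_end": int(ann.loc[mem, "end"].max()),
                    "member_cn_genes": ",".join(mem),
                    "nominated_gene": nominated,
                    "nomination_basis": basis,
                    "best_q": float(best["q"]),
                    "relation": best["relation"],
                    "direction": best["direction"],
                })
    return pd.DataFrame(rows, columns=cols)


def summarize_interactions(interactions: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Cross-tabulate relation x direction and report the loss-associated
    share as a percent (NaN when there are no interactions)."""
    if interactions.empty:
        return pd.DataFrame(), float("nan")
    tab = pd.crosstab(interactions["relation"], interactions["direction"])
    share = 100.0 * (interactions["direction"] == DIR_LOSS).mean()
    return tab, share
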