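"""The focused CYCLOPS screen.

For every gene measured in both matrices, samples are classified by the
gene's own copy number (loss: log2 <= -0.35, the boundary is a loss;
gain-state lines are excluded from both groups so they do not dilute
"neutral"; setting gain_threshold = +inf restores the strict two-class
scheme). The statistic is the delta dependency score -- mean score in
copy-loss lines minus mean in copy-neutral lines -- and significance comes
from a one-sided (toward more-negative delta) permutation test that
shuffles loss/neutral labels within each lineage stratum, preserving the
per-stratum group counts exactly. Genes with fewer than two copy-loss
lines are excluded. BH across tested genes defines candidates at q < 0.1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import RunConfig
from .stats import bh_adjust, binomial_tail

STATE_LOSS = "loss"
STATE_NEUTRAL = "neutral"
STATE_GAIN = "gain"

REASON_FEW_LOSS = "fewer than two copy-loss lines"
REASON_NO_NEUTRAL = "no copy-neutral lines"


def classify_copy_state(log2_values, loss_threshold: float = -0.35,
                        gain_threshold: float = 0.35) -> np.ndarray:
    """Map log2 relative copy numbers to {loss, neutral, gain} (NA -> NA)."""
    if not loss_threshold < gain_threshold:
        raise ValueError("loss_threshold must be below gain_threshold")
    v = np.asarray(log2_values, dtype=float)
    out = np.where(v <= loss_threshold, STATE_LOSS,
                   np.where(v >= gain_threshold, STATE_GAIN, STATE_NEUTRAL))
    out = out.astype(object)
    out[~np.isfinite(v)] = None
    return out


def delta_dependency(scores, states) -> float:
    """Mean loss-group score minus mean neutral-group score.

    Gain-state and NA entries are excluded; returns NaN when either group
    is empty.
    """
    s = np.asarray(scores, dtype=float)
    st = np.asarray(states, dtype=object)
    ok = np.isfinite(s)
    loss = ok & (st == STATE_LOSS)
    neut = ok & (st == STATE_NEUTRAL)
    if loss.sum() == 0 or neut.sum() == 0:
        return float("nan")
    return float(s[loss].mean() - s[neut].mean())


def _stratified_null_deltas(scores: np.ndarray, is_loss: np.ndarray,
                            strata: np.ndarray, B: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Null deltas from B within-stratum shuffles of loss/neutral labels.

    scores/is_loss/strata cover only the included (loss or neutral,
    finite-score) samples. Per-stratum loss counts are preserved exactly in
    every permutation by construction: within each stratum a uniformly
    random subset of the stratum's size-k loss slots is drawn.
    """
    n_loss = int(is_loss.sum())
    n_neut = int((~is_loss).sum())
    total = scores.sum()
    loss_sums = np.zeros(B)
    for lab in np.unique(strata):
        idx = np.nonzero(strata == lab)[0]
        k = int(is_loss[idx].sum())
        m = idx.size
        sub = scores[idx]
        if k == 0:
            continue
        if k == m:
            loss_sums += sub.sum()
            continue
        keys = rng.random((B, m))
        thr = np.partition(keys, k - 1, axis=1)[:, k - 1:k]
        mask = keys <= thr
        loss_sums += mask @ sub
    return loss_sums / n_loss - (total - loss_sums) / n_neut


def stratified_permutation_test(scores, states, lineages, B: int,
                                rng: np.random.Generator) -> tuple[float, float]:
    """One-sided lineage-stratified permutation test on the delta statistic.

    Returns (delta_obs, p_perm) with the add-one estimate
    p = (1 + #{delta_b <= delta_obs}) / (B + 1), one-sided toward
    more-negative delta (loss lines more dependent). A stratum whose labels
    are all one class contributes no shuffling; when every stratum is
    degenerate the p-value is NaN (with a warning).
    """
    s = np.asarray(scores, dtype=float)
    st = np.asarray(states, dtype=object)
    lin = np.asarray(lineages, dtype=object)
    include = np.isfinite(s) & ((st == STATE_LOSS) | (st == STATE_NEUTRAL))
    s, st, lin = s[include], st[include], lin[include]
    is_loss = st == STATE_LOSS
    if is_loss.sum() < 2:
        raise ValueError(REASON_FEW_LOSS)
    if (~is_loss).sum() == 0:
        raise ValueError(REASON_NO_NEUTRAL)
    delta_obs = s[is_loss].mean() - s[~is_loss].mean()
    shufflable = any(
        0 < is_loss[lin == lab].sum() < (lin == lab).sum() for lab in np.unique(lin)
    )
    if not shufflable:
        warnings.warn("all lineage strata are degenerate; permutation p is NA")
        return float(delta_obs), float("nan")
    null = _stratified_null_deltas(s, is_loss, lin, B, rng)
    p = (1.0 + np.count_nonzero(null <= delta_obs)) / (B + 1.0)
    return float(delta_obs), float(p)


def run_cyclops_screen(cn: pd.DataFrame, dep: pd.DataFrame,
                       sample_annotation: pd.DataFrame,
                       config: RunConfig) -> pd.DataFrame:
    """Per-gene own-copy-number CYCLOPS screen (cis same-gene family).

    Tests every gene present in both matrices against its own copy state;
    BH across tested (non-excluded) genes. Deterministic given config.seed.
    """
    shared_samples = cn.columns.intersection(dep.columns)
    if len(shared_samples) == 0:
        raise ValueError("no shared samples between matrices")
    lineage = sample_annotation.set_index("sample_id")["lineage"]
    lin = lineage.reindex(shared_samples).to_numpy(dtype=object)
    genes = dep.index.intersection(cn.index)
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 777])
    B = config.n_permutations

    rows = []
    for g in genes:
        states = classify_copy_state(cn.loc[g, shared_samples].to_numpy(),
                                     config.loss_threshold, config.gain_threshold)
        scores = dep.loc[g, shared_samples].to_numpy(dtype=float)
        ok = np.isfinite(scores)
        n_loss = int(((states == STATE_LOSS) & ok).sum())
        n_neut = int(((states == STATE_NEUTRAL) & ok).sum())
        if n_loss < 2:
            rows.append((g, np.nan, n_loss, n_neut, np.nan, True, REASON_FEW_LOSS))
            continue
        if n_neut == 0:
            rows.append((g, np.nan, n_loss, n_neut, np.nan, True, REASON_NO_NEUTRAL))
            continue
        delta, p = stratified_permutation_test(scores, states, lin, B, rng)
        rows.append((g, delta, n_loss, n_neut, p, False, ""))

    out = pd.DataFrame(rows, columns=["gene", "delta", "n_loss", "n_neutral",
                                      "p_perm", "excluded", "reason"])
    q = np.full(len(out), np.nan)
    tested = ~out["excluded"].to_numpy()
    q[tested] = bh_adjust(out.loc[tested, "p_perm"].to_numpy())
    out.insert(5, "q", q)
    return out


def cyclops_candidates(screen: pd.DataFrame, fdr: float = 0.10) -> pd.DataFrame:
    """Candidate CYCLOPS genes: tested, q below the screen FDR level."""
    keep = (~screen["excluded"]) & (screen["q"] < fdr)
    return screen.loc[keep.fillna(False)].reset_index(drop=True)


def validate_against_secondary(primary_hits, dep2: pd.DataFrame, cn2: pd.DataFrame,
                               sample_annotation2: pd.DataFrame, config: RunConfig,
                               alpha: float = 0.05) -> dict:
    """Cross-screen validation of primary hits in a second dependency screen.

    A hit validates when the secondary screen shows a delta in the same
    (negative) direction with one-sided permutation p < alpha. Reports the
    validated fraction and a one-sided binomial proportion p against the
    null validation rate alpha.
    """
    hits = [g for g in primary_hits
            if g in dep2.index and g in cn2.index]
    if not hits:
        raise ValueError("no primary hits measured in the secondary screen")
    screen2 = run_cyclops_screen(cn2.loc[[g for g in hits]],
                                 dep2.loc[[g for g in hits]],
                                 sample_annotation2, config)
    tested = screen2[~screen2["excluded"]]
    n = len(tested)
    if n == 0:
        raise ValueError("no primary hits testable in the secondary screen")
    validated = (tested["delta"] < 0) & (tested["p_perm"] < alpha)
    k = int(validated.sum())
    return {
        "n_validated": k,
        "n_tested": n,
        "fraction": k / n,
        "p_binomial": binomial_tail(k, n, alpha) if k > 0 else 1.0,
    }
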