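"""Synthetic panel generator with planted ground truth.

Emulates the statistical structure the screens assume: a cell-line panel
(~179 lines across lineages) with predominantly arm-scale copy losses
calibrated to a mean fraction-of-genome-lost of ~0.16, single-copy losses
encoded near log2(1/2) on a diploid baseline, Gaussian dependency-score
noise with planted loss-conditional (CYCLOPS) and trans effects,
loss-attenuated log-normal expression, and overdispersed beta-binomial
splice-junction counts.

Every generator is a pure function of (config, rng); the planted truth is
returned alongside the data so recovery tests never re-derive it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig

EVENT_CLASSES = ("intron_retention", "alt_3ss", "alt_5ss", "cassette_exon")

LOSS_LOG2 = -1.0  # single-copy loss on a diploid baseline: log2(1/2)

#: minimum planted-loss lines for a gene to be eligible as a planted effect
MIN_PLANT_LOSS_LINES = 5


@dataclass
class SimTruth:
    """Planted ground truth emitted beside every simulated dataset."""

    cyclops_genes: dict[str, float] = field(default_factory=dict)  # gene -> delta
    trans_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    dysregulated_junctions: dict[str, tuple[float, str]] = field(default_factory=dict)
    attenuation: pd.Series | None = None  # per-gene fractional drop upon loss
    loss_indicator: pd.DataFrame | None = None  # genes x samples, planted loss state


def simulate_genome(cfg: SimConfig, rng=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tile genes over p/q arms of each chromosome.

    Returns (gene annotation, arm-boundary table); genes are sorted by
    (chromosome index, start) and tile their arm without overlap.
    """
    genes, arms = [], []
    for c in range(1, cfg.n_chromosomes + 1):
        chrom = f"chr{c}"
        pos = 0
        for arm in ("p", "q"):
            arm_start = pos
            for i in range(cfg.genes_per_arm):
                genes.append({
                    "gene_id": f"G{c:02d}{arm}{i:03d}",
                    "chromosome": chrom,
                    "arm": arm,
                    "start": pos,
                    "end": pos + cfg.gene_span,
                })
                pos += cfg.gene_span
            arms.append({"chromosome": chrom, "arm": arm,
                         "start": arm_start, "end": pos})
    return pd.DataFrame(genes), pd.DataFrame(arms)


def _union_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def simulate_copy_number(
    genome: pd.DataFrame, arm_table: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw per-sample loss events and derive the gene-level log2 matrix.

    Per sample, each arm is lost whole with probability arm_loss_rate and
    additionally hit by a focal loss with probability focal_loss_rate (a
    random sub-interval covering focal_fraction_range of the arm). Lost
    intervals get log2 ~ LOSS_LOG2 + noise, the diploid background ~ 0 +
    noise; a gene's value is the length-weighted mean over its interval
    plus measurement noise. Segments tile every chromosome completely.

    Returns (cn matrix, SEG-style segment table, boolean loss-indicator
    matrix marking genes covered >= 50% by a planted loss event).
    """
    samples = [f"CL{i:03d}" for i in range(cfg.n_cell_lines)]
    gene_start = genome["start"].to_numpy()
    gene_end = genome["end"].to_numpy()
    gene_len = gene_end - gene_start
    chrom_of = genome["chromosome"].to_numpy()

    cn = np.zeros((len(genome), len(samples)))
    loss_ind = np.zeros((len(genome), len(samples)), dtype=bool)
    seg_rows = []
    arm_groups = arm_table.groupby("chromosome", sort=False)
    chrom_bounds = {c: (g["start"].min(), g["end"].max()) for c, g in arm_groups}

    for j, sample in enumerate(samples):
        for chrom, (cstart, cend) in chrom_bounds.items():
            lost: list[tuple[int, int]] = []
            for _, arm in arm_table[arm_table["chromosome"] == chrom].iterrows():
                if rng.random() < cfg.arm_loss_rate * cfg.per_lineage_rate_multiplier:
                    lost.append((int(arm["start"]), int(arm["end"])))
                if rng.random() < cfg.focal_loss_rate * cfg.per_lineage_rate_multiplier:
                    alen = arm["end"] - arm["start"]
                    frac = rng.uniform(*cfg.focal_fraction_range)
                    flen = max(1, int(frac * alen))
                    fstart = int(arm["start"]) + int(rng.integers(0, alen - flen + 1))
                    lost.append((fstart, fstart + flen))
            lost = _union_intervals(lost)

            # build segments tiling [cstart, cend)
            bounds = [cstart]
            for s, e in lost:
                bounds += [s, e]
            bounds.append(cend)
            bounds = sorted(set(bounds))
            in_chrom = chrom_of == chrom
            gvals = np.zeros(int(in_chrom.sum()))
            gidx = np.nonzero(in_chrom)[0]
            for s, e in zip(bounds[:-1], bounds[1:]):
                is_loss = any(ls <= s and e <= le for ls, le in lost)
                base = LOSS_LOG2 if is_loss else 0.0
                val = base + rng.normal(0.0, cfg.segment_noise_sd)
                seg_rows.append((sample, chrom, s, e, round(val, 4)))
                ov = np.clip(np.minimum(gene_end[gidx], e) - np.maximum(gene_start[gidx], s),
                             0, None)
                gvals += val * ov / gene_len[gidx]
            cn[gidx, j] = gvals + rng.normal(0.0, cfg.gene_noise_sd, size=len(gidx))

            if lost:
                cov = np.zeros(len(gidx))
                for s, e in lost:
                    cov += np.clip(np.minimum(gene_end[gidx], e)
                                   - np.maximum(gene_start[gidx], s), 0, None)
                loss_ind[gidx, j] = cov / gene_len[gidx] >= 0.5

    cn_df = pd.DataFrame(cn, index=genome["gene_id"].to_numpy(), columns=samples)
    cn_df.index.name = "gene_id"
    seg_df = pd.DataFrame(seg_rows, columns=["sample", "chromosome", "start", "end", "log2"])
    loss_df = pd.DataFrame(loss_ind, index=cn_df.index, columns=samples)
    return cn_df, seg_df, loss_df


def plant_truth(loss_indicator: pd.DataFrame, genome: pd.DataFrame,
                cfg: SimConfig, rng: np.random.Generator) -> SimTruth:
    """Choose planted CYCLOPS genes and trans pairs among sufficiently-lost genes."""
    n_loss = loss_indicator.sum(axis=1)
    eligible = n_loss.index[n_loss >= MIN_PLANT_LOSS_LINES].to_numpy()
    k = min(cfg.n_cyclops_genes, len(eligible))
    cyclops = list(rng.choice(eligible, size=k, replace=False)) if k else []
    truth = SimTruth(
        cyclops_genes={g: cfg.cyclops_delta for g in cyclops},
        loss_indicator=loss_indicator,
    )
    chrom = genome.set_index("gene_id")["chromosome"]
    remaining = [g for g in eligible if g not in truth.cyclops_genes]
    rng.shuffle(remaining)
    all_genes = genome["gene_id"].to_numpy()
    for cn_gene in remaining[: cfg.n_trans_pairs]:
        others = all_genes[chrom[all_genes].to_numpy() != chrom[cn_gene]]
        dep_gene = str(rng.choice(others))
        truth.trans_pairs.append((cn_gene, dep_gene, cfg.trans_delta))
    att = pd.Series(cfg.attenuation_background, index=genome["gene_id"].to_numpy())
    att.loc[list(truth.cyclops_genes)] = cfg.attenuation_cyclops
    truth.attenuation = att
    return truth


def simulate_dependencies(cn: pd.DataFrame, truth: SimTruth, cfg: SimConfig,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Gaussian dependency scores with planted loss-conditional effects.

    score(g, s) = N(0, sd) + delta_g * 1[s has planted loss of g] for
    CYCLOPS genes, plus trans terms conditional on loss of the partner.
    """
    for g in list(truth.cyclops_genes) + [p[0] for p in truth.trans_pairs]:
        if g not in cn.index:
            raise ValueError(f"planted gene {g!r} absent from the copy-number matrix")
    dep = pd.DataFrame(
        rng.normal(0.0, cfg.dependency_noise_sd, size=cn.shape),
        index=cn.index, columns=cn.columns,
    )
    loss = truth.loss_indicator
    for g, delta in truth.cyclops_genes.items():
        dep.loc[g] += delta * loss.loc[g].to_numpy()
    for cn_gene, dep_gene, delta in truth.trans_pairs:
        dep.loc[dep_gene] += delta * loss.loc[cn_gene].to_numpy()
    dep.index.name = "gene_id"
    return dep


def simulate_expression(cn: pd.DataFrame, truth: SimTruth, cfg: SimConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Loss-attenuated log-normal expression.

    expr(g, s) = baseline_g * (1 - attenuation_g * loss) * exp(N(0, sd_g)),
    where planted CYCLOPS genes get attenuation 0.28 vs 0.18 background and
    a smaller noise sd (uniformly-expressed gene class).
    """
    genes, samples = cn.index, cn.columns
    baseline = np.exp(rng.normal(np.log(100.0), 0.5, size=len(genes)))
    sd = np.full(len(genes), cfg.expression_noise_sd)
    is_cyclops = genes.isin(list(truth.cyclops_genes))
    sd[is_cyclops] *= cfg.cyclops_dispersion_factor
    att = truth.attenuation.reindex(genes).fillna(cfg.attenuation_background).to_numpy()
    loss = truth.loss_indicator.reindex(index=genes, columns=samples).to_numpy()
    noise = rng.normal(0.0, 1.0, size=(len(genes), len(samples))) * sd[:, None]
    expr = baseline[:, None] * (1.0 - att[:, None] * loss) * np.exp(noise)
    out = pd.DataFrame(expr, index=genes, columns=samples)
    out.index.name = "gene_id"
    return out


def _rbetabinom(rng: np.random.Generator, n: np.ndarray, pi: float, rho: float) -> np.ndarray:
    """Beta-binomial draws in the (mean pi, overdispersion rho) parameterization."""
    n = np.asarray(n)
    if rho <= 0.0:
        return rng.binomial(n, pi)
    theta = (1.0 - rho) / rho
    p = rng.beta(pi * theta, (1.0 - pi) * theta, size=n.shape)
    return rng.binomial(n, p)


def simulate_junction_counts(
    cfg: SimConfig, groups: pd.Series, rng: np.random.Generator,
    target_group: str | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Overdispersed junction inclusion/exclusion counts for >= 2 groups.

    Per junction and sample: total reads ~ Poisson(depth), inclusion ~
    BetaBinomial(total, pi, rho). A fraction_dysregulated share of
    junctions get pi shifted by +/- delta_psi in target_group (direction
    up with probability direction_bias); shifts are clipped into (0, 1)
    with a warning. Returns (junction table, truth with the planted set).
    """
    import warnings

    labels = groups.unique()
    if len(labels) < 2:
        raise ValueError("need at least two sample groups")
    if target_group is None:
        target_group = labels[-1]
    samples = groups.index.to_numpy()
    n_j = cfg.n_junctions
    pi0 = np.clip(rng.beta(2.0, 5.0, size=n_j), 0.02, 0.95)
    dys = rng.random(n_j) < cfg.fraction_dysregulated
    up = rng.random(n_j) < cfg.direction_bias
    shift = np.where(dys, np.where(up, cfg.delta_psi, -cfg.delta_psi), 0.0)
    pi_target = pi0 + shift
    clipped = (pi_target <= 0.0) | (pi_target >= 1.0)
    if clipped.any():
        warnings.warn(f"{int(clipped.sum())} planted PSI shifts clipped into (0, 1)")
        pi_target = np.clip(pi_target, 0.01, 0.99)

    ids = [f"J{i:05d}" for i in range(n_j)]
    classes = np.array(EVENT_CLASSES)[np.arange(n_j) % len(EVENT_CLASSES)]
    cols = {}
    for s in samples:
        is_target = groups[s] == target_group
        pis = pi_target if is_target else pi0
        totals = rng.poisson(cfg.junction_depth, size=n_j)
        if cfg.junction_rho <= 0.0:
            incl = rng.binomial(totals, pis)
        else:
            theta = (1.0 - cfg.junction_rho) / cfg.junction_rho
            p = rng.beta(pis * theta, (1.0 - pis) * theta)
            incl = rng.binomial(totals, p)
        cols[(s, "incl")] = incl
        cols[(s, "excl")] = totals - incl

    table = pd.DataFrame(index=pd.Index(ids, name="junction_id"))
    table[("event_class", "")] = classes
    for key, val in cols.items():
        table[key] = val
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["sample", "which"])
    truth = SimTruth(dysregulated_junctions={
        ids[i]: (float(shift[i]), target_group if up[i] else "other")
        for i in np.nonzero(dys)[0]
    })
    return table, truth


def simulate_panel(cfg: SimConfig) -> dict:
    """Run the full generator chain deterministically from cfg.seed.

    Returns a dict with genome, arm_table, sample annotation, cn matrix,
    segments, loss indicator, dependency and expression matrices, junction
    counts, and the combined SimTruth.
    """
    rng = np.random.default_rng([cfg.seed, 101])
    genome, arm_table = simulate_genome(cfg)
    cn, segments, loss = simulate_copy_number(genome, arm_table, cfg,
                                              np.random.default_rng([cfg.seed, 202]))
    truth = plant_truth(loss, genome, cfg, np.random.default_rng([cfg.seed, 303]))
    dep = simulate_dependencies(cn, truth, cfg, np.random.default_rng([cfg.seed, 404]))
    expr = simulate_expression(cn, truth, cfg, np.random.default_rng([cfg.seed, 505]))

    lineages = [f"lineage{i % cfg.n_lineages}" for i in range(cfg.n_cell_lines)]
    sample_annotation = pd.DataFrame({
        "sample_id": cn.columns, "lineage": lineages,
        "condition": [""] * cfg.n_cell_lines,
    })

    n_grp = cfg.n_samples_per_group
    grp = pd.Series(
        ["neutral"] * n_grp + ["loss"] * n_grp,
        index=[f"RNA{i:02d}" for i in range(2 * n_grp)],
    )
    junctions, jtruth = simulate_junction_counts(
        cfg, grp, np.random.default_rng([cfg.seed, 606]), target_group="loss")
    truth.dysregulated_junctions = jtruth.dysregulated_junctions
    del rng
    return {
        "genome": genome, "arm_table": arm_table,
        "sample_annotation": sample_annotation,
        "cn": cn, "segments": segments, "loss_indicator": loss,
        "dependency": dep, "expression": expr,
        "junctions": junctions, "junction_groups": grp,
        "truth": truth,
    }
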