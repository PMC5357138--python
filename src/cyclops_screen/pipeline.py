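"""Stage orchestration: simulate -> associate -> cyclops -> characterize -> splice.

Each stage reads the inputs named in a manifest (a dict of paths; the
simulate stage writes a manifest for the downstream stages), computes via
the library modules, and writes provenance-stamped TSVs into the output
directory. Outputs are byte-identical across re-runs with the same config
and seed. Every filtering step logs how many items it removed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import characterize as char
from . import cyclops as cyc
from . import io as cio
from . import splicing as spl
from .config import RunConfig, SimConfig, config_hash
from .simulate import simulate_panel

log = logging.getLogger("cyclops_screen")

STAGES = ("simulate", "associate", "cyclops", "characterize", "splice")

_STAGE_INPUTS = {
    "associate": ["copy_number", "dependency", "genome"],
    "cyclops": ["copy_number", "dependency", "sample_annotation"],
    "characterize": ["expression", "copy_number", "segments", "arm_table", "genome"],
    "splice": ["junctions", "junction_groups"],
}


class PipelineError(RuntimeError):
    pass


def _require(manifest: dict, stage: str) -> None:
    missing = [k for k in _STAGE_INPUTS.get(stage, []) if k not in manifest]
    if missing:
        raise PipelineError(f"stage {stage!r} requires manifest entries {missing}")


def _header(stage: str, run: RunConfig, sim: SimConfig | None) -> list[str]:
    h = cio.provenance_header(stage, run.seed, config_hash(run))
    if sim is not None:
        h.append(f"sim_config={config_hash(sim)}")
    return h


def run_pipeline(run_cfg: RunConfig, sim_cfg: SimConfig | None, manifest: dict,
                 outdir, stages=("simulate", "associate", "cyclops",
                                 "characterize", "splice")) -> dict:
    """Run the requested stages; returns the manifest extended with outputs.

    Raises PipelineError before any computation if a requested stage lacks
    its inputs (the simulate stage provides them for later stages).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = dict(manifest)
    for stage in stages:
        if stage not in STAGES:
            raise PipelineError(f"unknown stage {stage!r}")
    # pre-flight input check (simulate feeds downstream stages)
    provided = set(manifest)
    for stage in stages:
        if stage == "simulate":
            provided |= {"copy_number", "dependency", "expression", "genome",
                         "arm_table", "sample_annotation", "segments",
                         "junctions", "junction_groups"}
            continue
        missing = [k for k in _STAGE_INPUTS[stage] if k not in provided]
        if missing:
            raise PipelineError(f"stage {stage!r} requires manifest entries {missing}")

    for stage in stages:
        log.info("stage %s starting", stage)
        if stage == "simulate":
            manifest.update(_stage_simulate(run_cfg, sim_cfg or SimConfig(), outdir))
        elif stage == "associate":
            _require(manifest, stage)
            manifest.update(_stage_associate(run_cfg, sim_cfg, manifest, outdir))
        elif stage == "cyclops":
            _require(manifest, stage)
            manifest.update(_stage_cyclops(run_cfg, sim_cfg, manifest, outdir))
        elif stage == "characterize":
            _require(manifest, stage)
            manifest.update(_stage_characterize(run_cfg, sim_cfg, manifest, outdir))
        elif stage == "splice":
            _require(manifest, stage)
            manifest.update(_stage_splice(run_cfg, sim_cfg, manifest, outdir))
    return manifest


def _stage_simulate(run_cfg: RunConfig, sim_cfg: SimConfig, outdir: Path) -> dict:
    panel = simulate_panel(sim_cfg)
    h = _header("simulate", run_cfg, sim_cfg)
    paths = {}

    def put(name, writer):
        path = outdir / name
        writer(path)
        key = name.split(".")[0]
        paths[key] = path
        return path

    put("genome.tsv", lambda p: cio.write_table(panel["genome"], p, h))
    put("arm_table.tsv", lambda p: cio.write_table(panel["arm_table"], p, h))
    put("sample_annotation.tsv",
        lambda p: cio.write_table(panel["sample_annotation"], p, h))
    put("copy_number.tsv", lambda p: cio.write_matrix(panel["cn"], p, h))
    put("dependency.tsv", lambda p: cio.write_matrix(panel["dependency"], p, h))
    put("expression.tsv", lambda p: cio.write_matrix(panel["expression"], p, h))
    put("segments.tsv", lambda p: cio.write_segments(panel["segments"], p, h))
    put("junctions.tsv", lambda p: cio.write_junctions(panel["junctions"], p, h))
    grp = panel["junction_groups"].rename("group").rename_axis("sample_id").reset_index()
    put("junction_groups.tsv", lambda p: cio.write_table(grp, p, h))

    truth = panel["truth"]
    t_cyc = pd.DataFrame(sorted(truth.cyclops_genes.items()),
                         columns=["gene_id", "delta"])
    put("truth_cyclops.tsv", lambda p: cio.write_table(t_cyc, p, h))
    t_trans = pd.DataFrame(truth.trans_pairs,
                           columns=["cn_gene", "dep_gene", "delta"])
    put("truth_trans.tsv", lambda p: cio.write_table(t_trans, p, h))
    t_junc = pd.DataFrame(
        [(j, d, g) for j, (d, g) in sorted(truth.dysregulated_junctions.items())],
        columns=["junction_id", "delta_psi", "up_group"])
    put("truth_junctions.tsv", lambda p: cio.write_table(t_junc, p, h))
    att = truth.attenuation.rename("attenuation").rename_axis("gene_id").reset_index()
    put("truth_attenuation.tsv", lambda p: cio.write_table(att, p, h))
    loss = panel["loss_indicator"].astype(int)
    put("truth_loss_indicator.tsv", lambda p: cio.write_matrix(loss, p, h))
    log.info("simulate: %d genes x %d lines, %d junctions",
             len(panel["cn"]), panel["cn"].shape[1], len(panel["junctions"]))
    return paths


def _stage_associate(run_cfg, sim_cfg, manifest, outdir: Path) -> dict:
    cn = cio.read_matrix(manifest["copy_number"], "copy_number")
    dep = cio.read_matrix(manifest["dependency"], "dependency")
    genome = cio.read_annotation(manifest["genome"])
    paralogs = (cio.read_paralogs(manifest["paralogs"])
                if "paralogs" in manifest else {})
    h = _header("associate", run_cfg, sim_cfg)

    n_space = assoc.count_association_space(cn, dep)
    log.info("associate: %d candidate pairings", n_space)
    records = assoc.correlate_all_pairs(cn, dep, run_cfg.min_pairwise_samples)
    n_na = int(records["p"].isna().sum())
    log.info("associate: %d pairs dropped as NA (insufficient samples or "
             "degenerate)", n_na)
    records = assoc.add_fdr(records)
    records = assoc.classify_interactions(records, genome)
    sig = records[records["q"] < run_cfg.fdr_general].reset_index(drop=True)
    log.info("associate: %d significant records at q < %.2f",
             len(sig), run_cfg.fdr_general)
    interactions = assoc.collapse_independent(sig, cn, genome, paralogs,
                                              run_cfg.collapse_r_min)
    tab, share = assoc.summarize_interactions(interactions)
    summary = pd.DataFrame({
        "metric": ["n_pairings", "cyclops_family_share_pct", "n_significant",
                   "n_interactions", "loss_associated_share_pct"],
        "value": [n_space, assoc.cyclops_family_share(cn, dep), len(sig),
                  len(interactions), share],
    })
    cio.write_table(sig, outdir / "associations.tsv", h)
    cio.write_table(interactions, outdir / "interactions.tsv", h)
    cio.write_table(summary, outdir / "association_summary.tsv", h)
    return {"associations": outdir / "associations.tsv",
            "interactions": outdir / "interactions.tsv"}


def _stage_cyclops(run_cfg, sim_cfg, manifest, outdir: Path) -> dict:
    cn = cio.read_matrix(manifest["copy_number"], "copy_number")
    dep = cio.read_matrix(manifest["dependency"], "dependency")
    samples = cio.read_sample_annotation(manifest["sample_annotation"])
    h = _header("cyclops", run_cfg, sim_cfg)
    screen = cyc.run_cyclops_screen(cn, dep, samples, run_cfg)
    n_exc = int(screen["excluded"].sum())
    log.info("cyclops: %d of %d genes excluded (%s)", n_exc, len(screen),
             cyc.REASON_FEW_LOSS)
    n_cand = len(cyc.cyclops_candidates(screen, run_cfg.fdr_cyclops))
    log.info("cyclops: %d candidates at q < %.2f", n_cand, run_cfg.fdr_cyclops)
    cio.write_table(screen, outdir / "cyclops_candidates.tsv", h)
    return {"cyclops_screen": outdir / "cyclops_candidates.tsv"}


def _stage_characterize(run_cfg, sim_cfg, manifest, outdir: Path) -> dict:
    expr = cio.read_matrix(manifest["expression"], "expression")
    cn = cio.read_matrix(manifest["copy_number"], "copy_number")
    seg = cio.read_segments(manifest["segments"])
    arm_table = cio.read_table(manifest["arm_table"])
    h = _header("characterize", run_cfg, sim_cfg)

    uniformity = char.normalized_expression_variance(expr).rename("cv2")
    states = pd.DataFrame(
        cyc.classify_copy_state(cn.to_numpy(), run_cfg.loss_threshold,
                                run_cfg.gain_threshold),
        index=cn.index, columns=cn.columns)
    response = char.cn_expression_response(expr, states, cn)
    chrom_lengths = arm_table.groupby("chromosome")["end"].max() \
        - arm_table.groupby("chromosome")["start"].min()
    burden = char.fraction_genome_lost(seg, chrom_lengths,
                                       run_cfg.loss_threshold)
    sizes, hist, edges = char.event_size_profile(seg, arm_table,
                                                 run_cfg.loss_threshold)
    log.info("characterize: mean fraction of genome lost %.3f", burden.mean())

    cio.write_table(uniformity.rename_axis("gene_id").reset_index(),
                    outdir / "uniformity.tsv", h)
    cio.write_table(response.rename_axis("gene_id").reset_index(),
                    outdir / "cn_response.tsv", h)
    cio.write_table(burden.rename("fraction_genome_lost")
                    .rename_axis("sample").reset_index(),
                    outdir / "burden.tsv", h)
    cio.write_table(pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                                  "count": hist}),
                    outdir / "event_sizes.tsv", h)
    out = {"uniformity": outdir / "uniformity.tsv",
           "cn_response": outdir / "cn_response.tsv",
           "burden": outdir / "burden.tsv"}
    if "gene_sets" in manifest:
        sets = cio.read_gmt(manifest["gene_sets"])
        query = set(cio.read_table(manifest["query_genes"])["gene_id"]) \
            if "query_genes" in manifest else set()
        universe = set(expr.index)
        enr = char.set_enrichment(query & universe, universe, sets)
        cio.write_table(enr, outdir / "enrichment.tsv", h)
        out["enrichment"] = outdir / "enrichment.tsv"
    return out


def _stage_splice(run_cfg, sim_cfg, manifest, outdir: Path) -> dict:
    junctions = cio.read_junctions(manifest["junctions"])
    grp_tab = cio.read_table(manifest["junction_groups"])
    groups = grp_tab.set_index("sample_id")["group"]
    h = _header("splice", run_cfg, sim_cfg)
    records = spl.run_splicing_screen(junctions, groups, run_cfg)
    for cls, grp in records.groupby("event_class"):
        log.info("splice: family %s, %d junctions", cls, len(grp))
    summary = spl.direction_summary(records, run_cfg.fdr_splicing)
    cio.write_table(records, outdir / "splice_tests.tsv", h)
    cio.write_table(summary, outdir / "direction_summary.tsv", h)
    return {"splice_tests": outdir / "splice_tests.tsv",
            "direction_summary": outdir / "direction_summary.tsv"}
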