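"""Pipeline orchestration: simulate -> targets -> chromstate -> signal ->
enrich -> survival, driven by a single YAML-serializable config.

Each stage is a pure function of its input files and parameter block; the run
summary records the headline quantities of every stage plus SHA-256 hashes of
all outputs (relative names), so reruns with the same seed are byte-checkable.
All randomness derives from the single global seed through per-stage
substreams (``SeedSequence([seed, stage_index])``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chromatin_state, differential_signal, enrichment, target_calling
from .chromatin_state import DEFAULT_BIVALENT_GROUP
from .cohort_survival import run_stratified_survival
from .genomic_io import (
    read_bedgraph,
    read_cohort_table,
    read_expression_table,
    read_gene_annotation,
    read_gmt,
    read_narrowpeak,
    read_segmentation,
)
from .synthetic_data import CONDITIONS, MARKS, SimulationConfig, simulate_layout, simulate_study

__all__ = ["RunConfig", "run_all", "load_config"]

logger = logging.getLogger("bivalentscan")


def _block(cls, data: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) in config block {name!r}: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class TargetsParams:
    window: int = 100_000
    p_threshold: float = 1e-8
    fold_threshold: float = 4.0
    up_lfc: float = 2.0
    down_lfc: float = -2.0
    distance_edges: tuple = tuple(target_calling.DEFAULT_DISTANCE_EDGES)


@dataclass(frozen=True)
class ChromstateParams:
    flank: int = 2_000
    bin: int = 50
    bivalent_group: tuple = tuple(DEFAULT_BIVALENT_GROUP)


@dataclass(frozen=True)
class SignalParams:
    flank: int = 5_000
    bin: int = 50
    # With CPM scaling the mean scaled bin value is 1e6/n_bins, well below 1
    # for a 100+ Mb genome at 50 bp bins; a unit pseudocount would swamp the
    # signal, so the pipeline default is 0.25 (the library function keeps 1.0).
    pseudocount: float = 0.25
    loss_threshold: float = -0.5
    loss_max_gap: int = 2
    loss_min_width: int = 500
    center_halfwidth: int = 500


@dataclass(frozen=True)
class EnrichParams:
    n_perm: int = 1_000
    weight_exponent: float = 1.0
    top_overlap: int = 10


@dataclass(frozen=True)
class SurvivalParams:
    contexts: tuple = (("all", False), ("ras_driven", True), ("ras_activated", True))


@dataclass(frozen=True)
class RunConfig:
    seed: int
    simulate: SimulationConfig
    targets: TargetsParams = TargetsParams()
    chromstate: ChromstateParams = ChromstateParams()
    signal: SignalParams = SignalParams()
    enrich: EnrichParams = EnrichParams()
    survival: SurvivalParams = SurvivalParams()

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        seed = data.pop("seed", None)
        if seed is None:
            raise ValueError("config must set a global seed")
        sim = dict(data.pop("simulate", {}))
        sim.setdefault("seed", seed)
        blocks = {
            "targets": TargetsParams,
            "chromstate": ChromstateParams,
            "signal": SignalParams,
            "enrich": EnrichParams,
            "survival": SurvivalParams,
        }
        kwargs = {"seed": int(seed), "simulate": _block(SimulationConfig, sim, "simulate")}
        for key, klass in blocks.items():
            raw = data.pop(key, {})
            if key == "survival" and "contexts" in raw:
                raw = dict(raw)
                raw["contexts"] = tuple((c, bool(t)) for c, t in raw["contexts"])
            kwargs[key] = _block(klass, dict(raw), key)
        if data:
            raise ValueError(f"unknown top-level config key(s): {sorted(data)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["survival"]["contexts"] = [list(c) for c in self.survival.contexts]
        return out


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def _stage_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] & 0x7FFFFFFF)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig, outdir) -> dict:
    """Execute every stage in dependency order; returns the run summary."""
    outdir = Path(outdir)
    data_dir = outdir / "data"
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(name)s: %(message)s")
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    summary: dict = {"seed": config.seed, "stages": {}}
    current_stage = "setup"

    def stage(name):
        nonlocal current_stage
        current_stage = name
        logger.info("stage %s", name)

    try:
        stage("simulate")
        simulate_study(config.simulate, data_dir)
        layout = simulate_layout(config.simulate)

        stage("targets")
        genes = read_gene_annotation(data_dir / "genes.gtf", format="gtf")
        peaks = read_narrowpeak(data_dir / "peaks.narrowPeak")
        expression = read_expression_table(data_dir / "expression.tsv")
        tp = config.targets
        hc = target_calling.filter_high_confidence(peaks, tp.p_threshold, tp.fold_threshold)
        assignment = target_calling.assign_peaks_to_genes(hc, genes, tp.window)
        targets = target_calling.classify_targets(assignment, expression, genes,
                                                  tp.up_lfc, tp.down_lfc)
        peak_labels = target_calling.label_peaks(assignment, targets, hc)
        dist = target_calling.distance_distribution(assignment, tp.distance_edges)
        targets.to_csv(outdir / "targets.tsv", sep="\t", index=False, float_format="%.1f")
        peak_labels.to_csv(outdir / "peak_labels.tsv", sep="\t", index=False)
        assignment.to_csv(outdir / "assignment.tsv", sep="\t", index=False)
        dist.to_csv(outdir / "distance_hist.tsv", sep="\t", index=False, float_format="%.6f")
        n_act = int((targets["target_class"] == "activated").sum())
        n_rep = int((targets["target_class"] == "repressed").sum())
        summary["stages"]["targets"] = {
            "n_peaks": len(peaks),
            "n_high_confidence_peaks": len(hc),
            "n_activated_targets": n_act,
            "n_repressed_targets": n_rep,
        }

        stage("chromstate")
        seg = read_segmentation(data_dir / "segmentation.bed")
        cp = config.chromstate
        anchors_all = genes.tss_anchors().set_index("anchor_id")
        groups = {
            "activated_tss": targets.loc[targets["target_class"] == "activated", "gene_id"],
            "repressed_tss": targets.loc[targets["target_class"] == "repressed", "gene_id"],
            "null_tss": targets.loc[targets["target_class"] == "none", "gene_id"],
            "all_tss": targets["gene_id"],
        }
        frac_rows = []
        fractions = {}
        for gname, ids in groups.items():
            sub = anchors_all.loc[list(ids)].reset_index()
            if len(sub) == 0:
                continue
            table = chromatin_state.state_fractions(sub, seg, cp.bivalent_group)
            fractions[gname] = table.group_fraction
            for st, cnt in table.counts.items():
                frac_rows.append((gname, st, cnt, table.fractions[st], table.group_fraction,
                                  table.n_anchors))
        summit_groups = {
            "activating_summits": peak_labels.loc[peak_labels["label"] == "activating", "peak_id"],
            "repressive_summits": peak_labels.loc[peak_labels["label"] == "repressive", "peak_id"],
        }
        summit_anchors = hc.summit_anchors().set_index("anchor_id")
        for gname, ids in summit_groups.items():
            sub = summit_anchors.loc[list(ids)].reset_index()
            if len(sub) == 0:
                continue
            table = chromatin_state.state_fractions(sub, seg, cp.bivalent_group)
            fractions[gname] = table.group_fraction
            for st, cnt in table.counts.items():
                frac_rows.append((gname, st, cnt, table.fractions[st], table.group_fraction,
                                  table.n_anchors))
        pd.DataFrame(
            frac_rows,
            columns=["group", "state", "count", "fraction", "group_fraction", "n_anchors"],
        ).to_csv(outdir / "state_fractions.tsv", sep="\t", index=False, float_format="%.6f")
        prof_frames = []
        for gname in ("activated_tss", "repressed_tss"):
            sub = anchors_all.loc[list(groups[gname])].reset_index()
            if len(sub) == 0:
                continue
            prof = chromatin_state.positional_state_profile(
                sub, seg, dict(layout.chrom_lengths), cp.flank, cp.bin
            )
            prof_frames.append(prof.to_frame().assign(group=gname))
        if prof_frames:
            pd.concat(prof_frames, ignore_index=True).to_csv(
                outdir / "state_profile.tsv", sep="\t", index=False, float_format="%.6f"
            )
        summary["stages"]["chromstate"] = {
            f"bivalent_fraction_{g}": round(v, 6) for g, v in fractions.items()
        }

        stage("signal")
        sp = config.signal
        act = summit_anchors.loc[list(summit_groups["activating_summits"])].reset_index()
        rep = summit_anchors.loc[list(summit_groups["repressive_summits"])].reset_index()
        signal_summary = {}
        loss_regions = {}
        meta_frames = []
        for mark in MARKS:
            treat = read_bedgraph(data_dir / f"{mark}_{CONDITIONS[0]}.bedGraph", layout, sp.bin)
            control = read_bedgraph(data_dir / f"{mark}_{CONDITIONS[1]}.bedGraph", layout, sp.bin)
            ratio = differential_signal.log2_ratio_track(treat, control, sp.pseudocount)
            for gname, anchors in (("activating_summits", act), ("repressive_summits", rep)):
                if len(anchors) == 0:
                    continue
                prof = differential_signal.metaprofile(
                    ratio, anchors, sp.flank, sp.bin, anchor_group=f"{mark}:{gname}"
                )
                meta_frames.append(prof.to_frame())
                signal_summary[f"{mark}_{gname}_center_log2fc"] = round(
                    prof.center_mean(sp.center_halfwidth), 6
                )
            mat = differential_signal.anchor_matrix(ratio, act, sp.flank, sp.bin, sort_by="mean")
            pd.DataFrame(mat.values, index=list(mat.anchor_ids), columns=mat.offsets).to_csv(
                outdir / f"matrix_{mark}_activating.tsv", sep="\t", float_format="%.4f"
            )
            if mark in ("h3k27me3", "ezh2"):
                regions = differential_signal.call_loss_regions(
                    ratio, sp.loss_threshold, sp.loss_max_gap, sp.loss_min_width
                )
                loss_regions[mark] = regions
                regions.to_csv(outdir / f"loss_regions_{mark}.bed", sep="\t",
                               index=False, header=False)
                signal_summary[f"n_loss_regions_{mark}"] = len(regions)
        pd.concat(meta_frames, ignore_index=True).to_csv(
            outdir / "metaprofile.tsv", sep="\t", index=False, float_format="%.6f"
        )
        if len(loss_regions) == 2:
            signal_summary["loss_region_jaccard"] = round(
                differential_signal.interval_jaccard(
                    loss_regions["h3k27me3"], loss_regions["ezh2"]
                ),
                6,
            )
        summary["stages"]["signal"] = signal_summary

        stage("enrich")
        ep = config.enrich
        gene_sets = read_gmt(data_dir / "gene_sets.gmt")
        ranked = enrichment.rank_by_log2fc(expression)
        universe = set(expression["gene_id"])
        upregulated = set(
            expression.loc[
                expression["is_significant"] & (expression["log2fc"] > config.targets.up_lfc),
                "gene_id",
            ]
        )
        overlap = enrichment.overlap_table(upregulated, gene_sets, universe, ep.top_overlap)
        overlap.to_csv(outdir / "overlap_table.tsv", sep="\t", index=False, float_format="%.6g")
        gsea_rows = []
        enrich_summary = {}
        for i, name in enumerate(gene_sets.names()):
            res = enrichment.gsea_permutation(
                ranked,
                gene_sets.members(name),
                n_perm=ep.n_perm,
                seed=_stage_seed(config.seed, 100 + i),
                weight_exponent=ep.weight_exponent,
                set_name=name,
            )
            gsea_rows.append(
                (name, res.es, res.nes, res.nominal_p, res.n_permutations,
                 len(res.leading_edge))
            )
            if name == "PLANTED_ACTIVATED_TARGETS":
                enrich_summary.update(
                    planted_set_es=round(res.es, 6),
                    planted_set_nes=round(res.nes, 6),
                    planted_set_nominal_p=res.nominal_p,
                )
        pd.DataFrame(
            gsea_rows,
            columns=["set_name", "es", "nes", "nominal_p", "n_perm", "leading_edge_size"],
        ).to_csv(outdir / "gsea_results.tsv", sep="\t", index=False, float_format="%.6g")
        summary["stages"]["enrich"] = enrich_summary

        stage("survival")
        cohort = read_cohort_table(data_dir / "cohort.tsv")
        surv_rows = []
        km_frames = []
        surv_summary = {}
        for context, need_tp53 in config.survival.contexts:
            res = run_stratified_survival(cohort, context, need_tp53)
            key = f"{context}{'_tp53lof' if need_tp53 else ''}"
            surv_rows.append(
                (key, res.n_high, res.n_low, res.logrank.chi_square, res.logrank.p_value)
            )
            surv_summary[f"logrank_p_{key}"] = res.logrank.p_value
            for arm, curve in (("high", res.curve_high), ("low", res.curve_low)):
                km_frames.append(
                    pd.DataFrame(
                        {
                            "context": key,
                            "arm": arm,
                            "time": curve.event_times,
                            "survival": curve.survival,
                            "at_risk": curve.at_risk,
                        }
                    )
                )
        pd.DataFrame(
            surv_rows, columns=["context", "n_high", "n_low", "chi_square", "p_value"]
        ).to_csv(outdir / "logrank.tsv", sep="\t", index=False, float_format="%.6g")
        pd.concat(km_frames, ignore_index=True).to_csv(
            outdir / "km_curves.tsv", sep="\t", index=False, float_format="%.6f"
        )
        summary["stages"]["survival"] = surv_summary
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {current_stage!r}: {exc}") from exc

    hashes = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "run_summary.json":
            hashes[str(path.relative_to(outdir))] = _sha256(path)
    summary["file_sha256"] = hashes
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
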