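"""End-to-end pipeline orchestration on synthetic or user-supplied data.

Stages run in dependency order: simulate -> segment -> psi -> devas ->
patterns -> ortho -> motifs -> evolve -> summarize.  Every stage writes a
TSV table into the output directory; a run manifest records the resolved
configuration, seed and row counts.  Outputs are pure functions of
(config, seed): reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evolution import (
    SpeciesTree,
    apply_birth_filters,
    detect_alternification,
    find_interspaced_candidates,
    parsimony_age,
)
from .glm import add_log_age, run_devas
from .motifs import combined_enrichment
from .orthology import build_ortho_groups, read_mappings_tsv, write_ortho_groups_tsv
from .psi import psi_matrix, write_psi_matrix
from .segments import read_gtf_genes, segment_gene, write_segments_tsv
from .simulate import SimConfig, generate_dataset
from .stats import mds_embed, organ_pair_cooccurrence, psi_distance_matrix
from .trajectories import call_devas, classify_pattern, fit_psi_spline

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, defaulting to the published values."""

    outdir: str = "devsplice_run"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    # thresholds
    min_coverage: int = 10  # i+e below this -> PSI undefined
    eligibility_frac: float = 0.6
    eligibility_in_range: int = 4
    psi_range: tuple[float, float] = (0.1, 0.9)
    devas_alpha: float = 0.05
    devas_min_dpsi: float = 0.2
    pattern_ratio_low: float = 0.3
    pattern_ratio_high: float = 0.7
    iou_node_min: float = 0.6
    iou_edge_min: float = 0.6
    alternification_min_pairs: int = 4
    alternification_psi_cutoff: float = 0.9
    flank_length: int = 200
    score_window: int = 50
    microexon_max: int = 27
    te_min_overlap: int = 10
    new_exon_max_length: int = 500
    # stage toggles
    stages: tuple[str, ...] = (
        "simulate",
        "segment",
        "psi",
        "devas",
        "patterns",
        "ortho",
        "motifs",
        "evolve",
        "summarize",
    )

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        cfg = cls(sim=sim, **{k: v for k, v in raw.items()})
        if isinstance(cfg.psi_range, list):
            cfg.psi_range = tuple(cfg.psi_range)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_tsv(df: pd.DataFrame, path: str) -> int:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return len(df)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the run manifest."""
    out = config.outdir
    os.makedirs(out, exist_ok=True)
    config.sim.seed = config.seed
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "tables": {},
    }
    stages = set(config.stages)
    data = None

    if "simulate" in stages:
        data = generate_dataset(config.sim, out)
        manifest["tables"]["counts"] = len(data["counts"])

    if data is None:
        raise FileNotFoundError("non-synthetic runs require the simulate stage output")

    meta = add_log_age(data["meta"].drop(columns=["a"], errors="ignore"),
                       config.sim.gestation)

    seg_table = None
    if "segment" in stages:
        genes = read_gtf_genes(os.path.join(out, "annotation.gtf"))
        segments = [s for g in genes for s in segment_gene(g)]
        write_segments_tsv(segments, os.path.join(out, "segments.tsv"))
        seg_table = pd.DataFrame(
            {
                "segment_id": [s.segment_id for s in segments],
                "status": [s.status for s in segments],
                "as_class": [s.as_class for s in segments],
                "length": [s.length for s in segments],
            }
        )
        manifest["tables"]["segments"] = len(seg_table)

    psi = None
    if "psi" in stages:
        counts = data["counts"]
        lengths = (
            seg_table.set_index("segment_id")["length"]
            if seg_table is not None
            else pd.Series(
                config.sim.exon_length,
                index=sorted(counts["segment_id"].unique()),
            )
        )
        psi = psi_matrix(counts, lengths, config.sim.read_length)
        write_psi_matrix(psi, os.path.join(out, "psi_matrix.tsv"))
        manifest["tables"]["psi"] = int(psi.size)

    devas_table = None
    if "devas" in stages and psi is not None:
        devas_table = run_devas(
            data["counts"],
            psi,
            meta,
            alpha=config.devas_alpha,
            min_coverage=config.min_coverage,
            min_coverage_frac=config.eligibility_frac,
            min_in_range=config.eligibility_in_range,
            psi_range=config.psi_range,
        )
        manifest["tables"]["devas"] = _write_tsv(
            devas_table, os.path.join(out, "devas.tsv")
        )

    traj_table = None
    if "patterns" in stages and psi is not None and devas_table is not None:
        rows = []
        padj = devas_table.set_index(["segment_id", "species", "organ"])["padj_min"]
        for (sp, organ), sub in meta.groupby(["species", "organ"], sort=True):
            samples = [s for s in sub["sample_id"] if s in psi.columns]
            ages = sub.set_index("sample_id").loc[samples, "a"].to_numpy()
            for seg in psi.index:
                vals = psi.loc[seg, samples].to_numpy(dtype=float)
                if np.sum(~np.isnan(vals)) < 5:
                    continue
                fit = fit_psi_spline(vals, ages)
                stats_ = classify_pattern(fit)
                q = padj.get((seg, sp, organ), math.nan)
                rows.append(
                    {
                        "segment_id": seg,
                        "species": sp,
                        "organ": organ,
                        "dpsi": fit.dpsi,
                        "up": stats_.up,
                        "down": stats_.down,
                        "up_timing": stats_.up_timing,
                        "down_timing": stats_.down_timing,
                        "ratio": stats_.ratio,
                        "pattern": stats_.pattern,
                        "devas": (not math.isnan(q))
                        and call_devas(q, fit.dpsi, config.devas_alpha, config.devas_min_dpsi),
                    }
                )
        traj_table = pd.DataFrame(rows)
        manifest["tables"]["trajectories"] = _write_tsv(
            traj_table, os.path.join(out, "trajectories.tsv")
        )

    if "ortho" in stages:
        mappings = read_mappings_tsv(os.path.join(out, "mappings.tsv"))
        groups = build_ortho_groups(
            mappings,
            list(config.sim.species),
            node_min_iou=config.iou_node_min,
            edge_min_iou=config.iou_edge_min,
        )
        write_ortho_groups_tsv(groups, os.path.join(out, "ortho_groups.tsv"))
        manifest["tables"]["ortho_groups"] = len(groups)

    if "motifs" in stages and traj_table is not None:
        flanks: dict[str, dict[str, str]] = {}
        with open(os.path.join(out, "flanks.fa")) as fh:
            name = None
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    name = line[1:]
                elif name:
                    sp, seg, _region = name.split("|")
                    flanks.setdefault(sp, {})[seg] = line
        up_calls = traj_table[(traj_table["devas"]) & (traj_table["pattern"] == "up")]
        targets = {}
        background = {}
        for sp, seqs in flanks.items():
            segs_up = set(up_calls[up_calls["species"] == sp]["segment_id"])
            targets[sp] = [s for seg, s in seqs.items() if seg in segs_up]
            background[sp] = [s for seg, s in seqs.items() if seg not in segs_up]
        usable = {sp for sp in targets if targets[sp] and background[sp]}
        if usable:
            enr = combined_enrichment(
                {sp: targets[sp] for sp in sorted(usable)},
                {sp: background[sp] for sp in sorted(usable)},
            )
            enr.reset_index().to_csv(
                os.path.join(out, "hexamer_enrichment.tsv"),
                sep="\t",
                index=False,
                float_format="%.6g",
            )
            manifest["tables"]["hexamer_enrichment"] = len(enr)

    if "evolve" in stages:
        tree = SpeciesTree()
        cands = find_interspaced_candidates(
            data["border_pairs"], sorted(tree.leaves)
        )
        regions = data["target_regions"]
        rows = []
        for cand in cands:
            retained = apply_birth_filters(
                cand, regions.get(cand.pair_id, {}),
                max_length=config.new_exon_max_length,
            )
            event = parsimony_age(cand.presence, tree) if retained else None
            rows.append(
                {
                    "pair_id": cand.pair_id,
                    "useg_id": cand.useg_id,
                    "dseg_id": cand.dseg_id,
                    "presence": ",".join(
                        sp for sp, v in sorted(cand.presence.items()) if v
                    ),
                    "retained": retained,
                    "event": event.event if event else "",
                    "age_class": event.age_class if event else "",
                }
            )
        manifest["tables"]["new_exons"] = _write_tsv(
            pd.DataFrame(rows), os.path.join(out, "new_exons.tsv")
        )

        alt_rows = []
        for g, table in enumerate(data["alternification_tables"]):
            status, event = detect_alternification(
                table,
                tree,
                min_pairs=config.alternification_min_pairs,
                psi_cutoff=config.alternification_psi_cutoff,
            )
            alt_rows.append(
                {
                    "group": f"alt{g + 1}",
                    "alternative_in": ",".join(
                        sp for sp, v in sorted(status.items()) if v
                    ),
                    "event": event.event if event else "",
                    "age_class": event.age_class if event else "",
                }
            )
        manifest["tables"]["alternified"] = _write_tsv(
            pd.DataFrame(alt_rows), os.path.join(out, "alternified.tsv")
        )

    if "summarize" in stages and psi is not None:
        dist = psi_distance_matrix(psi)
        coords = mds_embed(dist.to_numpy(), k=2)
        mds = pd.DataFrame(
            {"sample_id": dist.index, "dim1": coords[:, 0], "dim2": coords[:, 1]}
        )
        manifest["tables"]["mds"] = _write_tsv(mds, os.path.join(out, "mds.tsv"))
        if traj_table is not None:
            mem = (
                traj_table[traj_table["devas"]]
                .assign(flag=True)
                .pivot_table(
                    index="segment_id", columns="organ", values="flag", aggfunc="any",
                    fill_value=False,
                )
            )
            if mem.shape[1] >= 2 and len(mem) > 0:
                pairs = organ_pair_cooccurrence(mem.astype(bool))
                manifest["tables"]["organ_pairs"] = _write_tsv(
                    pairs, os.path.join(out, "organ_pairs.tsv")
                )

    # resolved config + manifest (no timestamps: reruns stay byte-identical)
    resolved = config.to_dict()
    resolved.pop("outdir")  # runtime location, not an analysis parameter
    with open(os.path.join(out, "config_resolved.yaml"), "w") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
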