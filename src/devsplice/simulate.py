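"""Synthetic multi-species developmental AS datasets with known ground truth.

Generators for every pipeline input: PSI trajectories of the canonical
temporal shapes, overdispersed (beta-binomial) inclusion/exclusion counts,
flank sequences with planted hexamers, and exon gain/loss/alternification
scenarios on the species tree.  :func:`generate_dataset` writes a full
dataset (GTF, counts TSV, metadata TSV, flank FASTA, Newick, BED, PWM
text) together with ground-truth tables, reproducibly from a seed.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .evolution import (
    DEFAULT_SPECIES,
    DEFAULT_TREE_NEWICK,
    InterspacedExon,
    SpeciesTree,
)
from .glm import GESTATION_DAYS

__all__ = [
    "SimConfig",
    "default_stage_days",
    "generate_alternification_scenario",
    "generate_dataset",
    "generate_evolution_scenario",
    "plant_flank_motifs",
    "random_sequence",
    "simulate_counts",
    "simulate_trajectory",
]

PATTERNS = ("up", "down", "up-down", "down-up", "flat")


@dataclass
class SimConfig:
    """Configuration of a synthetic dataset; every field has a paper-like default."""

    n_genes: int = 60
    species: tuple[str, ...] = DEFAULT_SPECIES
    organs: tuple[str, ...] = ("brain", "heart")
    gestation: dict[str, float] = field(default_factory=lambda: dict(GESTATION_DAYS))
    pattern_mix: dict[str, float] = field(
        default_factory=lambda: {
            "up": 0.2,
            "down": 0.2,
            "up-down": 0.15,
            "down-up": 0.15,
            "flat": 0.3,
        }
    )
    amplitude: float = 0.6
    depth: float = 100.0
    rho: float = 0.05
    read_length: int = 100
    exon_length: int = 150
    motif_hexamer: str = "ACTAAC"
    motif_target_frac: float = 0.4
    motif_background_frac: float = 0.1
    flank_length: int = 200
    n_evo_groups: int = 20
    n_alternification_groups: int = 20
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.pattern_mix.values()) - 1.0) > 1e-9:
            raise ValueError("pattern mixture proportions must sum to 1")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("overdispersion rho must lie in [0, 1)")
        if not (0.0 < self.amplitude <= 1.0):
            raise ValueError("amplitude must lie in (0, 1]")


def default_stage_days(
    species: str, gestation: Mapping[str, float] | None = None
) -> dict[str, float]:
    """Stage grid in days post conception: dense prenatal, sparse postnatal."""
    g = (GESTATION_DAYS if gestation is None else gestation)[species]
    stages = {
        "e1": 0.3 * g,
        "e2": 0.5 * g,
        "e3": 0.7 * g,
        "e4": 0.9 * g,
        "newborn": 1.0 * g,
        "infant": g + 0.5 * g,
        "juvenile": g + 2.0 * g,
        "adult": g + 8.0 * g,
    }
    return stages


def simulate_trajectory(
    pattern: str, amplitude: float, ages: Sequence[float], baseline: Optional[float] = None
) -> np.ndarray:
    """True PSI values of a canonical temporal shape at the given log-ages.

    "up"/"down" are logistic; "up-down"/"down-up" are Gaussian bumps
    centered mid-range; "flat" is constant.  Values are rescaled so that
    max - min over the sampled ages equals ``amplitude`` exactly, centered
    at ``baseline`` (default: mid-range so the curve stays in [0, 1]).
    """
    ages = np.asarray(ages, dtype=float)
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}")
    if pattern == "flat":
        level = 0.5 if baseline is None else baseline
        return np.full(ages.shape, level)
    if not (0.0 < amplitude <= 1.0):
        raise ValueError("amplitude must lie in (0, 1]")
    span = ages.max() - ages.min()
    if span <= 0:
        raise ValueError("ages must span a positive range")
    x = (ages - ages.min()) / span  # normalized 0..1
    if pattern in ("up", "down"):
        y = 1.0 / (1.0 + np.exp(-10.0 * (x - 0.5)))
        if pattern == "down":
            y = -y
    else:
        y = np.exp(-0.5 * ((x - 0.5) / 0.18) ** 2)
        if pattern == "down-up":
            y = -y
    y = (y - y.min()) / (y.max() - y.min())  # in [0,1], range exactly 1
    low = (1.0 - amplitude) / 2.0 if baseline is None else baseline - amplitude / 2.0
    low = min(max(low, 0.0), 1.0 - amplitude)
    return low + amplitude * y


def simulate_counts(
    true_psi: Sequence[float],
    depth: float,
    rho: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (i, e) per sample: n ~ Poisson(depth), i ~ BetaBinomial(n, psi, rho).

    rho = 0 reduces to plain binomial sampling.
    """
    psi = np.asarray(true_psi, dtype=float)
    if np.any((psi < 0) | (psi > 1)):
        raise ValueError("true PSI must lie in [0, 1]")
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    n = rng.poisson(depth, size=psi.shape)
    p = psi.copy()
    if rho > 0:
        interior = (psi > 0) & (psi < 1)
        a = psi * (1.0 - rho) / rho
        b = (1.0 - psi) * (1.0 - rho) / rho
        p = np.where(
            interior,
            rng.beta(np.where(interior, a, 1.0), np.where(interior, b, 1.0)),
            psi,
        )
    i = rng.binomial(n, p)
    return i, n - i


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def plant_flank_motifs(
    n_target: int,
    n_background: int,
    hexamer: str,
    target_frac: float,
    background_frac: float,
    length: int,
    rng: np.random.Generator,
) -> tuple[list[str], list[str], np.ndarray, np.ndarray]:
    """Random flank sequences with the hexamer planted in given fractions.

    Returns (target flanks, background flanks, target planted flags,
    background planted flags).  The hexamer is inserted (overwritten) at a
    random position of each selected sequence.
    """
    if not (0.0 <= target_frac <= 1.0 and 0.0 <= background_frac <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")

    def make(n: int, frac: float) -> tuple[list[str], np.ndarray]:
        seqs = [random_sequence(rng, length) for _ in range(n)]
        planted = rng.random(n) < frac
        for idx in np.flatnonzero(planted):
            pos = int(rng.integers(0, length - len(hexamer) + 1))
            s = seqs[idx]
            seqs[idx] = s[:pos] + hexamer + s[pos + len(hexamer):]
        return seqs, planted

    t_seqs, t_flags = make(n_target, target_frac)
    b_seqs, b_flags = make(n_background, background_frac)
    return t_seqs, b_seqs, t_flags, b_flags


# ---------------------------------------------------------------------------
# Evolution scenarios
# ---------------------------------------------------------------------------

def generate_evolution_scenario(
    tree: SpeciesTree,
    events: Sequence[Optional[tuple[str, frozenset]]],
    rng: np.random.Generator,
    exon_length: int = 120,
    region_length: int = 300,
) -> tuple[list[dict], dict[str, dict[str, str]], list[dict]]:
    """Border-pair records implementing planted gain/loss events.

    ``events`` holds one entry per ortho group: None (no interspaced
    exon anywhere) or ``(event_type, clade)`` with event_type gain/loss
    and ``clade`` the set of species below the event's branch.  Presence
    species share an identical exon sequence; the border+inter-border
    regions of absence species are independent random sequences.

    Returns (border-pair records consumable by
    :func:`devsplice.evolution.find_interspaced_candidates`, per-pair
    target regions keyed pair_id -> species -> sequence, ground truth).
    """
    species = sorted(tree.leaves)
    pairs: list[dict] = []
    regions: dict[str, dict[str, str]] = {}
    truth: list[dict] = []
    for g, ev in enumerate(events):
        pair_id = f"bp{g + 1}"
        if ev is None:
            presence: frozenset = frozenset()
            label = "none"
        else:
            etype, clade = ev
            if etype == "gain":
                presence = frozenset(clade)
            elif etype == "loss":
                presence = tree.leaves - frozenset(clade)
            else:
                raise ValueError(f"unknown event type {etype!r}")
            label = etype
        exon_seq = random_sequence(rng, exon_length)
        interspaced = {
            sp: [
                InterspacedExon(
                    exon_id=f"{pair_id}.{sp}.x",
                    sequence=exon_seq,
                    flank5=random_sequence(rng, 4),
                    flank3=random_sequence(rng, 4),
                )
            ]
            for sp in species
            if sp in presence
        }
        pairs.append(
            {
                "pair_id": pair_id,
                "useg_id": f"{pair_id}.u",
                "dseg_id": f"{pair_id}.d",
                "interspaced": interspaced,
            }
        )
        regions[pair_id] = {
            sp: random_sequence(rng, region_length)
            for sp in species
            if sp not in presence
        }
        truth.append(
            {
                "pair_id": pair_id,
                "event": label,
                "clade": ",".join(sorted(ev[1])) if ev else "",
                "presence": ",".join(sorted(presence)),
            }
        )
    return pairs, regions, truth


def generate_alternification_scenario(
    tree: SpeciesTree,
    events: Sequence[Optional[tuple[str, frozenset]]],
    rng: np.random.Generator,
    n_organ_stage: int = 10,
) -> tuple[list[dict[str, np.ndarray]], list[dict]]:
    """Per-species organ-stage PSI tables implementing planted alternification.

    Cassette species get >= 4 organ-stage PSI values below 0.9 (around
    0.5); constitutive species stay at 0.95-1.0.  ``events`` entries are
    None (cassette everywhere — no event) or (``"gain"``/``"loss"``,
    clade) for alternification gain/loss.
    """
    species = sorted(tree.leaves)
    tables: list[dict[str, np.ndarray]] = []
    truth: list[dict] = []
    for g, ev in enumerate(events):
        if ev is None:
            cassette = frozenset(species)
            label = "none"
        else:
            etype, clade = ev
            cassette = (
                frozenset(clade) if etype == "gain" else tree.leaves - frozenset(clade)
            )
            label = f"alternification_{etype}"
        table = {}
        for sp in species:
            if sp in cassette:
                vals = rng.uniform(0.3, 0.7, size=n_organ_stage)
            else:
                vals = rng.uniform(0.95, 1.0, size=n_organ_stage)
            table[sp] = vals
        tables.append(table)
        truth.append(
            {
                "group": f"alt{g + 1}",
                "event": label,
                "clade": ",".join(sorted(ev[1])) if ev else "",
                "cassette_in": ",".join(sorted(cassette)),
            }
        )
    return tables, truth


# ---------------------------------------------------------------------------
# Full dataset emission
# ---------------------------------------------------------------------------

def _inclusion_read_prob(psi: np.ndarray, ls: int, lr: int) -> np.ndarray:
    """Read-level inclusion probability whose PSI estimate converges to psi.

    The PSI formula divides i by ls+lr-1 and e by lr-1; drawing inclusion
    reads with this adjusted probability makes the length-corrected PSI a
    consistent estimator of the true psi.
    """
    li, le = ls + lr - 1.0, lr - 1.0
    return psi * li / (psi * li + (1.0 - psi) * le)


def generate_dataset(config: SimConfig, outdir: str) -> dict[str, pd.DataFrame]:
    """Write a complete synthetic dataset plus ground truth to ``outdir``.

    Emits annotation.gtf, counts.tsv, samples.tsv, flanks.fa, tree.nwk,
    te.bed, motif.pwm and truth_*.tsv.  Fully reproducible from
    (config, config.seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    os.makedirs(outdir, exist_ok=True)

    species = list(config.species)
    patterns = list(config.pattern_mix)
    probs = np.array([config.pattern_mix[p] for p in patterns])
    gene_patterns = [
        patterns[k] for k in rng.choice(len(patterns), size=config.n_genes, p=probs)
    ]

    # --- annotation: one 3-exon gene per simulated cassette exon ----------
    gtf_lines = []
    seg_meta = []
    ls = config.exon_length
    for g in range(config.n_genes):
        gid = f"g{g + 1}"
        off = 10_000 * g
        exons = [(off + 100, off + 300), (off + 400, off + 400 + ls), (off + 500 + ls, off + 700 + ls)]
        for tid, use in (("t1", (0, 1, 2)), ("t2", (0, 2))):
            for k in use:
                s, e = exons[k]
                gtf_lines.append(
                    f"chr1\tsim\texon\t{s + 1}\t{e}\t.\t+\t."
                    f'\tgene_id "{gid}"; transcript_id "{gid}.{tid}";'
                )
        seg_meta.append({"gene_id": gid, "segment_id": f"{gid}.s3", "pattern": gene_patterns[g]})
    with open(os.path.join(outdir, "annotation.gtf"), "w") as fh:
        fh.write("\n".join(gtf_lines) + "\n")

    # --- samples and counts ----------------------------------------------
    meta_rows = []
    count_rows = []
    truth_rows = []
    for sp in species:
        stages = default_stage_days(sp, config.gestation)
        for organ in config.organs:
            for stage, days in stages.items():
                sid = f"{sp}.{organ}.{stage}"
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "species": sp,
                        "organ": organ,
                        "stage": stage,
                        "days_post_conception": days,
                    }
                )
    meta = pd.DataFrame(meta_rows)
    meta["a"] = np.log(meta["days_post_conception"])

    for sp in species:
        for organ in config.organs:
            sub = meta[(meta["species"] == sp) & (meta["organ"] == organ)]
            ages = sub["a"].to_numpy()
            for g in range(config.n_genes):
                pattern = gene_patterns[g]
                psi = simulate_trajectory(pattern, config.amplitude, ages)
                q = _inclusion_read_prob(psi, ls, config.read_length)
                i, e = simulate_counts(q, config.depth, config.rho, rng)
                for sid, iv, ev in zip(sub["sample_id"], i, e):
                    count_rows.append(
                        {
                            "segment_id": f"g{g + 1}.s3",
                            "sample_id": sid,
                            "i": int(iv),
                            "e": int(ev),
                        }
                    )
                truth_rows.append(
                    {
                        "segment_id": f"g{g + 1}.s3",
                        "species": sp,
                        "organ": organ,
                        "pattern": pattern,
                        "true_dpsi": 0.0 if pattern == "flat" else config.amplitude,
                    }
                )
    counts = pd.DataFrame(count_rows)
    truth_traj = pd.DataFrame(truth_rows)
    meta.drop(columns=["a"]).to_csv(os.path.join(outdir, "samples.tsv"), sep="\t", index=False)
    counts.to_csv(os.path.join(outdir, "counts.tsv"), sep="\t", index=False)

    # --- flanks with planted motif (per species) --------------------------
    fasta_lines = []
    flank_truth = []
    devas_genes = [m["segment_id"] for m in seg_meta if m["pattern"] == "up"]
    other_genes = [m["segment_id"] for m in seg_meta if m["pattern"] != "up"]
    for sp in species:
        t_seqs, b_seqs, t_flags, b_flags = plant_flank_motifs(
            len(devas_genes),
            len(other_genes),
            config.motif_hexamer,
            config.motif_target_frac,
            config.motif_background_frac,
            config.flank_length,
            rng,
        )
        for seg, seq, flag in zip(devas_genes, t_seqs, t_flags):
            fasta_lines.append(f">{sp}|{seg}|upstream\n{seq}")
            flank_truth.append(
                {"species": sp, "segment_id": seg, "group": "target", "planted": bool(flag)}
            )
        for seg, seq, flag in zip(other_genes, b_seqs, b_flags):
            fasta_lines.append(f">{sp}|{seg}|upstream\n{seq}")
            flank_truth.append(
                {"species": sp, "segment_id": seg, "group": "background", "planted": bool(flag)}
            )
    with open(os.path.join(outdir, "flanks.fa"), "w") as fh:
        fh.write("\n".join(fasta_lines) + "\n")

    # --- cross-species exon mappings (identical coordinates = perfect
    # orthology; occasional shifted mapping to exercise the IoU filter) ----
    map_rows = []
    for g in range(config.n_genes):
        off = 10_000 * g
        start, end = off + 400, off + 400 + ls
        shift = int(rng.integers(0, ls)) if g % 7 == 6 else 0  # break ~1/7 groups
        for sp in species:
            exon_id = f"{sp}:g{g + 1}.s3"
            for tsp in species:
                s = start + (shift if sp == species[-1] and tsp != sp else 0)
                map_rows.append(
                    {
                        "exon_id": exon_id,
                        "species": sp,
                        "target_species": tsp,
                        "chrom": "chr1",
                        "start": s,
                        "end": s + ls,
                    }
                )
    pd.DataFrame(map_rows).to_csv(
        os.path.join(outdir, "mappings.tsv"), sep="\t", index=False
    )

    # --- tree, PWM, TE intervals ------------------------------------------
    with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
        fh.write(DEFAULT_TREE_NEWICK + "\n")
    nuc_idx = {c: k for k, c in enumerate("ACGT")}
    with open(os.path.join(outdir, "motif.pwm"), "w") as fh:
        fh.write("Pos\tA\tC\tG\tU\n")
        for p, c in enumerate(config.motif_hexamer, start=1):
            row = [0.01, 0.01, 0.01, 0.01]
            row[nuc_idx[c]] = 0.97
            fh.write(f"{p}\t" + "\t".join(f"{v:.2f}" for v in row) + "\n")
    with open(os.path.join(outdir, "te.bed"), "w") as fh:
        for g in range(0, config.n_genes, 3):  # every third exon overlaps a TE
            off = 10_000 * g
            fh.write(f"chr1\t{off + 420}\t{off + 470}\tTE{g + 1}\n")

    # --- evolution / alternification scenarios ----------------------------
    tree = SpeciesTree()
    # clades whose complement is also a clade (the two root children) give
    # root-split-ambiguous patterns; keep planted events recoverable
    clade_pool = [c for c in tree.clades if (tree.leaves - c) not in tree.clades]
    evo_events: list[Optional[tuple[str, frozenset]]] = []
    for g in range(config.n_evo_groups):
        if g % 5 == 4:
            evo_events.append(None)
        else:
            clade = clade_pool[int(rng.integers(0, len(clade_pool)))]
            etype = "gain" if rng.random() < 0.7 else "loss"
            evo_events.append((etype, clade))
    pairs, regions, evo_truth = generate_evolution_scenario(tree, evo_events, rng)
    pd.DataFrame(evo_truth).to_csv(
        os.path.join(outdir, "truth_evolution.tsv"), sep="\t", index=False
    )

    alt_events: list[Optional[tuple[str, frozenset]]] = []
    for g in range(config.n_alternification_groups):
        if g % 5 == 4:
            alt_events.append(None)
        else:
            clade = clade_pool[int(rng.integers(0, len(clade_pool)))]
            alt_events.append(("gain" if rng.random() < 0.7 else "loss", clade))
    alt_tables, alt_truth = generate_alternification_scenario(tree, alt_events, rng)
    pd.DataFrame(alt_truth).to_csv(
        os.path.join(outdir, "truth_alternification.tsv"), sep="\t", index=False
    )

    truth_traj.to_csv(os.path.join(outdir, "truth_trajectories.tsv"), sep="\t", index=False)
    pd.DataFrame(flank_truth).to_csv(
        os.path.join(outdir, "truth_flanks.tsv"), sep="\t", index=False
    )

    return {
        "meta": meta,
        "counts": counts,
        "truth_trajectories": truth_traj,
        "truth_flanks": pd.DataFrame(flank_truth),
        "border_pairs": pairs,  # type: ignore[dict-item]
        "target_regions": regions,  # type: ignore[dict-item]
        "truth_evolution": pd.DataFrame(evo_truth),
        "alternification_tables": alt_tables,  # type: ignore[dict-item]
        "truth_alternification": pd.DataFrame(alt_truth),
    }
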