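"""Intronic hexamer enrichment and PWM motif annotation.

Hexamer enrichment compares 200-nt intronic flank sequences of devAS exons
against the remaining alternative exons with one-sided Fisher's exact
tests (presence/absence of the hexamer per flank), separately per species,
flank side and devAS direction.  Per-species p-values are combined with
the Irwin-Hall distribution (CDF of a sum of independent uniforms) and
BH-adjusted across the 4,096 hexamers within each side x direction
stratum.

Hexamers are linked to known RNA-binding motifs by the probability that a
PWM of length ``lm`` generates the hexamer at any offset ``o``::

    p(hex|motif) = 1 - prod_{o=1-lm}^{5} (1 - p_o)
    p_o = prod_j f_{j-o}(nt_j) * 0.25^m

where ``j`` runs over hexamer positions overlapping the motif at offset
``o`` and ``m`` counts the non-overlapping positions.  Per motif, every
hexamer whose probability is at least half the maximum over all 4,096
hexamers is annotated with that motif.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .glm import bh_adjust

__all__ = [
    "ALL_HEXAMERS",
    "PWM",
    "annotate_hexamers",
    "hexamer_fisher",
    "hexamer_presence_counts",
    "hexamer_scan",
    "irwin_hall_cdf",
    "irwin_hall_combine",
    "combined_enrichment",
    "positional_profile",
    "pwm_hexamer_prob",
    "read_pwm_file",
    "resampled_enrichment",
]

NUCS = "ACGT"
_NUC_INDEX = {c: i for i, c in enumerate(NUCS)}

#: The 4,096 hexamers over ACGT in lexicographic order.
ALL_HEXAMERS = tuple("".join(p) for p in itertools.product(NUCS, repeat=6))
_HEX_INDEX = {h: i for i, h in enumerate(ALL_HEXAMERS)}


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------

def hexamer_presence_counts(sequences: Iterable[str]) -> tuple[np.ndarray, int]:
    """Per-hexamer counts of sequences containing it; returns (counts, n)."""
    counts = np.zeros(len(ALL_HEXAMERS), dtype=np.int64)
    n = 0
    for seq in sequences:
        n += 1
        seq = seq.upper()
        seen = {seq[k : k + 6] for k in range(len(seq) - 5)}
        for h in seen:
            idx = _HEX_INDEX.get(h)
            if idx is not None:
                counts[idx] += 1
    return counts, n


def hexamer_fisher(
    target: Sequence[str], background: Sequence[str], hexamer: str
) -> float:
    """One-sided Fisher's exact p for enrichment of a hexamer in target flanks.

    The 2x2 table counts presence/absence of the hexamer per sequence.
    """
    if not target or not background:
        raise ValueError("target and background must be non-empty")
    t_with = sum(hexamer in s.upper() for s in target)
    b_with = sum(hexamer in s.upper() for s in background)
    table = [
        [t_with, len(target) - t_with],
        [b_with, len(background) - b_with],
    ]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def hexamer_scan(
    target: Sequence[str], background: Sequence[str]
) -> pd.Series:
    """One-sided Fisher p-values for all 4,096 hexamers (vectorized).

    Equivalent to :func:`hexamer_fisher` per hexamer, computed through the
    hypergeometric survival function.
    """
    if not target or not background:
        raise ValueError("target and background must be non-empty")
    tc, nt = hexamer_presence_counts(target)
    bc, nb = hexamer_presence_counts(background)
    total = nt + nb
    drawn = nt  # target sequences are the draws
    marked = tc + bc  # sequences containing the hexamer
    p = stats.hypergeom.sf(tc - 1, total, marked, drawn)
    return pd.Series(np.clip(p, 0.0, 1.0), index=list(ALL_HEXAMERS), name="p")


# ---------------------------------------------------------------------------
# Irwin-Hall combination
# ---------------------------------------------------------------------------

def irwin_hall_cdf(s: float, k: int) -> float:
    """Exact CDF of the sum of k independent Uniform(0,1) variables.

    Alternating-sum formula; valid for k up to a few dozen in double
    precision (k here is the number of species, <= 7).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if s <= 0:
        return 0.0
    if s >= k:
        return 1.0
    terms = [
        (-1.0) ** j * math.comb(k, j) * (s - j) ** k
        for j in range(int(math.floor(s)) + 1)
    ]
    val = math.fsum(terms) / math.factorial(k)
    return min(max(val, 0.0), 1.0)


def irwin_hall_combine(pvals: Sequence[float]) -> float:
    """Combine per-species p-values: Irwin-Hall CDF at their sum."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("at least one p-value required")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return irwin_hall_cdf(float(p.sum()), int(p.size))


def combined_enrichment(
    targets_by_species: Mapping[str, Sequence[str]],
    background_by_species: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Full enrichment scan for one flank-side x direction stratum.

    Runs :func:`hexamer_scan` per species, combines p-values across
    species with Irwin-Hall, and BH-adjusts the combined p-values across
    the 4,096 hexamers.
    """
    species = sorted(targets_by_species)
    if sorted(background_by_species) != species:
        raise ValueError("species sets of target and background differ")
    per_species = {
        sp: hexamer_scan(targets_by_species[sp], background_by_species[sp])
        for sp in species
    }
    df = pd.DataFrame({f"p_{sp}": per_species[sp] for sp in species})
    sums = df.to_numpy().sum(axis=1)
    k = len(species)
    df["p_combined"] = [irwin_hall_cdf(s, k) for s in sums]
    df["padj"] = bh_adjust(df["p_combined"].to_numpy())
    df.index.name = "hexamer"
    return df


def resampled_enrichment(
    target: Sequence[str],
    background: Sequence[str],
    hexamer: str,
    n_target: int,
    n_rep: int,
    seed: int,
) -> np.ndarray:
    """Robustness check: Fisher p over repeated target subsamples."""
    rng = np.random.default_rng(seed)
    target = list(target)
    out = np.empty(n_rep)
    for r in range(n_rep):
        idx = rng.choice(len(target), size=min(n_target, len(target)), replace=False)
        out[r] = hexamer_fisher([target[j] for j in idx], background, hexamer)
    return out


# ---------------------------------------------------------------------------
# PWM probability model
# ---------------------------------------------------------------------------

@dataclass
class PWM:
    """Position frequency matrix, rows = positions, columns = A, C, G, T."""

    motif_id: str
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != 4:
            raise ValueError("PWM must have shape (length, 4)")
        sums = self.freqs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: PWM columns must each sum to 1")

    @property
    def length(self) -> int:
        return self.freqs.shape[0]


def pwm_hexamer_prob(hexamer: str, pwm: PWM) -> float:
    """Probability that the motif generates the hexamer at any offset.

    Offsets run from ``1 - lm`` to 5; hexamer positions outside the motif
    contribute a 0.25 background factor each.  Hexamers containing N
    return 0.
    """
    hexamer = hexamer.upper().replace("U", "T")
    if len(hexamer) != 6:
        raise ValueError("hexamer must have length 6")
    if any(c not in _NUC_INDEX for c in hexamer):
        return 0.0
    lm = pwm.length
    miss = 1.0
    for o in range(1 - lm, 6):
        p_o = 1.0
        m = 0
        for j in range(1, 7):
            pos = j - o  # 1-based motif position
            if 1 <= pos <= lm:
                p_o *= pwm.freqs[pos - 1, _NUC_INDEX[hexamer[j - 1]]]
            else:
                m += 1
        p_o *= 0.25**m
        miss *= 1.0 - p_o
    return min(max(1.0 - miss, 0.0), 1.0)


def annotate_hexamers(
    pwms: Sequence[PWM], hexamers: Sequence[str] = ALL_HEXAMERS
) -> dict[str, list[str]]:
    """Annotate hexamers with motifs whose probability is >= half the max.

    Per PWM, the maximum generation probability over all candidate
    hexamers is found; every hexamer at or above half that maximum is
    tagged with the motif id.
    """
    annotations: dict[str, list[str]] = {h: [] for h in hexamers}
    for pwm in pwms:
        probs = {h: pwm_hexamer_prob(h, pwm) for h in hexamers}
        cutoff = max(probs.values()) / 2.0
        for h, p in probs.items():
            if p >= cutoff:
                annotations[h].append(pwm.motif_id)
    return annotations


def read_pwm_file(path: str, motif_id: Optional[str] = None) -> PWM:
    """Read a CISBP-style text PWM (columns Pos, A, C, G, U-or-T)."""
    rows = []
    with open(path) as fh:
        header = fh.readline().split()
        cols = [c.upper().replace("U", "T") for c in header[1:]]
        order = [cols.index(nt) for nt in NUCS]
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            vals = [float(x) for x in parts[1:]]
            rows.append([vals[i] for i in order])
    name = motif_id if motif_id is not None else path.rsplit("/", 1)[-1].split(".")[0]
    return PWM(motif_id=name, freqs=np.asarray(rows))


# ---------------------------------------------------------------------------
# Positional profile
# ---------------------------------------------------------------------------

def positional_profile(
    hexamer: str, flanks: Sequence[str], bin_width: int
) -> np.ndarray:
    """Histogram of hexamer match starts by distance from the splice site.

    Overlapping matches are counted at their start position.  Returns one
    count per ``bin_width``-nt bin over the flank length.
    """
    if bin_width < 1:
        raise ValueError("bin width must be >= 1")
    length = max((len(s) for s in flanks), default=0)
    if length < bin_width:
        raise ValueError("flank length must be >= bin width")
    n_bins = math.ceil(length / bin_width)
    counts = np.zeros(n_bins, dtype=np.int64)
    hexamer = hexamer.upper()
    for seq in flanks:
        seq = seq.upper()
        start = seq.find(hexamer)
        while start != -1:
            counts[start // bin_width] += 1
            start = seq.find(hexamer, start + 1)
    return counts
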