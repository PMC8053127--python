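"""MethScore computation from cleavage-end count tracks.

A 2'-O-methylated ribose blocks alkaline hydrolysis of the phosphodiester bond
3' of the modified nucleotide, so a methylated position shows a deficit of
cleavage ends relative to its neighbors.  The score for position i is

    S_i = 1 - n_i / (0.5 * (L_i + R_i))

where n_i is the combined end count at bond i and L_i, R_i are weighted
averages of end counts over the ``flank`` positions to the left and right,
with a tapering weight profile.  S_i approximates the methylation
stoichiometry: 1 for a fully protected bond, about 0 for unmethylated
positions, and negative where a site hydrolyzes faster than its neighborhood.
Negative scores are deliberately retained — they are needed for correct
between-sample score changes and methylation-level estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fragends import EndCountTrack
from .refdata import NmSite

#: Mask reason codes
END_REGION = "end_region"
LOW_COVERAGE = "low_coverage"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class ScoreConfig:
    """Tunables for MethScore computation.

    The neighbor taper ``weights`` (nearest first) is the main free parameter of
    the method; the default is a linear taper over +/-6 positions.  Twenty
    nucleotides at each RNA terminus are excluded because library end effects
    distort end counts there.  ``borrow_into_ends`` controls whether neighbor
    windows may reach into the excluded terminal regions; when they may not,
    truncated windows renormalize their weights over the available positions.
    """

    flank: int = 6
    weights: tuple[float, ...] = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5)
    end_exclusion: int = 20
    min_denominator: float = 10.0
    borrow_into_ends: bool = False

    def __post_init__(self) -> None:
        if len(self.weights) != self.flank:
            raise ValueError("weights length must equal flank")
        if any(w <= 0 for w in self.weights):
            raise ValueError("weights must be positive")
        if self.end_exclusion < 0:
            raise ValueError("end_exclusion must be >= 0")


@dataclass
class MethScoreTrack:
    """Per-position MethScores with mask reasons.

    ``scores[p]`` (1-based) is the score of nucleotide p, i.e. of the bond
    between p and p+1.  Masked positions hold NaN and a reason code in
    ``mask_reason``.  The source combined counts are kept for downstream
    artifact checks.
    """

    rna_id: str
    length: int
    scores: np.ndarray
    mask_reason: np.ndarray  # object array of '' or reason code, 1-based
    counts: np.ndarray  # combined end counts, 1-based

    def score_at(self, position: int) -> float:
        return float(self.scores[position])

    def is_masked(self, position: int) -> bool:
        return bool(self.mask_reason[position])

    @property
    def analyzable(self) -> np.ndarray:
        """1-based positions carrying a defined, unmasked score."""
        return np.flatnonzero(self.mask_reason[: self.length] == "")

    def to_dataframe(self, reference=None) -> pd.DataFrame:
        pos = np.arange(1, self.length)
        df = pd.DataFrame({
            "rna_id": self.rna_id,
            "position": pos,
            "score": self.scores[1:self.length],
            "masked": [bool(r) for r in self.mask_reason[1:self.length]],
            "reason": self.mask_reason[1:self.length],
        })
        if reference is not None:
            df.insert(2, "base", [reference.base(int(p)) for p in pos])
        return df


def _one_sided_weighted_mean(
    n: np.ndarray, valid: np.ndarray, weights: np.ndarray, direction: int
) -> np.ndarray:
    """Weighted mean of up to ``flank`` neighbors in one direction.

    ``n`` and ``valid`` are 1-based arrays over bond positions; neighbors whose
    ``valid`` flag is False are dropped and the weights renormalize over what
    remains.  Returns NaN where no neighbor is available.
    """
    size = n.shape[0]
    num = np.zeros(size)
    den = np.zeros(size)
    for d, w in enumerate(weights, start=1):
        shift = d * direction
        src = np.arange(size) + shift
        ok = (src >= 0) & (src < size)
        idx = np.clip(src, 0, size - 1)
        use = ok & valid[idx]
        num += np.where(use, w * n[idx], 0.0)
        den += np.where(use, w, 0.0)
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


def methscore_track(
    track: EndCountTrack, config: ScoreConfig = ScoreConfig()
) -> MethScoreTrack:
    """Compute the MethScore track for one RNA from its end-count track."""
    L = track.length
    if L < 2 * (config.flank + config.end_exclusion):
        raise ValueError(
            f"RNA of length {L} too short for flank={config.flank}, "
            f"end_exclusion={config.end_exclusion}"
        )
    n = track.combined.astype(float)  # 1-based, entries 1..L-1
    # Bond i sits between nucleotides i and i+1; excluding the terminal
    # end_exclusion nucleotides masks bonds i <= end_exclusion and
    # i > L - end_exclusion - 1.
    pos = np.arange(n.shape[0])
    in_range = (pos >= 1) & (pos <= L - 1)
    analyzed = in_range & (pos > config.end_exclusion) & (pos <= L - config.end_exclusion - 1)
    neighbor_pool = in_range if config.borrow_into_ends else analyzed

    w = np.asarray(config.weights, dtype=float)
    left = _one_sided_weighted_mean(n, neighbor_pool, w, direction=-1)
    right = _one_sided_weighted_mean(n, neighbor_pool, w, direction=+1)
    with np.errstate(invalid="ignore"):
        denom = 0.5 * (left + right)
        scores = 1.0 - n / denom

    mask = np.full(n.shape[0], "", dtype=object)
    mask[~analyzed] = END_REGION
    undef = analyzed & (np.isnan(denom) | (denom == 0))
    mask[undef] = UNDEFINED
    lowcov = analyzed & ~undef & (denom < config.min_denominator)
    mask[lowcov] = LOW_COVERAGE
    scores[mask != ""] = np.nan

    return MethScoreTrack(track.rna_id, L, scores, mask, track.combined)


def methylation_level(s_mod: float, s_unmod: float) -> float:
    """Methylation level from the scores of a modified and an unmodified state.

    (S_mod - S_unmod) / (1 - S_unmod); requires S_unmod < 1.
    """
    if s_unmod >= 1:
        raise ValueError("S_unmod must be < 1 (degenerate denominator)")
    return (s_mod - s_unmod) / (1.0 - s_unmod)


@dataclass
class ScoreDelta:
    """Per-site MethScore changes between two samples plus a paired test."""

    per_site: pd.DataFrame
    mean_delta: float
    t_statistic: float
    p_value: float  # one-tailed paired t-test, H1: mean delta > 0
    excluded: list[str] = field(default_factory=list)


def score_delta(
    track_a: MethScoreTrack,
    track_b: MethScoreTrack,
    sites: Sequence[NmSite],
) -> ScoreDelta:
    """Delta S = S_a - S_b at annotated sites (positive when a is more methylated).

    Sites masked in either track are excluded and listed.  The summary is the
    mean delta and a one-tailed paired t-test for mean delta > 0.
    """
    if (track_a.rna_id, track_a.length) != (track_b.rna_id, track_b.length):
        raise ValueError("score tracks are for different RNAs")
    rows, excluded = [], []
    for s in sites:
        if s.rna_id != track_a.rna_id:
            raise ValueError(f"site {s.label} not on {track_a.rna_id}")
        if track_a.is_masked(s.position) or track_b.is_masked(s.position):
            excluded.append(s.label)
            continue
        sa, sb = track_a.score_at(s.position), track_b.score_at(s.position)
        rows.append((s.rna_id, s.position, sa, sb, sa - sb))
    df = pd.DataFrame(rows, columns=["rna_id", "position", "score_a", "score_b", "delta"])
    if len(df) >= 2 and df["delta"].std(ddof=1) > 0:
        t, p = stats.ttest_rel(df["score_a"], df["score_b"], alternative="greater")
    else:
        t, p = float("nan"), float("nan")
    mean = float(df["delta"].mean()) if len(df) else float("nan")
    return ScoreDelta(df, mean, float(t), float(p), excluded)


def write_score_tsv(
    track: MethScoreTrack, path: str | Path, reference=None
) -> None:
    df = track.to_dataframe(reference)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)
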