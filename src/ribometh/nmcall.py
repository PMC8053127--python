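"""Nm site calling from MethScore tracks, plus coverage-reliability estimation.

Calling uses a fixed score threshold (default 0.8).  Sites scoring inside a
rescue window below the threshold can still be accepted when independent
evidence exists: an assigned guide snoRNA and a sufficient methylation loss in
a perturbation sample (e.g. a methyltransferase mutant).  Positions whose end
counts are highly uneven across the local window are flagged as likely
artifacts rather than silently removed.

Reliability is quantified by subsampling fragments to a grid of average end
counts (AEC = fragments / RNA length) and measuring the discovery rate
(TP/True) and precision (TP/Positive) of threshold calls against a truth set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .fragends import EndCountTrack, count_ends_arrays
from .methscore import MethScoreTrack, ScoreConfig, methscore_track
from .refdata import NmSite

logger = logging.getLogger(__name__)

CALLED = "called"
RESCUED = "rescued"
FLAGGED_ARTIFACT = "flagged_artifact"
REJECTED = "rejected"


@dataclass(frozen=True)
class CallConfig:
    """Thresholds for Nm calling.

    ``rescue_window`` is the half-open score interval [low, threshold) in which
    a site may be rescued by guide + perturbation evidence; ``rescue_delta`` is
    the minimum MethScore drop in the perturbation sample.  ``unevenness_cv_max``
    flags positions whose +/-flank end-count coefficient of variation exceeds
    the limit, automating the manual removal of uneven-coverage artifacts.
    """

    threshold: float = 0.8
    rescue_window: tuple[float, float] = (0.5, 0.8)
    rescue_delta: float = 0.1
    unevenness_cv_max: float = 3.0
    cv_flank: int = 6

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")
        if not self.rescue_window[0] < self.rescue_window[1] <= self.threshold:
            raise ValueError("rescue_window must lie below the threshold")


@dataclass
class NmCall:
    rna_id: str
    position: int
    score: float
    status: str
    evidence: list[str] = field(default_factory=list)


def _window_cv(counts: np.ndarray, position: int, flank: int, length: int) -> float:
    lo = max(1, position - flank)
    hi = min(length - 1, position + flank)
    window = counts[lo:hi + 1].astype(float)
    mean = window.mean()
    if mean == 0:
        return float("inf")
    return float(window.std(ddof=0) / mean)


def call_sites(
    score_track: MethScoreTrack,
    config: CallConfig = CallConfig(),
    guides_by_site: Optional[Mapping[int, Sequence[str]]] = None,
    perturbation_track: Optional[MethScoreTrack] = None,
) -> list[NmCall]:
    """Call Nm sites on one RNA.

    Candidates are unmasked positions scoring at or above the rescue-window
    floor.  S >= threshold gives ``called``; scores inside the rescue window
    give ``rescued`` when the position has an assigned guide and loses at least
    ``rescue_delta`` of score in the perturbation sample, ``rejected``
    otherwise.  Candidates with excessive end-count unevenness are
    ``flagged_artifact`` regardless of score.
    """
    guides_by_site = guides_by_site or {}
    calls: list[NmCall] = []
    for pos in score_track.analyzable:
        pos = int(pos)
        score = score_track.score_at(pos)
        if score < config.rescue_window[0]:
            continue
        cv = _window_cv(score_track.counts, pos, config.cv_flank, score_track.length)
        if cv > config.unevenness_cv_max:
            calls.append(NmCall(score_track.rna_id, pos, score, FLAGGED_ARTIFACT,
                                [f"count_cv={cv:.2f}"]))
            continue
        if score >= config.threshold:
            calls.append(NmCall(score_track.rna_id, pos, score, CALLED))
            continue
        # rescue path
        guides = list(guides_by_site.get(pos, ()))
        evidence, reasons = [], []
        if guides:
            evidence.append("guides=" + ";".join(guides))
        else:
            reasons.append("no_guide")
        delta = None
        if perturbation_track is not None and not perturbation_track.is_masked(pos):
            delta = score - perturbation_track.score_at(pos)
            if delta >= config.rescue_delta:
                evidence.append(f"perturbation_delta={delta:.3f}")
            else:
                reasons.append(f"perturbation_delta={delta:.3f}<{config.rescue_delta}")
        else:
            reasons.append("no_perturbation_evidence")
        if guides and delta is not None and delta >= config.rescue_delta:
            calls.append(NmCall(score_track.rna_id, pos, score, RESCUED, evidence))
        else:
            calls.append(NmCall(score_track.rna_id, pos, score, REJECTED, reasons))
    if not calls:
        logger.info("%s: no candidate positions above %.2f",
                    score_track.rna_id, config.rescue_window[0])
    return calls


def calls_to_dataframe(calls: Sequence[NmCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.rna_id, c.position, c.score, c.status, ";".join(c.evidence)) for c in calls],
        columns=["rna_id", "position", "score", "status", "evidence"],
    )


# ---------------------------------------------------------------------------
# Coverage reliability by fragment subsampling


@dataclass
class ReliabilityCurve:
    """Discovery rate and precision as a function of AEC.

    ``discovery`` = TP/True, ``precision`` = TP/Positive, averaged over
    replicates; NaN where a rate is undefined (0/0).  Per-replicate values are
    retained for dispersion estimates.
    """

    aec_grid: np.ndarray
    discovery: np.ndarray
    precision: np.ndarray
    discovery_reps: np.ndarray  # (n_reps, n_grid)
    precision_reps: np.ndarray
    n_reps: int
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "aec": self.aec_grid,
            "discovery_rate": self.discovery,
            "precision": self.precision,
        })


def subsample_reliability(
    starts: np.ndarray,
    ends: np.ndarray,
    rna_id: str,
    length: int,
    truth: Sequence[NmSite],
    aec_grid: Sequence[float],
    n_reps: int = 20,
    seed: int = 0,
    score_config: Optional[ScoreConfig] = None,
    call_config: CallConfig = CallConfig(),
) -> ReliabilityCurve:
    """Estimate call reliability at reduced coverage.

    For each target AEC, fragments are drawn without replacement to reach
    ``round(aec * length)`` fragments, the end-count track is rebuilt and
    scored, and positions with S >= threshold are called positive.  Rates are
    averaged over ``n_reps`` seeded replicates.

    Scoring here deliberately drops the ``min_denominator`` coverage floor
    (unless an explicit ``score_config`` is passed): the curve exists to
    expose the low-coverage failure mode — spurious high scores — that the
    floor would otherwise mask.
    """
    if score_config is None:
        score_config = ScoreConfig(min_denominator=0.0)
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    grid = np.asarray(sorted(aec_grid), dtype=float)
    truth_pos = {s.position for s in truth if s.rna_id == rna_id}
    n_avail = starts.size
    n_targets = np.rint(grid * length).astype(int)
    if n_targets.max(initial=0) > n_avail:
        raise ValueError(
            f"target AEC {grid.max()} needs {n_targets.max()} fragments, "
            f"only {n_avail} available"
        )
    rng = np.random.default_rng(seed)
    disc = np.full((n_reps, grid.size), np.nan)
    prec = np.full((n_reps, grid.size), np.nan)
    for rep in range(n_reps):
        perm = rng.permutation(n_avail)
        for gi, n_target in enumerate(n_targets):
            take = perm[:n_target]
            track = count_ends_arrays(rna_id, length, starts[take], ends[take])
            st = methscore_track(track, score_config)
            called = {
                int(p) for p in st.analyzable
                if st.scores[p] >= call_config.threshold
            }
            tp = len(called & truth_pos)
            if truth_pos:
                disc[rep, gi] = tp / len(truth_pos)
            if called:
                prec[rep, gi] = tp / len(called)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        return ReliabilityCurve(
            grid,
            np.nanmean(disc, axis=0),
            np.nanmean(prec, axis=0),
            disc, prec, n_reps, seed,
        )


def min_reliable_aec(
    curve: ReliabilityCurve, precision_floor: float = 0.9
) -> Optional[float]:
    """Smallest grid AEC whose mean precision reaches the floor (None if none)."""
    ok = np.flatnonzero(curve.precision >= precision_floor)
    if ok.size == 0:
        return None
    return float(curve.aec_grid[ok[0]])
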