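"""Leader-follower role inference and subjective-report reductions.

Objective roles are read from the asymmetry of directed information
flow: consistently positive per-trial TE(A->B) - TE(B->A) marks person A
as the leader.  The decision rule formalised here is a two-sided exact
sign test on the per-trial signs of the difference series; the verdict
is A_leads / B_leads when the test rejects with a matching median sign,
no_leader otherwise.

Subjective reports are reduced as in the study: each player's open
leadership answer is coded {1, 0, -1} = {I was leader, no leader at all,
partner was leader}; the two players' codes (and their Q1/Q2 Likert
ratings of help given/received) are subtracted and the sign taken.
Sign-reduced objective and subjective measures are then correlated with
an ordinary Pearson product-moment coefficient (ties retained).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .te import TEResult

__all__ = [
    "SubjectiveReport",
    "RoleCall",
    "te_difference_series",
    "classify_roles",
    "code_subjective",
    "last_third_objective_sign",
    "sign_correlation",
]

OPEN_ANSWER_CODES = (1, 0, -1)


@dataclass(frozen=True)
class SubjectiveReport:
    """One player's post-experiment report.

    open_answer_code: 1 = "I was leader", 0 = "there was no leader at
    all", -1 = "partner was leader" (free text is coded manually before
    it reaches this package).  q1: 1-7 rating of how much I helped my
    partner; q2: 1-7 rating of how much my partner helped me.
    """

    open_answer_code: int
    q1: int
    q2: int

    def __post_init__(self) -> None:
        if self.open_answer_code not in OPEN_ANSWER_CODES:
            raise ValueError("open_answer_code must be one of {1, 0, -1}")
        if not (1 <= self.q1 <= 7 and 1 <= self.q2 <= 7):
            raise ValueError("Likert ratings must lie in [1, 7]")


@dataclass
class RoleCall:
    """Verdict on a pair's leader-follower structure with its evidence."""

    pair_id: str
    verdict: str  # "A_leads", "B_leads", "no_leader"
    mean_diff: float
    sign_p: float
    n_trials: int
    seat_invariant: bool | None = None
    by_seating: dict = field(default_factory=dict)
    diff_series: np.ndarray | None = None


def te_difference_series(
    results: Sequence[TEResult], seat_aware: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, dict]:
    """Person-indexed per-trial TE difference series for one pair.

    Returns a frame with columns ``trial``, ``seat_of_A`` and
    ``diff_ab`` (person-indexed, so seat exchanges do not flip the
    sign by construction).  With ``seat_aware=True`` also returns the
    seating-subset breakdown: the two subset mean differences and
    whether their person-indexed signs agree ("seat invariance": player
    A transfers more entropy than player B regardless of the seat).
    """
    if not results:
        raise ValueError("no TE results given")
    pair_ids = {r.pair_id for r in results}
    if len(pair_ids) > 1:
        raise ValueError(f"results mix pairs {sorted(pair_ids)}")
    rows = sorted(results, key=lambda r: r.trial_index)
    frame = pd.DataFrame(
        {
            "trial": [r.trial_index for r in rows],
            "seat_of_A": [r.seat_of_player_A for r in rows],
            "diff_ab": [r.diff_ab for r in rows],
        }
    )
    if not seat_aware:
        return frame
    subsets = {}
    for seat, g in frame.groupby("seat_of_A"):
        subsets[seat] = {
            "trials": g["trial"].tolist(),
            "mean_diff": float(g["diff_ab"].mean()),
            "sign": int(np.sign(g["diff_ab"].mean())),
        }
    signs = {s["sign"] for s in subsets.values() if s["sign"] != 0}
    seat_invariant = len(signs) <= 1 if len(subsets) > 1 else True
    return frame, {"subsets": subsets, "seat_invariant": seat_invariant}


def classify_roles(
    diff_series, alpha: float = 0.05, pair_id: str = "?"
) -> RoleCall:
    """Two-sided exact sign test on the per-trial TE-difference signs.

    Zero differences are uninformative and dropped from the test; a pair
    with all-zero differences (or too few informative trials to ever
    reject) is called no_leader.
    """
    if isinstance(diff_series, pd.DataFrame):
        frame = diff_series
        diffs = frame["diff_ab"].to_numpy(dtype=float)
        seat_info = None
        if frame["seat_of_A"].nunique() > 1:
            signs_by_seat = {
                seat: int(np.sign(g["diff_ab"].mean()))
                for seat, g in frame.groupby("seat_of_A")
            }
            nz = {s for s in signs_by_seat.values() if s != 0}
            seat_info = len(nz) <= 1
    else:
        diffs = np.asarray(diff_series, dtype=float)
        seat_info = None
    n_trials = len(diffs)
    if n_trials == 0:
        raise ValueError("empty difference series")
    signs = np.sign(diffs)
    n_pos = int((signs > 0).sum())
    n_neg = int((signs < 0).sum())
    n_eff = n_pos + n_neg
    if n_eff == 0:
        return RoleCall(pair_id=pair_id, verdict="no_leader", mean_diff=0.0,
                        sign_p=1.0, n_trials=n_trials, seat_invariant=seat_info,
                        diff_series=diffs)
    p = stats.binomtest(n_pos, n_eff, 0.5, alternative="two-sided").pvalue
    if p <= alpha and n_pos != n_neg:
        verdict = "A_leads" if n_pos > n_neg else "B_leads"
    else:
        verdict = "no_leader"
    return RoleCall(
        pair_id=pair_id,
        verdict=verdict,
        mean_diff=float(diffs.mean()),
        sign_p=float(p),
        n_trials=n_trials,
        seat_invariant=seat_info,
        diff_series=diffs,
    )


def code_subjective(report_A: SubjectiveReport, report_B: SubjectiveReport) -> dict:
    """Sign-reduced between-player differences of the subjective measures.

    Antisymmetric by construction: swapping the two reports flips every
    sign.  Ties (sign 0) are retained.
    """
    return {
        "open_sign": int(np.sign(report_A.open_answer_code - report_B.open_answer_code)),
        "q1_sign": int(np.sign(report_A.q1 - report_B.q1)),
        "q2_sign": int(np.sign(report_A.q2 - report_B.q2)),
    }


def last_third_objective_sign(diff_series) -> int:
    """Sign of the mean TE difference over the final third of the trials.

    The subjective questionnaire is answered once, at the end of the
    experiment; the last ceil(T/3) trials are taken as representative of
    the coordination state the ratings refer to (15 trials -> trials
    11-15; 30 trials -> trials 21-30).
    """
    if isinstance(diff_series, pd.DataFrame):
        diffs = diff_series.sort_values("trial")["diff_ab"].to_numpy(dtype=float)
    else:
        diffs = np.asarray(diff_series, dtype=float)
    if len(diffs) == 0:
        raise ValueError("empty difference series")
    n_last = math.ceil(len(diffs) / 3)
    return int(np.sign(diffs[-n_last:].mean()))


def sign_correlation(obj_signs: Sequence[int], subj_signs: Sequence[int]) -> dict:
    """Pearson correlation between two per-pair sign vectors.

    Returns r, the two-sided p-value from the t transform, and the 95%
    Fisher-z confidence interval.  Requires >= 5 pairs and non-degenerate
    variance in both vectors.
    """
    x = np.asarray(obj_signs, dtype=float)
    y = np.asarray(subj_signs, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("sign vectors must be one-dimensional and equal-length")
    if len(x) < 5:
        raise ValueError("need at least 5 pairs")
    bad = set(np.unique(x)) | set(np.unique(y))
    if not bad <= {-1.0, 0.0, 1.0}:
        raise ValueError("inputs must be sign-reduced to {-1, 0, 1}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a sign vector; correlation undefined")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    n = len(x)
    if abs(r) < 1.0:
        z = np.arctanh(r)
        half = 1.959963984540054 / math.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    else:
        ci = (r, r)
    return {"r": r, "p": float(res.pvalue), "ci95": ci, "n": n}
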