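"""Surrogate-data significance testing of transfer-entropy values.

The observed TE of a trial is compared against a null distribution in
which the putative coupling is destroyed while each signal's marginal
dynamics are preserved.  The primary scheme re-pairs the source channel
with the same-role channel of a different, independently recorded dyad
("cross pairing", 1,000 random pairings per TE value by default); a
secondary block-shuffle scheme (cyclic rotation of the source by at
least 10 s) supports single-dyad use.  Empirical p-values use the
add-one rule p = (1 + #{null >= observed}) / (n_surrogates + 1), so
p = 0 never occurs.

Per-trial cohort significance follows the study's recipe: the per-pair
surrogate p-values of a trial are tested with a one-sample Wilcoxon
signed-rank test against the constant 0.05 (one-sided: values below the
conventional significance level), and the per-trial test p-values are
Bonferroni-Holm corrected across trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import EstimatorConfig, embed, resolve_channels
from .te import te_ksg
from .trial import DyadTrial

__all__ = [
    "SurrogateResult",
    "TrialSignificance",
    "surrogate_null",
    "wilcoxon_vs_threshold",
    "holm_adjust",
    "per_trial_significance",
]

DEFAULT_N_SURROGATES = 1000

#: minimum cyclic rotation for the block-shuffle scheme (seconds)
MIN_SHIFT_S = 10.0

#: minimum usable sample count after trimming donor/target to common length
MIN_COMMON_SAMPLES = 1000


@dataclass
class SurrogateResult:
    """Null TE distribution and empirical p-value for one directional TE."""

    observed_te: float
    null_te: np.ndarray
    p_value: float
    scheme: str
    direction: str
    seed: int
    pair_id: str = "?"
    trial_index: int = 0

    @property
    def n_surrogates(self) -> int:
        return len(self.null_te)


@dataclass
class TrialSignificance:
    """Cohort-level significance of one trial index."""

    trial_index: int
    raw_p: float
    adjusted_p: float
    significant: bool
    n_pairs: int


def _direction_series(trial: DyadTrial, direction: str):
    """(source, target) person series for a direction label 'A->B' / 'B->A'."""
    a, b = resolve_channels(trial)
    if direction in ("A->B", "ab"):
        return a, b
    if direction in ("B->A", "ba"):
        return b, a
    raise ValueError(f"unknown direction {direction!r}")


def surrogate_null(
    target_trial: DyadTrial,
    donor_pool: Sequence[DyadTrial],
    direction: str = "A->B",
    n_surrogates: int = DEFAULT_N_SURROGATES,
    config: EstimatorConfig | None = None,
    seed: int = 0,
    scheme: str = "cross_pairing",
) -> SurrogateResult:
    """Null TE distribution for one directional TE of one trial.

    cross_pairing: for each surrogate the source channel is replaced by
    the same-role channel of a uniformly drawn *different* dyad (same
    trial index when available, any trial of that dyad otherwise) and TE
    is recomputed with identical settings.  Donors are drawn with
    replacement across surrogates.  block_shuffle: the source is rotated
    cyclically by a random offset of at least 10 s.
    """
    if config is None:
        config = EstimatorConfig()
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    rng = np.random.default_rng(seed)

    source, target = _direction_series(target_trial, direction)
    observed = te_ksg(embed(source, target, config), config)

    null = np.empty(n_surrogates)
    if scheme == "cross_pairing":
        donors = [t for t in donor_pool if t.pair_id != target_trial.pair_id]
        if not donors:
            raise ValueError("donor pool contains no other dyads")
        by_pair: dict[str, list[DyadTrial]] = {}
        for t in donors:
            by_pair.setdefault(t.pair_id, []).append(t)
        pair_ids = sorted(by_pair)
        for s in range(n_surrogates):
            pid = pair_ids[rng.integers(len(pair_ids))]
            same_index = [t for t in by_pair[pid] if t.trial_index == target_trial.trial_index]
            pool = same_index if same_index else by_pair[pid]
            donor = pool[rng.integers(len(pool))]
            donor_source, _ = _direction_series(donor, direction)
            n_common = min(len(donor_source), len(target))
            if n_common < MIN_COMMON_SAMPLES:
                raise ValueError(
                    f"only {n_common} common samples between target and donor "
                    f"{donor.pair_id}; need >= {MIN_COMMON_SAMPLES}"
                )
            null[s] = te_ksg(
                embed(donor_source[:n_common], target[:n_common], config), config
            )
    elif scheme == "block_shuffle":
        min_shift = int(MIN_SHIFT_S * target_trial.sample_rate)
        n = len(source)
        if n <= 2 * min_shift:
            raise ValueError("trial too short for a >= 10 s cyclic rotation")
        for s in range(n_surrogates):
            shift = int(rng.integers(min_shift, n - min_shift))
            null[s] = te_ksg(embed(np.roll(source, shift), target, config), config)
    else:
        raise ValueError(f"unknown surrogate scheme {scheme!r}")

    p = (1 + int(np.sum(null >= observed))) / (n_surrogates + 1)
    return SurrogateResult(
        observed_te=observed,
        null_te=null,
        p_value=p,
        scheme=scheme,
        direction=direction,
        seed=seed,
        pair_id=target_trial.pair_id,
        trial_index=target_trial.trial_index,
    )


def _exact_signed_rank_cdf_p(ranks: np.ndarray, w_obs: float) -> float:
    """P(W+ <= w_obs) for signed ranks under the symmetric null.

    Exact by characteristic-polynomial convolution: W+ is the sum of an
    independent fair coin per rank.  Mid-ranks (halves) are handled by
    doubling all ranks to integers.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    w2 = int(np.floor(np.rint(2 * w_obs * 1e9) / 1e9))  # guard fp noise
    w2 = min(max(w2, -1), total)
    return float(dist[: w2 + 1].sum()) if w2 >= 0 else 0.0


def wilcoxon_vs_threshold(
    values: Sequence[float],
    threshold: float = 0.05,
    alternative: str = "less",
    exact_max_n: int = 25,
) -> float:
    """One-sample Wilcoxon signed-rank test of ``values`` against a constant.

    The study compares each trial's surrogate p-values against the
    conventional significance level 0.05, one-sided (values below the
    threshold).  Zero differences are dropped; ties are mid-ranked.  The
    null distribution is exact for n <= ``exact_max_n`` (by convolution
    over the observed signed ranks) and a continuity-corrected normal
    approximation above.
    """
    if alternative not in ("less", "greater", "two-sided"):
        raise ValueError("alternative must be 'less', 'greater' or 'two-sided'")
    d = np.asarray(values, dtype=float) - threshold
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise ValueError("all values equal the threshold; test undefined")
    if n < 5:
        raise ValueError(f"need >= 5 non-tied values, got {n}")
    ranks = stats.rankdata(np.abs(d))  # mid-ranks for ties
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_max_n:
        p_less = _exact_signed_rank_cdf_p(ranks, w_plus)
        total = float(ranks.sum())
        p_greater = _exact_signed_rank_cdf_p(ranks, total - w_plus)
    else:
        mu = n * (n + 1) / 4.0
        # tie-corrected variance of W+
        sigma2 = float(np.sum(ranks**2)) / 4.0
        z_less = (w_plus - mu + 0.5) / np.sqrt(sigma2)
        z_greater = (-(w_plus - mu) + 0.5) / np.sqrt(sigma2)
        p_less = float(stats.norm.cdf(z_less))
        p_greater = float(stats.norm.cdf(z_greater))

    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return float(min(1.0, 2.0 * min(p_less, p_greater)))


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values, in the input order.

    adjusted(i) = max_{j <= i} min(1, (m - j) * p_(j)) along the
    ascending sort (0-based j), which makes rejection at any level alpha
    equivalent to the classic sequential Holm procedure.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted_sorted = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adjusted_sorted = np.maximum.accumulate(adjusted_sorted)
    out = np.empty_like(p)
    out[order] = adjusted_sorted
    return out


def per_trial_significance(
    p_values_by_trial: Mapping[int, Sequence[float]] | pd.DataFrame,
    alpha: float = 0.05,
    threshold: float = 0.05,
    alternative: str = "less",
) -> list[TrialSignificance]:
    """Cohort-level significance per trial index, Holm-corrected.

    ``p_values_by_trial`` maps each trial index to the per-pair surrogate
    p-values of that trial (or is a DataFrame with columns ``trial`` and
    ``p_value``).  Each trial's values are Wilcoxon-tested against the
    0.05 constant, and the per-trial test p-values are Holm-adjusted
    across trials before flagging at ``alpha``.
    """
    if isinstance(p_values_by_trial, pd.DataFrame):
        grouped = {
            int(t): g["p_value"].to_numpy()
            for t, g in p_values_by_trial.groupby("trial")
        }
    else:
        grouped = {int(t): np.asarray(v, dtype=float) for t, v in p_values_by_trial.items()}
    if not grouped:
        raise ValueError("no trials given")
    trials = sorted(grouped)
    raw = [
        wilcoxon_vs_threshold(grouped[t], threshold=threshold, alternative=alternative)
        for t in trials
    ]
    adj = holm_adjust(raw)
    return [
        TrialSignificance(
            trial_index=t,
            raw_p=float(r),
            adjusted_p=float(a),
            significant=bool(a <= alpha),
            n_pairs=len(grouped[t]),
        )
        for t, r, a in zip(trials, raw, adj)
    ]
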