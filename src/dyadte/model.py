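"""Model-style facade over the analysis pipeline.

``DyadCoordinationModel`` bundles a cohort of trials with an estimator
configuration; ``fit()`` runs the per-trial transfer-entropy and
tracking-error computations and returns a ``CoordinationResults`` object
carrying the per-trial table, role calls, learning curve and summary,
with surrogate significance testing and subjective-report correlation
available as methods on the results.

    >>> trials, truth = simulate_experiment(ExperimentSchedule.design_A(6, seed=1))
    >>> res = DyadCoordinationModel(trials).fit()
    >>> print(res.summary())
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import EstimatorConfig, discard_initialization
from .performance import TrialPerformance, error_vs_coordination, trial_error
from .report import condition_contrast, learning_curve
from .roles import (
    RoleCall,
    SubjectiveReport,
    classify_roles,
    code_subjective,
    last_third_objective_sign,
    sign_correlation,
    te_difference_series,
)
from .surrogates import (
    DEFAULT_N_SURROGATES,
    per_trial_significance,
    surrogate_null,
)
from .te import TEResult, results_to_frame, te_both_directions
from .trial import DyadTrial

__all__ = ["DyadCoordinationModel", "CoordinationResults"]


class DyadCoordinationModel:
    """Directed-coupling analysis of a cohort of dyadic trials.

    Parameters
    ----------
    trials : sequence of DyadTrial
        Raw trial recordings (the initialization discard is applied here).
    config : EstimatorConfig, optional
        Estimator settings; defaults to m = n = 1, k = 4, 500-sample
        discard, bits.
    subjective : mapping pair_id -> (SubjectiveReport, SubjectiveReport), optional
        Post-experiment reports of persons A and B per pair.
    """

    def __init__(
        self,
        trials: Sequence[DyadTrial],
        config: EstimatorConfig | None = None,
        subjective: Mapping[str, tuple[SubjectiveReport, SubjectiveReport]] | None = None,
    ) -> None:
        if not trials:
            raise ValueError("no trials given")
        self.config = config or EstimatorConfig()
        self.raw_trials = list(trials)
        self.trials = [
            discard_initialization(t, self.config.discard_samples) for t in self.raw_trials
        ]
        self.subjective = dict(subjective) if subjective else {}

    def fit(self, compute_performance: bool = True) -> "CoordinationResults":
        """Estimate directional TE (and tracking error) for every trial."""
        te_results = [te_both_directions(t, self.config) for t in self.trials]
        performances = (
            [trial_error(t) for t in self.trials] if compute_performance else []
        )
        return CoordinationResults(self, te_results, performances)


class CoordinationResults:
    """Fitted per-trial estimates plus cohort-level derived quantities."""

    def __init__(
        self,
        model: DyadCoordinationModel,
        te_results: list[TEResult],
        performances: list[TrialPerformance],
    ) -> None:
        self.model = model
        self.config = model.config
        self.te_results = te_results
        self.performances = performances
        self.te_table = results_to_frame(te_results)

    # -- grouping helpers ---------------------------------------------------

    def _by_pair(self) -> dict[str, list[TEResult]]:
        by: dict[str, list[TEResult]] = {}
        for r in self.te_results:
            by.setdefault(r.pair_id, []).append(r)
        return by

    # -- cohort views -------------------------------------------------------

    def learning_curve(self) -> pd.DataFrame:
        return learning_curve(self.te_results)

    def condition_contrast(self) -> pd.DataFrame:
        return condition_contrast(self.te_results)

    def role_calls(self, alpha: float = 0.05) -> list[RoleCall]:
        """Leader-follower verdict per pair (exact sign test on diffs)."""
        calls = []
        for pair_id, results in sorted(self._by_pair().items()):
            series = te_difference_series(results)
            calls.append(classify_roles(series, alpha=alpha, pair_id=pair_id))
        return calls

    def roles_table(self, alpha: float = 0.05) -> pd.DataFrame:
        rows = []
        for call in self.role_calls(alpha=alpha):
            row = {
                "pair_id": call.pair_id,
                "verdict": call.verdict,
                "mean_diff_bits": call.mean_diff,
                "sign_p": call.sign_p,
                "seat_invariant": call.seat_invariant,
            }
            reports = self.model.subjective.get(call.pair_id)
            if reports is not None:
                row.update(code_subjective(*reports))
            rows.append(row)
        return pd.DataFrame(rows)

    def significance(
        self,
        n_surrogates: int = DEFAULT_N_SURROGATES,
        seed: int = 0,
        alpha: float = 0.05,
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Surrogate p-values per trial x direction, plus per-trial Wilcoxon.

        Sources are re-paired across dyads (cross pairing); each observed
        TE gets ``n_surrogates`` null values.  Returns the per-trial
        surrogate table and the Holm-corrected cohort significance table.
        """
        trials = self.model.trials
        rows = []
        rng = np.random.default_rng(seed)
        for trial in trials:
            for direction in ("A->B", "B->A"):
                sub_seed = int(rng.integers(2**31 - 1))
                res = surrogate_null(
                    trial, trials, direction=direction,
                    n_surrogates=n_surrogates, config=self.config, seed=sub_seed,
                )
                rows.append(
                    {
                        "pair_id": res.pair_id,
                        "trial": res.trial_index,
                        "direction": direction,
                        "observed_te": res.observed_te,
                        "p_value": res.p_value,
                        "n_surrogates": res.n_surrogates,
                    }
                )
        surro = pd.DataFrame(rows)
        per_trial = per_trial_significance(surro, alpha=alpha)
        per_trial_df = pd.DataFrame(
            [
                {
                    "trial": s.trial_index,
                    "raw_p": s.raw_p,
                    "adjusted_p": s.adjusted_p,
                    "significant": s.significant,
                    "n_pairs": s.n_pairs,
                }
                for s in per_trial
            ]
        )
        return surro, per_trial_df

    def sign_correlations(self) -> pd.DataFrame:
        """Correlate last-third objective TE-difference signs with the
        sign-reduced subjective measures, per questionnaire item."""
        if not self.model.subjective:
            raise ValueError("no subjective reports attached to the model")
        obj, subj = [], []
        for pair_id, results in sorted(self._by_pair().items()):
            reports = self.model.subjective.get(pair_id)
            if reports is None:
                continue
            series = te_difference_series(results)
            obj.append(last_third_objective_sign(series))
            subj.append(code_subjective(*reports))
        rows = []
        for item in ("open_sign", "q1_sign", "q2_sign"):
            svec = [s[item] for s in subj]
            try:
                stats = sign_correlation(obj, svec)
                rows.append({"item": item, **{k: stats[k] for k in ("r", "p", "n")},
                             "ci95_lo": stats["ci95"][0], "ci95_hi": stats["ci95"][1]})
            except ValueError as err:
                rows.append({"item": item, "r": np.nan, "p": np.nan, "n": len(svec),
                             "ci95_lo": np.nan, "ci95_hi": np.nan, "note": str(err)})
        return pd.DataFrame(rows)

    def performance_table(self) -> pd.DataFrame:
        return pd.DataFrame([p.to_row() for p in self.performances])

    def error_vs_te(self, n_bins: int = 5) -> tuple[pd.DataFrame, pd.DataFrame]:
        return error_vs_coordination(self.performances, self.te_results, n_bins=n_bins)

    # -- presentation -------------------------------------------------------

    def summary(self, alpha: float = 0.05) -> str:
        """Plain-text cohort summary in the spirit of a model results table."""
        frame = self.te_table
        c = self.config
        lines = []
        lines.append("Dyadic coordination transfer-entropy analysis")
        lines.append("=" * 54)
        lines.append(
            f"pairs: {frame['pair_id'].nunique():>4}    trials/pair: "
            f"{frame.groupby('pair_id').size().max():>3}    samples/trial: "
            f"{int(frame['n_used'].median())}"
        )
        lines.append(
            f"estimator: KSG k={c.k}, histories m={c.m}, n={c.n}, "
            f"delay={c.delay}, units={c.units}, discard={c.discard_samples}"
        )
        lines.append("-" * 54)
        lines.append(
            f"mean total TE        {frame['total_bits'].mean():8.4f} bits "
            f"(SD {frame['total_bits'].std(ddof=1):.4f})"
        )
        lines.append(
            f"mean |TE asymmetry|  {frame['diff_bits'].abs().mean():8.4f} bits"
        )
        curve = self.learning_curve()
        lines.append(
            f"learning: trial 1 total {curve['mean_total_bits'].iloc[0]:.4f} -> "
            f"final trial {curve['mean_total_bits'].iloc[-1]:.4f} bits"
        )
        lines.append("-" * 54)
        lines.append(f"{'pair':8} {'verdict':10} {'mean diff':>10} {'sign p':>9}")
        for call in self.role_calls(alpha=alpha):
            lines.append(
                f"{call.pair_id:8} {call.verdict:10} {call.mean_diff:10.4f} "
                f"{call.sign_p:9.4f}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<CoordinationResults: {self.te_table['pair_id'].nunique()} pairs, "
            f"{len(self.te_results)} trials>"
        )
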