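"""Per-subject summaries and exact binomial significance tests.

Each participant's rate of reporting the illusion (a two-target report on
an experimental trial) is compared against an error baseline with a
one-sided exact binomial test.  The baseline is the group's pooled
commission-error rate on catch trials where the design has them, and the
pooled omission-error rate otherwise.  The count of individually
significant participants feeds the population-prevalence posterior (see
:mod:`splitprev.prevalence`); no multiple-testing correction is applied
because the prevalence framework consumes raw per-test outcomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .designs import StudyDesign
from .observers import counts_from_trials

__all__ = [
    "BaselineSpec",
    "binomial_test_one_sided",
    "summarize_subjects",
    "summaries_from_counts",
    "pooled_baseline_rate",
    "flag_significant",
]

OVERALL = -1  # level_index sentinel for the across-levels row


@dataclass(frozen=True)
class BaselineSpec:
    """How the per-subject null probability is formed.

    kind
        ``commission`` (catch-trial error) or ``omission`` (reporting 0
        when one target was flashed).
    pooling
        ``pooled``: one baseline rate across all participants (total
        errors / total baseline trials); ``per_participant``: each
        subject tested against their own error rate.
    rate_method
        ``trial_weighted`` (default): total errors over total baseline
        trials.  ``mean_of_rates``: unweighted mean of per-subject rates;
        identical when all subjects have equal baseline trial counts, but
        kept distinct because the two readings differ on unbalanced data.
    alpha
        Per-test significance level.
    """

    kind: str = "commission"
    pooling: str = "pooled"
    rate_method: str = "trial_weighted"
    alpha: float = 0.05

    def __post_init__(self):
        if self.kind not in ("commission", "omission"):
            raise ValueError(f"kind must be 'commission' or 'omission', "
                             f"got {self.kind!r}")
        if self.pooling not in ("pooled", "per_participant"):
            raise ValueError(f"pooling must be 'pooled' or 'per_participant', "
                             f"got {self.pooling!r}")
        if self.rate_method not in ("trial_weighted", "mean_of_rates"):
            raise ValueError(f"unknown rate_method {self.rate_method!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    @classmethod
    def for_design(cls, design: StudyDesign, **kw) -> "BaselineSpec":
        return cls(kind=design.baseline_kind, **kw)


def binomial_test_one_sided(k: int, n: int, p0: float) -> float:
    """Exact one-sided (upper-tail) binomial p-value, P(X >= k | n, p0).

    The limiting case ``p0 == 0`` with ``k > 0`` has p-value 0; a warning
    is emitted because a zero baseline usually means the error rate could
    not be estimated (e.g. no errors observed in a small simulation).
    """
    k, n = int(k), int(n)
    if n < 0 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must be in [0, 1], got {p0}")
    if p0 == 0.0:
        if k > 0:
            warnings.warn("baseline rate is exactly 0 with k > 0; "
                          "p-value is the 0 limit", stacklevel=2)
            return 0.0
        return 1.0
    return float(stats.binom.sf(k - 1, n, p0))


def summarize_subjects(trials: pd.DataFrame, design: StudyDesign,
                       commission_counts: str = "any_report") -> pd.DataFrame:
    """Per-participant counts and percentage rates, per level and overall.

    One row per (participant, level) plus one overall row per participant
    (``level_index == -1``).  Rates are percentages in [0, 100]:
    ``pct_report2`` of experimental trials with a two-target report,
    ``pct_commission`` of catch trials with a reported target, and
    ``pct_omission`` of experimental trials with a zero report.
    """
    counts = counts_from_trials(trials, commission_counts=commission_counts)
    return summaries_from_counts(counts, design)


def summaries_from_counts(counts: pd.DataFrame,
                          design: StudyDesign) -> pd.DataFrame:
    """Build the summary table from per-(participant, level) counts."""
    zero_exp = counts.groupby("participant_id")["n_experimental"].sum()
    bad = zero_exp.index[zero_exp == 0].tolist()
    if bad:
        raise ValueError("participant(s) with zero experimental trials: "
                         + ", ".join(map(str, bad)))

    per_level = counts.copy()
    overall = counts.groupby("participant_id", as_index=False)[
        ["n_experimental", "n_report2", "n_omission", "n_catch", "n_commission"]
    ].sum()
    overall.insert(1, "level_index", OVERALL)
    out = pd.concat([per_level, overall], ignore_index=True)

    with np.errstate(divide="ignore", invalid="ignore"):
        out["pct_report2"] = 100.0 * out["n_report2"] / out["n_experimental"]
        out["pct_omission"] = 100.0 * out["n_omission"] / out["n_experimental"]
        out["pct_commission"] = np.where(
            out["n_catch"] > 0,
            100.0 * out["n_commission"] / out["n_catch"].replace(0, 1),
            np.nan)

    values = design.primary_values()
    lv = out["level_index"].to_numpy()
    out[design.primary_factor] = np.where(
        lv == OVERALL, np.nan, values[np.clip(lv, 0, design.n_levels - 1)])
    return out.sort_values(["participant_id", "level_index"], ignore_index=True)


def pooled_baseline_rate(summaries: pd.DataFrame, spec: BaselineSpec) -> float:
    """Group baseline error rate as a proportion in [0, 1]."""
    overall = summaries[summaries["level_index"] == OVERALL]
    if spec.kind == "commission":
        k, n = overall["n_commission"], overall["n_catch"]
    else:
        k, n = overall["n_omission"], overall["n_experimental"]
    if n.sum() == 0:
        raise ValueError(f"no baseline trials for kind={spec.kind!r}")
    if spec.rate_method == "mean_of_rates":
        with np.errstate(divide="ignore", invalid="ignore"):
            rates = (k / n).to_numpy(dtype=float)
        return float(np.nanmean(rates))
    return float(k.sum() / n.sum())


def _per_participant_rates(summaries: pd.DataFrame,
                           spec: BaselineSpec) -> pd.Series:
    overall = summaries[summaries["level_index"] == OVERALL].set_index(
        "participant_id")
    if spec.kind == "commission":
        return overall["n_commission"] / overall["n_catch"]
    return overall["n_omission"] / overall["n_experimental"]


def flag_significant(summaries: pd.DataFrame, spec: BaselineSpec,
                     per_level: bool = False):
    """Run the one-sided binomial test for every participant.

    Parameters
    ----------
    summaries
        Output of :func:`summarize_subjects`.
    spec
        Baseline specification (error kind, pooling, alpha).
    per_level
        If true, additionally test within each condition level, reusing
        the overall pooled baseline rate, for per-condition prevalence
        curves.

    Returns
    -------
    (table, k_sig, n)
        ``table`` has one row per participant (and per level if
        requested) with columns ``participant_id, level_index, k, n, p0,
        p_value, significant``; ``k_sig`` and ``n`` count significant and
        total participants on the overall test.
    """
    p0_pooled = pooled_baseline_rate(summaries, spec)
    own = _per_participant_rates(summaries, spec) if spec.pooling == "per_participant" else None

    rows = summaries if per_level else summaries[summaries["level_index"] == OVERALL]
    recs = []
    for _, r in rows.iterrows():
        p0 = float(own[r["participant_id"]]) if own is not None else p0_pooled
        p = binomial_test_one_sided(int(r["n_report2"]),
                                    int(r["n_experimental"]), p0)
        recs.append({
            "participant_id": r["participant_id"],
            "level_index": int(r["level_index"]),
            "k": int(r["n_report2"]),
            "n": int(r["n_experimental"]),
            "p0": p0,
            "p_value": p,
            "significant": p < spec.alpha,
        })
    table = pd.DataFrame.from_records(recs)
    overall = table[table["level_index"] == OVERALL]
    return table, int(overall["significant"].sum()), int(len(overall))
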