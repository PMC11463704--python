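"""Generative model of illusion-report data.

The population is a two-component mixture: a fraction ``gamma`` of
*perceivers*, whose probability of reporting two targets rises with the
condition value (frame speed or flash opacity) through a logistic link,
and *non-perceivers*, who report two targets only at their own
commission-error rate.  Every subject also has a commission rate (the
probability of reporting at least one target on a catch trial, where none
was flashed) and an omission rate (the probability of reporting zero
targets when one was flashed).  Per-subject error rates are drawn from
beta distributions parameterized by mean and standard deviation, so the
simulated between-subject dispersion can be matched to observed
subject-level spreads.

Responses are independent across trials: every downstream statistic in
this package operates on per-subject rates, for which the binomial trial
structure is sufficient.

Two sampling surfaces are provided:

:func:`simulate_trials`
    one row per trial, in randomized order — the interchange table the
    command-line pipeline writes and reads;
:func:`simulate_counts`
    per-(participant, level) binomial counts, distributionally identical
    to counting a simulated trial table, used for Monte-Carlo studies
    where materializing millions of trial rows would be waste.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .designs import FACTOR_NAMES, StudyDesign

__all__ = [
    "PopulationModel",
    "ObserverProfile",
    "default_population_model",
    "draw_population",
    "simulate_trials",
    "simulate_counts",
    "counts_from_trials",
    "validate_trials",
    "write_trials",
    "read_trials",
    "TRIAL_COLUMNS",
]

#: column set of the trial-table interchange format (CSV, header row)
TRIAL_COLUMNS = (
    "participant_id",
    "design_id",
    "trial_index",
    "trial_type",
    "level_index",
    "frame_speed",
    "flash_opacity",
    "attention_block",
    "n_presented",
    "response",
)

#: per-(participant, level) count table produced by the fast sampling path
COUNT_COLUMNS = (
    "participant_id",
    "level_index",
    "n_experimental",
    "n_report2",
    "n_omission",
    "n_catch",
    "n_commission",
)


@dataclass(frozen=True)
class PopulationModel:
    """Parameters of the simulated observer population.

    Parameters
    ----------
    gamma
        True population prevalence of perceivers, in [0, 1].
    link_intercept, link_slope
        Logistic-link coefficients for a perceiver's probability of
        reporting two targets as a function of the primary condition
        value ``v``:  ``p = expit(link_intercept + link_slope * v)``.
    commission_mean, commission_spread
        Mean and standard deviation of the per-subject beta distribution
        of commission rates (reporting >= 1 target on a catch trial).
        ``spread = 0`` gives every subject the mean rate.
    omission_mean, omission_spread
        Likewise for omission rates (reporting 0 when one target was
        flashed).
    nonperceiver_report2
        A non-perceiver's probability of reporting two targets on an
        experimental trial.  ``None`` (default) means "equal to the
        subject's own commission rate": without the illusion, a two-target
        report is just another commission error.
    two_dot_commission
        Fraction of commission errors on catch trials reported as two
        targets rather than one.  Defaults to 0: participants who are
        unsure default to reporting a single dot.
    seed
        Default random seed used when the sampling functions are called
        without one.
    """

    gamma: float = 0.5
    link_intercept: float = -2.8
    link_slope: float = 0.07
    commission_mean: float = 0.0327
    commission_spread: float = 0.0
    omission_mean: float = 0.0124
    omission_spread: float = 0.0
    nonperceiver_report2: float | None = None
    two_dot_commission: float = 0.0
    seed: int | None = None

    def validate(self, design: StudyDesign | None = None) -> list[str]:
        v: list[str] = []
        for name in ("gamma", "commission_mean", "omission_mean",
                     "two_dot_commission"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                v.append(f"{name} must be in [0, 1], got {x}")
        if self.nonperceiver_report2 is not None and not (
                0.0 <= self.nonperceiver_report2 <= 1.0):
            v.append(f"nonperceiver_report2 must be in [0, 1], got "
                     f"{self.nonperceiver_report2}")
        for name in ("commission_spread", "omission_spread"):
            if getattr(self, name) < 0:
                v.append(f"{name} must be non-negative, got {getattr(self, name)}")
        for name in ("commission", "omission"):
            m = getattr(self, f"{name}_mean")
            s = getattr(self, f"{name}_spread")
            if s > 0 and 0 < m < 1 and s * s >= m * (1 - m):
                v.append(f"{name}_spread {s} too large for mean {m}: "
                         "needs spread^2 < mean*(1-mean)")
        return v


def default_population_model(design: StudyDesign, **overrides) -> PopulationModel:
    """A design-appropriate default population.

    Error-rate means follow the observed group-level error rates of the
    corresponding experiment (commission ~3.3%, omission ~1.2% of trials);
    the perceiver link is increasing in frame speed and in flash opacity,
    with slopes on the natural scale of each factor.  These defaults are
    illustrative operating points, not fitted estimates.
    """
    params: dict = {}
    if design.primary_factor == "flash_opacity":
        # opacity runs 50..100%; weak positive dependence
        params.update(link_intercept=-2.0, link_slope=0.01)
    else:
        # speed runs ~4..35 deg/s; clear positive dependence
        params.update(link_intercept=-2.8, link_slope=0.07)
    if design.baseline_kind == "omission":
        params.update(omission_mean=0.0124)
    params.update(overrides)
    model = PopulationModel(**params)
    problems = model.validate(design)
    if problems:
        raise ValueError("invalid population model: " + "; ".join(problems))
    return model


@dataclass(frozen=True)
class ObserverProfile:
    """One subject's generative parameters for a given design."""

    participant_id: str
    is_perceiver: bool
    p_report2_by_level: tuple[float, ...]
    p_commission: float
    p_omission: float

    def validate(self, design: StudyDesign) -> list[str]:
        v: list[str] = []
        if len(self.p_report2_by_level) != design.n_levels:
            v.append(f"{self.participant_id}: {len(self.p_report2_by_level)} "
                     f"report-2 probabilities for {design.n_levels} levels")
        for name in ("p_commission", "p_omission"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                v.append(f"{self.participant_id}: {name} out of [0, 1]: {x}")
        for j, p in enumerate(self.p_report2_by_level):
            if not 0.0 <= p <= 1.0:
                v.append(f"{self.participant_id}: p_report2 at level {j} "
                         f"out of [0, 1]: {p}")
            if p + self.p_omission > 1.0 + 1e-12:
                v.append(f"{self.participant_id}: p_report2 + p_omission > 1 "
                         f"at level {j}")
        return v


def _beta_mean_spread(rng: np.random.Generator, mean: float, spread: float,
                      size: int) -> np.ndarray:
    """Draw from a beta distribution given its mean and standard deviation.

    spread = 0, or a degenerate mean of exactly 0 or 1, collapses to the
    constant ``mean``.
    """
    if spread == 0 or mean in (0.0, 1.0):
        return np.full(size, mean)
    nu = mean * (1 - mean) / spread**2 - 1
    if nu <= 0:
        raise ValueError(f"spread {spread} too large for mean {mean}")
    return rng.beta(mean * nu, (1 - mean) * nu, size)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def draw_population(model: PopulationModel, design: StudyDesign,
                    seed: int | None = None) -> list[ObserverProfile]:
    """Draw one observer profile per participant of the design.

    Each subject is a perceiver independently with probability
    ``model.gamma``.  Perceivers report two targets with the logistic-link
    probability at each condition level; non-perceivers use their own
    commission-style rate (constant across levels).  The joint report-2 /
    omission probability is kept feasible by scaling the omission rate
    down where the two would exceed 1.
    """
    problems = model.validate(design)
    if problems:
        raise ValueError("invalid population model: " + "; ".join(problems))

    if seed is None:
        seed = model.seed
    rng = np.random.default_rng(seed)
    n = design.n_participants

    is_perceiver = rng.random(n) < model.gamma
    commission = np.clip(
        _beta_mean_spread(rng, model.commission_mean, model.commission_spread, n),
        0.0, 1.0)
    omission = np.clip(
        _beta_mean_spread(rng, model.omission_mean, model.omission_spread, n),
        0.0, 1.0)

    values = design.primary_values()
    p_link = _expit(model.link_intercept + model.link_slope * values)

    width = len(str(n))
    profiles: list[ObserverProfile] = []
    for i in range(n):
        if is_perceiver[i]:
            p2 = p_link.copy()
        else:
            base = (model.nonperceiver_report2
                    if model.nonperceiver_report2 is not None else commission[i])
            p2 = np.full(design.n_levels, base)
        # feasibility: a trial cannot be both a two-target report and an omission
        pom = min(omission[i], float(1.0 - p2.max()))
        profiles.append(ObserverProfile(
            participant_id=f"p{i + 1:0{width}d}",
            is_perceiver=bool(is_perceiver[i]),
            p_report2_by_level=tuple(float(x) for x in p2),
            p_commission=float(commission[i]),
            p_omission=float(pom),
        ))
    return profiles


def _check_profiles(profiles: list[ObserverProfile], design: StudyDesign) -> None:
    if len(profiles) != design.n_participants:
        raise ValueError(f"{len(profiles)} profiles for a design with "
                         f"{design.n_participants} participants")
    problems = [p for prof in profiles for p in prof.validate(design)]
    if problems:
        raise ValueError("invalid profiles: " + "; ".join(problems[:5]))


def simulate_trials(profiles: list[ObserverProfile], design: StudyDesign,
                    seed: int | None = None) -> pd.DataFrame:
    """Simulate a full trial table, one row per trial.

    Per participant the design's exact per-level experimental and catch
    trial counts are laid out, shuffled into a randomized presentation
    order, and responses drawn:

    * experimental trials (one target flashed): response 2 with the
      subject's level-specific report-2 probability, response 0 with the
      omission probability, response 1 otherwise;
    * catch trials (no target): response >= 1 with the commission
      probability, split between 1 and 2 by the population's
      ``two_dot_commission`` ratio (recorded on the profile's simulator
      call via the model default of 0 — pass ``two_dot_commission``
      through :func:`simulate_trials_model` for other splits).

    The result is byte-stable for a given (profiles, design, seed).
    """
    return _simulate_trials_impl(profiles, design, seed, two_dot_commission=0.0)


def simulate_trials_model(profiles: list[ObserverProfile], design: StudyDesign,
                          model: PopulationModel,
                          seed: int | None = None) -> pd.DataFrame:
    """Like :func:`simulate_trials`, honouring the model's commission split."""
    return _simulate_trials_impl(profiles, design, seed,
                                 two_dot_commission=model.two_dot_commission)


def _simulate_trials_impl(profiles: list[ObserverProfile], design: StudyDesign,
                          seed: int | None,
                          two_dot_commission: float) -> pd.DataFrame:
    _check_profiles(profiles, design)
    rng = np.random.default_rng(seed)

    # fixed per-participant layout: level index, trial type
    level_idx = np.concatenate([
        np.full(lv.n_total, j, dtype=np.int64)
        for j, lv in enumerate(design.levels)
    ])
    is_catch = np.concatenate([
        np.r_[np.zeros(lv.n_experimental, dtype=bool), np.ones(lv.n_catch, dtype=bool)]
        for lv in design.levels
    ])
    n_trials = level_idx.size

    frames = []
    for prof in profiles:
        order = rng.permutation(n_trials)
        li = level_idx[order]
        catch = is_catch[order]

        p2 = np.asarray(prof.p_report2_by_level)[li]
        u = rng.random(n_trials)
        response = np.ones(n_trials, dtype=np.int64)
        response[u < p2] = 2
        response[(u >= p2) & (u < p2 + prof.p_omission)] = 0

        # catch trials override: commission yields 1 (or 2), else 0
        uc = rng.random(n_trials)
        commit = uc < prof.p_commission
        two = rng.random(n_trials) < two_dot_commission
        catch_resp = np.where(commit, np.where(two, 2, 1), 0)
        response[catch] = catch_resp[catch]

        frames.append(pd.DataFrame({
            "participant_id": prof.participant_id,
            "design_id": design.design_id,
            "trial_index": np.arange(n_trials),
            "trial_type": np.where(catch, "catch", "experimental"),
            "level_index": li,
            "n_presented": np.where(catch, 0, 1),
            "response": response,
        }))

    out = pd.concat(frames, ignore_index=True)
    # attach factor columns from the level index
    names = design.factor_names()
    for name in FACTOR_NAMES:
        if name in names:
            vals = [lv.factor_dict.get(name) for lv in design.levels]
            out[name] = pd.Series(vals, dtype=object).values[out["level_index"]]
        else:
            out[name] = pd.NA
    return out[list(TRIAL_COLUMNS)]


def simulate_counts(profiles: list[ObserverProfile], design: StudyDesign,
                    seed: int | None = None,
                    two_dot_commission: float = 0.0) -> pd.DataFrame:
    """Draw per-(participant, level) response counts directly.

    Because trials are independent given the profile, the per-cell counts
    of a simulated trial table are binomial; sampling them directly is
    distributionally identical to :func:`simulate_trials` followed by
    :func:`counts_from_trials`, at a small fraction of the cost.  Used
    for calibration, power and coverage studies.
    """
    _check_profiles(profiles, design)
    rng = np.random.default_rng(seed)

    n_exp = np.array([lv.n_experimental for lv in design.levels])
    n_catch = np.array([lv.n_catch for lv in design.levels])

    rows = []
    for prof in profiles:
        p2 = np.asarray(prof.p_report2_by_level)
        k2 = rng.binomial(n_exp, p2)
        # omissions among the remaining trials: conditional thinning keeps
        # the joint (report2, omission) multinomial per cell
        p_om_given_not2 = np.divide(prof.p_omission, 1.0 - p2,
                                    out=np.zeros_like(p2), where=p2 < 1.0)
        kom = rng.binomial(n_exp - k2, np.clip(p_om_given_not2, 0.0, 1.0))
        kc = rng.binomial(n_catch, prof.p_commission)
        rows.append(pd.DataFrame({
            "participant_id": prof.participant_id,
            "level_index": np.arange(design.n_levels),
            "n_experimental": n_exp,
            "n_report2": k2,
            "n_omission": kom,
            "n_catch": n_catch,
            "n_commission": kc,
        }))
    return pd.concat(rows, ignore_index=True)


def counts_from_trials(trials: pd.DataFrame,
                       commission_counts: str = "any_report") -> pd.DataFrame:
    """Collapse a trial table to per-(participant, level) counts.

    ``commission_counts`` selects whether a commission error on a catch
    trial is any non-zero report (default, matching "reported a dot when
    none was presented") or a two-target report only.
    """
    exp = trials[trials["trial_type"] == "experimental"]
    catch = trials[trials["trial_type"] == "catch"]

    g = exp.groupby(["participant_id", "level_index"], observed=True)
    out = g["response"].agg(
        n_experimental="size",
        n_report2=lambda r: int((r == 2).sum()),
        n_omission=lambda r: int((r == 0).sum()),
    ).reset_index()

    if len(catch):
        thresh = 2 if commission_counts == "two_only" else 1
        gc = catch.groupby(["participant_id", "level_index"], observed=True)
        cc = gc["response"].agg(
            n_catch="size",
            n_commission=lambda r: int((r >= thresh).sum()),
        ).reset_index()
        out = out.merge(cc, on=["participant_id", "level_index"], how="outer")
    else:
        out["n_catch"] = 0
        out["n_commission"] = 0

    for c in ("n_experimental", "n_report2", "n_omission", "n_catch",
              "n_commission"):
        out[c] = out[c].fillna(0).astype(np.int64)
    return out.sort_values(["participant_id", "level_index"],
                           ignore_index=True)[list(COUNT_COLUMNS)]


def validate_trials(trials: pd.DataFrame, design: StudyDesign) -> list[str]:
    """Schema-check a trial table against a design.

    Returns human-readable violations, each naming the offending column
    or row, empty if the table is valid.
    """
    v: list[str] = []
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        return [f"missing columns: {', '.join(missing)}"]

    alphabet = set(design.response_alphabet)
    bad_resp = trials.index[~trials["response"].isin(alphabet)]
    for i in bad_resp[:20]:
        v.append(f"row {i}: response {trials.at[i, 'response']!r} not in "
                 f"{sorted(alphabet)}")

    bad_type = trials.index[~trials["trial_type"].isin(["experimental", "catch"])]
    for i in bad_type[:20]:
        v.append(f"row {i}: trial_type {trials.at[i, 'trial_type']!r} invalid")

    catch = trials["trial_type"] == "catch"
    bad_pres = trials.index[(catch & (trials["n_presented"] != 0))
                            | (~catch & (trials["n_presented"] != 1))]
    for i in bad_pres[:20]:
        v.append(f"row {i}: n_presented {trials.at[i, 'n_presented']!r} "
                 f"inconsistent with trial_type {trials.at[i, 'trial_type']!r}")

    bad_level = trials.index[(trials["level_index"] < 0)
                             | (trials["level_index"] >= design.n_levels)]
    for i in bad_level[:20]:
        v.append(f"row {i}: level_index {trials.at[i, 'level_index']!r} outside "
                 f"0..{design.n_levels - 1}")
    return v


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "attention_block": str})
    return df
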