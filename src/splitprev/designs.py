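"""Declarative descriptions of the four illusion-report experiments.

A :class:`StudyDesign` records, for one experiment, the per-participant
trial budget broken down into condition levels (frame speed, flash
opacity, or attention block crossed with speed), how many of those trials
are catch trials (no target flashed), and which error baseline the
per-subject significance tests use:

``commission``
    the rate of reporting a target on catch trials (experiments with
    catch trials), or
``omission``
    the rate of reporting zero targets when one was flashed
    (experiments without catch trials).

Both the trial simulator and the analyzer consume the same design object,
so the simulated tables and the analysis are guaranteed to agree on trial
counts and condition labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "ConditionLevel",
    "StudyDesign",
    "builtin_design",
    "validate_design",
    "BUILTIN_DESIGN_IDS",
]

#: total trials per participant in each built-in design
_PRINTED_TOTALS = {"exp1a": 360, "exp1b": 240, "exp2a": 600, "exp2b": 300}

BUILTIN_DESIGN_IDS = tuple(_PRINTED_TOTALS)

#: admissible report values: number of targets the participant says they saw
RESPONSE_ALPHABET = (0, 1, 2)

#: factor columns a trial table may carry; unused factors are left empty
FACTOR_NAMES = ("frame_speed", "flash_opacity", "attention_block")

ATTENTION_BLOCKS = ("above-cued", "below-cued", "uncued")


@dataclass(frozen=True)
class ConditionLevel:
    """One cell of the design: a combination of factor values.

    Parameters
    ----------
    factors
        Mapping from factor name to its value at this level, e.g.
        ``{"frame_speed": 19.5}`` (degrees of visual angle per second) or
        ``{"frame_speed": 19.5, "attention_block": "uncued"}``.  Opacity
        is a percentage in (0, 100].
    n_experimental
        Number of trials at this level on which one target is flashed.
    n_catch
        Number of trials at this level on which no target is flashed.
    """

    factors: tuple[tuple[str, float | str], ...]
    n_experimental: int
    n_catch: int

    @property
    def factor_dict(self) -> dict[str, float | str]:
        return dict(self.factors)

    @property
    def n_total(self) -> int:
        return self.n_experimental + self.n_catch

    def label(self) -> str:
        return ", ".join(f"{k}={v}" for k, v in self.factors)


def _level(factors: dict[str, float | str], n_exp: int, n_catch: int) -> ConditionLevel:
    return ConditionLevel(tuple(factors.items()), n_exp, n_catch)


@dataclass(frozen=True)
class StudyDesign:
    """A complete per-participant trial layout for one experiment."""

    design_id: str
    n_participants: int
    levels: tuple[ConditionLevel, ...]
    baseline_kind: str  # "commission" | "omission"
    primary_factor: str  # numeric factor used for regressions on condition value
    response_alphabet: tuple[int, ...] = RESPONSE_ALPHABET

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def total_trials(self) -> int:
        return sum(lv.n_total for lv in self.levels)

    def total_catch(self) -> int:
        return sum(lv.n_catch for lv in self.levels)

    def total_experimental(self) -> int:
        return sum(lv.n_experimental for lv in self.levels)

    def primary_values(self) -> np.ndarray:
        """Numeric value of the primary factor at each level, in level order."""
        return np.array([lv.factor_dict[self.primary_factor] for lv in self.levels],
                        dtype=float)

    def factor_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for lv in self.levels:
            for k, _ in lv.factors:
                if k not in names:
                    names.append(k)
        return tuple(names)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "design_id": self.design_id,
            "n_participants": self.n_participants,
            "baseline_kind": self.baseline_kind,
            "primary_factor": self.primary_factor,
            "response_alphabet": list(self.response_alphabet),
            "levels": [
                {
                    "factors": lv.factor_dict,
                    "n_experimental": lv.n_experimental,
                    "n_catch": lv.n_catch,
                }
                for lv in self.levels
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        levels = tuple(
            _level(dict(lv["factors"]), int(lv["n_experimental"]), int(lv["n_catch"]))
            for lv in d["levels"]
        )
        return cls(
            design_id=str(d["design_id"]),
            n_participants=int(d["n_participants"]),
            levels=levels,
            baseline_kind=str(d["baseline_kind"]),
            primary_factor=str(d["primary_factor"]),
            response_alphabet=tuple(int(r) for r in d.get("response_alphabet", RESPONSE_ALPHABET)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "StudyDesign":
        return cls.from_dict(yaml.safe_load(text))


def builtin_design(design_id: str, n_participants: int | None = None) -> StudyDesign:
    """Return one of the four built-in experiment designs.

    ``exp1a``
        9 frame speeds uniformly spaced on [3.9, 35] °/s, 40 trials each
        (32 experimental + 8 catch); 360 trials, 45 participants.
    ``exp1b``
        6 flash opacities uniformly spaced on [50, 100] %, 32 experimental
        + 8 catch per level; 240 trials, 45 participants.
    ``exp2a``
        3 attention blocks (above-cued and below-cued: 150 trials each;
        uncued: 300) crossed with speeds {19.5, 27.3, 35} °/s allocated
        equally within block; 600 trials, 85 participants, no catch trials.
    ``exp2b``
        Motion-onset trials at the same 3 speeds, 100 each; 300 trials,
        85 participants, no catch trials.

    Parameters
    ----------
    design_id
        One of ``exp1a``, ``exp1b``, ``exp2a``, ``exp2b``.
    n_participants
        Optional override of the default sample size (45 for experiment 1,
        85 for experiment 2).
    """
    if design_id not in _PRINTED_TOTALS:
        raise ValueError(
            f"unknown design_id {design_id!r}; valid choices are "
            f"{', '.join(BUILTIN_DESIGN_IDS)}"
        )

    if design_id == "exp1a":
        speeds = np.linspace(3.9, 35.0, 9)
        levels = tuple(_level({"frame_speed": float(s)}, 32, 8) for s in speeds)
        d = StudyDesign("exp1a", n_participants or 45, levels, "commission",
                        "frame_speed")
    elif design_id == "exp1b":
        opacities = np.linspace(50.0, 100.0, 6)
        levels = tuple(_level({"flash_opacity": float(o)}, 32, 8) for o in opacities)
        d = StudyDesign("exp1b", n_participants or 45, levels, "commission",
                        "flash_opacity")
    elif design_id == "exp2a":
        speeds = (19.5, 27.3, 35.0)
        block_totals = {"above-cued": 150, "below-cued": 150, "uncued": 300}
        levels = tuple(
            _level({"frame_speed": s, "attention_block": blk}, total // 3, 0)
            for blk, total in block_totals.items()
            for s in speeds
        )
        d = StudyDesign("exp2a", n_participants or 85, levels, "omission",
                        "frame_speed")
    else:  # exp2b
        speeds = (19.5, 27.3, 35.0)
        levels = tuple(_level({"frame_speed": s}, 100, 0) for s in speeds)
        d = StudyDesign("exp2b", n_participants or 85, levels, "omission",
                        "frame_speed")

    return d


def validate_design(design: StudyDesign) -> list[str]:
    """Check a design against its structural invariants.

    Returns a list of human-readable violation messages; an empty list
    means the design is valid.  Violations are data, not exceptions, so a
    caller can report all problems at once.
    """
    v: list[str] = []

    if design.n_participants <= 0:
        v.append(f"n_participants must be positive, got {design.n_participants}")
    if design.baseline_kind not in ("commission", "omission"):
        v.append(f"baseline_kind must be 'commission' or 'omission', got "
                 f"{design.baseline_kind!r}")
    if not design.levels:
        v.append("design has no condition levels")

    for i, lv in enumerate(design.levels):
        fd = lv.factor_dict
        if lv.n_experimental < 0:
            v.append(f"level {i} ({lv.label()}): negative n_experimental "
                     f"({lv.n_experimental})")
        if lv.n_catch < 0:
            v.append(f"level {i} ({lv.label()}): negative n_catch ({lv.n_catch})")
        if "frame_speed" in fd and not float(fd["frame_speed"]) > 0:
            v.append(f"level {i}: frame_speed must be positive, got "
                     f"{fd['frame_speed']}")
        if "flash_opacity" in fd:
            o = float(fd["flash_opacity"])
            if not (0 < o <= 100):
                v.append(f"level {i}: flash_opacity must be in (0, 100], got {o}")
        if design.primary_factor not in fd:
            v.append(f"level {i} ({lv.label()}): missing primary factor "
                     f"{design.primary_factor!r}")

    total = design.total_trials()
    printed = _PRINTED_TOTALS.get(design.design_id)
    if printed is not None and total != printed:
        v.append(f"{design.design_id}: total trials per participant is {total}, "
                 f"expected {printed}")

    if design.design_id in ("exp1a", "exp1b"):
        catch = design.total_catch()
        if printed is not None and catch * 5 != printed:
            v.append(f"{design.design_id}: catch trials are {catch} of {printed}, "
                     "expected 20% of the total")
        per_level = {lv.n_catch for lv in design.levels}
        if len(per_level) > 1:
            v.append(f"{design.design_id}: catch trials not evenly divided over "
                     f"levels (counts {sorted(per_level)})")
    elif design.design_id in ("exp2a", "exp2b"):
        if design.total_catch() != 0:
            v.append(f"{design.design_id}: must have zero catch trials")
        if design.baseline_kind != "omission":
            v.append(f"{design.design_id}: baseline_kind must be 'omission'")

    return v
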