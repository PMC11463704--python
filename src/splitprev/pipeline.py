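"""End-to-end orchestration: simulate -> summarize -> test -> prevalence.

A :class:`RunConfig` captures everything a run needs (design, population
parameters, baseline, prevalence model, seed); every stage writes
comma-separated tables plus a JSON provenance sidecar carrying the config
hash, seed and package version, so any stage can be re-run bit-identically
from its recorded inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .designs import StudyDesign, builtin_design, validate_design
from .groupstats import (anova_bayes_factor, one_way_anova,
                         regression_bayes_factor, simple_regression,
                         welch_t_from_values)
from .observers import (default_population_model, draw_population,
                        read_trials, simulate_trials, validate_trials,
                        write_trials)
from .prevalence import curve_table, estimate, prevalence_curve
from .subjects import OVERALL, BaselineSpec, flag_significant, summarize_subjects

log = logging.getLogger("splitprev")

__all__ = ["RunConfig", "RunReport", "run_simulate", "run_analyze",
           "load_design"]


@dataclass
class RunConfig:
    """Configuration for a pipeline run; YAML round-trippable."""

    design: str = "exp1a"  # builtin id or path to a design YAML
    seed: int = 0
    population: dict = field(default_factory=dict)  # PopulationModel overrides
    baseline: dict = field(default_factory=dict)    # BaselineSpec overrides
    model: str = "test_calibrated"
    alpha_fp: float = 0.05
    hpdi_mass: float = 0.96
    out_dir: str = "splitprev_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**d)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Headline numbers and output locations of an analyze run."""

    files: dict
    headline: dict
    provenance: dict

    def render(self) -> str:
        h = self.headline
        lines = [
            f"design            : {self.provenance['design_id']}",
            f"participants      : {h['n_participants']}",
            f"illusion rate     : M = {h['illusion_rate_mean']:.2f}%, "
            f"SD = {h['illusion_rate_sd']:.2f}%",
            f"error rate ({h['baseline_kind']:>9s}): M = {h['error_rate_mean']:.2f}%, "
            f"SD = {h['error_rate_sd']:.2f}%",
            f"illusion vs error : t({h['welch_df']:.2f}) = {h['welch_t']:.2f}, "
            f"p = {h['welch_p']:.3g}",
            f"significant       : {h['k_sig']} of {h['n_participants']}",
            f"prevalence MAP    : {h['map']:.2f} "
            f"({int(round(100 * h['hpdi_mass']))}% HPDI = "
            f"[{h['hpdi_low']:.2f}, {h['hpdi_high']:.2f}]; model {h['model']})",
        ]
        if "regression_r2" in h:
            lines.append(
                f"trend on {h['regression_factor']:>12s}: R^2 = "
                f"{h['regression_r2']:.2f}, F(1, {h['regression_df_den']}) = "
                f"{h['regression_f']:.2f}, p = {h['regression_p']:.3g}")
        if "anova_f" in h:
            lines.append(
                f"attention ANOVA   : F({h['anova_df_between']}, "
                f"{h['anova_df_within']}) = {h['anova_f']:.2f}, "
                f"p = {h['anova_p']:.3g}; BF10 = {h['anova_bf10']:.2f} "
                "(BIC approximation)")
        lines.append(f"seed {self.provenance['seed']}, config "
                     f"{self.provenance['config_hash']}, splitprev "
                     f"{self.provenance['version']}")
        return "\n".join(lines)


def load_design(spec: str) -> StudyDesign:
    """Resolve a builtin design id or a path to a design YAML file."""
    p = Path(spec)
    if p.suffix in (".yaml", ".yml") or p.exists():
        design = StudyDesign.from_yaml(p.read_text())
    else:
        design = builtin_design(spec)
    problems = validate_design(design)
    if problems:
        raise ValueError("invalid design: " + "; ".join(problems))
    return design


def _provenance(config: RunConfig, design: StudyDesign) -> dict:
    return {
        "design_id": design.design_id,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": __version__,
        "config": config.to_dict(),
    }


def run_simulate(config: RunConfig) -> Path:
    """Simulate a trial table; returns the path of the written CSV."""
    design = load_design(config.design)
    model = default_population_model(design, **config.population,
                                    seed=config.seed)
    log.info("simulating %s: %d participants x %d trials", design.design_id,
             design.n_participants, design.total_trials())
    profiles = draw_population(model, design, seed=config.seed)
    # separate stream for trials so population and trial noise are decoupled
    trials = simulate_trials(profiles, design, seed=config.seed + 1)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "trials.csv"
    write_trials(trials, path)
    prov = _provenance(config, design)
    prov["n_perceivers_true"] = sum(p.is_perceiver for p in profiles)
    (out / "trials.provenance.json").write_text(json.dumps(prov, indent=2))
    log.info("wrote %s (%d rows)", path, len(trials))
    return path


def run_analyze(trials_path, config: RunConfig) -> RunReport:
    """Analyze a trial table: summaries, tests, prevalence, group stats."""
    design = load_design(config.design)
    trials = read_trials(trials_path)
    problems = validate_trials(trials, design)
    if problems:
        raise ValueError("trial table failed schema validation:\n  "
                         + "\n  ".join(problems))

    summaries = summarize_subjects(trials, design)
    spec = BaselineSpec.for_design(design, **config.baseline)
    sig_table, k_sig, n = flag_significant(summaries, spec, per_level=True)

    # prevalence, overall and per level
    per_level = {"overall": (k_sig, n)}
    for li, grp in sig_table[sig_table["level_index"] != OVERALL].groupby(
            "level_index"):
        per_level[f"level_{li}"] = (int(grp["significant"].sum()), len(grp))
    estimates = prevalence_curve(per_level, model=config.model,
                                 alpha_fp=config.alpha_fp,
                                 mass=config.hpdi_mass)
    prev_summary, prev_curves = curve_table(estimates)

    overall = summaries[summaries["level_index"] == OVERALL]
    illusion = overall["pct_report2"].to_numpy(dtype=float)
    err_col = ("pct_commission" if spec.kind == "commission" else "pct_omission")
    error = overall[err_col].to_numpy(dtype=float)
    welch = welch_t_from_values(illusion, error)

    est = estimates["overall"]
    headline = {
        "n_participants": int(n),
        "baseline_kind": spec.kind,
        "illusion_rate_mean": float(np.mean(illusion)),
        "illusion_rate_sd": float(np.std(illusion, ddof=1)),
        "error_rate_mean": float(np.mean(error)),
        "error_rate_sd": float(np.std(error, ddof=1)),
        "welch_t": welch.t, "welch_df": welch.df, "welch_p": welch.p,
        "k_sig": int(k_sig),
        "model": config.model,
        "map": est.map, "hpdi_low": est.hpdi_low, "hpdi_high": est.hpdi_high,
        "hpdi_mass": config.hpdi_mass,
    }

    stat_rows = [{
        "statistic": "welch_t_illusion_vs_error", "value": welch.t,
        "df1": welch.df, "df2": np.nan, "p": welch.p,
    }]

    # trend of per-(subject, condition value) illusion rate on the primary
    # factor; levels sharing a factor value (e.g. speeds repeated across
    # attention blocks) are averaged within subject first
    per_lv = summaries[summaries["level_index"] != OVERALL]
    per_val = per_lv.groupby(["participant_id", design.primary_factor],
                             as_index=False)["pct_report2"].mean()
    x = per_val[design.primary_factor].to_numpy(dtype=float)
    y = per_val["pct_report2"].to_numpy(dtype=float)
    if np.ptp(x) > 0:
        reg = simple_regression(x, y)
        bf_reg = regression_bayes_factor(x, y)
        headline.update(regression_factor=design.primary_factor,
                        regression_r2=reg.r_squared, regression_f=reg.f,
                        regression_df_den=reg.df_den, regression_p=reg.p)
        stat_rows.append({"statistic": f"regression_on_{design.primary_factor}",
                          "value": reg.f, "df1": 1.0, "df2": reg.df_den,
                          "p": reg.p})
        stat_rows.append({"statistic": "regression_bf10_bic", "value": bf_reg.bf10,
                          "df1": np.nan, "df2": np.nan, "p": np.nan})

    # attention effect, where the design crosses attention with speed
    if "attention_block" in design.factor_names():
        lv_block = {j: lv.factor_dict["attention_block"]
                    for j, lv in enumerate(design.levels)}
        pl = per_lv.assign(block=per_lv["level_index"].map(lv_block))
        # one mean per subject x block
        means = pl.groupby(["participant_id", "block"])["pct_report2"].mean()
        blocks = [means.xs(b, level="block").to_numpy()
                  for b in means.index.get_level_values("block").unique()]
        an = one_way_anova(blocks)
        bf = anova_bayes_factor(blocks)
        headline.update(anova_f=an.f, anova_df_between=an.df_between,
                        anova_df_within=an.df_within, anova_p=an.p,
                        anova_bf10=bf.bf10)
        stat_rows.append({"statistic": "anova_attention", "value": an.f,
                          "df1": float(an.df_between),
                          "df2": float(an.df_within), "p": an.p})
        stat_rows.append({"statistic": "anova_bf10_bic", "value": bf.bf10,
                          "df1": np.nan, "df2": np.nan, "p": np.nan})

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "subject_summaries": out / "subject_summaries.csv",
        "significance": out / "significance.csv",
        "prevalence": out / "prevalence.csv",
        "prevalence_curves": out / "prevalence_curves.csv",
        "group_stats": out / "group_stats.csv",
        "report": out / "report.json",
    }
    summaries.to_csv(files["subject_summaries"], index=False)
    sig_table.to_csv(files["significance"], index=False)
    prev_summary.to_csv(files["prevalence"], index=False)
    prev_curves.to_csv(files["prevalence_curves"], index=False)
    pd.DataFrame(stat_rows).to_csv(files["group_stats"], index=False)

    prov = _provenance(config, design)
    report = RunReport(files={k: str(v) for k, v in files.items()},
                       headline=headline, provenance=prov)
    files["report"].write_text(json.dumps(
        {"files": report.files, "headline": headline, "provenance": prov},
        indent=2))
    return report
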