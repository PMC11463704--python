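"""Inspect the built-in experiment designs.

Each design records one participant's trial budget: condition levels,
experimental vs catch trials per level, and which error baseline the
per-subject significance tests will use.
"""

from splitprev import builtin_design, validate_design

for design_id in ("exp1a", "exp1b", "exp2a", "exp2b"):
    d = builtin_design(design_id)
    print(f"{design_id}: {d.n_participants} participants, "
          f"{d.total_trials()} trials each "
          f"({d.total_catch()} catch), {d.n_levels} levels of "
          f"{d.primary_factor}, baseline = {d.baseline_kind}, "
          f"violations = {validate_design(d)}")

d = builtin_design("exp1a")
print("\nexp1a frame speeds (deg/s):",
      [round(float(v), 2) for v in d.primary_values()])
print("Each level:", d.levels[0].n_experimental, "experimental +",
      d.levels[0].n_catch, "catch trials")
# The speed grid is 9 uniform steps from 3.9 to 35 deg/s; 20% of the 360
# trials are catch trials, evenly divided over the levels.
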