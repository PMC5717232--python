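"""Transfer localizer classifiers to the RSVP stream and contrast
target-locked positions, lags and reports.

Classifiers trained at the early (170 ms) and late (370 ms) anchors on each
subject's localizer are applied, without refitting, to the 0-900 ms epochs
of every stream position.  The mean correct-class probability in the
400-550 ms window is then compared across positions relative to the target
(T-4..T+2), across inter-target lags, and across reports (Guess 1/2/3 and a
random unreported control), with signed-rank + FDR statistics.
"""

import dataclasses

from streamselect import ExperimentConfig, SimulationConfig
from streamselect.pipeline import run_transfer_stage

sim = SimulationConfig(n_subjects=6, n_rsvp_trials=80, rng_seed=2)
config = ExperimentConfig(sim=sim)

for mode in ("gradual", "discrete"):
    cfg = dataclasses.replace(
        config, model=dataclasses.replace(config.model, mode=mode))
    res = run_transfer_stage(cfg)
    print(f"\n=== {mode} generator ===")
    pos = res["position_early"]
    print("early anchor (170 ms), 400-550 ms window mean by position "
          "(lags 7 & 9):")
    for off, mean in pos["group_mean"].items():
        star = "*" if pos["tests"][off].p_fdr < 0.05 else " "
        print(f"  T{off:+d}: {mean:.3f} {star}")
    guess = res["guess_late"]
    print("late anchor (370 ms), window mean by report:")
    for name, mean in guess["group_mean"].items():
        star = "*" if guess["tests"][name].p_fdr < 0.05 else " "
        print(f"  {name:>10}: {mean:.3f} {star}")

print("\nGradual generator: the early code of the target and the one or two "
      "preceding stimuli stays decodable late in the window (graded "
      "enhancement), while the late anchor sees nothing. Discrete "
      "generator: only reported stimuli carry late activity, graded "
      "Guess 1 > 2 > 3, and the unreported control sits at chance.")
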