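"""Channelwise GLM activation analysis on the finger-tapping scenario.

Fits the canonical-HRF design to one synthetic subject whose first ten
channels carry a true tapping response (beta = 0.6) and prints the
estimated effects for active vs inactive channels.
"""

import numpy as np

import fnirslab as fl

spec = fl.standard_scenarios(seed=2024)["task_finger"]
rec, truth = fl.generate_subject(spec, subject=0)
print(f"subject 1: {rec.n_channels} channels, {rec.duration_s:.0f} s; "
      f"conditions: {rec.task.condition_names}; true beta = {truth.betas}")

rec = fl.detrend(rec, order=1)  # remove the slow instrumental drift first
dm = fl.build_design(rec.task, rec.n_times, rec.fs)
res = fl.fit_glm(rec, dm, chromophore="HbO")
con = fl.contrast(res, [1.0, 0.0])  # tapping vs baseline

active = con["effect"][:10]
inactive = con["effect"][10:]
print(f"mean estimated effect, active channels 1-10:  {active.mean():+.3f}")
print(f"mean estimated effect, inactive channels:     {inactive.mean():+.3f}")
print(f"mean |t|, active: {np.abs(con['t'][:10]).mean():.1f}; "
      f"inactive: {np.abs(con['t'][10:]).mean():.1f} (dof {con['dof']})")
print("Active channels recover the injected tapping amplitude; inactive ones")
print("stay near zero, with t-statistics reflecting the contrast-to-noise ratio.")
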