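"""Goodness-of-fit, c-hat, and QAICc ranking of a small model set.

Simulates data with area-specific survival, runs the CJS goodness-of-
fit components on the collapsed detection histories (the trap-
dependence z should be clearly positive, since the generator is
trap-happy: p_aware = 0.6 vs p_unaware = 0.4), then ranks a constant-
vs area-survival model pair by QAICc corrected with the residual c-hat.
"""

import multievent as me

cfg = me.default_paper_config(survival="area", n_individuals=1104, seed=4)
data, _, _ = me.simulate_dataset(cfg)

gof = me.cjs_gof(data.detection_matrix())
for comp in gof.components:
    z = f" z={comp.z:+.2f}" if comp.z is not None else ""
    print(f"{comp.name:16s} chi2={comp.chi2:8.2f} df={comp.df:2d} "
          f"p={comp.p_value:.3g}{z}")
print(f"overall c-hat = {gof.chat:.3f}; after modelling trap-dependence "
      f"use {gof.chat_without('trap_dependence'):.3f}")

chat = max(gof.chat_without("trap_dependence"), 1.0)
specs = [me.ModelSpec(survival="constant", change="constant",
                      initial="canary_others", recapture="trap",
                      name="constant"),
         me.ModelSpec(survival="area", change="constant",
                      initial="canary_others", recapture="trap",
                      name="area")]
table = me.run_model_set(data, specs, chat=chat, n_starts=2,
                         compute_se=False)
print("\n", table, sep="")
print("\nthe area model should win: the generating truth has survival "
      "0.961/0.428/0.821/0.903 across areas")
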