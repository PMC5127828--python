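"""Generate a small labeled synthetic cohort and inspect its ground truth.

Builds HC / AD-like / VaD-like group profiles, draws subjects around them,
and prints the group means of the true spectral parameters at the occipital
channel O1 — showing the built-in dementia contrasts (AD/VaD: more delta
power S, less and slower posterior alpha A/c).
"""

import qeeglda as q

config = q.CohortConfig(groups=("HC", "AD", "VaD"), n_per_group=20,
                        effect_scale=1.0, mode="spectra")
cohort = q.synthesize_cohort(config, seed=1)

truth = cohort.truth_frame()
o1 = truth[truth.channel == "O1"]
means = o1.merge(cohort.manifest[["subject", "group"]], on="subject") \
          .groupby("group")[list(q.PARAM_NAMES)].mean()

print(f"cohort: {len(cohort.subjects)} subjects "
      f"({config.n_per_group} per group), fully seeded\n")
print("group-mean TRUE parameters at O1 (S,A,b in µV²/bin; c,w in Hz):")
print(means.round(2).to_string())
print("\nReading: relative to HC, both dementia groups carry more delta "
      "power (S) and a lower, slower posterior alpha peak (A, c); the "
      "VaD-like group has the strongest delta increase.")
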