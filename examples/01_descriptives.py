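"""Cohort descriptives: layer summaries, gender mixing, attribute t-test.

Builds a small synthetic two-gender roster cohort and prints the kind of
descriptive table a sociometric analysis starts from.
"""

import dataclasses

import numpy as np
import pandas as pd

import dissonet as dn

boys = dn.generate_cohort(dataclasses.replace(dn.BOYS_PROFILE, n_actors=30, seed=1))
girls = dn.generate_cohort(dataclasses.replace(dn.GIRLS_PROFILE, n_actors=30, seed=2))

for label, (g, attrs) in (("boys", boys), ("girls", girls)):
    print(f"\n=== {label} cohort (n={g.n}) ===")
    frames = {
        name: dn.summarize_layer(g.layer(code), g.n).to_series()
        for code, name in (("F", "Friendship"), ("D", "Dislike"))
    }
    report = pd.DataFrame(frames)
    report.loc["Exchange (friendship-for-dislike) pairs"] = [
        dn.count_exchange_pairs(g.F, g.D), "",
    ]
    print(report.to_string())

# a pooled two-sample t on the wellbeing scores of the two cohorts, as one
# would test for a gender difference before fitting separate models
b_pwb, g_pwb = boys[1].pwb, girls[1].pwb
t, df = dn.pooled_t(
    g_pwb.mean(), g_pwb.std(ddof=1), len(g_pwb),
    b_pwb.mean(), b_pwb.std(ddof=1), len(b_pwb),
)
print(f"\nwellbeing difference girls vs boys: t({df}) = {t:.2f}")
print("negative t means the girls' cohort scored lower on average;")
print("density ~0.07-0.09 and a handful of exchange pairs mirror a typical")
print("year-level friendship/dislike roster survey.")
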