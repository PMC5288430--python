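"""Exposure by SES band and the two headline t-tests.

Produces the age/sex-adjusted means of each exposure measure across SES
bands (the analysis-of-variance table) and tests (i) whether students sit
socially closer to smokers than to alters in general and (ii) whether
friendship ties are homophilous on parental education.
"""

import pandas as pd

from silnet import descriptive_tests, exposure_anova
from silnet.io import read_metrics_table, write_table

IN = "results/metrics.csv"


def main():
    table = read_metrics_table(IN)

    anova = exposure_anova(table)
    write_table(anova, "results/exposure_by_ses.csv")
    print("age/sex-adjusted means by number of lowest SES categories:")
    print(anova.round(2).to_string(index=False))

    tests = descriptive_tests(table)
    write_table(tests, "results/descriptive_tests.csv")
    d = tests.iloc[0]
    print(f"\nmean distance to smokers {d['mean_1']:.2f} vs all alters "
          f"{d['mean_2']:.2f} (paired t = {d['t']:.1f}, p = {d['p']:.2g})")
    c = tests.iloc[1]
    print(f"mean Coleman index {c['mean_1']:.2f} vs 0 "
          f"(t = {c['t']:.1f}, p = {c['p']:.2g})")


if __name__ == "__main__":
    main()
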