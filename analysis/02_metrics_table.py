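"""Impute SES, build the composite score and compute the network measures.

Reads results/cohort/, applies the missing-data substitution rules, scores
the "number of lowest SES categories" composite and computes per-student
peer exposure (degrees 1-3), relative distance to smokers and the
individual Coleman homophily index.  Writes results/metrics.csv and prints
the descriptive block that the survey reports.
"""

from silnet import compute_metrics_table, read_cohort, score_cohort
from silnet.io import write_table

IN = "results/cohort"
OUT = "results/metrics.csv"


def main():
    records, edges = read_cohort(IN)
    records, composites = score_cohort(records)
    table = compute_metrics_table(records, edges, composites)
    write_table(table, OUT)

    with_net = table.dropna(subset=["exp_deg1"])
    print(f"{len(table)} respondents, {len(with_net)} with at least one "
          f"nomination (isolates get missing exposures)")
    print("SES composite distribution (%):")
    print((100 * table["ses_band"].value_counts(normalize=True)
           .sort_index()).round(1).to_string())
    for col, label in [("exp_deg1", "smokers among 1st-degree friends (%)"),
                       ("exp_deg2", "smokers among 2nd-degree friends (%)"),
                       ("exp_deg3", "smokers among 3rd-degree friends (%)"),
                       ("rel_dist_smokers", "relative distance to smokers (%)"),
                       ("coleman_parental_edu", "Coleman index, parental edu")]:
        print(f"{label:38s} {table[col].mean():6.2f} (sd {table[col].std():.2f})")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
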