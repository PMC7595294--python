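#!/usr/bin/env python
"""Homing-success analysis on release records with the field group sizes.

Builds synthetic release records with the published group structure
(104 control bees with 90 returners; 149 treated with 128), computes the
return percentages, the exact 2x2 test, the Kaplan-Meier curves with
120-min censoring and the log-rank test, and writes results/homing.json.
"""

import json
from pathlib import Path

from hivesignals import (
    fisher_exact_2x2,
    homing_proportion,
    km_curve,
    logrank_test,
    simulate_release_records,
    table_from_records,
)
from hivesignals.homing import write_release_records

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = simulate_release_records(seed=1)
    OUT.mkdir(parents=True, exist_ok=True)
    write_release_records(records, OUT / "releases.csv")

    report = {}
    for group in ("control", "treated"):
        n_ret, n_tot, pct = homing_proportion(records, group)
        report[group] = {"returned": n_ret, "total": n_tot, "percent": pct}
        print(f"{group}: {n_ret}/{n_tot} returned ({pct}%)")

    table = table_from_records(records)
    report["fisher_p"] = fisher_exact_2x2(table)
    print(f"Fisher exact test on [[{table.a},{table.b}],[{table.c},{table.d}]]: "
          f"p = {report['fisher_p']:.4f}")

    chi2, p = logrank_test(
        [r for r in records if r.group == "control"],
        [r for r in records if r.group == "treated"],
    )
    report["logrank"] = {"chi2": round(chi2, 3), "p": round(p, 4)}
    print(f"log-rank: chi2(1) = {chi2:.2f}, p = {p:.3f}")

    for group in ("control", "treated"):
        c = km_curve(records, group)
        report[f"km_{group}"] = {
            "times_min": c.event_times.tolist(),
            "survival": c.survival_probabilities.round(4).tolist(),
            "censored": c.n_censored,
        }
    (OUT / "homing.json").write_text(json.dumps(report, indent=2))
    print(f"wrote {OUT / 'homing.json'}")


if __name__ == "__main__":
    main()
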