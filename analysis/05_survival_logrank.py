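#!/usr/bin/env python
"""Survival comparison of two treatment arms by the log-rank test.

Simulates exponential survival with a 3-fold hazard difference (an
adjuvant arm versus chemotherapy alone), writes the survival table, and
tests the difference.  Expected finding: the lower-hazard arm survives
longer, detected by the log-rank test at moderate arm sizes.
"""

from pathlib import Path

import ivmotion as m

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    surv = m.simulate_survival(
        {"chemo_plus_adjuvant": 0.05, "chemo_alone": 0.15},
        20, follow_up=60.0, seed=SEED,
    )
    surv.to_csv(OUT / "survival_table.csv", index=False)
    r = m.log_rank(surv)
    med = surv.groupby("group").time_days.median()
    for g in med.index:
        n_events = int(surv.loc[surv.group == g, "event"].sum())
        print(f"{g}: median {med[g]:.1f} days, {n_events}/20 events")
    print(f"log-rank: chi2={r.statistic:.2f}, p={r.pvalue:.4f}")


if __name__ == "__main__":
    main()
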