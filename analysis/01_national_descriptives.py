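"""National descriptive analysis of the packaged mortality table.

Computes, from the 13 age-group x 2 gender national aggregate: total and
per-gender death counts with percentages, crude age-specific rates per
100,000, and the directly standardized rate per gender (European Standard
Population 2013, renormalized over ages 25+).  Writes
results/descriptives.csv and prints the headline numbers.
"""

import os

import pandas as pd

from gapc.data_model import esp2013_standard, table1_fixture
from gapc.rates import age_specific_rates, crude_rate, direct_standardized_rate

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    ds = table1_fixture()
    std = esp2013_standard()
    table = age_specific_rates(ds)
    total = int(ds.deaths.sum())
    rows = []
    for g, gender in enumerate(ds.genders):
        deaths = int(ds.deaths[g].sum())
        pop = float(ds.population[g].sum())
        rates = table[table.gender == gender]["rate"].to_numpy()
        asr = direct_standardized_rate(rates, std, ds.age_groups)
        rows.append(
            {
                "gender": gender,
                "deaths": deaths,
                "pct_of_total": round(100 * deaths / total, 2),
                "crude_rate_per1e5": round(crude_rate(deaths, pop), 3),
                "asr_esp2013_25plus_per1e5": round(asr, 3),
            }
        )
        print(
            f"{gender}: {deaths:,} deaths ({rows[-1]['pct_of_total']}%), "
            f"crude {rows[-1]['crude_rate_per1e5']} / ASR {rows[-1]['asr_esp2013_25plus_per1e5']} per 100,000"
        )
    print(f"total deaths: {total:,}")
    os.makedirs(OUT, exist_ok=True)
    summary = pd.DataFrame(rows)
    summary.to_csv(os.path.join(OUT, "descriptives.csv"), index=False)
    table.to_csv(os.path.join(OUT, "age_specific_rates.csv"), index=False)


if __name__ == "__main__":
    main()
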