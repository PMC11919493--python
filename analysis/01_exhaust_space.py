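#!/usr/bin/env python
"""How fast can a 120 bp gene exhaust its naive polymorphic space?

Two demographic regimes for a gene of length 120 over 4 nucleotides at a
slow bacterial mutation rate (2.54e-10 per site per generation):

* unlimited doubling from a single replicant -- the space is covered in a
  few hundred generations (days of E. coli growth);
* a constant effective population of 2e8 -- the space takes ~1e69 years,
  effectively infinite.

The gap between these two accountings is the paperweight of the whole
analysis: whether the molecular clock can saturate depends entirely on
which space (naive vs effective) and which demography you grant.

Writes results/exhaustion.json.
"""

import json
import math
from pathlib import Path

from polyspace import (
    ExhaustionScenario,
    Regime,
    SemantideSpec,
    TimeScale,
    generations_to_duration,
    generations_to_exhaust,
    space_log_size,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    gene = SemantideSpec.dna(120)
    ts = TimeScale(generation_time_minutes=20)

    n_dbl = generations_to_exhaust(
        ExhaustionScenario.from_space(gene, mu=2.54e-10, n0=1)
    )
    days = generations_to_duration(math.ceil(n_dbl.value), ts).days.value

    n_const = generations_to_exhaust(
        ExhaustionScenario.from_space(gene, mu=2.54e-10, ne=2e8, regime=Regime.CONSTANT_NE)
    )
    years = generations_to_duration(n_const, ts).years

    summary = {
        "space_log10": space_log_size(gene),
        "unlimited_doubling": {
            "n_generations": n_dbl.value,
            "n_rounded_up": math.ceil(n_dbl.value),
            "days_at_20min": days,
        },
        "constant_Ne_2e8": {
            "n_generations_sci": n_const.sci(),
            "n_log10": n_const.log10,
            "years_sci": years.sci(),
            "years_log10": years.log10,
        },
    }
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "exhaustion.json").write_text(json.dumps(summary, indent=2) + "\n")

    print(f"naive space of a 120 bp gene: 10^{summary['space_log10']:.2f} variants")
    print(
        f"unlimited doubling: n = {n_dbl.value:.2f} -> {math.ceil(n_dbl.value)} "
        f"generations (~{days:.1f} days at 20 min/generation)"
    )
    print(
        f"constant Ne = 2e8:  n = {n_const.sci()} generations "
        f"= {years.sci()} years (age of universe ~ 1.38e10 years)"
    )


if __name__ == "__main__":
    main()
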