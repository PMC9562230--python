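#!/usr/bin/env python
"""Select aroma-active compounds by OAV and assemble the modulator sets.

Reads the simulated chemistry (run 01 first), computes each compound's
odour activity value at its mean concentration, applies the OAV > 1 rule
with the literature overrides, and groups the survivors into the five
flavour modulators.  Output: results/modulators.json.
"""

import json
from pathlib import Path

import pandas as pd

from winepi.modulators import (
    DEFAULT_ASSIGNMENT,
    DEFAULT_OVERRIDES,
    CompoundRecord,
    assemble_modulators,
    select_compounds,
)
from winepi.synthetic import default_compound_specs

STUDY = Path("results/study")
OUT = Path("results/modulators.json")


def main() -> None:
    chemistry = pd.read_csv(STUDY / "chemistry.csv", index_col="wine_id")
    odt = {s.name: s.odt for s in default_compound_specs()}
    # a compound is aroma-active if its OAV exceeds 1 in at least one wine,
    # so selection scores each compound at its maximum concentration
    max_conc = chemistry.max(axis=0)
    records = [
        CompoundRecord(name=name, concentration=float(max_conc[name]), odt=odt[name])
        for name in chemistry.columns
    ]
    selected = select_compounds(records)
    sets = assemble_modulators(selected, DEFAULT_ASSIGNMENT)

    by_rule = [r.name for r in records if r.oav > 1]
    by_override = [n for n in selected if n not in by_rule]
    print(f"{len(by_rule)} compounds exceed OAV 1: {by_rule}")
    print(f"{len(by_override)} admitted by override "
          f"(literature-selected: {sorted(DEFAULT_OVERRIDES)}): {by_override}")
    for s in sets:
        print(f"  {s.label:>6}: {', '.join(s.members)}")

    OUT.write_text(
        json.dumps(
            {
                "selected": selected,
                "selected_by_oav": by_rule,
                "selected_by_override": by_override,
                "modulators": {s.label: list(s.members) for s in sets},
                "oav_at_max_concentration": {r.name: round(r.oav, 4) for r in records},
            },
            indent=2,
        )
    )
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
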