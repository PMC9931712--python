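#!/usr/bin/env python
"""Cleavage-product mass tables and MALDI peak assignment.

Enumerates theoretical AICD and Abeta product masses for the C100-His6
substrate and its poly-Leu chimeras at the canonical epsilon/zeta/gamma
sites, then demonstrates the assignment logic on a synthetic peak list
(species masses jittered by 0.3 Da, singly protonated, 1 Da tolerance).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from dhxflex.cleavage import (
    PROTON,
    assign_peaks,
    enumerate_species,
    standard_constructs,
)

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    tables = []
    for name, cons in standard_constructs().items():
        species = enumerate_species(cons)
        species.insert(0, "construct", name)
        tables.append(species)

        peaks = pd.DataFrame(
            {
                "mz": species["avg_mass"] + PROTON + rng.normal(0, 0.3, len(species)),
                "intensity": rng.uniform(5, 100, len(species)),
            }
        )
        assigned = assign_peaks(peaks, species, tolerance=1.0)
        aicd = species[species.side == "C"].set_index("site")
        print(
            f"{name:14s} AICD50 {aicd.loc['eps49', 'avg_mass']:9.2f} Da, "
            f"AICD51 {aicd.loc['eps48', 'avg_mass']:9.2f} Da; "
            f"assigned {int(assigned.assigned.sum())}/{len(assigned)} synthetic peaks"
        )
        assigned.to_csv(OUT / f"assignments_{name}.tsv", sep="\t",
                        index=False, float_format="%.3f")

    pd.concat(tables).to_csv(OUT / "cleavage_species.tsv", sep="\t",
                             index=False, float_format="%.4f")
    print(f"\nspecies table -> {OUT / 'cleavage_species.tsv'}")


if __name__ == "__main__":
    main()
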