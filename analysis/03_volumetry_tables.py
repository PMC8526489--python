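#!/usr/bin/env python
"""Reference volumetry of the Bombus terrestris standard brain.

Computes relative neuropil volumes of the published standard brain — with
and without the lamina/ocellar exclusion used for cross-species comparison —
and the extent comparison of the three hymenopteran standard brain models.
Writes results/standard_brain_percentages.csv and results/atlas_extents.csv.
"""

from pathlib import Path

import pandas as pd

from isatlas.core import round_half_up
from isatlas.volumetry import (
    atlas_extent_stats,
    load_reference_brain,
    load_reference_extents,
    relative_volumes,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ref = load_reference_brain()
    vols = ref["standard_brain_volumes_um3"]
    groups = ref["groups"]
    rel = relative_volumes(vols, groups)
    rel_excl = relative_volumes(vols, groups, exclude=set(ref["exclude_for_comparison"]))
    table = pd.DataFrame({
        "volume (µm³)": pd.Series(vols),
        "relative volume (%)": pd.Series({k: round_half_up(v * 10) / 10 for k, v in rel.items()}),
        "relative volume w/o LA, OC (%)": pd.Series(
            {k: round_half_up(v * 10) / 10 for k, v in rel_excl.items()}
        ),
    })
    (ROOT / "results").mkdir(exist_ok=True)
    table.to_csv(ROOT / "results" / "standard_brain_percentages.csv", float_format="%.6g")
    print(table.loc[["RN", "OC", "CX", "OL", "MB"]])

    extents = atlas_extent_stats(load_reference_extents())
    extents.to_csv(ROOT / "results" / "atlas_extents.csv")
    cols = [c for c in extents.columns if c.startswith("size")]
    print(extents[cols])


if __name__ == "__main__":
    main()
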