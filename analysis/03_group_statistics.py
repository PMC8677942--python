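#!/usr/bin/env python
"""GEE group statistics on the extracted features.

Fits, per ERG feature, marginal linear models of feature vs optic-
neuropathy status (unadjusted and age-adjusted) with exchangeable working
correlation and sandwich standard errors, plus the control-source
contrasts (fellow vs other controls, healthy vs other controls).
"""

from pathlib import Path

import pandas as pd

from phnrlab.stats import (compare_control_sources, compare_on_vs_control,
                           fits_to_frame)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    features = pd.read_csv(OUT / "features.csv")
    usable = features[features["qc_pass"].astype(bool)]
    tables = [
        fits_to_frame(compare_on_vs_control(usable), "on_vs_control"),
        fits_to_frame(compare_on_vs_control(usable, adjust_age=True),
                      "on_vs_control_age_adjusted"),
    ]
    for contrast, fits in compare_control_sources(usable).items():
        tables.append(fits_to_frame(fits, f"control_sources:{contrast}"))
    stats = pd.concat(tables, ignore_index=True)
    stats.to_csv(OUT / "gee_models.csv", index=False)

    on_rows = stats[(stats["model"] == "on_vs_control") & (stats["term"] == "on")]
    print("ON-status effects (exchangeable GEE, sandwich SE):")
    print(on_rows[["feature", "estimate", "robust_se", "p"]]
          .to_string(index=False))
    ctl = stats[stats["model"].str.startswith("control_sources")]
    ctl = ctl[~ctl["term"].eq("intercept")]
    print("\ncontrol-source contrasts (expected null):")
    print(ctl[["model", "feature", "estimate", "p"]].to_string(index=False))


if __name__ == "__main__":
    main()
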