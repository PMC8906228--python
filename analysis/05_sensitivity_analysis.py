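#!/usr/bin/env python
"""Error-zeroing sensitivity analysis of the margin budget.

For every site/axis budget, zero each error source (and the stated pairs),
recompute both margins, and classify the interaction level.  Summarizes
which sources the margin actually hinges on.
"""

from pathlib import Path

import pandas as pd

from synchromargin import cli_report, deformation as dfm, error_model as em, sensitivity as sdt
from synchromargin.log_io import AXES

OUT = Path("results")
SEED = 1


def main():
    OUT.mkdir(exist_ok=True)
    cfg = cli_report.RunConfig(seed=SEED, output_dir=str(OUT))
    cohort = cli_report.simulate_from_config(cfg)

    rows = []
    for site, _, _ in cohort.config.sites:
        bundles = cohort.by_site(site)
        est = dfm.site_deformation(bundles, k=cfg.kmeans_k, seed=SEED)
        budgets = em.build_budget(bundles, site, est.deformation_uncertainty_mm, cfg.constants())
        for axis in AXES:
            for method in ("van_herk", "uncertainty"):
                for hyp in sdt.HYPOTHESES:
                    r = sdt.zero_and_recompute(budgets[axis], hyp, method=method)
                    rows.append(
                        {
                            "tumor_site": site,
                            "axis": axis,
                            "method": method,
                            "hypothesis": hyp,
                            "original_mm": r.original_margin_mm,
                            "recalculated_mm": r.recalculated_margin_mm,
                            "interaction_mm": r.interaction_level_mm,
                            "impact_class": r.impact_class,
                        }
                    )

    table = pd.DataFrame(rows)
    table.to_csv(OUT / "sdt.csv", index=False, float_format="%.4f")

    vh = table.query("method == 'van_herk'")
    by_hyp = vh.groupby("hypothesis")["interaction_mm"].mean().sort_values(ascending=False)
    print("mean interaction level by hypothesis (Van Herk, mm):")
    for hyp, val in by_hyp.items():
        print(f"  {hyp:26s} {val:.2f}")
    robot = vh.query("hypothesis == 'robot'")["interaction_mm"]
    pair = vh.query("hypothesis == 'correlation+prediction'")["interaction_mm"]
    print(
        f"robot impact is low everywhere (max {robot.max():.2f} mm); the tracking pair "
        f"dominates (mean {pair.mean():.2f} mm, max {pair.max():.2f} mm)"
    )
    print(f"wrote {OUT/'sdt.csv'}")


if __name__ == "__main__":
    main()
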