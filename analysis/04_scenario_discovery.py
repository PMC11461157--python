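#!/usr/bin/env python
"""Scenario discovery on the threshold-analysis output.

Step 1: rank the four designed test characteristics (plus the parameter-set
label) by random-forest mean-decrease-in-Gini importance for predicting a
scenario's cost-effectiveness.  Step 2: smooth net monetary benefit over the
three most important characteristics with locally weighted regression,
conditioned on 92% CRC sensitivity (the best case), on an evenly spaced grid
of ~10,000 points, and extract iso-NMB contours including the decennial
colonoscopy reference level — the "map" a test developer can read the
required (cost, AA sensitivity, interval) combinations from.

Reads results/scenarios.csv (run 03 first); writes results/importance.csv,
results/nmb_surface.csv, results/contours.json and a heat-map figure under
scratch/.
"""

import sys
from pathlib import Path

import numpy as np

from crcscreen.config import RunConfig
from crcscreen.pipeline import read_output_csv, run_discovery

N = 5_000
SEED = 1


def main() -> int:
    scen_path = Path("results/scenarios.csv")
    if not scen_path.exists():
        print("results/scenarios.csv missing - run analysis/03_threshold_grid.py"
              " first", file=sys.stderr)
        return 1
    table = read_output_csv(scen_path)
    config = RunConfig(cohort_n=N, seed=SEED, output_dir=Path("results"))

    ranking, surface, contours = run_discovery(config, scenario_table=table)
    print("variable importance (mean decrease in Gini):")
    for var, score, rank in ranking.entries:
        print(f"  {rank}. {var:<10} {score:.3f}")
    print(f"\nsurface: {len(surface.table)} grid points over "
          f"{surface.axis_vars} per {surface.panel_var} panel, conditioned on "
          f"{surface.conditioning}")
    print(f"colonoscopy reference NMB: ${surface.reference_level:,.0f}")

    above = surface.table[surface.table.nmb_smoothed >= surface.reference_level]
    if len(above):
        print(f"{len(above)} of {len(surface.table)} grid points match or "
              f"exceed the colonoscopy NMB; among them max cost = "
              f"${above.cost.max():.0f}, min AA sensitivity = "
              f"{above.aa_sens.min():.0%}")
    else:
        print("no grid point reaches the colonoscopy NMB under these settings")

    try:
        _plot(surface)
    except Exception as exc:  # plotting is cosmetic
        print(f"(figure skipped: {exc})")
    print("wrote results/importance.csv, results/nmb_surface.csv, "
          "results/contours.json")
    return 0


def _plot(surface) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    levels = np.sort(surface.table[surface.panel_var].unique())
    fig, axes = plt.subplots(1, len(levels), figsize=(4 * len(levels), 3.4),
                             sharey=True)
    for ax, lv in zip(np.atleast_1d(axes), levels):
        xs, ys, z = surface.panel(lv)
        im = ax.pcolormesh(xs, ys, z.T, shading="auto", cmap="viridis")
        cs = ax.contour(xs, ys, z.T, colors="white", linestyles="--",
                        linewidths=0.8)
        ax.clabel(cs, fontsize=6, fmt="%.0f")
        if surface.reference_level is not None:
            ax.contour(xs, ys, z.T, levels=[surface.reference_level],
                       colors="black", linestyles="--", linewidths=1.6)
        ax.set_title(f"{surface.panel_var} = {lv:g} y")
        ax.set_xlabel(surface.axis_vars[0])
    np.atleast_1d(axes)[0].set_ylabel(surface.axis_vars[1])
    fig.colorbar(im, ax=axes, label="smoothed NMB ($/person)")
    out = Path("scratch")
    out.mkdir(exist_ok=True)
    fig.savefig(out / "nmb_map.png", dpi=150)
    print("figure: scratch/nmb_map.png")


if __name__ == "__main__":
    sys.exit(main())
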