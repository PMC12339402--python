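#!/usr/bin/env python
"""Quantify peripheral vs internal nuclear marker distributions.

Simulates nuclei whose marker is peripherally ring-shaped (lamina-tethered
heterochromatin), internally focal (nucleoplasmic aggregates) or uniform,
then computes total intensity, 25-shell radial profiles, and a TEM-style
nuclear-envelope : nucleoplasm integrated-density ratio from 40 sampled
0.2 um squares per region.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ladkit.config import Config
from ladkit.imaging import (
    radial_shell_profile,
    sample_region_points,
    tem_periphery_ratio,
    total_intensity,
)
from ladkit.pipeline import stage_seed
from ladkit.simulate import SimParams, simulate_nucleus

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
SEED = 20_240_101 % (2**31)


def main() -> None:
    config = Config()
    params = SimParams(image_noise_sd=3.0)
    rows = []
    for mode in ("peripheral", "internal", "uniform"):
        img = simulate_nucleus(params, mode=mode,
                               seed=stage_seed(SEED, f"nucleus:{mode}"))
        prof = radial_shell_profile(img, "marker", config.n_shells)
        for shell in range(config.n_shells):
            rows.append({"mode": mode, "shell": shell + 1,
                         "intensity_fraction": prof.intensity_fraction[shell],
                         "area_fraction": prof.area_fraction[shell],
                         "normalized_mean": prof.normalized_mean[shell]})
        outer2 = prof.intensity_fraction[-2:].sum()
        print(f"{mode}: total intensity {total_intensity(img, 'marker'):.3g}, "
              f"outermost 2 of {config.n_shells} shells hold {outer2:.1%} "
              f"of marker signal")

        # TEM-style ratio on the same nucleus, with pixel size matched so a
        # 0.2 um square is 2 px wide
        ne = sample_region_points(img.mask, "NE", config.tem_n_squares,
                                  seed=stage_seed(SEED, f"ne:{mode}"),
                                  pixel_size=params.pixel_size_um)
        npl = sample_region_points(img.mask, "nucleoplasm",
                                   config.tem_n_squares,
                                   seed=stage_seed(SEED, f"np:{mode}"),
                                   pixel_size=params.pixel_size_um)
        q = tem_periphery_ratio(img.channels["marker"], ne, npl,
                                config.tem_square_um, params.pixel_size_um)
        print(f"  NE:nucleoplasm integrated-density ratio = {q.ratio:.2f}")

    pd.DataFrame(rows).to_csv(OUT / "radial_profiles.tsv", sep="\t",
                              index=False)
    print(f"wrote {OUT / 'radial_profiles.tsv'}")


if __name__ == "__main__":
    main()
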