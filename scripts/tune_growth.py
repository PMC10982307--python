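#!/usr/bin/env python
"""Sweep RUE and seed-fill fraction and report the continental archetype's
best-maturity-group potential yield for each pair.

Used to choose the packaged GrowthConfig defaults so continental potential
yields land in a realistic 3-5 t/ha window; the chosen values are defaults,
not measurements.

Usage: python scripts/tune_growth.py [--seed 1]
"""

from __future__ import annotations

import argparse

import numpy as np

import eurosoy as es
from eurosoy.growth import GrowthConfig


def best_potential(growth_cfg: GrowthConfig, seed: int) -> float:
    grid = es.gen_site_grid(1, 1).assign(lat=[47.0])
    weather = {0: es.gen_weather(es.DEFAULT_ARCHETYPES["continental"], 10,
                                 seed=seed, lat=47.0)}
    soils = {0: es.gen_soil(seed)}
    res = es.run_factorial(grid, weather, soils, growth_cfg=growth_cfg)
    pot = res[res["config"] == "potential"]
    return float(pot.groupby("maturity_group")["yield_t_ha"].mean().max())


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    print(f"{'rue':>5} {'fill':>5} {'best potential t/ha':>20}")
    for rue in (0.75, 0.85, 0.95, 1.05):
        for fill in (0.45, 0.55, 0.65):
            cfg = GrowthConfig(rue=rue, seed_fill_fraction=fill)
            y = best_potential(cfg, args.seed)
            marker = " <- default" if (rue, fill) == (0.85, 0.55) else ""
            print(f"{rue:5.2f} {fill:5.2f} {y:20.2f}{marker}")


if __name__ == "__main__":
    main()
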