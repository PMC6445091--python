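"""Mechanism sweep: effects of a prescribed, constant fixation rate.

A single-pool stand with fixer physiology is simulated for 100 years
across a grid of prescribed per-biomass fixation rates, at the low and
2030 deposition levels (tropical parameterization).  CO2 sequestration
rises with fixation while nitrogen is limiting and plateaus once it is
not; soil N2O emissions stay flat while fixed N is absorbed by growth
and rise once it is not — with the rise starting at a lower fixation
rate under high deposition.

Run after 01_calibrate.py:  python analysis/03_fixation_sweep.py
"""

import argparse
import importlib.util
from pathlib import Path

import numpy as np
import pandas as pd

import nfixclim as nx
from nfixclim import config as cfg, io

_mod = importlib.util.spec_from_file_location(
    "calib_loader", Path(__file__).parent / "02_ecosystem_effects.py"
)
_loader = importlib.util.module_from_spec(_mod)
_mod.loader.exec_module(_loader)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--config", default=None)
    ap.add_argument("--out-dir", default="results", type=Path)
    ap.add_argument("--biome", default="tropical")
    ap.add_argument("--n-points", type=int, default=21)
    ap.add_argument("--f-max", type=float, default=2.5e-3)
    args = ap.parse_args()

    calcfg = _loader.load_calibrated(args.out_dir, args.config)
    params = cfg.get_parameter_set(calcfg, args.biome)
    F = np.linspace(0.0, args.f_max, args.n_points)

    tables = []
    for level in ("low", "high_2030"):
        dep = cfg.deposition_rate(calcfg, args.biome, level)
        table = nx.single_pool_sweep(F, params, dep, calcfg)
        table.insert(0, "deposition", level)
        tables.append(table)
    out = pd.concat(tables, ignore_index=True)

    io.write_table(out, args.out_dir / f"fixation_sweep_{args.biome}.tsv")
    io.write_manifest(args.out_dir / f"fixation_sweep_{args.biome}.manifest.json",
                      calcfg, "03_fixation_sweep", extra={"biome": args.biome})

    for level in ("low", "high_2030"):
        sub = out[out.deposition == level]
        seq = -sub.co2_gwp.values / 1000
        n2o = sub.n2o_gwp.values / 1000
        print(f"{args.biome} {level}: CO2 sequestration {seq[0]:.2f} -> {seq[-1]:.2f} "
              f"Mg CO2/ha/yr (plateau); N2O effect {n2o[0]:.2f} -> {n2o[-1]:.2f}")
    print(f"wrote {args.out_dir}/fixation_sweep_{args.biome}.tsv")


if __name__ == "__main__":
    main()
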