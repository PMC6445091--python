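"""Ecosystem-scale CO2 and N2O effects of N-fixing trees.

Runs the full factorial design (biome x composition x deposition x
initial soil N, 100-yr simulations) under the calibrated parameters and
tabulates absolute and relative effects under both accounting methods,
plus the initial-soil-N sensitivity summary.  The headline pattern: at
low deposition every fixation strategy cools relative to non-fixers
(incomplete regulator most), while at 2030 deposition the obligate and
incomplete-regulator strategies warm and the facultative effect is
negligible.

Run after 01_calibrate.py:  python analysis/02_ecosystem_effects.py
"""

import argparse
from pathlib import Path

import yaml

import nfixclim as nx
from nfixclim import io


def load_calibrated(results_dir: Path, config_path: str | None):
    cal = results_dir / "calibrated_config.yaml"
    if cal.exists():
        return yaml.safe_load(cal.read_text())
    print("calibrated_config.yaml not found; calibrating now")
    config = nx.load_config(config_path)
    calcfg, _ = nx.calibrated_config(config)
    return calcfg


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--config", default=None)
    ap.add_argument("--out-dir", default="results", type=Path)
    args = ap.parse_args()

    calcfg = load_calibrated(args.out_dir, args.config)
    grid = nx.run_experiment_grid(calcfg)
    sens = nx.initial_soil_sensitivity(grid)

    io.write_table(grid, args.out_dir / "ecosystem_effects.tsv")
    io.write_table(sens, args.out_dir / "initial_soil_sensitivity.tsv")
    io.write_manifest(args.out_dir / "ecosystem_effects.manifest.json", calcfg,
                      "02_ecosystem_effects", extra={"rows": len(grid)})

    rel = grid[(grid.kind == "relative") & (grid.initial_n == "intermediate")]
    print("Net relative effects (Mg CO2-eq/ha/yr; negative = cooling):")
    for biome in calcfg["biomes"]:
        for dep in ("low", "high_2030"):
            sub = rel[(rel.biome == biome) & (rel.deposition == dep)]
            vals = ", ".join(
                f"{r.composition}={r.net_gwp / 1000:+.2f}" for r in sub.itertuples()
            )
            print(f"  {biome:9s} {dep:10s}: {vals}")
    print(f"max initial-soil-N spread: {sens.spread_mg_co2.max():.2f} Mg CO2-eq/ha/yr")
    print(f"wrote {args.out_dir}/ecosystem_effects.tsv ({len(grid)} rows)")


if __name__ == "__main__":
    main()
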