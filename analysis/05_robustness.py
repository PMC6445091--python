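"""Robustness of the qualitative conclusions to parameter uncertainty.

Draws a seeded ensemble of tropical parameter sets (every rate constant
perturbed by an independent log-uniform factor) and evaluates the
sign-structure claims on each member: all strategies cool at low
deposition; the obligate strategy warms at 2030 deposition; the
facultative effect is negligible at 2030 deposition.  Reports the
fraction of members satisfying each claim.

Run after 01_calibrate.py:  python analysis/05_robustness.py
"""

import argparse
import importlib.util
from pathlib import Path

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
    ap.add_argument("--n", type=int, default=16)
    ap.add_argument("--spread", type=float, default=0.1)
    ap.add_argument("--seed", type=int, default=20260921)
    args = ap.parse_args()

    calcfg = _loader.load_calibrated(args.out_dir, args.config)
    nominal = cfg.get_parameter_set(calcfg, args.biome)
    ensemble = nx.sample_parameter_ensemble(nominal, args.spread, args.n, args.seed)
    report = nx.qualitative_invariant_battery(ensemble, calcfg, args.biome)

    io.write_table(report, args.out_dir / f"robustness_{args.biome}.tsv")
    io.write_manifest(args.out_dir / f"robustness_{args.biome}.manifest.json",
                      calcfg, "05_robustness", seed=args.seed,
                      extra={"n_members": args.n, "spread": args.spread})
    print(report.to_string(index=False))
    print(f"wrote {args.out_dir}/robustness_{args.biome}.tsv")


if __name__ == "__main__":
    main()
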