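#!/usr/bin/env python
"""Regenerate the packaged octahedral quadrature grids.

Solves the moment conditions for every packaged grid size (see
dracopcm.gridgen) and writes src/dracopcm/data/grid_params.json.  Existing
entries are kept unless --force is given, so interrupted runs resume.
"""

import argparse
import json
from pathlib import Path

from dracopcm.gridgen import COMPOSITIONS, generate_grid

OUT = Path(__file__).resolve().parent.parent / "src" / "dracopcm" / "data" / "grid_params.json"


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--orders", type=int, nargs="*", default=None)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--tries", type=int, default=40)
    ap.add_argument("--force", action="store_true")
    args = ap.parse_args()

    table = {}
    if OUT.exists() and not args.force:
        table = json.loads(OUT.read_text())
    for order in sorted(args.orders or COMPOSITIONS):
        if str(order) in table and not args.force:
            print(f"size {order:4d}: kept (degree {table[str(order)]['degree']})")
            continue
        rec, degree, err = generate_grid(order, seed=args.seed, tries=args.tries)
        table[str(order)] = rec
        OUT.parent.mkdir(parents=True, exist_ok=True)
        OUT.write_text(json.dumps(table, indent=1, sort_keys=True) + "\n")
        print(f"size {order:4d}: degree {degree}, residual {err:.2e}", flush=True)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
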