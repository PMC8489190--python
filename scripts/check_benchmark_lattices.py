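#!/usr/bin/env python
"""Optional external check: solution-space size of a hierarchy collection.

The ARX genetic-benchmark repository
(https://github.com/arx-deidentifier/genetic-benchmark) publishes the
generalization hierarchies of six public evaluation datasets together with
the size of the resulting solution-space lattice, e.g. 49,478,023,249,920
schemes for the 24-attribute credit-card dataset and 203,843,174,400 for the
30-attribute community-survey dataset.  After downloading those hierarchies
(this script performs no network access itself), point it at the directory of
hierarchy files for one dataset to recompute the lattice size with
``anonlattice.lattice_size`` and compare it with the published value:

    python scripts/check_benchmark_lattices.py path/to/hierarchies \
        --expected 49478023249920

This check is deliberately separate from the test suite and the acceptance
script, which run fully offline on generated data.
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

from anonlattice import lattice_size, read_hierarchy


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("hierarchy_dir", type=Path,
                        help="Directory with one hierarchy CSV per attribute.")
    parser.add_argument("--delimiter", default=";",
                        help="Hierarchy file delimiter (default ';').")
    parser.add_argument("--expected", type=int, default=None,
                        help="Published solution-space size to compare with.")
    args = parser.parse_args()

    files = sorted(args.hierarchy_dir.glob("*.csv"))
    if not files:
        print(f"no hierarchy files found in {args.hierarchy_dir}",
              file=sys.stderr)
        return 2
    heights = []
    for path in files:
        h = read_hierarchy(path, delimiter=args.delimiter)
        heights.append(h.height)
        print(f"{path.name}: height {h.height}")
    size = lattice_size(heights)
    print(f"lattice size over {len(heights)} attributes: {size:,}")
    if args.expected is not None:
        if size == args.expected:
            print("matches the published size")
            return 0
        print(f"MISMATCH: published size is {args.expected:,}",
              file=sys.stderr)
        return 1
    return 0


if __name__ == "__main__":
    sys.exit(main())
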