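"""Regenerate the shipped steady-state snapshots.

Pre-paces every standard configuration (variant x cell type x cycle
length x coupling mode used by the test-suite and the drug-trial
protocols) to the beat-to-beat convergence criterion, starting from the
bootstrap resting state, using the calibrated contraction parameters.

Usage: python scripts/make_snapshots.py
"""

import sys
import time
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from emcell.snapshots import generate_snapshot

CONFIGS = [
    # (variant, celltype, cl, coupled)
    ("torord", "endo", 1000.0, True),
    ("torord", "endo", 1000.0, False),
    ("torord", "epi", 1000.0, True),
    ("torord", "mid", 1000.0, True),
    ("torord", "endo", 4000.0, True),
    ("torord", "endo", 4000.0, False),
    ("torord", "endo", 2000.0, True),
    ("torord", "endo", 500.0, True),
    ("ord", "endo", 1000.0, True),
    ("ord", "endo", 1000.0, False),
    ("ord", "epi", 1000.0, True),
    ("ord", "mid", 1000.0, True),
]


def main() -> None:
    for variant, celltype, cl, coupled in CONFIGS:
        t0 = time.time()
        path = generate_snapshot(variant, celltype, cl, coupled)
        print(f"{path.name}: {time.time() - t0:.0f} s")


if __name__ == "__main__":
    main()
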