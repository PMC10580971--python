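#!/usr/bin/env python
"""Generate the synthetic 48-sample study (4 sites x 4 depths x 3 replicates).

Emits, under results/demo/inputs/: a niche-leaning "mcrA" OTU table (strong
water-table filtering), a neutral-leaning "pmoA" table (m = 0.5), sample
metadata with the four site water-table levels, chamber CH4 series at the
four site flux levels, production/oxidation incubation series, and a qPCR
standard curve — plus the pipeline config that analyses them.
"""

from pathlib import Path

from peatmethane.pipeline import generate_demo

ROOT = Path(__file__).resolve().parents[1]

if __name__ == "__main__":
    cfg = generate_demo(ROOT / "results" / "demo", seed=7)
    print(f"synthetic study written; pipeline config at {cfg}")
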