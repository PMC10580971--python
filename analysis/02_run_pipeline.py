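#!/usr/bin/env python
"""Run the full analysis pipeline on the synthetic study.

Per marker gene: rarefaction, alpha diversity, Bray-Curtis PCoA, PERMANOVA
(site and depth), neutral-model fit with taxon partitioning, within-site
MST, Levins niche breadth, and the thresholded Spearman co-occurrence
network; plus chamber fluxes, incubation rates and qPCR quantification.
Outputs land under results/demo/results/ with a reproducibility manifest.
"""

import json
from pathlib import Path

from peatmethane.pipeline import PipelineConfig, run_pipeline

ROOT = Path(__file__).resolve().parents[1]

if __name__ == "__main__":
    cfg_path = ROOT / "results" / "demo" / "config.yaml"
    if not cfg_path.exists():
        raise SystemExit("run analysis/01_simulate_study.py first")
    manifest = run_pipeline(PipelineConfig.from_yaml(cfg_path))
    print(f"{len(manifest.outputs)} outputs, {len(manifest.warnings)} warnings")
    outdir = ROOT / "results" / "demo" / "results"
    for marker in ("mcrA", "pmoA"):
        s = json.loads((outdir / marker / "summary.json").read_text())
        print(
            f"{marker}: NCM m={s['ncm']['m']:.3f} R2={s['ncm']['R2']:.3f} | "
            f"MST={s['mst']['overall_mean_pct']:.1f}% | "
            f"niche breadth B={s['niche_breadth_mean']:.2f} | "
            f"PERMANOVA site p={s['permanova_site']['p']:.4f}"
        )
    print("expected contrast: the niche-leaning marker (mcrA) shows the lower "
          "NCM R2 and an MST below 50%; the neutral-leaning marker (pmoA) the "
          "opposite.")
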