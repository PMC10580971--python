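"""Configuration-driven orchestration of the full analysis graph.

A single YAML config names the inputs (OTU tables per marker gene, sample
metadata, gas series, qPCR tables — or a synthetic demo block), the
thresholds, and an explicit seed for every stochastic stage. ``run_pipeline``
executes rarefaction -> alpha diversity -> dissimilarity -> PCoA/PERMANOVA
-> neutral model -> MST -> niche breadth -> co-occurrence networks -> gas
kinetics, writes every result as TSV/JSON under the output directory, and
returns a manifest (config hash, version, seeds, file list, warnings) that
fully determines re-execution: re-running the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assembly import compute_mst, fit_ncm, niche_breadth, partition_taxa
from .community import (
    OTUTable,
    SampleMetadata,
    alpha_diversity,
    beta_dissimilarity,
    pcoa,
    permanova,
    rarefy,
    read_metadata,
    read_otu_table,
)
from .gas import (
    ChamberSeries,
    IncubationSeries,
    chamber_flux,
    dilution_correct,
    fit_standard_curve,
    potential_rate,
    quantify_abundance,
)
from .network import build_network, filter_taxa, network_topology
from .synthetic import (
    GasSimConfig,
    NeutralSimConfig,
    NicheSimConfig,
    simulate_chamber_series,
    simulate_incubation_series,
    simulate_neutral_table,
    simulate_niche_table,
    simulate_qpcr_curve,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "generate_demo"]

_REQUIRED_SEED_STAGES = ("rarefy", "permanova", "mst")

SITES = ("EHB1", "NNF1", "YLC2", "YLC6")
# water table levels (cm) of the four study sites
SITE_WTL = {"EHB1": -2.63, "NNF1": -8.07, "YLC2": -1.01, "YLC6": 2.65}
DEPTH_LAYERS = ("0-5", "10-15", "20-25", "30-35")
N_REPLICATES = 3


# --------------------------------------------------------------------------
# config
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    raw: dict

    def __post_init__(self) -> None:
        cfg = self.raw
        seeds = cfg.get("seeds")
        if not isinstance(seeds, dict):
            raise ValueError("config must define a 'seeds' mapping")
        missing = [s for s in _REQUIRED_SEED_STAGES if s not in seeds]
        if missing:
            raise ValueError(f"config missing explicit seeds for stages: {missing}")
        thr = cfg.get("thresholds", {})
        r = thr.get("network_r", 0.7)
        p = thr.get("network_p", 0.01)
        mra = thr.get("min_rel_abundance", 0.001)
        if not 0 < r < 1 or not 0 < p < 1 or not 0 <= mra < 1:
            raise ValueError("thresholds out of valid ranges")
        if thr.get("mst_randomizations", 1000) < 100:
            raise ValueError("mst_randomizations must be >= 100")
        if "markers" not in cfg or not cfg["markers"]:
            raise ValueError("config must name at least one marker-gene OTU table")
        if "metadata" not in cfg:
            raise ValueError("config must name a metadata table")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    @property
    def seeds(self) -> dict:
        return self.raw["seeds"]

    @property
    def thresholds(self) -> dict:
        return self.raw.get("thresholds", {})

    def hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seeds: dict
    outputs: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        rec = {
            "config_hash": self.config_hash,
            "version": self.version,
            "seeds": self.seeds,
            "outputs": sorted(self.outputs),
            "warnings": self.warnings,
        }
        Path(path).write_text(json.dumps(rec, indent=2, sort_keys=True) + "\n")


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def _analyse_marker(
    name: str,
    table: OTUTable,
    meta: SampleMetadata,
    cfg: PipelineConfig,
    outdir: Path,
    manifest: RunManifest,
) -> None:
    thr = cfg.thresholds
    mdir = outdir / name
    mdir.mkdir(parents=True, exist_ok=True)

    def emit(relpath: str) -> Path:
        manifest.outputs.append(f"{name}/{relpath}")
        return mdir / relpath

    depth_spec = cfg.raw.get("rarefaction_depth", "min")
    depth = int(table.sample_depths().min()) if depth_spec == "min" else int(depth_spec)
    rt = rarefy(table, depth, seed=cfg.seeds["rarefy"])
    rt.to_tsv(emit("rarefied.tsv"))

    alpha_diversity(rt).to_csv(emit("alpha_diversity.tsv"), sep="\t")

    summary: dict = {"marker": name, "rarefaction_depth": depth}
    dm = beta_dissimilarity(rt, "bray_curtis")
    dm.to_tsv(emit("bray_curtis.tsv"))
    ord_res = pcoa(dm)
    ord_res.to_tsv(emit("pcoa.tsv"))
    summary["pcoa_explained"] = [float(x) for x in ord_res.explained[:3]]

    n_perm = int(cfg.raw.get("permanova_permutations", 999))
    for factor in ("site", "depth_layer"):
        groups = meta.group_labels(factor, rt.sample_ids)
        res = permanova(dm, groups, n_perm, seed=cfg.seeds["permanova"])
        summary[f"permanova_{factor}"] = {
            "pseudo_F": res.pseudo_f, "R2": res.r2, "p": res.p_value,
        }

    fit = fit_ncm(rt)
    fit.taxa.to_csv(emit("ncm_taxa.tsv"), sep="\t")
    parts = partition_taxa(fit, rt)
    summary["ncm"] = fit.summary()
    summary["ncm"]["taxon_fractions"] = parts.taxon_fractions.to_dict()
    summary["ncm"]["sequence_fractions"] = parts.sequence_fractions.to_dict()

    groups = meta.group_labels("site", rt.sample_ids)
    mst = compute_mst(
        rt, groups,
        n_randomizations=int(thr.get("mst_randomizations", 1000)),
        seed=cfg.seeds["mst"],
    )
    mst.pairs.to_csv(emit("mst_pairs.tsv"), sep="\t", index=False)
    summary["mst"] = {
        "overall_mean_pct": mst.overall_mean_pct,
        "group_means_pct": mst.group_means_pct.to_dict(),
        "null_model": mst.null_model,
        "n_randomizations": mst.n_randomizations,
        "seed": mst.seed,
    }
    if mst.n_excluded_pairs:
        manifest.warnings.append(
            f"{name}: {mst.n_excluded_pairs} MST pairs excluded (degenerate null)"
        )

    nb = niche_breadth(rt, min_occurrence=int(thr.get("niche_min_occurrence", 1)))
    nb.per_taxon.to_csv(emit("niche_breadth.tsv"), sep="\t")
    summary["niche_breadth_mean"] = nb.community_mean

    filtered = filter_taxa(rt, float(thr.get("min_rel_abundance", 0.001)))
    net = build_network(
        filtered,
        r_threshold=float(thr.get("network_r", 0.7)),
        p_threshold=float(thr.get("network_p", 0.01)),
    )
    net.to_edge_tsv(emit("network_edges.tsv"))
    if net.n_zero_variance_skipped:
        manifest.warnings.append(
            f"{name}: {net.n_zero_variance_skipped} zero-variance taxa skipped in network"
        )
    if net.n_edges > 0:
        topo = network_topology(net)
        topo.to_json(emit("network_topology.json"))
        summary["network"] = topo.to_dict()
    else:
        manifest.warnings.append(f"{name}: network has no edges at thresholds")
        summary["network"] = None

    _write_json(emit("summary.json"), summary)


def _analyse_gas(cfg: PipelineConfig, outdir: Path, manifest: RunManifest) -> None:
    gas_cfg = cfg.raw.get("gas")
    if not gas_cfg:
        return
    gdir = outdir / "gas"
    gdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for entry in gas_cfg.get("chamber_series", []):
        df = pd.read_csv(entry["path"])
        series = ChamberSeries(
            times_h=df["time_h"].to_numpy(),
            ch4_ppm=df["ch4_ppm"].to_numpy(),
            chamber_height_m=float(entry["chamber_height_m"]),
            temperature_k=float(entry["temperature_k"]),
            pressure_kpa=float(entry["pressure_kpa"]),
        )
        res = chamber_flux(series)
        rows.append(
            {
                "label": entry.get("label", Path(entry["path"]).stem),
                "flux_mg_m2_h": res.value,
                "slope_ppm_h": res.slope_ppm_h,
                "r_squared": res.r_squared,
                "n_points": res.n_points,
                "qc_flags": ";".join(res.qc_flags),
            }
        )
        for flag in res.qc_flags:
            manifest.warnings.append(f"chamber {rows[-1]['label']}: {flag}")
    if rows:
        pd.DataFrame(rows).to_csv(gdir / "chamber_fluxes.tsv", sep="\t", index=False)
        manifest.outputs.append("gas/chamber_fluxes.tsv")

    rows = []
    for entry in gas_cfg.get("incubation_series", []):
        df = pd.read_csv(entry["path"])
        series = IncubationSeries(
            times_h=df["time_h"].to_numpy(),
            ch4_ppm=df["ch4_ppm"].to_numpy(),
            headspace_ml=float(entry["headspace_ml"]),
            removal_ml=float(entry["removal_ml"]),
            sampling_times_h=df["time_h"].to_numpy(),
            peat_fresh_mass_g=float(entry["peat_fresh_mass_g"]),
            water_content=float(entry["water_content"]),
        )
        corrected = dilution_correct(series)
        res = potential_rate(corrected, mode=entry["mode"])
        rows.append(
            {
                "label": entry.get("label", Path(entry["path"]).stem),
                "mode": res.mode,
                "rate_ug_g_dw_d": res.value,
                "slope_ug_h": res.slope_ug_h,
                "r_squared": res.r_squared,
                "qc_flags": ";".join(res.qc_flags),
            }
        )
        for flag in res.qc_flags:
            manifest.warnings.append(f"incubation {rows[-1]['label']}: {flag}")
    if rows:
        pd.DataFrame(rows).to_csv(gdir / "incubation_rates.tsv", sep="\t", index=False)
        manifest.outputs.append("gas/incubation_rates.tsv")

    qcfg = gas_cfg.get("qpcr")
    if qcfg:
        curve = fit_standard_curve(pd.read_csv(qcfg["standards"]))
        out = {
            "slope": curve.slope,
            "intercept": curve.intercept,
            "r_squared": curve.r_squared,
            "efficiency": curve.efficiency,
            "qc_pass": curve.qc_pass,
            "qc_flags": curve.qc_flags,
        }
        if not curve.qc_pass:
            manifest.warnings.append("qpcr: " + "; ".join(curve.qc_flags))
        rows = []
        for sample in qcfg.get("samples", []):
            res = quantify_abundance(
                curve,
                cq=float(sample["cq"]),
                eluate_volume_ul=float(sample["eluate_volume_ul"]),
                template_volume_ul=float(sample["template_volume_ul"]),
                fresh_mass_g=float(sample["fresh_mass_g"]),
            )
            rows.append(
                {
                    "label": sample.get("label", "sample"),
                    "cq": sample["cq"],
                    "copies_per_g_fresh": res.copies_per_g,
                    "flags": ";".join(res.flags),
                }
            )
        _write_json(gdir / "qpcr_standard_curve.json", out)
        manifest.outputs.append("gas/qpcr_standard_curve.json")
        if rows:
            pd.DataFrame(rows).to_csv(gdir / "qpcr_abundances.tsv", sep="\t", index=False)
            manifest.outputs.append("gas/qpcr_abundances.tsv")


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None) -> RunManifest:
    """Execute all configured stages; returns the reproducibility manifest."""
    outdir = Path(outdir if outdir is not None else cfg.raw.get("outdir", "pipeline_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=cfg.hash(), version=__version__, seeds=dict(cfg.seeds)
    )
    meta = read_metadata(cfg.raw["metadata"])
    for name, block in cfg.raw["markers"].items():
        logger.info("pipeline: analysing marker %s", name)
        table = read_otu_table(block["otu_table"])
        meta.validate_against(table)
        try:
            _analyse_marker(name, table, meta, cfg, outdir, manifest)
        except Exception as exc:
            raise RuntimeError(f"stage failure for marker {name!r} "
                               f"(input {block['otu_table']}): {exc}") from exc
    _analyse_gas(cfg, outdir, manifest)
    manifest.outputs.append("manifest.json")
    manifest.to_json(outdir / "manifest.json")
    return manifest


# --------------------------------------------------------------------------
# demo study generator
# --------------------------------------------------------------------------

def _demo_sample_ids() -> tuple[list[str], pd.DataFrame]:
    rows = []
    for site in SITES:
        for depth in DEPTH_LAYERS:
            for rep in range(1, N_REPLICATES + 1):
                rows.append(
                    {
                        "sample_id": f"{site}-{depth}-R{rep}",
                        "site": site,
                        "depth_layer": depth,
                        "water_table_level": SITE_WTL[site],
                    }
                )
    meta = pd.DataFrame(rows)
    return list(meta["sample_id"]), meta


def generate_demo(outdir: str | Path, seed: int = 0) -> Path:
    """Emit a complete synthetic study and the config that analyses it.

    48 samples (4 sites x 4 depths x 3 replicates, water table levels as in
    the field design); a niche-leaning marker table ("mcrA", strong
    water-table filtering) and a neutral-leaning one ("pmoA", m = 0.5);
    chamber series at the four site fluxes; one production and one
    oxidation incubation; and a qPCR standard curve with samples. Returns
    the path of the written config YAML.
    """
    outdir = Path(outdir)
    (outdir / "inputs").mkdir(parents=True, exist_ok=True)
    sample_ids, meta = _demo_sample_ids()
    SampleMetadata(meta).to_tsv(outdir / "inputs" / "metadata.tsv")

    env = meta["water_table_level"].to_numpy(dtype=float)
    niche = simulate_niche_table(
        NicheSimConfig(
            n_taxa=300, n_samples=48, reads_per_sample=2000,
            env_values=env, sigma=1.2, seed=seed + 1,
        )
    )
    niche.counts.columns = sample_ids
    niche.to_tsv(outdir / "inputs" / "mcrA_otu_table.tsv")

    neutral = simulate_neutral_table(
        NeutralSimConfig(
            n_taxa=150, n_samples=48, reads_per_sample=2000,
            migration_rate=0.5, seed=seed + 2,
        )
    )
    neutral.counts.columns = sample_ids
    neutral.to_tsv(outdir / "inputs" / "pmoA_otu_table.tsv")

    chamber_entries = []
    site_fluxes = {"NNF1": 0.12, "EHB1": 0.32, "YLC2": 1.41, "YLC6": 0.65}
    for k, (site, flux) in enumerate(sorted(site_fluxes.items())):
        series = simulate_chamber_series(
            GasSimConfig(
                true_rate=flux, duration_h=0.5, sampling_interval_h=2.0 / 60.0,
                noise_sd_ppm=0.05, chamber_height_m=0.2,
                temperature_k=293.15, pressure_kpa=101.325, seed=seed + 10 + k,
            )
        )
        path = outdir / "inputs" / f"chamber_{site}.csv"
        series.to_csv(path)
        chamber_entries.append(
            {
                "label": site, "path": str(path), "chamber_height_m": 0.2,
                "temperature_k": 293.15, "pressure_kpa": 101.325,
            }
        )

    incubation_entries = []
    for mode, rate, c0, tag in (
        ("production", 8.0, 1.9, "anoxic"),
        ("oxidation", -60.0, 5555.0, "oxic"),
    ):
        series = simulate_incubation_series(
            GasSimConfig(
                true_rate=rate, duration_h=72.0, sampling_interval_h=24.0,
                noise_sd_ppm=0.0, initial_ppm=c0, headspace_ml=90.0,
                removal_ml=0.5, peat_fresh_mass_g=10.0, water_content=0.9,
                seed=seed + 20,
            )
        )
        path = outdir / "inputs" / f"incubation_{tag}.csv"
        series.to_csv(path)
        incubation_entries.append(
            {
                "label": tag, "path": str(path), "mode": mode,
                "headspace_ml": 90.0, "removal_ml": 0.5,
                "peat_fresh_mass_g": 10.0, "water_content": 0.9,
            }
        )

    standards = simulate_qpcr_curve(efficiency=0.95, intercept=38.0, n_dilutions=6,
                                    noise_sd=0.0, seed=seed + 30)
    standards.to_csv(outdir / "inputs" / "qpcr_standards.csv", index=False)

    config = {
        "outdir": str(outdir / "results"),
        "metadata": str(outdir / "inputs" / "metadata.tsv"),
        "rarefaction_depth": "min",
        "markers": {
            "mcrA": {"otu_table": str(outdir / "inputs" / "mcrA_otu_table.tsv")},
            "pmoA": {"otu_table": str(outdir / "inputs" / "pmoA_otu_table.tsv")},
        },
        "thresholds": {
            "network_r": 0.7,
            "network_p": 0.01,
            "min_rel_abundance": 0.001,
            "mst_randomizations": 200,
        },
        "permanova_permutations": 199,
        "seeds": {"rarefy": seed + 101, "permanova": seed + 102, "mst": seed + 103},
        "gas": {
            "chamber_series": chamber_entries,
            "incubation_series": incubation_entries,
            "qpcr": {
                "standards": str(outdir / "inputs" / "qpcr_standards.csv"),
                "samples": [
                    {"label": "E1-10", "cq": 24.5, "eluate_volume_ul": 100.0,
                     "template_volume_ul": 1.0, "fresh_mass_g": 0.5},
                    {"label": "N1-0", "cq": 27.0, "eluate_volume_ul": 100.0,
                     "template_volume_ul": 1.0, "fresh_mass_g": 0.5},
                ],
            },
        },
    }
    cfg_path = outdir / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return cfg_path
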