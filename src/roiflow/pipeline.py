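"""End-to-end orchestration: normalize -> diffexp -> enrich -> netprop.

One flat declarative config drives the run; compartments are processed
independently and reported side by side. All outputs are TSV/JSON under
the configured output directory, and a run is byte-identical given the
same config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from roiflow import __version__
from roiflow import diffexp, enrich, netprop, normalize
from roiflow.errors import PipelineError
from roiflow.io import RoiCountMatrix, read_counts
from roiflow.netprop import KeyGeneReport

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat run configuration; file values can be overridden per key."""

    counts: str
    metadata: str
    gmt: str
    network: str
    outdir: str
    normalization_method: str = "upper"
    ruv_k: int = 1
    adjust_matrix: bool = False  # False: pass factors as DE covariates
    alpha: float = 0.05
    lfc_min: float = 0.5
    background_size: int = enrich.DEFAULT_BACKGROUND_SIZE
    restart_rate: float = 0.5
    rwr_tol: float = 1e-8
    top_n: int = 20
    seed_mode: str = "abs"
    seed: int = 0
    compartments: tuple[str, ...] = ("plexus", "epithelium")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "compartments" in raw:
            raw["compartments"] = tuple(raw["compartments"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["compartments"] = list(d["compartments"])
        return d


def validate_config(cfg: RunConfig) -> list[str]:
    """Return a list of problems; empty iff the config is runnable."""
    problems = []
    for key in ("counts", "metadata", "gmt", "network"):
        path = getattr(cfg, key)
        if not path:
            problems.append(f"{key}: no path configured")
        elif not Path(path).exists():
            problems.append(f"{key}: file not found: {path}")
    if cfg.normalization_method not in ("upper", "full", "median"):
        problems.append(f"normalization_method: unknown {cfg.normalization_method!r}")
    if cfg.ruv_k < 0:
        problems.append("ruv_k: must be >= 0")
    if not 0 < cfg.alpha < 1:
        problems.append(f"alpha: must lie in (0, 1), got {cfg.alpha}")
    if cfg.lfc_min < 0:
        problems.append("lfc_min: must be >= 0")
    if cfg.background_size < 1:
        problems.append("background_size: must be positive")
    if not 0 < cfg.restart_rate <= 1:
        problems.append(f"restart_rate: must lie in (0, 1], got {cfg.restart_rate}")
    if cfg.top_n < 1:
        problems.append("top_n: must be >= 1")
    if cfg.seed_mode not in ("abs", "signed_positive"):
        problems.append(f"seed_mode: unknown {cfg.seed_mode!r}")
    for comp in cfg.compartments:
        if comp not in ("plexus", "epithelium"):
            problems.append(f"compartments: unknown compartment {comp!r}")
    return problems


@dataclass
class CompartmentResult:
    deg_table: pd.DataFrame
    enrichment_up: list
    enrichment_down: list
    key_report: KeyGeneReport | None
    summary: dict = field(default_factory=dict)


@dataclass
class RunReport:
    version: str
    config: dict
    compartments: dict[str, dict]

    def to_json(self) -> str:
        return json.dumps(
            {"version": self.version, "config": self.config,
             "compartments": self.compartments},
            indent=1, sort_keys=True,
        )


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return out
    return wrap


def run_compartment(m: RoiCountMatrix, cfg: RunConfig, lib, net,
                    outdir: Path, label: str) -> CompartmentResult:
    outdir.mkdir(parents=True, exist_ok=True)

    normalized = _stage("normalize")(
        normalize.between_lane_normalize, m, cfg.normalization_method)

    covariates = None
    if cfg.ruv_k > 0:
        groups = normalize.replicate_groups_from_metadata(normalized.metadata)
        factors = _stage("ruv")(
            normalize.estimate_unwanted_variation, normalized, groups, cfg.ruv_k)
        factors.factor_matrix.to_csv(outdir / "unwanted_factors.tsv", sep="\t",
                                     index_label="roi_id")
        if cfg.adjust_matrix:
            normalized = _stage("ruv-adjust")(
                normalize.remove_unwanted, normalized, factors)
        else:
            covariates = factors.factor_matrix

    normalized.counts.to_csv(outdir / "normalized_counts.tsv", sep="\t",
                             index_label="gene_id")

    table = _stage("diffexp")(diffexp.nb_wald_test, normalized, covariates=covariates)
    table = diffexp.select_degs(table, alpha=cfg.alpha, lfc_min=cfg.lfc_min)
    table.to_csv(outdir / "deg_table.tsv", sep="\t", index_label="gene_id",
                 columns=diffexp.DEG_TABLE_COLUMNS)

    up = diffexp.deg_genes(table, "up")
    down = diffexp.deg_genes(table, "down")
    logger.info("%s: %d up / %d down DEGs", label, len(up), len(down))

    rows_up = _stage("enrich-up")(enrich.enrich, set(up), lib) if up else []
    rows_down = _stage("enrich-down")(enrich.enrich, set(down), lib) if down else []
    enrich.rows_to_frame(rows_up).to_csv(outdir / "enrichment_up.tsv", sep="\t",
                                         index=False)
    enrich.rows_to_frame(rows_down).to_csv(outdir / "enrichment_down.tsv", sep="\t",
                                           index=False)

    key_report = None
    if table["is_deg"].any():
        sig = enrich.significant(rows_up, cfg.alpha) + enrich.significant(rows_down, cfg.alpha)
        try:
            p0 = netprop.initialize_seed(table, net, mode=cfg.seed_mode)
            w_prime = net.column_normalize()
            prob = netprop.rwr(w_prime, p0, r=cfg.restart_rate, tol=cfg.rwr_tol)
            prob = pd.Series(prob, index=net.node_order, name="probability")
            bc = _stage("betweenness")(netprop.betweenness, net)
            key_report = netprop.select_key_genes(prob, bc, sig, top_n=cfg.top_n)
            key_report.ranked.to_csv(outdir / "ranked_genes.tsv", sep="\t",
                                     index_label="gene_id")
            pd.Series(key_report.key_genes, name="gene_id").to_csv(
                outdir / "key_genes.tsv", sep="\t", index=False)
        except Exception as exc:
            raise PipelineError(f"stage 'netprop' ({label}) failed: {exc}") from exc

    summary = {
        "n_rois": m.shape[1],
        "n_genes": m.shape[0],
        "n_deg_up": len(up),
        "n_deg_down": len(down),
        "n_significant_terms_up": len(enrich.significant(rows_up, cfg.alpha)),
        "n_significant_terms_down": len(enrich.significant(rows_down, cfg.alpha)),
        "key_genes": key_report.key_genes if key_report else [],
    }
    return CompartmentResult(table, rows_up, rows_down, key_report, summary)


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute all stages per compartment and write tables plus a report."""
    problems = validate_config(cfg)
    if problems:
        raise PipelineError("invalid config: " + "; ".join(problems))

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    m = _stage("read-counts")(read_counts, cfg.counts, cfg.metadata)
    lib = _stage("read-gmt")(enrich.read_gmt, cfg.gmt, cfg.background_size)
    fmt = "biogrid_tab3" if cfg.network.endswith((".tab3", ".tab3.txt")) else "edge_list"
    net = _stage("read-network")(netprop.read_network, cfg.network, fmt)

    compartments = {}
    for comp in cfg.compartments:
        sub = m.subset_compartment(comp)
        result = run_compartment(sub, cfg, lib, net, outdir / comp, comp)
        compartments[comp] = result.summary

    report = RunReport(version=__version__, config=cfg.resolved(),
                       compartments=compartments)
    (outdir / "report.json").write_text(report.to_json() + "\n")
    return report
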