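"""Synthetic study designs, NB count matrices, PPI networks and gene sets.

Emulates the structure the downstream stages assume: a two-arm spatial
profiling study (PD vs control slides, two tissue compartments, several
ROIs per compartment), negative-binomial counts with planted group effects,
slide-level batch factors, and area-driven library sizes — plus a
scale-free interaction network and a GMT-writable gene-set library with
planted enriched terms.

All randomness flows from the single integer seed in
:class:`SimulationParams`, fanned out to the individual generators through
:class:`numpy.random.SeedSequence` spawning.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from roiflow.errors import ConfigurationError
from roiflow.io import METADATA_COLUMNS, RoiCountMatrix
from roiflow.enrich import GeneSetLibrary

#: Area ranges (um^2) observed per compartment.
AREA_RANGES = {"plexus": (5000.0, 30000.0), "epithelium": (15000.0, 150000.0)}
#: Nuclei-count ranges per compartment; QC keeps only ROIs with > 20 nuclei.
NUCLEI_RANGES = {"plexus": (21, 100), "epithelium": (101, 1000)}


@dataclass(frozen=True)
class RoiDesign:
    """One ROI of the study design."""

    roi_id: str
    slide_id: str
    group: str  # "PD" | "control"
    compartment: str  # "plexus" | "epithelium"
    area: float  # um^2
    nuclei: int


@dataclass
class SimulationParams:
    """Knobs of the synthetic study.

    Defaults reproduce the reference design: 5 PD + 5 control slides with
    12 ROIs each (6 per compartment) and an 18,677-gene whole-transcriptome
    panel. ``dispersion`` is the NB size parameter (gamma shape), so
    Var = mu + mu^2 / dispersion; larger values approach Poisson.
    """

    n_pd: int = 5
    n_ctrl: int = 5
    rois_per_compartment: int = 6
    n_genes: int = 18677
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    dispersion: float = 5.0
    n_deg: int = 200
    lfc_magnitude: float = 1.0
    n_batch_factors: int = 1
    batch_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_pd", "n_ctrl", "rois_per_compartment", "n_genes"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_deg < 0 or self.n_deg > self.n_genes:
            raise ConfigurationError("n_deg must lie in [0, n_genes]")
        if self.dispersion <= 0 and not math.isinf(self.dispersion):
            raise ConfigurationError("dispersion must be positive (or inf for Poisson)")
        if self.lfc_magnitude < 0:
            raise ConfigurationError("lfc_magnitude must be >= 0")
        if self.n_batch_factors < 0:
            raise ConfigurationError("n_batch_factors must be >= 0")
        if self.batch_sd < 0:
            raise ConfigurationError("batch_sd must be >= 0")


@dataclass
class GroundTruth:
    """What was planted, for parameter-recovery tests.

    ``deg_lfc`` maps each planted DEG to its signed true log2 fold change
    (positive = higher in PD); ``batch_factor_matrix`` is the ROIs x k
    column-centered nuisance factor matrix; ``library_size_factors`` the
    per-ROI depth multipliers.
    """

    deg_lfc: dict[str, float]
    batch_factor_matrix: pd.DataFrame
    library_size_factors: pd.Series

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "deg_lfc.json", "w") as fh:
            json.dump(self.deg_lfc, fh, indent=1, sort_keys=True)
        self.batch_factor_matrix.to_csv(outdir / "batch_factors.tsv", sep="\t",
                                        index_label="roi_id")
        self.library_size_factors.rename("library_size_factor").to_csv(
            outdir / "library_size_factors.tsv", sep="\t", index_label="roi_id")

    @classmethod
    def read(cls, outdir: str | Path) -> "GroundTruth":
        outdir = Path(outdir)
        with open(outdir / "deg_lfc.json") as fh:
            deg_lfc = json.load(fh)
        batch = pd.read_csv(outdir / "batch_factors.tsv", sep="\t", index_col="roi_id")
        lib = pd.read_csv(outdir / "library_size_factors.tsv", sep="\t",
                          index_col="roi_id")["library_size_factor"]
        return cls(deg_lfc, batch, lib)


def default_gene_universe(n_genes: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n_genes + 1)]


def generate_design(params: SimulationParams) -> list[RoiDesign]:
    """Lay out slides, compartments and ROIs for the configured study.

    Deterministic given the seed; every slide carries
    ``2 * rois_per_compartment`` ROIs with balanced compartment labels,
    areas drawn uniformly within the compartment's plausible range and
    nuclei counts always above the QC threshold of 20.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(1)[0])
    slides = [("PD", f"PD{i + 1:02d}") for i in range(params.n_pd)] + [
        ("control", f"CT{i + 1:02d}") for i in range(params.n_ctrl)
    ]
    design: list[RoiDesign] = []
    for group, slide_id in slides:
        for compartment in ("plexus", "epithelium"):
            lo, hi = AREA_RANGES[compartment]
            nlo, nhi = NUCLEI_RANGES[compartment]
            for i in range(params.rois_per_compartment):
                design.append(
                    RoiDesign(
                        roi_id=f"{slide_id}_{compartment}_{i + 1:02d}",
                        slide_id=slide_id,
                        group=group,
                        compartment=compartment,
                        area=float(rng.uniform(lo, hi)),
                        nuclei=int(rng.integers(nlo, nhi + 1)),
                    )
                )
    return design


def design_to_frame(design: list[RoiDesign]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(d) for d in design]).set_index("roi_id")
    return df[METADATA_COLUMNS]


def simulate_counts(
    design: list[RoiDesign],
    params: SimulationParams,
    baseline: np.ndarray | None = None,
    deg_lfc: dict[str, float] | None = None,
) -> tuple[RoiCountMatrix, GroundTruth]:
    """Draw an NB count matrix over the design and return it with the truth.

    Per-gene mean is ``baseline * 2^(lfc * [PD] * [is DEG]) * exp(batch
    effects) * library factor``; the library factor scales with ROI area
    times log-normal noise. ``baseline`` (per-gene means) and ``deg_lfc``
    (gene -> signed log2FC) override the randomly drawn defaults, which is
    how tests plant specific effects.
    """
    if not design:
        raise ConfigurationError("empty design")
    params.validate()
    seeds = np.random.SeedSequence(params.seed).spawn(5)
    rng_base = np.random.default_rng(seeds[1])
    rng_batch = np.random.default_rng(seeds[2])
    rng_lib = np.random.default_rng(seeds[3])
    rng_counts = np.random.default_rng(seeds[4])

    genes = default_gene_universe(params.n_genes)
    meta = design_to_frame(design)
    rois = list(meta.index)
    n_rois = len(rois)

    if baseline is None:
        baseline = np.exp(
            rng_base.normal(params.baseline_log_mean, params.baseline_log_sd,
                            size=params.n_genes)
        )
    else:
        baseline = np.asarray(baseline, dtype=float)
        if baseline.shape != (params.n_genes,):
            raise ConfigurationError("baseline length must equal n_genes")
        if (baseline < 0).any():
            raise ConfigurationError("baseline means must be >= 0")

    if deg_lfc is None:
        deg_idx = rng_base.choice(params.n_genes, size=params.n_deg, replace=False)
        signs = rng_base.choice([-1.0, 1.0], size=params.n_deg)
        deg_lfc = {genes[i]: float(s * params.lfc_magnitude)
                   for i, s in zip(deg_idx, signs)}
    else:
        unknown = set(deg_lfc) - set(genes)
        if unknown:
            raise ConfigurationError(f"deg_lfc genes outside universe: {sorted(unknown)[:5]}")

    lfc = np.zeros(params.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g, v in deg_lfc.items():
        lfc[gene_pos[g]] = v

    is_pd = (meta["group"] == "PD").to_numpy(dtype=float)

    # Slide-level batch factors on the log-mean scale, column-centered.
    k = params.n_batch_factors
    slide_ids = meta["slide_id"].to_numpy()
    uniq_slides = list(dict.fromkeys(slide_ids))
    batch = np.zeros((n_rois, k))
    batch_effect = np.zeros((params.n_genes, n_rois))
    if k > 0:
        slide_vals = rng_batch.normal(0.0, params.batch_sd, size=(len(uniq_slides), k))
        slide_pos = {s: i for i, s in enumerate(uniq_slides)}
        batch = np.array([slide_vals[slide_pos[s]] for s in slide_ids])
        batch -= batch.mean(axis=0, keepdims=True)
        loadings = rng_batch.normal(0.0, 1.0, size=(params.n_genes, k))
        batch_effect = loadings @ batch.T

    area = meta["area"].to_numpy(dtype=float)
    lib = area / area.mean() * rng_lib.lognormal(0.0, 0.1, size=n_rois)

    log2_group = lfc[:, None] * is_pd[None, :]
    mu = baseline[:, None] * np.exp2(log2_group) * np.exp(batch_effect) * lib[None, :]

    if math.isinf(params.dispersion):
        counts = rng_counts.poisson(mu)
    else:
        size = params.dispersion
        lam = np.where(mu > 0, rng_counts.gamma(size, 1.0, size=mu.shape) * mu / size, 0.0)
        counts = rng_counts.poisson(lam)

    counts_df = pd.DataFrame(counts.astype(np.int64), index=genes, columns=rois)
    truth = GroundTruth(
        deg_lfc=dict(deg_lfc),
        batch_factor_matrix=pd.DataFrame(
            batch, index=rois, columns=[f"batch_{j + 1}" for j in range(k)]
        ).rename_axis("roi_id"),
        library_size_factors=pd.Series(
            lib, index=rois, name="library_size_factor"
        ).rename_axis("roi_id"),
    )
    return RoiCountMatrix(counts_df, meta), truth


def simulate_ppi(
    n_nodes: int,
    attach_m: int,
    seed: int,
    universe: list[str] | None = None,
):
    """Scale-free (preferential attachment) PPI stand-in.

    Connected and undirected by construction; node labels are the first
    ``n_nodes`` symbols of ``universe`` (default synthetic gene ids).
    """
    from roiflow.netprop import PpiNetwork

    if n_nodes < 2:
        raise ConfigurationError("n_nodes must be >= 2")
    if not (n_nodes > attach_m >= 1):
        raise ConfigurationError("require n_nodes > attach_m >= 1")
    if universe is None:
        universe = default_gene_universe(n_nodes)
    if len(universe) < n_nodes:
        raise ConfigurationError("universe smaller than n_nodes")
    g = nx.barabasi_albert_graph(n_nodes, attach_m, seed=seed)
    mapping = {i: universe[i] for i in g.nodes}
    return PpiNetwork.from_graph(nx.relabel_nodes(g, mapping))


def simulate_gene_sets(
    universe: list[str],
    n_terms: int,
    size_range: tuple[int, int],
    enriched_terms: dict[str, list[str]] | None = None,
    seed: int = 0,
    background_size: int | None = None,
) -> GeneSetLibrary:
    """Random gene-set library with optional planted (enriched) terms.

    ``enriched_terms`` maps a term id to the genes forced into that term;
    each term is then padded with random universe genes up to a size drawn
    from ``size_range``.
    """
    if not universe:
        raise ConfigurationError("empty gene universe")
    lo, hi = size_range
    if not (1 <= lo <= hi <= len(universe)):
        raise ConfigurationError("size_range must lie within [1, len(universe)]")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    enriched_terms = dict(enriched_terms or {})

    terms: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for term, planted in enriched_terms.items():
        missing = set(planted) - set(universe)
        if missing:
            raise ConfigurationError(f"planted genes outside universe: {sorted(missing)[:5]}")
        size = int(rng.integers(max(lo, len(planted)), max(hi, len(planted)) + 1))
        genes = set(planted)
        pool = [g for g in universe if g not in genes]
        extra = size - len(genes)
        if extra > 0:
            genes |= set(rng.choice(pool, size=extra, replace=False))
        terms[term] = genes
        descriptions[term] = "planted enriched term"
    for i in range(n_terms - len(enriched_terms)):
        term = f"T{i + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        terms[term] = set(rng.choice(universe, size=size, replace=False))
        descriptions[term] = "random term"
    n = background_size if background_size is not None else len(universe)
    return GeneSetLibrary(terms, descriptions, background_size=n,
                          universe=set(universe))


def make_demo_dataset(
    outdir: str | Path,
    seed: int = 0,
    n_genes: int = 1500,
    n_ppi_nodes: int = 400,
    n_hubs: int = 8,
    n_deg: int = 40,
    lfc_magnitude: float = 1.5,
    n_terms: int = 50,
) -> dict:
    """Write a complete, self-consistent demo study to ``outdir``.

    Plants the study's true effects so recovery is checkable end to end:
    the highest-degree nodes of the simulated PPI network are upregulated
    DEGs, and one gene-set term is seeded with the upregulated genes.
    Writes counts.tsv, metadata.tsv, genesets.gmt, network.tsv, a ground
    truth directory, and returns the paths plus the planted structure.
    """
    from roiflow import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = SimulationParams(
        n_genes=n_genes, n_deg=n_deg, lfc_magnitude=lfc_magnitude, seed=seed
    )
    params.validate()
    universe = default_gene_universe(n_genes)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]).spawn(1)[0])

    net = simulate_ppi(n_ppi_nodes, attach_m=2, seed=seed, universe=universe)
    degree = dict(net.graph.degree())
    hubs = sorted(degree, key=lambda g: (-degree[g], g))[:n_hubs]
    others = [g for g in net.node_order if g not in hubs]
    extra = list(rng.choice(others, size=n_deg - n_hubs, replace=False))
    signs = rng.choice([-1.0, 1.0], size=len(extra))
    deg_lfc = {g: lfc_magnitude for g in hubs}
    deg_lfc.update({g: float(s * lfc_magnitude) for g, s in zip(extra, signs)})

    design = generate_design(params)
    counts, truth = simulate_counts(design, params, deg_lfc=deg_lfc)

    up_genes = [g for g, v in deg_lfc.items() if v > 0]
    lib = simulate_gene_sets(
        universe, n_terms=n_terms, size_range=(20, 60),
        enriched_terms={"PLANTED_UP": up_genes}, seed=seed,
    )

    io.write_counts(counts, outdir / "counts.tsv")
    io.write_metadata(counts.metadata, outdir / "metadata.tsv")
    from roiflow.enrich import write_gmt

    write_gmt(lib, outdir / "genesets.gmt")
    io.write_edge_list(sorted(net.graph.edges), outdir / "network.tsv")
    truth.write(outdir / "truth")

    return {
        "counts": str(outdir / "counts.tsv"),
        "metadata": str(outdir / "metadata.tsv"),
        "gmt": str(outdir / "genesets.gmt"),
        "network": str(outdir / "network.tsv"),
        "truth_dir": str(outdir / "truth"),
        "hubs": hubs,
        "deg_lfc": deg_lfc,
        "background_size": lib.background_size,
        "params": params,
    }
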