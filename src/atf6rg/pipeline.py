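"""Configuration-driven orchestration of the full analysis.

Stages, in order: acquire data (synthetic generation or user files) ->
per-contrast NB differential expression -> CARG/IARG set derivation and
overlaps -> ERSE motif scan of set members -> ChIP promoter-signal
summary per set -> recovery report against planted truth (when
available).  Every run writes a manifest with the config, seed, package
version and a sha256 of each output file, sufficient to reproduce the
run bit-identically.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, chip, io, motifs, sets
from .de import (
    DEFAULT_ALPHA,
    DEFAULT_LFC_MIN,
    Contrast,
    CountMatrix,
    call_degs,
    estimate_dispersions,
    fpkm,
    nb_wald_contrast,
    size_factors,
)
from .synthetic import (
    SampleDesign,
    SimParams,
    TruthLabels,
    build_design,
    simulate_chip_tracks,
    simulate_counts,
    simulate_promoters,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("data", "de", "sets", "scan", "chip", "report")


class PipelineError(RuntimeError):
    """Stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class ResultBundle:
    """In-memory results of a pipeline run plus the output manifest."""

    design: SampleDesign | None = None
    counts: CountMatrix | None = None
    truth: TruthLabels | None = None
    de_results: dict = field(default_factory=dict)  # cell_type -> contrast -> DataFrame
    deg_sets: dict = field(default_factory=dict)  # cell_type -> contrast -> (up, down)
    gene_sets: dict = field(default_factory=dict)  # cell_type -> ResponsiveGeneSets
    overlaps: dict = field(default_factory=dict)
    partition: sets.OverlapPartition | None = None
    motif_hits: pd.DataFrame | None = None
    has_canonical: pd.Series | None = None
    chip_summary: pd.DataFrame | None = None
    promoter_signals: pd.DataFrame | None = None
    recovery: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)
    outdir: Path | None = None


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def validate_config(config: dict) -> dict:
    config = dict(config)
    has_syn = "synthetic" in config
    has_inp = "inputs" in config
    if has_syn == has_inp:
        raise ValueError("config must contain exactly one of 'synthetic' or 'inputs'")
    de_cfg = config.setdefault("de", {})
    de_cfg.setdefault("alpha", DEFAULT_ALPHA)
    de_cfg.setdefault("lfc_min", DEFAULT_LFC_MIN)
    if not 0 < de_cfg["alpha"] < 1 or de_cfg["lfc_min"] < 0:
        raise ValueError("invalid DE thresholds")
    config.setdefault("seed", 0)
    config.setdefault("motif", {}).setdefault("mode", "canonical")
    config["motif"].setdefault("max_mm", 1)
    config["motif"].setdefault("n_background_genes", 50)
    chip_cfg = config.setdefault("chip", {})
    chip_cfg.setdefault("half_window", 2000)
    chip_cfg.setdefault("bin_width", 100)
    chip_cfg.setdefault("n_null_genes", 100)
    config.setdefault("outdir", "atf6rg_results")
    return config


def contrasts_for(cell_type: str, has_passages: bool) -> list[Contrast]:
    """The study's contrasts for one cell type.

    With a passage axis: knockout-vs-WT at vehicle EP and LP (CARG
    inputs) plus the two tunicamycin contrasts (IARG inputs, paired at
    EP).  Without: the tunicamycin contrasts only.
    """
    ct = {"cell_type": cell_type}
    out = []
    if has_passages:
        for p in ("EP", "LP"):
            out.append(
                Contrast(
                    f"KO_vs_WT.vehicle.{p}",
                    {**ct, "genotype": "KO", "condition": "vehicle", "passage": p},
                    {**ct, "genotype": "WT", "condition": "vehicle", "passage": p},
                )
            )
    out.append(
        Contrast(
            "TM_vs_vehicle.WT",
            {**ct, "genotype": "WT", "condition": "TM"},
            {**ct, "genotype": "WT", "condition": "vehicle", **({"passage": "EP"} if has_passages else {})},
        )
    )
    out.append(
        Contrast(
            "KO_vs_WT.TM",
            {**ct, "genotype": "KO", "condition": "TM"},
            {**ct, "genotype": "WT", "condition": "TM"},
        )
    )
    return out


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage boundary
                raise PipelineError(name, str(exc)) from exc

        return wrapper

    return deco


@_stage("data")
def _run_data(config: dict, bundle: ResultBundle) -> None:
    if "synthetic" in config:
        syn = config["synthetic"]
        cell_types = syn.get("cell_types", ["hMSC"])
        n_reps = syn.get("n_reps", 3)
        frames = []
        for ct in cell_types:
            d = build_design(
                [ct], n_reps=n_reps, include_passages=(ct == "hMSC"), include_tm=True
            )
            frames.append(d.samples)
        design = SampleDesign(samples=pd.concat(frames))
        params = SimParams(seed=config["seed"], **syn.get("params", {}))
        cm, truth = simulate_counts(design, params)
        bundle.design, bundle.counts, bundle.truth = design, cm, truth
    else:
        inp = config["inputs"]
        bundle.counts = io.load_counts(inp["counts"], inp["samples"])
        bundle.design = SampleDesign(samples=bundle.counts.samples)
        bundle.truth = None


@_stage("de")
def _run_de(config: dict, bundle: ResultBundle) -> None:
    cm = bundle.counts
    alpha = config["de"]["alpha"]
    lfc_min = config["de"]["lfc_min"]
    for ct in bundle.design.cell_types:
        ct_samples = cm.samples[cm.samples["cell_type"] == ct]
        sub = CountMatrix(
            counts=cm.counts[ct_samples.index],
            samples=ct_samples,
            gene_lengths=cm.gene_lengths,
        )
        sf = size_factors(sub.counts)
        groups = (
            ct_samples["genotype"].astype(str)
            + "."
            + ct_samples["condition"].astype(str)
            + "."
            + ct_samples["passage"].astype(str)
        )
        disp = estimate_dispersions(sub.counts, sf, groups)
        has_passages = set(ct_samples["passage"]) >= {"EP", "LP"}
        bundle.de_results[ct] = {}
        bundle.deg_sets[ct] = {}
        for contrast in contrasts_for(ct, has_passages):
            res = nb_wald_contrast(sub, contrast, sf=sf, dispersions=disp)
            bundle.de_results[ct][contrast.name] = res
            bundle.deg_sets[ct][contrast.name] = call_degs(res, alpha, lfc_min)


@_stage("sets")
def _run_sets(config: dict, bundle: ResultBundle) -> None:
    thresholds = dict(config["de"])
    for ct, degs in bundle.deg_sets.items():
        rs = sets.ResponsiveGeneSets(
            cell_type=ct, contrasts={k: "nb_wald" for k in degs}, thresholds=thresholds
        )
        if "KO_vs_WT.vehicle.EP" in degs and "KO_vs_WT.vehicle.LP" in degs:
            carg_down, const_up = sets.derive_cargs(
                degs["KO_vs_WT.vehicle.EP"], degs["KO_vs_WT.vehicle.LP"]
            )
            rs.carg_down, rs.const_up = carg_down, const_up
        if "TM_vs_vehicle.WT" in degs and "KO_vs_WT.TM" in degs:
            up_tm, _ = degs["TM_vs_vehicle.WT"]
            _, down_ko_tm = degs["KO_vs_WT.TM"]
            rs.iarg = sets.derive_iargs(up_tm, down_ko_tm)
        bundle.gene_sets[ct] = rs
        if rs.carg_down or rs.iarg:
            bundle.overlaps[ct] = sets.carg_iarg_overlap(rs.carg_down, rs.iarg)
    iarg_sets = {ct: rs.iarg for ct, rs in bundle.gene_sets.items()}
    if len(iarg_sets) == 3:
        bundle.partition = sets.cross_celltype_partition(iarg_sets)


@_stage("scan")
def _run_scan(config: dict, bundle: ResultBundle) -> None:
    mcfg = config["motif"]
    patterns = motifs.compile_patterns(mcfg["mode"], mcfg.get("max_mm", 1))
    if "synthetic" in config:
        members = set()
        for rs in bundle.gene_sets.values():
            members |= rs.carg_down | rs.const_up | rs.iarg
        rng = np.random.default_rng(config["seed"] + 1)
        null_genes = bundle.truth.labels.index[bundle.truth.labels == "null"]
        n_bg = min(mcfg["n_background_genes"], len(null_genes))
        members |= set(rng.choice(null_genes, size=n_bg, replace=False))
        genes = sorted(members)
        plants = bundle.truth.motif_plants
        plants = plants[plants["gene_id"].isin(genes)]
        seqs, tss, _ = simulate_promoters(
            genes, plants, seed=config["seed"] + 1
        )
        promoters = motifs.PromoterSet(sequences=seqs, upstream=10_000, downstream=2_000)
    else:
        inp = config["inputs"]
        seqs = io.read_fasta(inp["promoters"])
        promoters = motifs.PromoterSet(
            sequences=seqs,
            upstream=inp.get("upstream", 10_000),
            downstream=inp.get("downstream", 2_000),
        )
    bundle.motif_hits, bundle.has_canonical = motifs.scan_promoters(promoters, patterns)


@_stage("chip")
def _run_chip(config: dict, bundle: ResultBundle) -> None:
    ccfg = config["chip"]
    if "synthetic" not in config:
        if "chip_tracks" not in config["inputs"]:
            logger.info("no ChIP tracks supplied; skipping chip stage")
            return
        tss = io.read_bed6(config["inputs"]["tss"])
        pairs = {
            sid: (io.read_bedgraph(p["treat"]), io.read_bedgraph(p["control"]))
            for sid, p in config["inputs"]["chip_tracks"].items()
        }
        genotypes = pd.Series(
            {sid: bundle.counts.samples.loc[sid, "genotype"] for sid in pairs}
        )
    else:
        truth = bundle.truth
        rng = np.random.default_rng(config["seed"] + 2)
        carg_genes = truth.genes_with("carg_down", "both")
        iarg_genes = truth.genes_with("iarg")
        null_genes = truth.labels.index[truth.labels == "null"]
        n_null = min(ccfg["n_null_genes"], len(null_genes))
        null_pick = set(rng.choice(null_genes, size=n_null, replace=False))
        genes = sorted(carg_genes | iarg_genes | null_pick)
        _, tss, _ = simulate_promoters(genes, None, seed=config["seed"] + 2)
        meta = bundle.design.samples
        mask = (meta["condition"] == "vehicle") & (
            meta["cell_type"] == bundle.design.cell_types[0]
        )
        if "EP" in set(meta["passage"]):
            mask &= meta["passage"] == "EP"
        chip_design = SampleDesign(samples=meta[mask])
        tracks = simulate_chip_tracks(
            chip_design,
            truth,
            tss,
            bin_width=ccfg["bin_width"],
            half_window=ccfg["half_window"],
            seed=config["seed"] + 2,
        )
        pairs = tracks
        genotypes = chip_design.samples["genotype"]

    signals = {}
    for sid, (treat, control) in pairs.items():
        norm = chip.normalize_density(treat, control)
        summary, _ = chip.promoter_signal(
            norm, tss, half_window=ccfg["half_window"], bin_width=ccfg["bin_width"]
        )
        signals[sid] = summary["signal"]
    bundle.promoter_signals = pd.DataFrame(signals)

    gene_sets = {}
    for ct, rs in bundle.gene_sets.items():
        if rs.carg_down:
            gene_sets[f"CARG_{ct}"] = rs.carg_down
        if rs.iarg:
            gene_sets[f"IARG_{ct}"] = rs.iarg
    if bundle.truth is not None:
        gene_sets["null"] = set(
            bundle.promoter_signals.index
        ) & set(bundle.truth.labels.index[bundle.truth.labels == "null"])
    if gene_sets:
        bundle.chip_summary = chip.group_signal_summary(
            bundle.promoter_signals, gene_sets, genotypes
        )


@_stage("report")
def _run_report(config: dict, bundle: ResultBundle) -> None:
    if bundle.truth is None:
        return
    truth = bundle.truth
    planted = {
        "carg_down": truth.genes_with("carg_down", "both"),
        "const_up": truth.genes_with("const_up"),
        "iarg": truth.genes_with("iarg", "both"),
    }
    universe = set(truth.labels.index)
    for ct, rs in bundle.gene_sets.items():
        has_carg_axis = "KO_vs_WT.vehicle.EP" in bundle.deg_sets.get(ct, {})
        rec = {}
        if has_carg_axis:
            rec["carg_down"] = sets.evaluate_recovery(
                rs.carg_down, planted["carg_down"], universe
            )
            rec["const_up"] = sets.evaluate_recovery(
                rs.const_up, planted["const_up"], universe
            )
        rec["iarg"] = sets.evaluate_recovery(rs.iarg, planted["iarg"], universe)
        bundle.recovery[ct] = rec


def _write_outputs(config: dict, bundle: ResultBundle) -> None:
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.outdir = outdir
    written = []

    io.write_counts(bundle.counts, outdir / "counts.tsv", outdir / "samples.tsv")
    written += ["counts.tsv", "samples.tsv"]
    if bundle.counts.gene_lengths is not None:
        expr = fpkm(bundle.counts.counts, bundle.counts.gene_lengths)
        expr.round(4).to_csv(outdir / "fpkm.tsv", sep="\t", index_label="gene_id")
        written.append("fpkm.tsv")
    for ct, results in bundle.de_results.items():
        for cname, res in results.items():
            fname = f"de_{ct}_{cname}.tsv"
            res.to_csv(outdir / fname, sep="\t", index_label="gene_id")
            written.append(fname)
    all_sets = {}
    for ct, rs in bundle.gene_sets.items():
        all_sets[f"{ct}_carg_down"] = rs.carg_down
        all_sets[f"{ct}_const_up"] = rs.const_up
        all_sets[f"{ct}_iarg"] = rs.iarg
    region_counts = {}
    for ct, ov in bundle.overlaps.items():
        region_counts[f"{ct}_carg_iarg_shared"] = len(ov["shared"])
        region_counts[f"{ct}_carg_only"] = ov["n_carg_only"]
        region_counts[f"{ct}_iarg_only"] = ov["n_iarg_only"]
    if bundle.partition is not None:
        for k, v in bundle.partition.counts().items():
            region_counts[f"iarg_venn_{k}"] = v
    if all_sets:
        io.write_gene_sets(all_sets, outdir / "gene_sets", region_counts)
        written += [f"gene_sets/{n}.txt" for n in all_sets] + ["gene_sets/gene_sets.json"]
    if bundle.motif_hits is not None:
        bundle.motif_hits.to_csv(outdir / "motif_hits.tsv", sep="\t", index=False)
        bundle.has_canonical.to_csv(
            outdir / "motif_summary.tsv", sep="\t", index_label="gene_id"
        )
        written += ["motif_hits.tsv", "motif_summary.tsv"]
    if bundle.chip_summary is not None:
        bundle.chip_summary.to_csv(outdir / "chip_summary.tsv", sep="\t")
        bundle.promoter_signals.round(6).to_csv(
            outdir / "promoter_signals.tsv", sep="\t", index_label="gene_id"
        )
        written += ["chip_summary.tsv", "promoter_signals.tsv"]
    if bundle.recovery:
        io.write_json(bundle.recovery, outdir / "recovery.json")
        written.append("recovery.json")

    hashes = {}
    for rel in written:
        hashes[rel] = hashlib.sha256((outdir / rel).read_bytes()).hexdigest()
    bundle.manifest = {
        "version": __version__,
        "seed": config["seed"],
        "config": {k: v for k, v in config.items() if k != "outdir"},
        "thresholds": config["de"],
        "output_hashes": hashes,
    }
    io.write_json(bundle.manifest, outdir / "manifest.json")


def run_pipeline(
    config: dict, stages=ALL_STAGES, write: bool = True
) -> ResultBundle:
    """Execute the pipeline stages in order on a validated config.

    Any stage failure raises :class:`PipelineError` carrying the stage
    name; outputs written so far are retained alongside a FAILED marker.
    """
    config = validate_config(config)
    bundle = ResultBundle()
    stages = list(stages)
    runners = {
        "data": _run_data,
        "de": _run_de,
        "sets": _run_sets,
        "scan": _run_scan,
        "chip": _run_chip,
        "report": _run_report,
    }
    try:
        for name in ALL_STAGES:
            if name in stages:
                logger.info(
                    "stage %s (seed=%s, alpha=%s, lfc_min=%s)",
                    name,
                    config["seed"],
                    config["de"]["alpha"],
                    config["de"]["lfc_min"],
                )
                runners[name](config, bundle)
    except PipelineError as exc:
        if write:
            outdir = Path(config["outdir"])
            outdir.mkdir(parents=True, exist_ok=True)
            (outdir / "FAILED").write_text(f"{exc.stage}: {exc}\n")
        raise
    if write:
        _write_outputs(config, bundle)
    return bundle
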