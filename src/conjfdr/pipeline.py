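"""End-to-end orchestration: read -> harmonize -> exclude -> weights ->
genomic control -> conditional Q-Q -> conjFDR -> clump -> annotate.

Every stage is a pure function of (inputs, config, seed); the run directory
contains the harmonized pair, pruning weights, λ report, Q-Q tables, the
conjFDR table, the locus report, optional figures, and a machine-readable
manifest (parameters, versions, per-stage record counts, and sha256 of every
output) sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, InputError
from .fdr import GridSpec, compute_conjfdr, conditional_qq, curves_to_frame
from .inflation import apply_genomic_control, estimate_lambda
from .ld import LDReference, compute_r2, pruning_weights, read_plink_raw
from .loci import annotate_genes, clump_loci, loci_report, read_genes_bed
from .sumstats import (
    DEFAULT_EXCLUSION_REGIONS,
    GenomicRegion,
    apply_exclusion_regions,
    harmonize_pair,
    read_bed_regions,
    read_sumstats,
    write_pair,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and parameters of one pipeline run.

    Defaults follow the analysis conditions this package reproduces:
    r² = 0.1 pruning over 100 iterations in a ±20 Mb window, Q-Q strata
    {1, 0.1, 0.01, 0.001}, conjFDR significance 0.05, locus members at
    r² > 0.6, genes within 100 kb, and the HLA/MAPT exclusion regions.
    """

    trait1: str = ""
    trait2: str = ""
    ld_table: str | None = None          # precomputed 3-column r2 list
    genotype_panel: str | None = None    # PLINK additive text, alternative to ld_table
    genes_bed: str | None = None
    exclusion_bed: str | None = None     # override the default HLA/MAPT regions
    r2_prune: float = 0.1
    n_iterations: int = 100
    window_bp: int = 20_000_000
    qq_strata: tuple = (1.0, 0.1, 0.01, 0.001)
    conjfdr_threshold: float = 0.05
    member_r2: float = 0.6
    gene_window_bp: int = 100_000
    seed: int = 0
    make_figures: bool = False
    column_map1: dict = field(default_factory=dict)
    column_map2: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "qq_strata" in raw:
            raw["qq_strata"] = tuple(raw["qq_strata"])
        return cls(**raw)

    def validate(self) -> None:
        if not self.trait1 or not self.trait2:
            raise ConfigurationError("trait1 and trait2 sumstats paths are required")
        for name, val, lo, hi in [
            ("r2_prune", self.r2_prune, 0.0, 1.0),
            ("conjfdr_threshold", self.conjfdr_threshold, 0.0, 1.0),
            ("member_r2", self.member_r2, 0.0, 1.0),
        ]:
            if not (lo < val < hi or (name == "conjfdr_threshold" and val == 1.0)):
                raise ConfigurationError(f"{name} = {val} out of range ({lo}, {hi})")
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig, out_dir: str) -> dict:
    """Execute every stage in order and write the run directory.

    Returns the manifest dict (also written as ``manifest.json``).  Any stage
    error propagates with the stage name attached.
    """
    config.validate()
    os.makedirs(out_dir, exist_ok=True)
    stages: list[dict] = []
    outputs: dict[str, str] = {}

    def record(stage: str, n: int) -> None:
        logger.info("[%s] %d records", stage, n)
        stages.append({"stage": stage, "n_records": int(n)})

    def stage_guard(name):
        class _Guard:
            def __enter__(self):
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise type(exc)(f"stage {name!r}: {exc}") from exc
                return False

        return _Guard()

    with stage_guard("read"):
        t1 = read_sumstats(config.trait1, config.column_map1 or None)
        t2 = read_sumstats(config.trait2, config.column_map2 or None)
    record("read", len(t1) + len(t2))

    with stage_guard("harmonize"):
        pair = harmonize_pair(t1, t2)
    record("harmonize", len(pair))

    with stage_guard("exclude_regions"):
        regions: tuple[GenomicRegion, ...] = (
            tuple(read_bed_regions(config.exclusion_bed))
            if config.exclusion_bed
            else DEFAULT_EXCLUSION_REGIONS
        )
        pair = apply_exclusion_regions(pair, regions)
    record("exclude_regions", len(pair))
    if pair.empty:
        raise InputError("no records remain after region exclusion")

    with stage_guard("ld"):
        if config.ld_table:
            ld = LDReference.from_table(config.ld_table)
        elif config.genotype_panel:
            dosages, _ = read_plink_raw(config.genotype_panel)
            pos = pair.set_index("snp_id")[["chrom", "pos"]]
            keep = [c for c in dosages.columns if c in pos.index]
            ld = compute_r2(dosages[keep], pos.loc[keep], window_bp=config.window_bp)
        else:
            logger.warning("no LD source given; all pruning weights will be 1")
            ld = LDReference()
    record("ld_pairs", ld.n_pairs)

    with stage_guard("weights"):
        weights = pruning_weights(
            ld,
            list(pair["snp_id"]),
            n_iterations=config.n_iterations,
            r2_threshold=config.r2_prune,
            rng_seed=config.seed,
        )
        wpath = os.path.join(out_dir, "pruning_weights.tsv")
        weights.to_tsv(wpath)
        outputs["pruning_weights"] = wpath
    record("weights", len(weights.weights))

    with stage_guard("genomic_control"):
        w = weights.for_snps(pair["snp_id"])
        est1 = estimate_lambda(pair["p1"], w)
        est2 = estimate_lambda(pair["p2"], w)
        pair = pair.assign(
            p1=apply_genomic_control(pair["p1"], est1),
            p2=apply_genomic_control(pair["p2"], est2),
        )
        logger.info(
            "[genomic_control] lambda_trait1=%.4f lambda_trait2=%.4f",
            est1.lambda_gc, est2.lambda_gc,
        )
        ppath = os.path.join(out_dir, "harmonized_pair.tsv")
        write_pair(
            pair, ppath,
            header_lines=[
                f"lambda_trait1={est1.lambda_gc:.6f}",
                f"lambda_trait2={est2.lambda_gc:.6f}",
                f"seed={config.seed}",
            ],
        )
        outputs["harmonized_pair"] = ppath
    record("genomic_control", len(pair))

    with stage_guard("conditional_qq"):
        curves = conditional_qq(pair, weights, thresholds=config.qq_strata)
        qpath = os.path.join(out_dir, "conditional_qq.tsv")
        curves_to_frame(curves).to_csv(qpath, sep="\t", index=False, float_format="%.6g")
        outputs["conditional_qq"] = qpath
    record("conditional_qq", sum(len(c.expected) for c in curves))

    with stage_guard("conjfdr"):
        table = compute_conjfdr(pair, weights, GridSpec())
        tpath = os.path.join(out_dir, "conjfdr.tsv")
        table.to_csv(tpath, sep="\t", index=False, float_format="%.6g")
        outputs["conjfdr"] = tpath
    record("conjfdr", len(table))

    with stage_guard("clump"):
        loci = clump_loci(
            table, ld,
            fdr_threshold=config.conjfdr_threshold,
            independence_r2=config.r2_prune,
            member_r2=config.member_r2,
        )
    record("clump", len(loci))

    with stage_guard("annotate"):
        if config.genes_bed:
            genes = read_genes_bed(config.genes_bed)
            loci = [annotate_genes(l, genes, config.gene_window_bp) for l in loci]
        lpath = os.path.join(out_dir, "loci.tsv")
        loci_report(loci).to_csv(lpath, sep="\t", index=False, float_format="%.6g")
        outputs["loci"] = lpath
    record("annotate", len(loci))

    if config.make_figures:
        with stage_guard("figures"):
            from .plotting import plot_manhattan, plot_qq

            fq = os.path.join(out_dir, "conditional_qq.png")
            plot_qq(curves, fq)
            outputs["qq_figure"] = fq
            fm = os.path.join(out_dir, "manhattan.png")
            plot_manhattan(table, config.conjfdr_threshold, fm)
            outputs["manhattan_figure"] = fm

    manifest = {
        "package": "conjfdr",
        "version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if not isinstance(v, dict)
        },
        "stages": stages,
        "outputs": {k: os.path.basename(v) for k, v in outputs.items()},
        "checksums": {os.path.basename(v): _sha256(v) for v in outputs.values()},
    }
    mpath = os.path.join(out_dir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=list)
        fh.write("\n")
    return manifest
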