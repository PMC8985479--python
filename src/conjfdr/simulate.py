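"""Synthetic bivariate GWAS data with controllable shared architecture.

The generator draws paired summary statistics from a four-group polygenic
mixture: each SNP is null, causal for trait 1 only, causal for trait 2 only,
or causal for both, with fractions (pi1, pi2, pi12).  Causal effects are
normal with per-trait variances; shared SNPs get bivariate-normal effects
with correlation rho_shared.  LD is blockwise-exchangeable: SNPs in a block
share a single pairwise r², which keeps the relation between pruning weights
and block size analytically checkable (a fully linked block of size B gives
expected weight 1/B).  Marginal z-scores per block are

    z = sqrt(N) * (R @ beta) + eps,   eps ~ MVN(0, R),

with R the block's exchangeable correlation (off-diagonal sqrt(block_r2),
since test-statistic correlation equals genotype correlation r, not r²).
An inflation factor can be injected by scaling z by sqrt(lambda_inject), so
the mean null χ² equals lambda_inject and the genomic-control module can be
validated end to end.  Two-sided p-values come from the normal tail; the
beta column is emitted as z/sqrt(N) for schema completeness.

Everything is seeded and byte-reproducible; written files round-trip through
:mod:`conjfdr.sumstats` unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .ld import LDReference
from .loci import GeneModel
from .sumstats import P_FLOOR

# allele pairs that survive harmonization (no A/T, C/G ambiguity)
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                 ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]

_SNP_SPACING_BP = 5_000
_BLOCK_GAP_BP = 50_000
_N_CHROMS = 22


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic GWAS pair.

    Defaults emulate a desk-scale version of a cross-trait analysis: 10,000
    SNPs in 2,000 five-SNP LD blocks of moderate LD (r² = 0.5), 1% of SNPs
    causal per trait plus 1% shared, and per-SNP effect variances sized so a
    causal variant carries a typical |z| of about 5 at N = 20,000
    (sqrt(N · sigma²) = 5) — comfortably detectable without being
    genome-wide trivial.
    """

    n_snps: int = 10_000
    n_blocks: int = 2_000
    block_r2: float = 0.5
    pi1: float = 0.01
    pi2: float = 0.01
    pi12: float = 0.01
    sigma_beta1_sq: float = 1.25e-3
    sigma_beta2_sq: float = 1.25e-3
    rho_shared: float = 0.5
    n1: int = 20_000
    n2: int = 20_000
    lambda_inject: float = 1.0
    seed: int = 0
    # where sample overlap between the two GWAS would enter (shared-control
    # correlation of eps across traits); overlap is not simulated.
    overlap_hook: None = None

    def validate(self) -> None:
        if self.pi1 + self.pi2 + self.pi12 > 1:
            raise ConfigurationError("pi1 + pi2 + pi12 must be <= 1")
        if not (0.0 <= self.block_r2 < 1.0):
            raise ConfigurationError("block_r2 must be in [0, 1)")
        if min(self.pi1, self.pi2, self.pi12) < 0:
            raise ConfigurationError("causal fractions must be >= 0")
        if min(self.sigma_beta1_sq, self.sigma_beta2_sq) < 0:
            raise ConfigurationError("effect variances must be >= 0")
        if abs(self.rho_shared) > 1:
            raise ConfigurationError("rho_shared must be in [-1, 1]")
        if self.lambda_inject < 1:
            raise ConfigurationError("lambda_inject must be >= 1")
        if self.n_blocks < 1 or self.n_snps < self.n_blocks:
            raise ConfigurationError("need n_snps >= n_blocks >= 1")


@dataclass
class SyntheticBundle:
    sumstats1: pd.DataFrame
    sumstats2: pd.DataFrame
    ld: LDReference
    causal_labels: pd.Series  # snp_id -> {null, trait1, trait2, shared}
    genes: list[GeneModel]
    config: SimConfig


def _positions(n_snps: int, n_blocks: int, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign SNPs to blocks and lay blocks contiguously across 22 autosomes."""
    block_of = np.sort(rng.integers(0, n_blocks, size=n_snps - n_blocks))
    block_of = np.sort(np.concatenate([np.arange(n_blocks), block_of]))  # each block non-empty
    chrom_of_block = (np.arange(n_blocks) * _N_CHROMS) // n_blocks + 1
    chroms = chrom_of_block[block_of]
    pos = np.zeros(n_snps, dtype=np.int64)
    cursor, last_chrom, last_block = 0, 0, -1
    for i in range(n_snps):
        if chroms[i] != last_chrom:
            cursor = 1_000_000
            last_chrom = chroms[i]
        elif block_of[i] != last_block:
            cursor += _BLOCK_GAP_BP
        else:
            cursor += _SNP_SPACING_BP
        last_block = block_of[i]
        pos[i] = cursor
    return block_of, chroms, pos


def simulate_pair(config: SimConfig) -> SyntheticBundle:
    """Draw one synthetic GWAS pair under ``config`` (seeded, reproducible)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_snps

    block_of, chroms, pos = _positions(n, config.n_blocks, rng)
    snp_ids = np.array([f"snp{i:06d}" for i in range(n)])
    alleles = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    a1 = np.array([_ALLELE_PAIRS[k][0] for k in alleles])
    a2 = np.array([_ALLELE_PAIRS[k][1] for k in alleles])

    # causal mixture
    u = rng.random(n)
    labels = np.full(n, "null", dtype=object)
    labels[u < config.pi12] = "shared"
    labels[(u >= config.pi12) & (u < config.pi12 + config.pi1)] = "trait1"
    labels[
        (u >= config.pi12 + config.pi1)
        & (u < config.pi12 + config.pi1 + config.pi2)
    ] = "trait2"

    beta1 = np.zeros(n)
    beta2 = np.zeros(n)
    s1 = np.sqrt(config.sigma_beta1_sq)
    s2 = np.sqrt(config.sigma_beta2_sq)
    m1 = labels == "trait1"
    m2 = labels == "trait2"
    ms = labels == "shared"
    beta1[m1] = rng.normal(0.0, s1, size=m1.sum())
    beta2[m2] = rng.normal(0.0, s2, size=m2.sum())
    if ms.any():
        zpair = rng.multivariate_normal(
            [0.0, 0.0],
            [[1.0, config.rho_shared], [config.rho_shared, 1.0]],
            size=ms.sum(),
        )
        beta1[ms] = s1 * zpair[:, 0]
        beta2[ms] = s2 * zpair[:, 1]

    # per-block marginal z with exchangeable correlation rho = sqrt(block_r2)
    rho = np.sqrt(config.block_r2)
    z1 = np.empty(n)
    z2 = np.empty(n)
    counts = np.bincount(block_of, minlength=config.n_blocks)
    shared_noise = rng.normal(size=(config.n_blocks, 2))
    own_noise = rng.normal(size=(n, 2))
    sums1 = np.bincount(block_of, weights=beta1, minlength=config.n_blocks)
    sums2 = np.bincount(block_of, weights=beta2, minlength=config.n_blocks)
    rb1 = (1 - rho) * beta1 + rho * sums1[block_of]
    rb2 = (1 - rho) * beta2 + rho * sums2[block_of]
    eps1 = np.sqrt(1 - rho) * own_noise[:, 0] + np.sqrt(rho) * shared_noise[block_of, 0]
    eps2 = np.sqrt(1 - rho) * own_noise[:, 1] + np.sqrt(rho) * shared_noise[block_of, 1]
    z1 = np.sqrt(config.n1) * rb1 + eps1
    z2 = np.sqrt(config.n2) * rb2 + eps2
    if config.lambda_inject > 1:
        z1 *= np.sqrt(config.lambda_inject)
        z2 *= np.sqrt(config.lambda_inject)

    p1 = np.clip(2.0 * stats.norm.sf(np.abs(z1)), P_FLOOR, 1.0)
    p2 = np.clip(2.0 * stats.norm.sf(np.abs(z2)), P_FLOOR, 1.0)

    def table(z, p, nsamp):
        return pd.DataFrame(
            {
                "snp_id": snp_ids,
                "chrom": chroms.astype(str),
                "pos": pos,
                "a1": a1,
                "a2": a2,
                "z": z,
                "p": p,
                "beta": z / np.sqrt(nsamp),
            }
        )

    ld = LDReference()
    if config.block_r2 >= ld.floor:
        start = 0
        for b, cnt in enumerate(counts):
            for i in range(start, start + cnt):
                for j in range(i + 1, start + cnt):
                    ld.add(snp_ids[i], snp_ids[j], config.block_r2)
            start += cnt

    genes = _gene_intervals(chroms, pos, rng)
    return SyntheticBundle(
        sumstats1=table(z1, p1, config.n1),
        sumstats2=table(z2, p2, config.n2),
        ld=ld,
        causal_labels=pd.Series(labels, index=pd.Index(snp_ids, name="snp_id")),
        genes=genes,
        config=config,
    )


def _gene_intervals(chroms, pos, rng, every: int = 50) -> list[GeneModel]:
    """Synthetic gene intervals near every ``every``-th SNP."""
    genes = []
    for k, i in enumerate(range(0, len(pos), every)):
        length = int(rng.integers(5_000, 50_000))
        start = max(1, int(pos[i]) - length // 2)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"GENE{k:04d}", str(chroms[i]), start, start + length, strand))
    return genes


def simulate_genotype_panel(
    config: SimConfig, n_samples: int = 200
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Additive-coded genotype panel whose within-block r² converges to block_r2.

    Each block has one minor allele frequency (uniform on [0.05, 0.5]); a
    sample's dosage at a SNP copies a block-shared draw with probability
    block_r2**(1/4) and is drawn fresh otherwise, giving pairwise dosage
    correlation block_r2**(1/2), i.e. r² = block_r2, in expectation.
    Returns (dosages, positions) as consumed by :func:`conjfdr.ld.compute_r2`.
    """
    config.validate()
    rng = np.random.default_rng((config.seed, 7))
    block_of, chroms, pos = _positions(config.n_snps, config.n_blocks, rng)
    snp_ids = [f"snp{i:06d}" for i in range(config.n_snps)]
    maf = rng.uniform(0.05, 0.5, size=config.n_blocks)
    phi = config.block_r2 ** 0.25
    shared = rng.binomial(2, maf[None, :], size=(n_samples, config.n_blocks))
    fresh = rng.binomial(2, maf[block_of][None, :], size=(n_samples, config.n_snps))
    copy = rng.random((n_samples, config.n_snps)) < phi
    dos = np.where(copy, shared[:, block_of], fresh).astype(float)
    dosages = pd.DataFrame(dos, columns=snp_ids)
    positions = pd.DataFrame({"chrom": chroms.astype(str), "pos": pos}, index=snp_ids)
    return dosages, positions


def simulate_skat_fixture(
    n_samples: int,
    n_variants: int,
    effect_size: float,
    seed: int = 0,
    n_causal: int | None = None,
):
    """Case-control genotype fixture for SKAT.

    Genotypes are binomial(2, MAF) with MAF ~ uniform(0.005, 0.3); the
    phenotype follows a logistic model with log-odds ``effect_size`` per
    causal dosage on a random causal subset (default: 60% of variants,
    e.g. 3 of 5).  ``effect_size = 0`` gives the null.
    """
    from .skat import SkatInput

    if n_samples < 20:
        raise ConfigurationError("need n_samples >= 20")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.005, 0.3, size=n_variants)
    G = rng.binomial(2, maf[None, :], size=(n_samples, n_variants)).astype(float)
    if n_causal is None:
        n_causal = max(1, round(0.6 * n_variants))
    causal = rng.choice(n_variants, size=n_causal, replace=False)
    eta = effect_size * (G[:, causal] - 2 * maf[causal]).sum(axis=1)
    prob = 1.0 / (1.0 + np.exp(-eta))
    y = rng.binomial(1, prob).astype(float)
    if y.min() == y.max():  # ensure both classes; flip one sample deterministically
        y[0] = 1.0 - y[0]
    return SkatInput(genotypes=G, phenotype=y, gene="simulated")


def write_vcf_panel(dosages: pd.DataFrame, positions: pd.DataFrame, path) -> None:
    """Write an additive genotype panel as a minimal plain-text VCF (GT only).

    Dosage 0/1/2 becomes 0/0, 0/1, 1/1; missing becomes ./.; REF/ALT are
    placeholders (A/G).  Readable by :func:`conjfdr.ld.read_vcf_dosages`.
    """
    samples = [str(s) for s in dosages.index]
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in positions["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        order = positions.sort_values(["chrom", "pos"], kind="mergesort").index
        for snp in order:
            chrom, pos = positions.loc[snp, "chrom"], positions.loc[snp, "pos"]
            calls = [
                gt_map.get(float(d), "./.") if pd.notna(d) else "./."
                for d in dosages[snp]
            ]
            fh.write(f"{chrom}\t{pos}\t{snp}\tA\tG\t.\t.\t.\tGT\t"
                     + "\t".join(calls) + "\n")


# -- worked fixture --------------------------------------------------------

# Hand-computed conditional-FDR values for the 10-SNP worked fixture below.
# Stratum p2 <= 0.1 holds the 5 SNPs with p1 = {0.001, 0.02, 0.3, 0.5, 0.9}
# (unit weights): the weighted ecdf at those points is {1,2,3,4,5}/5, so
# cFDR = p1/ecdf = {0.005, 0.05, 0.5, 0.625, 0.9}.  The remaining 5 SNPs all
# have p1 > 0.9, so looser conditioning strata can only lower the ecdf at
# these query points and the cross-cut monotonization leaves the column
# unchanged.
WORKED_FIXTURE_EXPECTED = {
    "stratum_p2": 0.1,
    "cfdr_at": {0.001: 0.005, 0.02: 0.05, 0.3: 0.5, 0.5: 0.625, 0.9: 0.9},
}

_WORKED_P1 = [0.001, 0.02, 0.3, 0.5, 0.9, 0.91, 0.92, 0.95, 0.97, 0.99]
_WORKED_P2 = [0.01, 0.05, 0.02, 0.1, 0.08, 0.3, 0.5, 0.6, 0.8, 0.9]


def make_worked_fixture() -> SyntheticBundle:
    """Tiny 10-SNP bundle with hand-set p-value pairs and unit weights.

    The conditioning stratum p2 <= 0.1 contains exactly 5 equally weighted
    SNPs, chosen so the conditional-FDR grid can be audited by counting
    (see :data:`WORKED_FIXTURE_EXPECTED`).  There is no LD, so every pruning
    weight is 1.
    """
    n = len(_WORKED_P1)
    snp_ids = np.array([f"fix{i:02d}" for i in range(n)])
    pos = np.arange(1, n + 1) * 1_000_000
    base = {
        "snp_id": snp_ids,
        "chrom": np.full(n, "1"),
        "pos": pos,
        "a1": np.full(n, "A"),
        "a2": np.full(n, "G"),
    }
    p1 = np.array(_WORKED_P1)
    p2 = np.array(_WORKED_P2)
    t1 = pd.DataFrame({**base, "z": stats.norm.isf(p1 / 2), "p": p1})
    t2 = pd.DataFrame({**base, "z": stats.norm.isf(p2 / 2), "p": p2})
    return SyntheticBundle(
        sumstats1=t1,
        sumstats2=t2,
        ld=LDReference(),
        causal_labels=pd.Series("null", index=pd.Index(snp_ids, name="snp_id")),
        genes=[],
        config=SimConfig(n_snps=n, n_blocks=n, block_r2=0.0,
                         pi1=0, pi2=0, pi12=0, seed=0),
    )


# -- file emission ---------------------------------------------------------

def write_bundle(bundle: SyntheticBundle, out_dir) -> dict[str, str]:
    """Write the bundle as plain-text files; returns {artifact: path}."""
    import os

    import yaml

    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    def sumstats_path(df, name):
        path = os.path.join(out_dir, name)
        out = df.rename(
            columns={"snp_id": "SNP", "chrom": "CHR", "pos": "BP",
                     "a1": "A1", "a2": "A2", "z": "Z", "p": "P", "beta": "BETA"}
        )
        out.to_csv(path, sep="\t", index=False)
        return path

    paths["sumstats1"] = sumstats_path(bundle.sumstats1, "trait1.sumstats.tsv")
    paths["sumstats2"] = sumstats_path(bundle.sumstats2, "trait2.sumstats.tsv")

    ld_path = os.path.join(out_dir, "ld_pairs.tsv")
    bundle.ld.to_table(ld_path)
    paths["ld"] = ld_path

    genes_path = os.path.join(out_dir, "genes.bed")
    with open(genes_path, "w") as fh:
        for g in bundle.genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.symbol}\t0\t{g.strand}\n")
    paths["genes"] = genes_path

    labels_path = os.path.join(out_dir, "causal_labels.tsv")
    bundle.causal_labels.rename("label").to_csv(labels_path, sep="\t")
    paths["labels"] = labels_path

    cfg_path = os.path.join(out_dir, "sim_config.yaml")
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(asdict(bundle.config), fh, sort_keys=True)
    paths["config"] = cfg_path
    return paths
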