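"""Pairwise LD (r²) estimation and random-pruning SNP weights.

Empirical p-value distributions built from dense GWAS summary statistics are
distorted by linkage disequilibrium: a strongly associated region contributes
many correlated records.  The de-correlation device used throughout this
package is *random pruning*: repeatedly select one random SNP from each clump
of SNPs in LD (r² above a threshold) and average each SNP's inclusion
indicator over iterations.  The resulting per-SNP weight in [0, 1] then
multiplies that SNP's contribution to every empirical distribution
(inflation estimate, Q-Q curves, conditional ecdfs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

try:  # optional JIT for the greedy pruning kernel; results are identical
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

DEFAULT_WINDOW_BP = 20_000_000  # +/- window for r2 estimation
DEFAULT_R2_FLOOR = 0.05  # pairs below this r2 are not stored
DEFAULT_PRUNE_R2 = 0.1
DEFAULT_N_ITERATIONS = 100


class LDReference:
    """Sparse symmetric map of pairwise r² values.

    Only intra-chromosome pairs within a window and above a storage floor are
    kept.  ``r2(i, i)`` is implicitly 1.  The storage floor must not exceed
    any pruning/clumping threshold the reference will be used with.
    """

    def __init__(self, floor: float = DEFAULT_R2_FLOOR):
        self.floor = float(floor)
        self._adj: dict[str, dict[str, float]] = {}

    def add(self, snp_i: str, snp_j: str, r2: float) -> None:
        if snp_i == snp_j:
            return
        if not (0.0 <= r2 <= 1.0 + 1e-9):
            raise ConfigurationError(f"r2 out of range: {r2}")
        r2 = min(float(r2), 1.0)
        if r2 < self.floor:
            return
        self._adj.setdefault(snp_i, {})[snp_j] = r2
        self._adj.setdefault(snp_j, {})[snp_i] = r2

    def r2(self, snp_i: str, snp_j: str) -> float:
        if snp_i == snp_j:
            return 1.0
        return self._adj.get(snp_i, {}).get(snp_j, 0.0)

    def neighbors(self, snp: str, min_r2: float = 0.0) -> dict[str, float]:
        nb = self._adj.get(snp, {})
        if min_r2 <= self.floor:
            return dict(nb)
        return {k: v for k, v in nb.items() if v > min_r2}

    @property
    def n_pairs(self) -> int:
        return sum(len(v) for v in self._adj.values()) // 2

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_table(cls, path, floor: float = DEFAULT_R2_FLOOR) -> "LDReference":
        """Load a precomputed 3-column (snp_i, snp_j, r2) text file."""
        ld = cls(floor=floor)
        df = pd.read_csv(path, sep=r"\s+", comment="#")
        if df.shape[1] < 3:
            raise ConfigurationError(f"{path}: expected 3 columns (snp_i snp_j r2)")
        ci, cj, cr = df.columns[:3]
        for i, j, r2 in zip(df[ci], df[cj], df[cr]):
            ld.add(str(i), str(j), float(r2))
        return ld

    def to_table(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("snp_i\tsnp_j\tr2\n")
            seen = set()
            for i in sorted(self._adj):
                for j, r2 in sorted(self._adj[i].items()):
                    key = (i, j) if i < j else (j, i)
                    if key in seen:
                        continue
                    seen.add(key)
                    fh.write(f"{key[0]}\t{key[1]}\t{r2:.6g}\n")


def compute_r2(
    dosages: pd.DataFrame,
    positions: pd.DataFrame,
    window_bp: int = DEFAULT_WINDOW_BP,
    floor: float = DEFAULT_R2_FLOOR,
) -> LDReference:
    """Estimate pairwise r² from an additive-coded genotype panel.

    Parameters
    ----------
    dosages
        samples × variants DataFrame of 0/1/2 dosages (NaN = missing).
    positions
        DataFrame indexed like ``dosages.columns`` with columns
        ``chrom`` and ``pos``; only intra-chromosome pairs within
        ``window_bp`` are computed.

    r² is the squared Pearson correlation of dosages over pairwise-complete
    observations.  Pairs with fewer than 3 complete observations, or with a
    monomorphic variant among the complete observations, are omitted (logged).
    """
    if dosages.shape[0] < 2:
        raise InputError("genotype panel needs at least 2 samples")
    ld = LDReference(floor=floor)
    X = dosages.to_numpy(dtype=float)
    snps = list(dosages.columns)
    pos = positions.loc[snps]
    n_skipped = 0
    for chrom, sub in pos.groupby("chrom", sort=False):
        order = np.argsort(sub["pos"].to_numpy(), kind="mergesort")
        names = sub.index.to_numpy()[order]
        bp = sub["pos"].to_numpy()[order]
        cols = [snps.index(n) for n in names]
        for ai in range(len(names)):
            for bi in range(ai + 1, len(names)):
                if bp[bi] - bp[ai] > window_bp:
                    break
                x, y = X[:, cols[ai]], X[:, cols[bi]]
                ok = ~(np.isnan(x) | np.isnan(y))
                if ok.sum() < 3:
                    n_skipped += 1
                    continue
                xs, ys = x[ok], y[ok]
                if xs.std() == 0.0 or ys.std() == 0.0:
                    n_skipped += 1
                    continue
                r = np.corrcoef(xs, ys)[0, 1]
                ld.add(names[ai], names[bi], r * r)
    if n_skipped:
        logger.info("compute_r2: omitted %d pairs (monomorphic or <3 complete obs)", n_skipped)
    return ld


def read_plink_raw(path) -> tuple[pd.DataFrame, pd.Index]:
    """Read a PLINK ``--recode A``-style additive text file.

    Returns (samples × variants dosage DataFrame, sample index).  The six
    standard leading columns (FID IID PAT MAT SEX PHENOTYPE) are recognized
    and dropped; otherwise the first column is taken as the sample id.
    """
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    lead = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
    if "IID" in df.columns:
        idx = df["IID"].astype(str)
        geno = df.drop(columns=lead)
    else:
        idx = df.iloc[:, 0].astype(str)
        geno = df.iloc[:, 1:]
    geno.index = pd.Index(idx, name="sample")
    # strip PLINK's _<counted allele> suffix from variant names
    geno.columns = [c.rsplit("_", 1)[0] if "_" in c else c for c in geno.columns]
    return geno.astype(float), geno.index


def read_vcf_dosages(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read GT fields from a VCF into (dosages, positions) for :func:`compute_r2`.

    Dosage counts the ALT allele; missing genotypes become NaN.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    names, chroms, bps, rows = [], [], [], []
    for v in vcf:
        name = v.ID or f"{v.CHROM}:{v.POS}"
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(v.gt_types, dtype=float)
        dose = np.where(gt == 3, 2.0, gt)
        dose[gt == 2] = np.nan
        names.append(name)
        chroms.append(str(v.CHROM).removeprefix("chr"))
        bps.append(int(v.POS))
        rows.append(dose)
    dosages = pd.DataFrame(np.array(rows).T, index=samples, columns=names)
    positions = pd.DataFrame({"chrom": chroms, "pos": bps}, index=names)
    return dosages, positions


# -- random pruning --------------------------------------------------------


def _build_csr(ld: LDReference, snps: list[str], r2_threshold: float):
    """Adjacency (r2 > threshold) of `snps` in CSR form."""
    index = {s: k for k, s in enumerate(snps)}
    indptr = np.zeros(len(snps) + 1, dtype=np.int64)
    cols: list[np.ndarray] = []
    for k, s in enumerate(snps):
        nb = [index[t] for t, r2 in ld.neighbors(s).items() if r2 > r2_threshold and t in index]
        nb_arr = np.asarray(sorted(nb), dtype=np.int64)
        cols.append(nb_arr)
        indptr[k + 1] = indptr[k] + len(nb_arr)
    indices = np.concatenate(cols) if cols else np.zeros(0, dtype=np.int64)
    return indptr, indices


def _greedy_prune_py(order, indptr, indices):
    n = len(order)
    retained = np.zeros(n, dtype=np.bool_)
    blocked = np.zeros(n, dtype=np.bool_)
    for idx in order:
        if blocked[idx]:
            continue
        retained[idx] = True
        for k in range(indptr[idx], indptr[idx + 1]):
            blocked[indices[k]] = True
    return retained


if _HAVE_NUMBA:
    _greedy_prune = njit(cache=False)(_greedy_prune_py)
else:  # pragma: no cover
    _greedy_prune = _greedy_prune_py


def random_prune(
    ld: LDReference,
    snps: list[str],
    r2_threshold: float = DEFAULT_PRUNE_R2,
    rng_seed: int = 0,
) -> set[str]:
    """One iteration of random pruning: a greedy maximal independent set.

    SNPs are visited in a seeded random order; a SNP is retained iff no
    already-retained SNP has r² > threshold with it.  Consequently every
    non-retained SNP is in LD (r² > threshold) with at least one retained SNP.
    """
    if not (0.0 < r2_threshold < 1.0):
        raise ConfigurationError("r2_threshold must be in (0, 1)")
    if ld.floor > r2_threshold:
        raise ConfigurationError(
            f"LD storage floor {ld.floor} exceeds pruning threshold {r2_threshold}"
        )
    indptr, indices = _build_csr(ld, list(snps), r2_threshold)
    order = np.random.default_rng(rng_seed).permutation(len(snps))
    retained = _greedy_prune(order, indptr, indices)
    return {s for s, r in zip(snps, retained) if r}


@dataclass
class PruningWeights:
    """Per-SNP average inclusion frequency over random-pruning iterations."""

    weights: pd.Series  # index: snp_id, values in [0, 1]
    n_iterations: int
    r2_threshold: float
    seed: int
    _logged_missing: set = field(default_factory=set, repr=False, compare=False)

    def get(self, snp: str, default: float = 1.0) -> float:
        try:
            return float(self.weights[snp])
        except KeyError:
            if snp not in self._logged_missing:
                logger.debug("no pruning weight for %s; using %g", snp, default)
                self._logged_missing.add(snp)
            return default

    def for_snps(self, snps) -> np.ndarray:
        """Vector of weights aligned to `snps`; missing SNPs get weight 1 (logged)."""
        w = self.weights.reindex(snps)
        n_missing = int(w.isna().sum())
        if n_missing:
            logger.info("pruning weights: %d SNPs missing, assigned weight 1", n_missing)
        return w.fillna(1.0).to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#n_iterations={self.n_iterations}\n")
            fh.write(f"#r2_threshold={self.r2_threshold}\n")
            fh.write(f"#seed={self.seed}\n")
            fh.write("snp_id\tweight\n")
            for s, w in self.weights.items():
                fh.write(f"{s}\t{w:.6f}\n")

    @classmethod
    def from_tsv(cls, path) -> "PruningWeights":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                k, _, v = line[1:].strip().partition("=")
                meta[k] = v
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, sep="\t")
        return cls(
            weights=pd.Series(df["weight"].to_numpy(), index=df["snp_id"].astype(str)),
            n_iterations=int(meta.get("n_iterations", 0)),
            r2_threshold=float(meta.get("r2_threshold", np.nan)),
            seed=int(meta.get("seed", 0)),
        )


def pruning_weights(
    ld: LDReference,
    snps: list[str],
    n_iterations: int = DEFAULT_N_ITERATIONS,
    r2_threshold: float = DEFAULT_PRUNE_R2,
    rng_seed: int = 0,
) -> PruningWeights:
    """Average greedy random pruning over `n_iterations` seeded iterations.

    weight_i = (#iterations in which SNP i was retained) / n_iterations.
    Each iteration draws its visit order from an independent RNG stream
    keyed by (rng_seed, iteration), so iterations are order-independent.
    A SNP with no neighbor above the threshold has weight exactly 1.
    """
    if n_iterations < 1:
        raise ConfigurationError("n_iterations must be >= 1")
    if not (0.0 < r2_threshold < 1.0):
        raise ConfigurationError("r2_threshold must be in (0, 1)")
    if ld.floor > r2_threshold:
        raise ConfigurationError(
            f"LD storage floor {ld.floor} exceeds pruning threshold {r2_threshold}"
        )
    snps = list(snps)
    indptr, indices = _build_csr(ld, snps, r2_threshold)
    counts = np.zeros(len(snps), dtype=np.int64)
    for it in range(n_iterations):
        order = np.random.default_rng((rng_seed, it)).permutation(len(snps))
        counts += _greedy_prune(order, indptr, indices)
    w = counts / float(n_iterations)
    return PruningWeights(
        weights=pd.Series(w, index=pd.Index(snps, name="snp_id")),
        n_iterations=n_iterations,
        r2_threshold=r2_threshold,
        seed=rng_seed,
    )
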