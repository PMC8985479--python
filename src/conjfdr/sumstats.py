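"""Reading, validation, and cross-trait harmonization of GWAS summary statistics.

A summary-statistics table is a :class:`pandas.DataFrame` with the standard
columns ``snp_id, chrom, pos, a1, a2, z, p`` (plus ``beta``/``se`` when the
source provides them).  ``a1`` is the effect allele, ``a2`` the other allele,
``z`` the association z-score on the effect-allele scale, and ``p`` the
two-sided association p-value in (0, 1].  Coordinates are GRCh37, 1-based
inclusive, autosomes only.

A harmonized pair is a single DataFrame with columns
``snp_id, chrom, pos, a1, a2, z1, p1, z2, p2`` in which both traits refer to
the same effect-allele orientation: where the second trait reported the
alleles swapped, its z-score has been sign-flipped.  Strand-ambiguous
(A/T and C/G) variants and allele mismatches are removed, because without
strand information their orientation cannot be resolved between studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

#: Smallest p-value used in -log10 space; avoids underflow of log/quantile maps.
P_FLOOR = 1e-300

VALID_ALLELES = frozenset("ACGT")
AMBIGUOUS_PAIRS = frozenset({frozenset("AT"), frozenset("CG")})
AUTOSOMES = tuple(str(c) for c in range(1, 23))

#: Default mapping of standard field -> source column name.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "a1": "A1",
    "a2": "A2",
    "beta": "BETA",
    "se": "SE",
    "z": "Z",
    "p": "P",
}

PAIR_COLUMNS = ["snp_id", "chrom", "pos", "a1", "a2", "z1", "p1", "z2", "p2"]


@dataclass(frozen=True)
class GenomicRegion:
    """A 1-based inclusive genomic interval on GRCh37."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ConfigurationError(
                f"region start {self.start} > end {self.end} on chr{self.chrom}"
            )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


# Extended-LD regions excluded from all empirical FDR estimation: the
# HLA/MHC region and the 17q21 inversion (MAPT) region, GRCh37.
HLA_REGION = GenomicRegion("6", 25119106, 33854733)
MAPT_REGION = GenomicRegion("17", 40000000, 47000000)
DEFAULT_EXCLUSION_REGIONS: tuple[GenomicRegion, ...] = (HLA_REGION, MAPT_REGION)


def _normalize_chrom(values: pd.Series) -> pd.Series:
    s = values.astype(str).str.strip()
    s = s.str.replace("^chr", "", case=False, regex=True)
    return s


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a delimited summary-statistics file into a validated table.

    Parameters
    ----------
    path
        Whitespace- or tab-delimited text file with a header row.
    column_map
        Mapping of standard field name (``snp_id, chrom, pos, a1, a2, beta,
        se, z, p``) to the source column name.  Unspecified fields fall back
        to the defaults (SNP, CHR, BP, A1, A2, BETA, SE, Z, P).
    sep
        Field separator; default splits on any whitespace.

    Mandatory fields are chrom, pos, a1, a2, p and at least one of z or
    beta+se (beta alone is accepted: |z| is then recovered from the p-value
    and signed by beta).  Records with missing or out-of-range p (outside
    (0, 1]), non-ACGT alleles, or non-autosomal chromosomes are dropped and
    the counts logged.  Duplicate (chrom, pos) records keep the smallest p.
    The result is sorted by (chrom, pos).
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=sep if sep is not None else r"\s+")

    for field in ("chrom", "pos", "a1", "a2", "p"):
        if cmap[field] not in raw.columns:
            raise ConfigurationError(
                f"mandatory column {cmap[field]!r} (field {field!r}) "
                f"not found in {path}"
            )
    has_z = cmap["z"] in raw.columns
    has_beta = cmap["beta"] in raw.columns
    has_se = cmap["se"] in raw.columns
    if not has_z and not has_beta:
        raise ConfigurationError(
            f"need a z column ({cmap['z']!r}) or an effect-size column "
            f"({cmap['beta']!r}) in {path}"
        )

    df = pd.DataFrame(
        {
            "chrom": _normalize_chrom(raw[cmap["chrom"]]),
            "pos": pd.to_numeric(raw[cmap["pos"]], errors="coerce"),
            "a1": raw[cmap["a1"]].astype(str).str.upper().str.strip(),
            "a2": raw[cmap["a2"]].astype(str).str.upper().str.strip(),
            "p": pd.to_numeric(raw[cmap["p"]], errors="coerce"),
        }
    )
    if cmap["snp_id"] in raw.columns:
        df["snp_id"] = raw[cmap["snp_id"]].astype(str)
    else:
        df["snp_id"] = df["chrom"] + ":" + df["pos"].astype("Int64").astype(str)
    if has_beta:
        df["beta"] = pd.to_numeric(raw[cmap["beta"]], errors="coerce")
    if has_se:
        df["se"] = pd.to_numeric(raw[cmap["se"]], errors="coerce")
    if has_z:
        df["z"] = pd.to_numeric(raw[cmap["z"]], errors="coerce")

    n0 = len(df)
    bad_p = df["p"].isna() | (df["p"] <= 0) | (df["p"] > 1)
    if bad_p.any():
        logger.info("%s: dropped %d records with missing/out-of-range p", path, bad_p.sum())
    df = df[~bad_p]

    bad_allele = ~(df["a1"].isin(VALID_ALLELES) & df["a2"].isin(VALID_ALLELES))
    if bad_allele.any():
        logger.info("%s: dropped %d records with non-ACGT alleles", path, bad_allele.sum())
    df = df[~bad_allele]

    bad_chrom = ~df["chrom"].isin(AUTOSOMES)
    if bad_chrom.any():
        logger.info("%s: dropped %d non-autosomal records", path, bad_chrom.sum())
    df = df[~bad_chrom]

    bad_pos = df["pos"].isna() | (df["pos"] < 1)
    df = df[~bad_pos]
    df["pos"] = df["pos"].astype(np.int64)

    if "z" not in df.columns or df["z"].isna().any():
        z_from = _derive_z(df)
        if "z" in df.columns:
            df["z"] = df["z"].where(~df["z"].isna(), z_from)
        else:
            df["z"] = z_from
    df = df[~df["z"].isna()]

    # de-duplicate (chrom, pos): keep the smallest p
    df = df.sort_values(["chrom", "pos", "p"], kind="mergesort")
    dup = df.duplicated(subset=["chrom", "pos"], keep="first")
    if dup.any():
        logger.info("%s: dropped %d duplicate-position records (kept smallest p)", path, dup.sum())
    df = df[~dup]

    if df.empty:
        raise InputError(f"no valid records in {path} (started with {n0})")

    df["_c"] = df["chrom"].astype(int)
    df = df.sort_values(["_c", "pos"], kind="mergesort").drop(columns="_c")
    front = ["snp_id", "chrom", "pos", "a1", "a2", "z", "p"]
    rest = [c for c in df.columns if c not in front]
    return df[front + rest].reset_index(drop=True)


def _derive_z(df: pd.DataFrame) -> pd.Series:
    """z from beta/se where available, else |z| from p signed by beta."""
    if "beta" in df.columns and "se" in df.columns:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = df["beta"] / df["se"]
        missing = ~np.isfinite(z)
    else:
        z = pd.Series(np.nan, index=df.index)
        missing = pd.Series(True, index=df.index)
    if missing.any() and "beta" in df.columns:
        p = df.loc[missing, "p"].clip(lower=P_FLOOR)
        zabs = stats.norm.isf(p / 2.0)
        z = z.copy()
        z.loc[missing] = np.sign(df.loc[missing, "beta"]).replace(0, 1) * zabs
    return pd.Series(np.where(np.isfinite(z), z, np.nan), index=df.index)


def harmonize_pair(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Allele-align two validated tables into one paired table.

    Records are joined on (chrom, pos) — not on variant id, whose dialect
    differs between GWAS releases.  Where the second trait's alleles are the
    reverse of the first trait's, z2 is sign-flipped.  Strand-ambiguous
    (A/T, C/G) and allele-mismatched variants are dropped with logged counts.
    Record order follows the (chrom, pos) sort of the first table.
    """
    m = a.merge(
        b[["chrom", "pos", "a1", "a2", "z", "p"]],
        on=["chrom", "pos"],
        suffixes=("", "_b"),
        how="inner",
    )
    if m.empty:
        raise InputError("no shared (chrom, pos) records between the two tables")

    same = (m["a1"] == m["a1_b"]) & (m["a2"] == m["a2_b"])
    flipped = (m["a1"] == m["a2_b"]) & (m["a2"] == m["a1_b"])
    ambiguous = [frozenset((x, y)) in AMBIGUOUS_PAIRS for x, y in zip(m["a1"], m["a2"])]
    ambiguous = np.asarray(ambiguous)

    n_mismatch = int((~(same | flipped)).sum())
    n_ambig = int((ambiguous & (same | flipped).to_numpy()).sum())
    if n_mismatch:
        logger.info("harmonize: dropped %d allele-mismatched records", n_mismatch)
    if n_ambig:
        logger.info("harmonize: dropped %d strand-ambiguous (A/T, C/G) records", n_ambig)

    keep = (same | flipped).to_numpy() & ~ambiguous
    m = m[keep]
    if m.empty:
        raise InputError("no records survive allele harmonization")
    flipped = flipped.to_numpy()[keep]

    out = pd.DataFrame(
        {
            "snp_id": m["snp_id"].to_numpy(),
            "chrom": m["chrom"].to_numpy(),
            "pos": m["pos"].to_numpy(),
            "a1": m["a1"].to_numpy(),
            "a2": m["a2"].to_numpy(),
            "z1": m["z"].to_numpy(),
            "p1": m["p"].to_numpy(),
            "z2": np.where(flipped, -m["z_b"].to_numpy(), m["z_b"].to_numpy()),
            "p2": m["p_b"].to_numpy(),
        }
    )
    return out.reset_index(drop=True)


def apply_exclusion_regions(
    pair: pd.DataFrame,
    regions: Sequence[GenomicRegion] = DEFAULT_EXCLUSION_REGIONS,
) -> pd.DataFrame:
    """Remove every record falling inside any of the given 1-based inclusive
    regions (defaults: the extended-LD HLA and MAPT regions).  Idempotent;
    an empty region list is a no-op."""
    if not len(regions):
        return pair
    drop = np.zeros(len(pair), dtype=bool)
    chrom = pair["chrom"].to_numpy()
    pos = pair["pos"].to_numpy()
    for r in regions:
        drop |= (chrom == r.chrom) & (pos >= r.start) & (pos <= r.end)
    if drop.any():
        logger.info("exclusion regions: removed %d records", int(drop.sum()))
    return pair[~drop].reset_index(drop=True)


def read_bed_regions(path) -> list[GenomicRegion]:
    """Read exclusion regions from BED (0-based half-open), returning 1-based
    inclusive intervals."""
    bed = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    return [
        GenomicRegion(str(c).removeprefix("chr"), int(s) + 1, int(e))
        for c, s, e in zip(bed[0], bed[1], bed[2])
    ]


def write_pair(pair: pd.DataFrame, path, header_lines: Sequence[str] = ()) -> None:
    """Write a harmonized pair as TSV with fixed column order; optional
    ``#key=value`` provenance lines precede the header."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"#{line.lstrip('#')}\n")
        pair[PAIR_COLUMNS].to_csv(fh, sep="\t", index=False)


def read_pair(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df["chrom"] = df["chrom"].astype(str)
    return df[PAIR_COLUMNS]
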