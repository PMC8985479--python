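"""Collapse significant SNPs into LD-independent loci and annotate genes.

A locus is seeded by the most significant (smallest conjFDR) remaining SNP,
which becomes its lead; every remaining significant SNP in LD with the lead
above the independence threshold joins that locus.  Reported locus members
are those in high LD (r² above the display threshold) with the lead.  Gene
annotation lists all gene intervals within a window of the lead position and
classifies the lead as inside the closest gene or upstream/downstream of it
relative to the closest gene's strand (5' side = upstream).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import ConfigurationError
from .ld import LDReference

logger = logging.getLogger(__name__)

DEFAULT_FDR_THRESHOLD = 0.05
DEFAULT_INDEPENDENCE_R2 = 0.1
DEFAULT_MEMBER_R2 = 0.6
DEFAULT_GENE_WINDOW_BP = 100_000


@dataclass(frozen=True)
class GeneModel:
    """A gene interval, 1-based inclusive, with strand."""

    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start > self.end:
            raise ConfigurationError(f"gene {self.symbol}: start > end")
        if self.strand not in ("+", "-"):
            raise ConfigurationError(f"gene {self.symbol}: bad strand {self.strand!r}")


@dataclass
class Locus:
    lead_snp: str
    chrom: str
    pos: int
    lead_conjfdr: float
    lead_p1: float
    lead_p2: float
    members: list = field(default_factory=list)  # (snp_id, r2 with lead), r2 > display thr
    genes: list = field(default_factory=list)    # gene symbols within the window
    closest_gene: str | None = None
    relation: str | None = None                  # inside / upstream / downstream


def clump_loci(
    table: pd.DataFrame,
    ld: LDReference,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    independence_r2: float = DEFAULT_INDEPENDENCE_R2,
    member_r2: float = DEFAULT_MEMBER_R2,
) -> list[Locus]:
    """Greedy clumping of a conjFDR table into LD-independent loci.

    Among SNPs with conjfdr < ``fdr_threshold``, iteratively take the
    smallest-conjfdr SNP as a lead (ties broken by smaller p1, then by
    chromosome/position), assign to its locus every significant SNP with
    r² > ``independence_r2`` with the lead, remove them, and repeat.  The
    result is invariant to input record order, and no two leads are in LD
    above the independence threshold.
    """
    if not (0 < fdr_threshold <= 1) or not (0 < independence_r2 < 1):
        raise ConfigurationError("thresholds must be in (0, 1)")
    sig = table[table["conjfdr"] < fdr_threshold]
    if sig.empty:
        return []
    sig = sig.assign(_c=sig["chrom"].astype(str)).sort_values(
        ["conjfdr", "p1", "_c", "pos"], kind="mergesort"
    )
    remaining = list(sig.itertuples(index=False))
    loci: list[Locus] = []
    while remaining:
        lead = remaining[0]
        members, rest = [], []
        for rec in remaining[1:]:
            r2 = ld.r2(lead.snp_id, rec.snp_id)
            if r2 > independence_r2:
                members.append((rec.snp_id, r2))
            else:
                rest.append(rec)
        loci.append(
            Locus(
                lead_snp=lead.snp_id,
                chrom=str(lead.chrom),
                pos=int(lead.pos),
                lead_conjfdr=float(lead.conjfdr),
                lead_p1=float(lead.p1),
                lead_p2=float(lead.p2),
                members=[(lead.snp_id, 1.0)]
                + [(s, r) for s, r in members if r > member_r2],
            )
        )
        remaining = rest
    return loci


def annotate_genes(
    locus: Locus,
    genes: list[GeneModel],
    window_bp: int = DEFAULT_GENE_WINDOW_BP,
) -> Locus:
    """Attach genes whose interval intersects [lead - window, lead + window].

    The window is inclusive: a gene whose edge lies exactly ``window_bp``
    from the lead is included.  ``closest_gene`` minimizes the distance from
    the lead to the gene interval (0 if the lead is inside); ties break on
    the smaller gene start.  ``relation`` is 'inside' when the lead falls in
    the closest gene's interval, otherwise 'upstream'/'downstream' of it
    according to its strand.
    """
    near = [
        g
        for g in genes
        if g.chrom == locus.chrom
        and g.start <= locus.pos + window_bp
        and g.end >= locus.pos - window_bp
    ]
    if not near:
        logger.info("locus %s: no gene within %d bp", locus.lead_snp, window_bp)
        return replace(locus, genes=[], closest_gene=None, relation=None)

    def distance(g: GeneModel) -> int:
        if g.start <= locus.pos <= g.end:
            return 0
        return g.start - locus.pos if locus.pos < g.start else locus.pos - g.end

    near_sorted = sorted(near, key=lambda g: (distance(g), g.start, g.symbol))
    closest = near_sorted[0]
    if distance(closest) == 0:
        relation = "inside"
    else:
        before_start = locus.pos < closest.start
        if closest.strand == "+":
            relation = "upstream" if before_start else "downstream"
        else:
            relation = "downstream" if before_start else "upstream"
    return replace(
        locus,
        genes=[g.symbol for g in sorted(near, key=lambda g: (g.start, g.symbol))],
        closest_gene=closest.symbol,
        relation=relation,
    )


def read_genes_bed(path) -> list[GeneModel]:
    """Read gene intervals from BED (0-based half-open; BED6 strand in
    column 6, '+' assumed when absent), converted to 1-based inclusive."""
    bed = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    genes = []
    for row in bed.itertuples(index=False):
        chrom = str(row[0]).removeprefix("chr")
        start, end = int(row[1]) + 1, int(row[2])
        symbol = str(row[3]) if len(row) > 3 else f"{chrom}:{start}-{end}"
        strand = str(row[5]) if len(row) > 5 and str(row[5]) in ("+", "-") else "+"
        genes.append(GeneModel(symbol, chrom, start, end, strand))
    return genes


def loci_report(loci: list[Locus]) -> pd.DataFrame:
    """Tabular locus report: lead SNP, position, conjFDR, members, genes."""
    rows = []
    for loc in loci:
        rows.append(
            {
                "lead_snp": loc.lead_snp,
                "chrom": loc.chrom,
                "pos": loc.pos,
                "conjfdr": loc.lead_conjfdr,
                "p1": loc.lead_p1,
                "p2": loc.lead_p2,
                "n_members": len(loc.members),
                "members": ",".join(f"{s}:{r:.2f}" for s, r in loc.members),
                "genes_within_window": ",".join(loc.genes),
                "closest_gene": loc.closest_gene or "",
                "relation": loc.relation or "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "lead_snp", "chrom", "pos", "conjfdr", "p1", "p2",
            "n_members", "members", "genes_within_window",
            "closest_gene", "relation",
        ],
    )
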