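"""Peak-to-gene linking within +/-50 kb windows and hypergeometric overlap
enrichment.

The enrichment statistic is the hypergeometric upper tail P(X >= m) for an
overlap of m between sets of sizes n1 and n2 drawn from a universe of n,
computed as a log-space sum of log-binomial terms so that log10 p stays
finite far below the double-precision underflow point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
from scipy.special import gammaln, logsumexp

from .core import GeneModel, Interval, Peak, overlaps

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 50_000
DEFAULT_UNIVERSE = 25_592  # GRCz11 coding genes


@dataclass(frozen=True)
class PeakGeneLink:
    peak_id: str
    gene_id: str
    distance: int  # 0 if the peak overlaps the gene body; negative = TSS side


@dataclass(frozen=True)
class EnrichmentResult:
    n: int
    n1: int
    n2: int
    m: int
    log10_p: float

    @property
    def expected_overlap(self) -> float:
        return self.n1 * self.n2 / self.n if self.n else 0.0

    @property
    def p_value(self) -> float:
        return float(10.0**self.log10_p)


# ---------------------------------------------------------------------------
# windows and linking


def gene_windows(
    genes: Sequence[GeneModel],
    chrom_sizes: Dict[str, int],
    left: int = DEFAULT_WINDOW,
    right: int = DEFAULT_WINDOW,
    strand_aware: bool = True,
) -> Dict[str, Interval]:
    """Extend each gene body by left/right bp; for '-' strand genes the two
    extensions are swapped when strand_aware (bedtools-window -sw semantics).
    Windows are clipped at 0 and the chromosome length."""
    out: Dict[str, Interval] = {}
    for g in genes:
        if g.chrom not in chrom_sizes:
            raise ValueError(f"no chromosome size for {g.chrom} (gene {g.gene_id})")
        if strand_aware and g.strand == "-":
            up, down = right, left
        else:
            up, down = left, right
        start = max(0, g.start - up)
        end = min(chrom_sizes[g.chrom], g.end + down)
        out[g.gene_id] = Interval(g.chrom, start, end, name=g.gene_id)
    return out


def _signed_distance(peak: Peak, gene: GeneModel) -> int:
    if overlaps(peak.start, peak.end, gene.start, gene.end):
        return 0
    if peak.end <= gene.start:  # peak left of gene
        gap = gene.start - peak.end
        return -gap if gene.strand == "+" else gap
    gap = peak.start - gene.end  # peak right of gene
    return gap if gene.strand == "+" else -gap


def link_peaks_to_genes(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    windows: Dict[str, Interval],
) -> List[PeakGeneLink]:
    """Link every peak to every gene whose window it overlaps by >=1 bp."""
    gene_by_id = {g.gene_id: g for g in genes}
    by_chrom: Dict[str, List[Interval]] = {}
    for w in windows.values():
        by_chrom.setdefault(w.chrom, []).append(w)
    for lst in by_chrom.values():
        lst.sort(key=lambda w: w.start)
    links: List[PeakGeneLink] = []
    for p in peaks:
        for w in by_chrom.get(p.chrom, ()):  # windows are few per chrom; linear scan
            if overlaps(p.start, p.end, w.start, w.end):
                links.append(
                    PeakGeneLink(p.peak_id, w.name, _signed_distance(p, gene_by_id[w.name]))
                )
    return links


# ---------------------------------------------------------------------------
# hypergeometric upper tail


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(n: int, n1: int, n2: int, m: int) -> float:
    """log10 of P(X >= m), X ~ Hypergeometric(n, n1, n2).

    Summed in log space: log P(X=k) = logC(n1,k) + logC(n-n1,n2-k) - logC(n,n2).
    """
    if not (0 <= n1 <= n and 0 <= n2 <= n):
        raise ValueError(f"invalid marginals n={n}, n1={n1}, n2={n2}")
    upper = min(n1, n2)
    if m > upper:
        raise ValueError(f"m={m} exceeds min(n1, n2)={upper}")
    if m <= max(0, n1 + n2 - n):
        return 0.0  # P(X >= m) = 1
    k = np.arange(m, upper + 1)
    log_terms = _log_binom(n1, k) + _log_binom(n - n1, n2 - k) - _log_binom(n, n2)
    return float(logsumexp(log_terms) / np.log(10.0))


def hypergeom_upper_tail_cdf_form(n: int, n1: int, n2: int, m: int) -> float:
    """Difference-of-CDFs form of the same tail, P(X <= min(n1,n2)) - P(X <= m-1),
    on the natural scale. Underflows below ~1e-308; kept for cross-checks."""
    from scipy.stats import hypergeom

    return float(hypergeom.cdf(min(n1, n2), n, n1, n2) - hypergeom.cdf(m - 1, n, n1, n2))


# ---------------------------------------------------------------------------
# enrichment wrappers


def de_gene_rre_enrichment(
    de_genes: Iterable[str],
    links: Sequence[PeakGeneLink],
    gene_universe: Iterable[str],
    n: int = None,
) -> EnrichmentResult:
    """Overlap enrichment of DE genes among RRE-linked genes.

    n defaults to the size of the supplied gene universe; pass n=25592 to use
    the zebrafish coding-gene universe. DE genes absent from the universe are
    excluded with a warning.
    """
    universe: Set[str] = set(gene_universe)
    if n is None:
        n = len(universe)
    de: Set[str] = set(de_genes)
    missing = de - universe
    if missing:
        logger.warning(
            "%d DE genes absent from the gene universe were excluded: %s",
            len(missing),
            sorted(missing)[:5],
        )
        de &= universe
    linked = {l.gene_id for l in links} & universe
    m = len(linked & de)
    return EnrichmentResult(
        n=n, n1=len(linked), n2=len(de), m=m,
        log10_p=hypergeom_upper_tail(n, len(linked), len(de), m),
    )


def cne_overlap_enrichment(
    rres_linked_to_de: Iterable[str],
    cnes: Sequence[Interval],
    universe_rres: Sequence[Peak],
) -> Tuple[int, EnrichmentResult]:
    """Enrichment of CNE overlap among DE-linked RREs over the RRE universe.

    An RRE overlaps a CNE when they share >=1 bp (half-open; bookends do not
    count). Returns (number of CNE-overlapping RREs, enrichment result with
    n = universe size, n1 = CNE-overlapping, n2 = DE-linked, m = both).
    """
    cne_by_chrom: Dict[str, List[Interval]] = {}
    for c in cnes:
        cne_by_chrom.setdefault(c.chrom, []).append(c)
    overlapping: Set[str] = set()
    for p in universe_rres:
        for c in cne_by_chrom.get(p.chrom, ()):
            if overlaps(p.start, p.end, c.start, c.end):
                overlapping.add(p.peak_id)
                break
    de_linked = set(rres_linked_to_de) & {p.peak_id for p in universe_rres}
    n = len(universe_rres)
    n1 = len(overlapping)
    n2 = len(de_linked)
    m = len(overlapping & de_linked)
    return n1, EnrichmentResult(
        n=n, n1=n1, n2=n2, m=m, log10_p=hypergeom_upper_tail(n, n1, n2, m)
    )
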