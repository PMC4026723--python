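"""Branch-wise gene-set enrichment with a hypergeometric tail statistic.

Genes proximal to sites that gained their CpG on a given stem lineage are
tested, term by term, against the background universe of genes proximal to
all retained sites.  For a term annotating K of N universe genes, observing
k annotated genes among a selection of n has one-sided upper-tail p-value
P[X >= k] with X ~ Hypergeometric(N, K, n).  Benjamini–Hochberg adjustment
is applied across terms within each branch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .errors import UsageError
from .origins import OriginAssignment
from .phylo import BRANCH_NAMES, PRE_MAMMAL, SiteRecord

logger = logging.getLogger(__name__)


class AnnotationMap:
    """Bidirectional gene ↔ term index; empty term sets are not stored."""

    def __init__(self, gene_to_terms: Mapping[str, Iterable[str]] | None = None):
        self._gene_to_terms: dict[str, set[str]] = {}
        self._term_to_genes: dict[str, set[str]] = {}
        if gene_to_terms:
            for gene, terms in gene_to_terms.items():
                for term in terms:
                    self.add(gene, term)

    def add(self, gene: str, term: str) -> None:
        self._gene_to_terms.setdefault(gene, set()).add(term)
        self._term_to_genes.setdefault(term, set()).add(gene)

    def terms_for(self, gene: str) -> set[str]:
        return set(self._gene_to_terms.get(gene, set()))

    def genes_for(self, term: str) -> set[str]:
        return set(self._term_to_genes.get(term, set()))

    @property
    def terms(self) -> list[str]:
        return sorted(self._term_to_genes)

    def __len__(self) -> int:
        return len(self._term_to_genes)

    @classmethod
    def from_tsv(cls, path) -> "AnnotationMap":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        if not {"gene", "term"} <= set(df.columns):
            raise UsageError("annotation TSV needs columns: gene, term")
        amap = cls()
        for row in df.itertuples(index=False):
            amap.add(str(row.gene), str(row.term))
        return amap

    def to_tsv(self, path) -> None:
        rows = [
            (gene, term)
            for gene in sorted(self._gene_to_terms)
            for term in sorted(self._gene_to_terms[gene])
        ]
        pd.DataFrame(rows, columns=["gene", "term"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    branch: str
    overlap: int  # k
    selection_size: int  # n
    term_size: int  # K, within the universe
    universe_size: int  # N
    p: float
    fdr: float


def _bh_adjust(pvalues: Sequence[float]) -> list[float]:
    return list(stats.false_discovery_control(pvalues, method="bh"))


def hypergeom_enrich(
    selection: Iterable[str],
    universe: Iterable[str],
    annotations: AnnotationMap,
    branch: str = "",
) -> list[EnrichmentResult]:
    """Per-term upper-tail hypergeometric enrichment of ``selection``.

    Every term with at least one universe gene is tested; results are sorted
    by p-value with BH-FDR computed across the tested terms.
    """
    uni = set(universe)
    sel = set(selection)
    stray = sorted(sel - uni)
    if stray:
        raise UsageError(f"selection genes outside universe: {', '.join(stray)}")
    N, n = len(uni), len(sel)
    rows: list[EnrichmentResult] = []
    for term in annotations.terms:
        term_genes = annotations.genes_for(term) & uni
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & sel)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(EnrichmentResult(term, branch, k, n, K, N, min(p, 1.0), 1.0))
    if not rows:
        return []
    fdrs = _bh_adjust([r.p for r in rows])
    adjusted = [
        EnrichmentResult(r.term, r.branch, r.overlap, r.selection_size,
                         r.term_size, r.universe_size, r.p, float(q))
        for r, q in zip(rows, fdrs)
    ]
    return sorted(adjusted, key=lambda r: (r.p, r.term))


def branch_gene_sets(
    assignments: Sequence[OriginAssignment],
    manifest: Sequence[SiteRecord],
) -> dict[str, set[str]]:
    """Deduplicated proximal-gene sets per origin branch.

    All eight stems plus ``pre_mammal`` are present in the result even when
    empty; sites without a gene annotation are skipped with a log line.
    """
    gene_of = {r.site_id: r.gene for r in manifest}
    sets: dict[str, set[str]] = {name: set() for name in (*BRANCH_NAMES, PRE_MAMMAL)}
    for a in assignments:
        gene = gene_of.get(a.site_id, "")
        if not gene:
            logger.info("site %s has no proximal gene; skipped", a.site_id)
            continue
        sets[a.origin].add(gene)
    return sets


def enrich_by_branch(
    assignments: Sequence[OriginAssignment],
    manifest: Sequence[SiteRecord],
    annotations: AnnotationMap,
    universe: set[str] | None = None,
) -> list[EnrichmentResult]:
    """Run the hypergeometric test branch by branch.

    Each branch's proximal-gene set is the selection; the universe defaults
    to the union of all branch gene sets but is normally the background
    genes of the full retained data set.
    """
    sets = branch_gene_sets(assignments, manifest)
    if universe is None:
        universe = set().union(*sets.values())
    results: list[EnrichmentResult] = []
    for branch, genes in sets.items():
        if not genes or not universe:
            continue
        results.extend(hypergeom_enrich(genes, universe, annotations, branch))
    return results
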