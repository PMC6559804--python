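"""Hypergeometric over-representation of predictions in a reference list.

Validates a knockout screen at scale: are the predicted target genes
enriched for an independently curated reference set (e.g. genes whose
perturbation predisposes to seizures)?  The test is the exact upper
tail P(X ≥ k) of a hypergeometric draw — k observed reference genes
among n predictions drawn from a universe of N genes containing K
reference genes — inclusive of the observed overlap.

The universe defaults to the screen's candidate genes: a prediction can
only ever be drawn from the candidate set, so that is the correct draw
population.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from scipy import stats

__all__ = ["EnrichmentResult", "hypergeometric_test", "read_gene_list"]


@dataclass(frozen=True)
class EnrichmentResult:
    universe_size: int       # N
    marked: int              # K: reference genes inside the universe
    drawn: int               # n: predicted genes
    overlap: int             # k
    p_value: float           # P(X >= k), inclusive
    fold_enrichment: float   # (k/n) / (K/N)
    overlap_genes: frozenset[str] = frozenset()

    def as_dict(self) -> dict:
        return {
            "universe_size": self.universe_size,
            "marked": self.marked,
            "drawn": self.drawn,
            "overlap": self.overlap,
            "p_value": self.p_value,
            "fold_enrichment": self.fold_enrichment,
            "overlap_genes": sorted(self.overlap_genes),
        }


def hypergeometric_test(
    predicted: Iterable[str],
    reference: Iterable[str],
    universe: Iterable[str],
) -> EnrichmentResult:
    """Exact upper-tail hypergeometric enrichment test.

    ``predicted`` must be a subset of ``universe``; the marked set is
    ``reference ∩ universe``.  ``p_value = P(X ≥ k)`` where
    ``X ~ Hypergeom(N, K, n)``.
    """
    predicted = frozenset(predicted)
    reference = frozenset(reference)
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    outside = sorted(predicted - universe)
    if outside:
        raise ValueError(f"predicted genes outside the universe: {outside}")
    marked = reference & universe
    overlap = predicted & marked
    N, K, n, k = len(universe), len(marked), len(predicted), len(overlap)
    # survival function is exclusive: P(X > k-1) = P(X >= k)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, 0.0), 1.0)
    fold = (k / n) / (K / N) if n > 0 and K > 0 else float("nan")
    return EnrichmentResult(N, K, n, k, p, fold, frozenset(overlap))


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; '#' starts a comment; blanks ignored."""
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.append(line)
    return genes
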