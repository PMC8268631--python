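"""Gene-set machinery: per-sample GSZ scores, gene-set maps over a
trained SOM, and set-overlap enrichment statistics.

The GSZ score standardizes a set's summed value in one sample against
its exact sampling moments under random drawing of an equally sized set
without replacement from that sample (hypergeometric sampling): with N
genes of mean mu_s and population variance sigma2_s, a random size-n sum
has mean n*mu_s and variance n*sigma2_s*(N-n)/(N-1).  For a random set
the score is therefore mean 0, variance ~1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import OmicsMatrix, ConfigurationError
from .som import SomModel


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: Tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise ConfigurationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            object.__setattr__(self, "genes",
                               tuple(dict.fromkeys(self.genes)))

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[str]) -> "GeneSet":
        return cls(name, tuple(genes))


def gsz_score(gene_set: GeneSet, m: OmicsMatrix) -> pd.Series:
    """Per-sample GSZ score of one set against a (centered) matrix.

    score_s = (sum_{g in set} e_gs - n*mu_s) / sqrt(n*sigma2_s*(N-n)/(N-1))
    with population variance sigma2_s; a zero-variance sample scores 0.
    Only set genes present in the matrix are used.
    """
    genes = pd.Index(gene_set.genes).intersection(m.gene_ids)
    if len(genes) == 0:
        raise ConfigurationError(
            f"gene set {gene_set.name!r} shares no genes with the matrix")
    values = m.values
    n_genes = values.shape[0]
    n = len(genes)
    mu = values.mean(axis=0)
    sigma2 = values.var(axis=0)  # population (1/N)
    set_sum = m.data.loc[genes].to_numpy().sum(axis=0)
    if n_genes > 1:
        var_sum = n * sigma2 * (n_genes - n) / (n_genes - 1)
    else:
        var_sum = np.zeros_like(sigma2)
    score = np.zeros(values.shape[1])
    ok = var_sum > 0
    score[ok] = (set_sum[ok] - n * mu[ok]) / np.sqrt(var_sum[ok])
    return pd.Series(score, index=m.sample_ids, name=gene_set.name)


def gsz_profiles(sets: Dict[str, List[str]], m: OmicsMatrix) -> pd.DataFrame:
    """Set x sample GSZ score table; sets with no shared gene are skipped."""
    rows = {}
    for name, genes in sets.items():
        try:
            rows[name] = gsz_score(GeneSet.from_iterable(name, genes), m)
        except ConfigurationError:
            continue
    if not rows:
        raise ConfigurationError("no gene set overlaps the matrix")
    return pd.DataFrame(rows).T


def gene_set_map(gene_set: GeneSet, model: SomModel) -> np.ndarray:
    """Per-unit count of set genes (via BMU assignment); counts sum to the
    size of the set's intersection with the model's genes."""
    genes = pd.Index(gene_set.genes)
    pos = model.gene_ids.get_indexer(genes)
    pos = pos[pos >= 0]
    if len(pos) == 0:
        raise ConfigurationError(
            f"gene set {gene_set.name!r} shares no genes with the map")
    counts = np.bincount(model.bmu[pos], minlength=model.n_units)
    return counts.reshape(model.grid_k, model.grid_k)


@dataclass
class OverlapResult:
    overlap: int
    odds_ratio: float
    p: float


def fisher_overlap(a: Iterable[str], b: Iterable[str], universe_size: int,
                   two_sided: bool = False) -> OverlapResult:
    """Enrichment of the overlap of two gene sets in a universe of size N.

    One-sided p = P(X >= k) with X ~ Hypergeometric(N, |a|, |b|); the
    odds ratio comes from the 2x2 table with a 0.5 Haldane correction
    when any cell is zero.  `two_sided=True` uses Fisher's exact test.
    """
    set_a, set_b = set(a), set(b)
    k = len(set_a & set_b)
    na, nb = len(set_a), len(set_b)
    if na > universe_size or nb > universe_size:
        raise ConfigurationError("set larger than the universe")
    if universe_size - na - nb + k < 0:
        raise ConfigurationError(
            "universe too small for the observed table")
    table = np.array([[k, na - k], [nb - k, universe_size - na - nb + k]],
                     dtype=float)
    if two_sided:
        _, p = stats.fisher_exact(table.astype(int), alternative="two-sided")
    else:
        p = float(stats.hypergeom.sf(k - 1, universe_size, na, nb))
    if (table == 0).any():
        table = table + 0.5
    odds = float(table[0, 0] * table[1, 1] / (table[0, 1] * table[1, 0]))
    return OverlapResult(overlap=k, odds_ratio=odds, p=float(p))
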