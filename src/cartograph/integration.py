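"""Integration of the expression and methylation layers.

Three views: (i) covariance maps that color each unit of a host map by
the mean gene-level covariance between expression and promoter
methylation of the genes collected in that unit; (ii) the coupled E-M
spot network joining expression and methylation spots with significant
gene overlap and anti-correlated per-sample profiles; (iii) sample
similarity structure (correlation heatmap order, similarity net) in
metagene space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from scipy import stats

from .matrix import OmicsMatrix, ConfigurationError
from .som import SomModel
from .spots import Spot
from .genesets import fisher_overlap


@dataclass
class CovarianceMap:
    """Per-unit mean expression-methylation covariance on a host map."""

    grid: np.ndarray
    gene_counts: np.ndarray
    valid: np.ndarray          # False where a unit hosts no shared gene

    def to_frame(self) -> pd.DataFrame:
        k = self.grid.shape[0]
        rows, cols = np.divmod(np.arange(k * k), k)
        return pd.DataFrame({"unit_row": rows, "unit_col": cols,
                             "covariance": self.grid.ravel(),
                             "n_genes": self.gene_counts.ravel(),
                             "valid": self.valid.ravel().astype(int)})


def gene_em_covariance(expr: OmicsMatrix, meth: OmicsMatrix) -> pd.Series:
    """Population (1/n) covariance between each gene's expression and
    promoter beta across the shared samples."""
    genes = expr.gene_ids.intersection(meth.gene_ids)
    samples = expr.sample_ids.intersection(meth.sample_ids)
    if len(samples) < 3:
        raise ConfigurationError("need >= 3 shared samples")
    if len(genes) == 0:
        raise ConfigurationError("no shared genes between layers")
    e = expr.data.loc[genes, samples].to_numpy()
    b = meth.data.loc[genes, samples].to_numpy()
    cov = (e * b).mean(axis=1) - e.mean(axis=1) * b.mean(axis=1)
    return pd.Series(cov, index=genes, name="em_covariance")


def covariance_map(host: SomModel, expr: OmicsMatrix,
                   meth: OmicsMatrix) -> CovarianceMap:
    """Average the per-gene E-M covariance over each host-map unit.

    The per-gene covariances are geometry-free: computing them on the
    expression or the methylation map gives identical values; only the
    aggregation into units differs.
    """
    cov = gene_em_covariance(expr, meth)
    pos = host.gene_ids.get_indexer(cov.index)
    keep = pos >= 0
    units = host.bmu[pos[keep]]
    vals = cov.to_numpy()[keep]
    sums = np.bincount(units, weights=vals, minlength=host.n_units)
    counts = np.bincount(units, minlength=host.n_units)
    grid = np.zeros(host.n_units)
    valid = counts > 0
    grid[valid] = sums[valid] / counts[valid]
    k = host.grid_k
    return CovarianceMap(grid.reshape(k, k), counts.reshape(k, k),
                         valid.reshape(k, k))


@dataclass
class EmEdge:
    e_spot: str
    m_spot: str
    overlap: int
    fisher_p: float
    profile_r: float


@dataclass
class EmNetwork:
    """Bipartite network of coupled expression and methylation spots."""

    edges: List[EmEdge]
    e_spots: List[str]
    m_spots: List[str]
    p_max: float
    r_max: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"e_spot": e.e_spot, "m_spot": e.m_spot, "overlap": e.overlap,
              "p": e.fisher_p, "r": e.profile_r} for e in self.edges],
            columns=["e_spot", "m_spot", "overlap", "p", "r"])

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for s in self.e_spots:
            g.add_node(f"E:{s}", layer="expression")
        for s in self.m_spots:
            g.add_node(f"M:{s}", layer="methylation")
        for e in self.edges:
            g.add_edge(f"E:{e.e_spot}", f"M:{e.m_spot}", overlap=e.overlap,
                       p=e.fisher_p, r=e.profile_r)
        return g

    def write_graphml(self, path: str) -> None:
        nx.write_graphml(self.graph(), path)

    def coupled_components(self) -> List[List[str]]:
        """Connected components with >= 1 edge: the combined regulatory
        modes of the cohort (descriptive output)."""
        g = self.graph()
        return sorted((sorted(c) for c in nx.connected_components(g)
                       if len(c) > 1), key=lambda c: (-len(c), c))


def build_em_network(e_spots: Sequence[Spot], m_spots: Sequence[Spot],
                     universe_size: int, p_max: float = 1e-3,
                     r_max: float = 0.0) -> EmNetwork:
    """Join E- and M-spots whose gene sets overlap more than chance
    (one-sided Fisher p < p_max) and whose per-sample profiles are
    anti-correlated (Pearson r < r_max, default: any negative r).
    """
    edges = []
    for es in e_spots:
        for ms in m_spots:
            shared = es.profile.index.intersection(ms.profile.index)
            if len(shared) < 3:
                raise ConfigurationError(
                    "spot profiles share fewer than 3 samples")
            res = fisher_overlap(es.genes, ms.genes, universe_size)
            ep = es.profile.loc[shared].to_numpy()
            mp = ms.profile.loc[shared].to_numpy()
            if ep.std() == 0 or mp.std() == 0:
                continue
            r = float(np.corrcoef(ep, mp)[0, 1])
            if res.p < p_max and r < r_max:
                edges.append(EmEdge(es.spot_id, ms.spot_id, res.overlap,
                                    res.p, r))
    return EmNetwork(edges=edges,
                     e_spots=[s.spot_id for s in e_spots],
                     m_spots=[s.spot_id for s in m_spots],
                     p_max=p_max, r_max=r_max)


@dataclass
class SampleSimilarity:
    correlation: pd.DataFrame          # sample x sample Pearson r
    order: List[str]                   # dendrogram leaf order
    linkage: np.ndarray                # scipy linkage matrix (average, 1-r)
    edges: List[Tuple[str, str, float]]  # top-k neighbor net, r > 0
    flagged: List[str]                 # samples with constant metagene vector

    def cut(self, k: int) -> pd.Series:
        """Flat cluster labels from cutting the dendrogram into k groups."""
        from scipy.cluster.hierarchy import fcluster
        labels = fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.correlation.index, name="cluster")


def sample_similarity(model: SomModel, top_k: int = 3) -> SampleSimilarity:
    """Pairwise Pearson similarity of samples in metagene space, with
    average-linkage ordering (heatmap) and a top-k neighbor net."""
    samples = list(model.sample_ids)
    if len(samples) < 2:
        raise ConfigurationError("need >= 2 samples")
    cb = model.codebook
    sd = cb.std(axis=0)
    flagged = [s for s, ok in zip(samples, sd > 0) if not ok]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(cb.T)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    corr_df = pd.DataFrame(corr, index=samples, columns=samples)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = average(squareform(dist, checks=False))
    order = [samples[i] for i in leaves_list(link)]
    edges = []
    seen = set()
    for i, s in enumerate(samples):
        neigh = np.argsort(-corr[i])
        picked = 0
        for j in neigh:
            if j == i or corr[i, j] <= 0:
                continue
            key = (min(i, j), max(i, j))
            if key not in seen:
                seen.add(key)
                edges.append((samples[key[0]], samples[key[1]],
                              float(corr[i, j])))
            picked += 1
            if picked >= top_k:
                break
    return SampleSimilarity(correlation=corr_df, order=order, linkage=link,
                            edges=edges, flagged=flagged)
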