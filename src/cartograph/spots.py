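"""Spot modules: segmentation of the map into connected regions of
concerted over-expression (or over-methylation), their per-sample
profiles, binary spot calls, co-occurrence statistics, and gene-based
mapping of spots between independently trained maps.

A spot is a connected component (8-connectivity by default) of units
whose summary-map value lies strictly above a high nearest-rank quantile.
Spots are labelled A, B, ... by descending peak height; labels are
per-run and carry no meaning across maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .matrix import OmicsMatrix, ConfigurationError
from .som import Portrait, SomModel, group_mean_portrait


def nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Nearest-rank (no interpolation) q-quantile: the ceil(q*n)-th order
    statistic, 1-based, clamped into [1, n]."""
    if not 0.0 < q < 1.0:
        raise ConfigurationError("quantile must lie in (0, 1)")
    flat = np.sort(np.asarray(values, dtype=float).ravel())
    if flat.size == 0:
        raise ConfigurationError("empty value set")
    rank = min(max(int(np.ceil(q * flat.size)), 1), flat.size)
    return float(flat[rank - 1])


def _spot_labels(n: int) -> List[str]:
    """A..Z, then AA, AB, ... for pathological spot counts."""
    out = []
    for i in range(n):
        label = ""
        j = i
        while True:
            label = chr(ord("A") + j % 26) + label
            j = j // 26 - 1
            if j < 0:
                break
        out.append(label)
    return out


@dataclass
class Spot:
    """A labelled connected region of the map."""

    spot_id: str
    units: List[Tuple[int, int]]          # (row, col) grid coordinates
    genes: List[str]
    profile: pd.Series                    # per-sample mean metagene value
    peak: float = 0.0

    @property
    def flat_units(self) -> List[int]:
        return [r * self._grid_k + c for r, c in self.units]

    _grid_k: int = 0


def overexpression_summary_map(model: SomModel,
                               labels: Dict[str, str]) -> Portrait:
    """Pixel-wise maximum over all group-mean portraits: an overview of
    every region upregulated in at least one group."""
    groups = sorted(set(labels.values()))
    if not groups:
        raise ConfigurationError("need at least one group")
    stack = np.stack([group_mean_portrait(model, labels, g).grid
                      for g in groups])
    return Portrait(stack.max(axis=0), label="overexpression summary",
                    layer=model.layer)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in (4, 8):
        raise ConfigurationError("connectivity must be 4 or 8")
    return (np.ones((3, 3), dtype=int) if connectivity == 8
            else ndimage.generate_binary_structure(2, 1))


def _components(grid: np.ndarray, threshold: float, min_size: int,
                structure: np.ndarray):
    """(peak, [(row, col), ...]) for every connected component of
    grid > threshold with at least min_size units."""
    mask = grid > threshold
    labelled, n_comp = ndimage.label(mask, structure=structure)
    out = []
    for comp_id in range(1, n_comp + 1):
        coords = np.argwhere(labelled == comp_id)
        if len(coords) < min_size:
            continue
        peak = float(grid[tuple(coords.T)].max())
        out.append((peak, [tuple(map(int, rc)) for rc in coords]))
    return out


def _build_spots(comps, model: SomModel) -> List[Spot]:
    comps = sorted(comps, key=lambda t: (-t[0], t[1]))
    unit_genes = model.unit_genes
    spots = []
    for label, (peak, coords) in zip(_spot_labels(len(comps)), comps):
        flat = [r * model.grid_k + c for r, c in coords]
        genes = sorted(g for u in flat for g in unit_genes.get(u, []))
        profile = pd.Series(model.codebook[flat].mean(axis=0),
                            index=model.sample_ids, name=label)
        spot = Spot(spot_id=label, units=coords, genes=genes,
                    profile=profile, peak=peak)
        spot._grid_k = model.grid_k
        spots.append(spot)
    return spots


def detect_spots(summary: Portrait, model: SomModel, q: float = 0.98,
                 min_size: int = 3, connectivity: int = 8,
                 negate: bool = False) -> List[Spot]:
    """Segment the summary map into spots.

    Units with value strictly above the nearest-rank `q`-quantile of all
    unit values form the foreground; connected components (4- or
    8-connectivity) smaller than `min_size` are discarded; the rest are
    labelled by descending component maximum.  `negate=True` segments
    under-expression instead (the map is negated first).

    A flat map yields zero spots (nothing exceeds its own quantile).
    """
    structure = _structure(connectivity)
    grid = -summary.grid if negate else summary.grid
    if grid.shape != (model.grid_k, model.grid_k):
        raise ConfigurationError("summary grid does not match model")
    threshold = nearest_rank_quantile(grid, q)
    comps = _components(grid, threshold, min_size, structure)
    return _build_spots(comps, model)


def detect_group_spots(model: SomModel, labels: Dict[str, str],
                       q: float = 0.98, min_size: int = 3,
                       connectivity: int = 8,
                       negate: bool = False) -> List[Spot]:
    """Group-resolved spot segmentation.

    The summary map's pixel-wise maximum can bridge regions upregulated
    in *different* groups when they happen to sit adjacently on the grid.
    Here the nearest-rank `q`-quantile threshold is computed once on the
    summary map (max over group-mean portraits) but applied to each
    group-mean portrait separately, so only regions genuinely elevated in
    that group form components; components from different groups are then
    merged when they share units.  With subtype-specific modules this
    segments each module even when two modules touch on the map.
    """
    structure = _structure(connectivity)
    groups = sorted(set(labels.values()))
    if not groups:
        raise ConfigurationError("need at least one group")
    grids = [group_mean_portrait(model, labels, g).grid for g in groups]
    if negate:
        grids = [-g for g in grids]
    summary = np.max(np.stack(grids), axis=0)
    threshold = nearest_rank_quantile(summary, q)
    comps = []
    for grid in grids:
        comps.extend(_components(grid, threshold, min_size, structure))
    # merge components from different groups that share units
    merged: List[tuple] = []
    for peak, coords in comps:
        units = set(coords)
        hits = [m for m in merged if m[1] & units]
        for m in hits:
            merged.remove(m)
            units |= m[1]
            peak = max(peak, m[0])
        merged.append((peak, units))
    return _build_spots([(p, sorted(u)) for p, u in merged], model)


def call_spots(spots: Sequence[Spot], model: SomModel,
               q: float = 0.90) -> pd.DataFrame:
    """Binary spot x sample call matrix.

    A spot is called in a sample iff the sample's mean portrait value over
    the spot's units strictly exceeds the nearest-rank `q`-quantile of
    that sample's own unit values — a rank-based rule, invariant to
    adding a constant to one sample's portrait.
    """
    calls = {}
    for j, s in enumerate(model.sample_ids):
        vals = model.codebook[:, j]
        thr = nearest_rank_quantile(vals, q)
        calls[s] = [float(np.mean(vals[sp.flat_units])) > thr for sp in spots]
    return pd.DataFrame(calls, index=[sp.spot_id for sp in spots])


def spot_number_distribution(calls: pd.DataFrame,
                             groups: Dict[str, str]) -> pd.DataFrame:
    """Per-group histogram of spots-per-sample (heterogeneity summary).

    Rows are spot counts 0..n_spots; each column sums to its group size.
    """
    n_spots = calls.shape[0]
    per_sample = calls.sum(axis=0)
    out = {}
    for g in sorted(set(groups.values())):
        members = [s for s in calls.columns if groups.get(s) == g]
        hist = np.bincount(per_sample[members].to_numpy(dtype=int),
                           minlength=n_spots + 1)
        out[g] = hist
    return pd.DataFrame(out, index=pd.RangeIndex(n_spots + 1, name="n_spots"))


@dataclass
class ImplicationEdge:
    spot_a: str
    spot_b: str
    conf_ab: float   # P(B called | A called)
    conf_ba: float


def spot_implication(calls: pd.DataFrame, group_samples: Sequence[str],
                     conf_min: float = 0.5):
    """Undirected co-occurrence edges between spots within one group.

    conf(A->B) = |A and B| / |A| over the group's samples; an edge is
    emitted iff both directional confidences exceed `conf_min`.  Spots
    never called in the group are excluded and listed separately.
    """
    group_samples = [s for s in group_samples if s in calls.columns]
    if not group_samples:
        raise ConfigurationError("group has no samples in the call matrix")
    sub = calls[group_samples].to_numpy(dtype=bool)
    spot_ids = list(calls.index)
    counts = sub.sum(axis=1)
    never = [spot_ids[i] for i in range(len(spot_ids)) if counts[i] == 0]
    edges = []
    for i in range(len(spot_ids)):
        if counts[i] == 0:
            continue
        for j in range(i + 1, len(spot_ids)):
            if counts[j] == 0:
                continue
            both = int(np.sum(sub[i] & sub[j]))
            conf_ij = both / counts[i]
            conf_ji = both / counts[j]
            if min(conf_ij, conf_ji) > conf_min:
                edges.append(ImplicationEdge(spot_ids[i], spot_ids[j],
                                             conf_ij, conf_ji))
    return edges, never


def spot_expression_methylation_scatter(
        spot: Spot, expr: OmicsMatrix, meth: OmicsMatrix,
        groups: Dict[str, str]) -> pd.DataFrame:
    """Per-group (mean expression, mean beta) over the spot's genes.

    Genes must be present in both matrices (the intersection is used);
    means are taken over spot genes and the group's shared samples.
    """
    genes = (pd.Index(spot.genes).intersection(expr.gene_ids)
             .intersection(meth.gene_ids))
    if len(genes) == 0:
        raise ConfigurationError(
            f"spot {spot.spot_id}: no genes shared by both matrices")
    samples = expr.sample_ids.intersection(meth.sample_ids)
    rows = []
    for g in sorted(set(groups.values())):
        members = [s for s in samples if groups.get(s) == g]
        if not members:
            continue
        rows.append({
            "group": g,
            "n_samples": len(members),
            "mean_expr": float(expr.data.loc[genes, members].to_numpy().mean()),
            "mean_beta": float(meth.data.loc[genes, members].to_numpy().mean()),
        })
    return pd.DataFrame(rows)


def crossmap_genes(genes: Iterable[str], target: SomModel,
                   target_spots: Sequence[Spot]):
    """Map a gene list into another trained map.

    Returns the per-unit gene density grid and a dispersion score: the
    Shannon entropy of the gene distribution over the target's spot bins
    plus one background bin, normalized by log(n_bins).  0 = all genes in
    one bin ("tight" correspondence), 1 = uniform spread ("melting").
    """
    genes = pd.Index(genes)
    pos = target.gene_ids.get_indexer(genes)
    pos = pos[pos >= 0]
    if len(pos) == 0:
        raise ConfigurationError("no gene shared with the target map")
    units = target.bmu[pos]
    density = np.bincount(units, minlength=target.n_units).astype(float)
    density = density.reshape(target.grid_k, target.grid_k)
    unit_to_bin = np.full(target.n_units, len(target_spots))  # background
    for b, sp in enumerate(target_spots):
        unit_to_bin[sp.flat_units] = b
    n_bins = len(target_spots) + 1
    bin_counts = np.bincount(unit_to_bin[units], minlength=n_bins)
    p = bin_counts / bin_counts.sum()
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    dispersion = entropy / np.log(n_bins) if n_bins > 1 else 0.0
    return density, float(dispersion)


def spots_to_frame(spots: Sequence[Spot]) -> pd.DataFrame:
    """Long-form spot table (spot_id, unit_row, unit_col, gene list row)."""
    rows = []
    for sp in spots:
        for (r, c) in sp.units:
            rows.append({"spot_id": sp.spot_id, "unit_row": r, "unit_col": c})
    return pd.DataFrame(rows, columns=["spot_id", "unit_row", "unit_col"])


def spot_gene_sets(spots: Sequence[Spot]) -> Dict[str, List[str]]:
    return {sp.spot_id: list(sp.genes) for sp in spots}


def module_recovery(truth_modules: Dict[int, List[str]],
                    spots: Sequence[Spot]) -> pd.DataFrame:
    """Best gene-set Jaccard between each planted module and any spot."""
    rows = []
    for m, genes in truth_modules.items():
        gset = set(genes)
        best_j, best_spot = 0.0, None
        for sp in spots:
            sset = set(sp.genes)
            if not sset:
                continue
            j = len(gset & sset) / len(gset | sset)
            if j > best_j:
                best_j, best_spot = j, sp.spot_id
        rows.append({"module": m, "best_spot": best_spot,
                     "jaccard": best_j})
    return pd.DataFrame(rows)
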