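"""Batch self-organizing map on gene profiles and portrait generation.

Genes are points in sample space; the map's codebook holds grid_k^2
"metagene" prototype profiles.  One training epoch assigns every gene to
its Euclidean best-matching unit (BMU) and then replaces each codebook
vector by the neighborhood-kernel-weighted mean of the gene profiles,
with a Gaussian kernel over grid distance.  The kernel radius anneals
linearly from `radius_start` to `radius_end` over the first
`anneal_fraction` of the epochs and then stays frozen, so the final
epochs behave like (soft) k-means and the quantization error settles.

A "portrait" is the grid_k x grid_k image of one sample's (or a group
mean's) metagene values; with row-centered input, red/blue pixels read as
up/down regulation relative to each gene's cohort mean.  Retraining the
same operation on a sample subset yields a higher-resolution "zoom-in"
map — no separate code path exists.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .matrix import OmicsMatrix, ConfigurationError


@dataclass
class SomParams:
    """Training hyper-parameters.

    grid_k defaults to 30 (suits <= ~10k genes); 50 is the conventional
    choice for large expression cohorts.  radius_start=None means
    grid_k / 2.
    """

    grid_k: int = 30
    epochs: int = 40
    radius_start: Optional[float] = None
    radius_end: float = 0.5
    anneal_fraction: float = 0.75
    init: str = "pca_linear"  # or "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_k < 1:
            raise ConfigurationError("grid_k must be >= 1")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        start = self.resolved_radius_start()
        if start < self.radius_end or self.radius_end < 0:
            raise ConfigurationError(
                "need radius_start >= radius_end >= 0")
        if self.init not in ("pca_linear", "random"):
            raise ConfigurationError("init must be 'pca_linear' or 'random'")
        if not 0.0 < self.anneal_fraction <= 1.0:
            raise ConfigurationError("anneal_fraction must lie in (0, 1]")

    def resolved_radius_start(self) -> float:
        return self.grid_k / 2.0 if self.radius_start is None else self.radius_start

    def radius_schedule(self) -> np.ndarray:
        """Per-epoch radius: linear anneal, then frozen at radius_end."""
        start = self.resolved_radius_start()
        n_anneal = max(1, int(round(self.anneal_fraction * self.epochs)))
        if n_anneal == 1:
            anneal = np.array([self.radius_end])
        else:
            anneal = np.linspace(start, self.radius_end, n_anneal)
        frozen = np.full(self.epochs - n_anneal, self.radius_end)
        return np.concatenate([anneal, frozen])


@dataclass
class Portrait:
    """grid_k x grid_k image of metagene values for one sample or group."""

    grid: np.ndarray
    label: str
    layer: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2 or self.grid.shape[0] != self.grid.shape[1]:
            raise ConfigurationError("portrait grid must be square")

    @property
    def grid_k(self) -> int:
        return self.grid.shape[0]


@dataclass
class SomModel:
    """Trained map: codebook (grid_k^2 x n_samples) + gene->unit assignment."""

    params: SomParams
    codebook: np.ndarray
    gene_ids: pd.Index
    sample_ids: pd.Index
    bmu: np.ndarray                     # flat unit index per gene
    qe_history: np.ndarray
    layer: str = ""

    @property
    def grid_k(self) -> int:
        return self.params.grid_k

    @property
    def n_units(self) -> int:
        return self.grid_k ** 2

    @property
    def unit_genes(self) -> Dict[int, List[str]]:
        """Inverse map unit -> member gene ids (empty units omitted)."""
        out: Dict[int, List[str]] = {}
        for gene, u in zip(self.gene_ids, self.bmu):
            out.setdefault(int(u), []).append(gene)
        return out

    def unit_coords(self, unit: int) -> tuple:
        return divmod(int(unit), self.grid_k)

    def sample_index(self, sample: str) -> int:
        idx = self.sample_ids.get_indexer([sample])[0]
        if idx < 0:
            raise KeyError(f"unknown sample id {sample!r}")
        return int(idx)

    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        cb = pd.DataFrame(self.codebook, columns=self.sample_ids)
        cb.index.name = "unit"
        cb.to_csv(os.path.join(directory, "codebook.tsv"), sep="\t",
                  float_format="%.10g")
        pd.DataFrame({"gene_id": self.gene_ids, "unit": self.bmu}).to_csv(
            os.path.join(directory, "bmu.tsv"), sep="\t", index=False)
        meta = {
            "grid_k": self.params.grid_k, "epochs": self.params.epochs,
            "radius_start": self.params.resolved_radius_start(),
            "radius_end": self.params.radius_end,
            "anneal_fraction": self.params.anneal_fraction,
            "init": self.params.init, "seed": self.params.seed,
            "layer": self.layer,
            "qe_history": [float(q) for q in self.qe_history],
        }
        with open(os.path.join(directory, "params.yaml"), "w") as fh:
            yaml.safe_dump(meta, fh)

    @classmethod
    def load(cls, directory: str) -> "SomModel":
        cb = pd.read_csv(os.path.join(directory, "codebook.tsv"), sep="\t",
                         index_col=0)
        bmu = pd.read_csv(os.path.join(directory, "bmu.tsv"), sep="\t")
        with open(os.path.join(directory, "params.yaml")) as fh:
            meta = yaml.safe_load(fh)
        params = SomParams(grid_k=meta["grid_k"], epochs=meta["epochs"],
                           radius_start=meta["radius_start"],
                           radius_end=meta["radius_end"],
                           anneal_fraction=meta["anneal_fraction"],
                           init=meta["init"], seed=meta["seed"])
        return cls(params=params, codebook=cb.to_numpy(dtype=float),
                   gene_ids=pd.Index(bmu["gene_id"]),
                   sample_ids=pd.Index(cb.columns),
                   bmu=bmu["unit"].to_numpy(dtype=int),
                   qe_history=np.asarray(meta["qe_history"], dtype=float),
                   layer=meta.get("layer", ""))


def _grid_sqdist(grid_k: int) -> np.ndarray:
    """n_units x n_units squared Euclidean distances between grid nodes."""
    rows, cols = np.divmod(np.arange(grid_k * grid_k), grid_k)
    dr = rows[:, None] - rows[None, :]
    dc = cols[:, None] - cols[None, :]
    return (dr * dr + dc * dc).astype(float)


def _init_codebook(values: np.ndarray, params: SomParams) -> np.ndarray:
    n_genes, n_samples = values.shape
    k = params.grid_k
    rng = np.random.default_rng(params.seed)
    if params.init == "random" or n_genes < 2 or n_samples < 1:
        pick = rng.integers(0, n_genes, size=k * k)
        return values[pick].copy()
    # linear init: span the grid over the first two principal axes
    mean = values.mean(axis=0)
    centered = values - mean
    # deterministic SVD; components sign-fixed by largest-magnitude entry
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    axes = vt[:2]
    for i in range(axes.shape[0]):
        j = np.argmax(np.abs(axes[i]))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    sds = s[:2] / np.sqrt(max(n_genes - 1, 1))
    coord = (np.linspace(-1.0, 1.0, k) if k > 1 else np.zeros(1))
    cb = np.empty((k * k, n_samples))
    for u in range(k * k):
        r, c = divmod(u, k)
        cb[u] = mean + coord[r] * 2.0 * sds[0] * axes[0]
        if axes.shape[0] > 1:
            cb[u] += coord[c] * 2.0 * sds[1] * axes[1]
    return cb


def _assign_bmu(values: np.ndarray, codebook: np.ndarray):
    """Return (bmu index per gene, squared distance to BMU)."""
    # ||g - c||^2 = ||g||^2 - 2 g.c + ||c||^2; argmin ties -> lowest index
    cross = values @ codebook.T
    cnorm = np.einsum("ij,ij->i", codebook, codebook)
    d2 = cnorm[None, :] - 2.0 * cross
    bmu = np.argmin(d2, axis=1)
    gnorm = np.einsum("ij,ij->i", values, values)
    d2_bmu = gnorm + d2[np.arange(len(bmu)), bmu]
    return bmu, np.maximum(d2_bmu, 0.0)


def train_som(m: OmicsMatrix, params: Optional[SomParams] = None) -> SomModel:
    """Train a batch SOM on the gene profiles of `m`.

    Deterministic given (matrix, params): the linear initialization has no
    random component and the batch updates are order-free; `seed` only
    enters through `init='random'`.
    """
    if params is None:
        params = SomParams()
    values = m.values
    if values.size == 0:
        raise ConfigurationError("cannot train on an empty matrix")
    if not np.isfinite(values).all():
        raise ConfigurationError("matrix contains NaN/Inf")
    n_genes = values.shape[0]
    n_units = params.grid_k ** 2
    if n_genes < n_units / 4:
        import warnings
        warnings.warn(
            f"{n_genes} genes for {n_units} units: map will be sparse",
            stacklevel=2)

    codebook = _init_codebook(values, params)
    sqdist = _grid_sqdist(params.grid_k)
    qe_history = []
    bmu = np.zeros(n_genes, dtype=int)
    for radius in params.radius_schedule():
        bmu, d2 = _assign_bmu(values, codebook)
        qe_history.append(float(d2.mean()))
        counts = np.bincount(bmu, minlength=n_units).astype(float)
        sums = np.zeros((n_units, values.shape[1]))
        np.add.at(sums, bmu, values)
        if radius > 0:
            kernel = np.exp(-sqdist / (2.0 * radius * radius))
            wsum = kernel @ sums
            wcount = kernel @ counts
        else:
            wsum, wcount = sums, counts
        nonempty = wcount > 1e-12
        codebook[nonempty] = wsum[nonempty] / wcount[nonempty, None]
        # units with no (weighted) support keep their codebook vector
    bmu, d2 = _assign_bmu(values, codebook)
    qe_history.append(float(d2.mean()))
    return SomModel(params=params, codebook=codebook,
                    gene_ids=m.gene_ids, sample_ids=m.sample_ids,
                    bmu=bmu, qe_history=np.asarray(qe_history),
                    layer=m.layer)


def portrait(model: SomModel, sample: str) -> Portrait:
    """One sample's metagene image."""
    j = model.sample_index(sample)
    grid = model.codebook[:, j].reshape(model.grid_k, model.grid_k)
    return Portrait(grid, label=str(sample), layer=model.layer)


def group_mean_portrait(model: SomModel, labels: Dict[str, str],
                        group: str) -> Portrait:
    """Pixel-wise mean of the portraits of all samples labelled `group`."""
    members = [s for s in model.sample_ids if labels.get(s) == group]
    if not members:
        raise ConfigurationError(f"group {group!r} has no samples")
    idx = [model.sample_index(s) for s in members]
    grid = model.codebook[:, idx].mean(axis=1).reshape(model.grid_k,
                                                       model.grid_k)
    return Portrait(grid, label=str(group), layer=model.layer)


def difference_portrait(a: Portrait, b: Portrait) -> Portrait:
    """Pixel-wise a - b (e.g. subtype minus reference)."""
    if a.grid.shape != b.grid.shape:
        raise ConfigurationError("portrait shapes differ")
    return Portrait(a.grid - b.grid, label=f"{a.label}-{b.label}",
                    layer=a.layer)


def portrait_to_frame(p: Portrait) -> pd.DataFrame:
    """Long-form (row, col, value) table of a portrait, for TSV export."""
    k = p.grid_k
    rows, cols = np.divmod(np.arange(k * k), k)
    return pd.DataFrame({"unit_row": rows, "unit_col": cols,
                         "value": p.grid.ravel()})


def save_portrait_png(p: Portrait, path: str, cmap: str = "RdBu_r") -> None:
    """Render a portrait heatmap (symmetric color scale about 0)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lim = float(np.abs(p.grid).max()) or 1.0
    fig, ax = plt.subplots(figsize=(3.2, 3.2))
    ax.imshow(p.grid, cmap=cmap, vmin=-lim, vmax=lim, origin="lower")
    ax.set_title(p.label, fontsize=9)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
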