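"""Gene-centric omics matrices and annotation tables.

The common currency of the pipeline is a gene x sample value grid carried
by :class:`OmicsMatrix`.  Expression values are on log10 scale after
preprocessing; promoter methylation is a beta fraction in [0, 1]; centered
matrices have zero mean per gene row.  Annotation tables (gene annotation,
CpG tables, phenotype tables) are plain :class:`pandas.DataFrame` objects
with validated column contracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Allowed layer tags for an OmicsMatrix.
LAYERS = ("expression_log10", "methylation_beta", "centered")

GENE_ANNOTATION_COLUMNS = ("gene_id", "chromosome", "tss", "strand")
CPG_KEY_COLUMNS = ("cpg_id", "chromosome", "position")
PHENOTYPE_COLUMNS = ("sample_id", "subtype", "age", "sex", "tlr",
                     "surv_time", "surv_event")


class ConfigurationError(ValueError):
    """Raised when a configuration or table violates its contract."""


@dataclass
class OmicsMatrix:
    """A gene x sample real-valued grid with a layer tag.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with sample ids as columns.
    layer
        One of ``expression_log10``, ``methylation_beta``, ``centered``.
    """

    data: pd.DataFrame
    layer: str = "expression_log10"

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ConfigurationError(
                f"layer must be one of {LAYERS}, got {self.layer!r}")
        if self.data.index.duplicated().any():
            raise ConfigurationError("duplicate gene ids")
        if self.data.columns.duplicated().any():
            raise ConfigurationError("duplicate sample ids")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise ConfigurationError(
                "matrix contains missing or non-finite values; impute or "
                "filter upstream")
        if self.layer == "methylation_beta" and values.size:
            if values.min() < 0.0 or values.max() > 1.0:
                raise ConfigurationError("beta values must lie in [0, 1]")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes) -> "OmicsMatrix":
        keep = self.data.index.intersection(pd.Index(genes))
        return OmicsMatrix(self.data.loc[keep], self.layer)

    def with_layer(self, layer: str) -> "OmicsMatrix":
        return OmicsMatrix(self.data, layer)


def validate_gene_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Check the gene annotation contract and return the frame.

    Required columns: gene_id, chromosome, tss (1-based), strand (+/-).
    """
    missing = set(GENE_ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise ConfigurationError(f"gene annotation missing columns {sorted(missing)}")
    if (ann["tss"] < 1).any():
        raise ConfigurationError("tss positions must be >= 1 (1-based)")
    bad = ~ann["strand"].isin(["+", "-"])
    if bad.any():
        raise ConfigurationError(
            f"invalid strand values: {sorted(ann.loc[bad, 'strand'].unique())}")
    if ann["gene_id"].duplicated().any():
        raise ConfigurationError("duplicate gene ids in annotation")
    return ann


def validate_cpg_table(cpgs: pd.DataFrame) -> pd.DataFrame:
    """Check the CpG beta table contract and return the frame.

    Key columns cpg_id, chromosome, position; every remaining column is a
    sample of beta values in [0, 1] (NaN allowed: a CpG may be unmeasured
    in a sample and is then dropped from that sample's promoter mean).
    """
    missing = set(CPG_KEY_COLUMNS) - set(cpgs.columns)
    if missing:
        raise ConfigurationError(f"CpG table missing columns {sorted(missing)}")
    if (cpgs["position"] < 1).any():
        raise ConfigurationError("CpG positions must be >= 1 (1-based)")
    sample_cols = [c for c in cpgs.columns if c not in CPG_KEY_COLUMNS]
    betas = cpgs[sample_cols].to_numpy(dtype=float)
    finite = betas[np.isfinite(betas)]
    if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
        raise ConfigurationError("beta values must lie in [0, 1]")
    return cpgs


def cpg_sample_columns(cpgs: pd.DataFrame) -> list:
    return [c for c in cpgs.columns if c not in CPG_KEY_COLUMNS]


@dataclass
class SurvivalTable:
    """Right-censored survival outcomes, one row per sample."""

    sample_id: pd.Index
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_id = pd.Index(self.sample_id)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(self.sample_id) != len(self.time) or len(self.time) != len(self.event):
            raise ConfigurationError("survival table lengths differ")
        if (self.time <= 0).any():
            raise ConfigurationError("survival times must be > 0")
        if not np.isin(self.event, [0, 1]).all():
            raise ConfigurationError("event flags must be 0 or 1")

    @classmethod
    def from_phenotype(cls, pheno: pd.DataFrame) -> "SurvivalTable":
        return cls(pd.Index(pheno["sample_id"]),
                   pheno["surv_time"].to_numpy(dtype=float),
                   pheno["surv_event"].to_numpy(dtype=int))

    def reindex(self, samples) -> "SurvivalTable":
        """Restrict/reorder to `samples` (must all be present)."""
        pos = self.sample_id.get_indexer(pd.Index(samples))
        if (pos < 0).any():
            raise KeyError("samples missing from survival table")
        return SurvivalTable(pd.Index(samples), self.time[pos], self.event[pos])

    def __len__(self) -> int:
        return len(self.time)
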