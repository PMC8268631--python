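"""Readers and writers for the pipeline's plain-text formats.

Matrices travel as TSV with a header row of sample ids and a first column
of gene/CpG ids; gene sets as GMT; phenotypes as CSV with the fixed column
set ``sample_id, subtype, age, sex, tlr, surv_time, surv_event``.
All numeric output uses a fixed float format so reruns are byte-identical.
"""

from __future__ import annotations

import os
from typing import Dict, List

import pandas as pd

from .matrix import (OmicsMatrix, ConfigurationError, PHENOTYPE_COLUMNS,
                     validate_cpg_table, validate_gene_annotation)

FLOAT_FORMAT = "%.10g"


def read_matrix_tsv(path: str, layer: str = "expression_log10") -> OmicsMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return OmicsMatrix(df, layer)


def write_matrix_tsv(m: OmicsMatrix, path: str, id_name: str = "gene_id") -> None:
    df = m.data.copy()
    df.index.name = id_name
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_gene_annotation(path: str) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "strand": str})
    return validate_gene_annotation(ann)


def write_gene_annotation(ann: pd.DataFrame, path: str) -> None:
    validate_gene_annotation(ann).to_csv(path, sep="\t", index=False)


def read_cpg_table(path: str) -> pd.DataFrame:
    cpgs = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return validate_cpg_table(cpgs)


def write_cpg_table(cpgs: pd.DataFrame, path: str) -> None:
    validate_cpg_table(cpgs).to_csv(path, sep="\t", index=False,
                                    float_format=FLOAT_FORMAT)


def read_phenotype_csv(path: str) -> pd.DataFrame:
    pheno = pd.read_csv(path)
    missing = set(PHENOTYPE_COLUMNS) - set(pheno.columns)
    if missing:
        raise ConfigurationError(f"phenotype table missing columns {sorted(missing)}")
    bad_sex = ~pheno["sex"].isin(["F", "M"])
    if bad_sex.any():
        raise ConfigurationError("sex must be 'F' or 'M'")
    return pheno


def write_phenotype_csv(pheno: pd.DataFrame, path: str) -> None:
    pheno.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_gmt(path: str) -> Dict[str, List[str]]:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate gene ids within a set are collapsed (order preserved).
    """
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ConfigurationError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">=1 gene")
            name = fields[0]
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise ConfigurationError(f"{path}:{lineno}: empty gene set {name!r}")
            sets[name] = genes
    return sets


def write_gmt(sets: Dict[str, List[str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, ""] + list(genes)) + "\n")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
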