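"""Survival analysis on the map: per-unit Cox hazard ratios and
Kaplan-Meier curves for spot-defined groups.

A module with a planted adverse hazard shows up as a red (log HR > 0)
region of the prognostic map; subtype survival curves separate under
the log-rank test.
"""

import numpy as np
import pandas as pd

from cartograph import (CohortConfig, SomParams, SurvivalTable, center_genes,
                        generate_cohort, km_logrank, prognostic_map,
                        train_som)

cfg = CohortConfig(n_genes=1000, n_samples=160, n_subtypes=2, n_modules=2,
                   genes_per_module=40, cpgs_per_gene=1,
                   hazard_beta=np.array([np.log(2.5), 0.0]), seed=11)
expr, _, _, pheno, truth = generate_cohort(cfg)
model = train_som(center_genes(expr), SomParams(grid_k=12, epochs=20, seed=11))
surv = SurvivalTable.from_phenotype(pheno)

pm = prognostic_map(model, surv)
genes = truth.module_members[0]
pos = model.gene_ids.get_indexer(pd.Index(genes))
units = np.unique(model.bmu[pos[pos >= 0]])
print(f"adverse module units: median log HR per SD "
      f"{np.median(pm.grid.ravel()[units]):.2f}")
bg = np.setdiff1d(np.flatnonzero(pm.valid.ravel()), units)
print(f"background units:     median log HR per SD "
      f"{np.median(pm.grid.ravel()[bg]):.2f}")
print("-> the planted hazard (log 2.5 per unit activity) concentrates on "
      "the module's map region.")

by_subtype = {}
for s, t in truth.subtype_of_sample.items():
    by_subtype.setdefault(f"S{t}", []).append(s)
curves, chi2, p = km_logrank(by_subtype, surv)
print(f"log-rank between subtypes: chi2 = {chi2:.1f}, p = {p:.2e}")
print("-> subtype S0 carries the adverse module, so its curve falls "
      "faster.")
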