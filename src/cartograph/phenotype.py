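"""Phenotype maps: per-unit survival, covariate and sex associations.

The prognostic map fits, per map unit, a univariate Cox proportional
hazards model with the unit's metagene value (standardized, so the
hazard ratio is per SD) as continuous covariate.  The Cox fitter is a
single-covariate Newton-Raphson maximizer of the partial likelihood with
Breslow tie handling (Efron available), written out explicitly so that a
brute-force grid search over the same likelihood can serve as an
independent oracle.  Kaplan-Meier curves and the log-rank test are
delegated to lifelines.

No multiple-testing correction is applied to the maps: they are
descriptive visualizations; per-unit z-values are exported so users can
apply FDR downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .matrix import OmicsMatrix, ConfigurationError, SurvivalTable
from .som import SomModel
from .spots import nearest_rank_quantile


@dataclass
class CoxResult:
    beta: float
    hr: float
    se: float
    z: float
    valid: bool
    n_events: int


@dataclass
class PhenotypeMap:
    """Per-unit association statistic over the map grid.

    Invalid units (constant covariate, no events, non-convergence) are
    flagged, never silently zeroed.
    """

    grid: np.ndarray
    statistic: str                       # log_hr | pearson_r | female_diff
    valid: np.ndarray
    z: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        k = self.grid.shape[0]
        rows, cols = np.divmod(np.arange(k * k), k)
        out = pd.DataFrame({"unit_row": rows, "unit_col": cols,
                            "value": self.grid.ravel(),
                            "valid": self.valid.ravel().astype(int)})
        if self.z is not None:
            out["z"] = self.z.ravel()
        return out


def cox_partial_loglik(beta: float, x: np.ndarray, time: np.ndarray,
                       event: np.ndarray, ties: str = "breslow") -> float:
    """Partial log-likelihood of a univariate Cox model (oracle target)."""
    ll, _, _ = _cox_derivatives(beta, x, time, event, ties)
    return ll


def _cox_derivatives(beta, x, time, event, ties):
    order = np.argsort(time, kind="stable")
    xs, ts, ev = x[order], time[order], event[order].astype(bool)
    w = np.exp(beta * xs)
    # reverse cumulative sums: risk set of t = all with time >= t
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w * xs)[::-1])[::-1]
    s2 = np.cumsum((w * xs * xs)[::-1])[::-1]
    ll = 0.0
    score = 0.0
    info = 0.0
    i = 0
    n = len(ts)
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        d_idx = np.arange(i, j)[ev[i:j]]
        d = len(d_idx)
        if d:
            xsum = float(xs[d_idx].sum())
            ll += beta * xsum
            S0, S1, S2 = s0[i], s1[i], s2[i]
            if ties == "breslow":
                ll -= d * np.log(S0)
                score += xsum - d * S1 / S0
                info += d * (S2 / S0 - (S1 / S0) ** 2)
            elif ties == "efron":
                t0 = float(w[d_idx].sum())
                t1 = float((w[d_idx] * xs[d_idx]).sum())
                t2 = float((w[d_idx] * xs[d_idx] ** 2).sum())
                for el in range(d):
                    f = el / d
                    a0 = S0 - f * t0
                    a1 = S1 - f * t1
                    a2 = S2 - f * t2
                    ll -= np.log(a0)
                    score += -a1 / a0
                    info += a2 / a0 - (a1 / a0) ** 2
                score += xsum
            else:
                raise ConfigurationError("ties must be 'breslow' or 'efron'")
        i = j
    return ll, score, info


def cox_fit(x: np.ndarray, surv: SurvivalTable, ties: str = "breslow",
            max_iter: int = 50, tol: float = 1e-8,
            beta_max: float = 10.0) -> CoxResult:
    """Univariate Cox PH fit by Newton-Raphson.

    Returns valid=False (with HR reported as 1) for a constant covariate,
    fewer than 2 events, non-convergence, or a monotone likelihood
    (|beta| beyond `beta_max`, i.e. complete separation of events along
    the covariate; such fits have no finite maximizer).
    """
    x = np.asarray(x, dtype=float)
    if len(x) != len(surv):
        raise ConfigurationError("covariate length does not match survival")
    n_events = int(surv.event.sum())
    if n_events < 2 or np.ptp(x) == 0.0:
        return CoxResult(0.0, 1.0, np.nan, np.nan, False, n_events)
    beta = 0.0
    for _ in range(max_iter):
        _, score, info = _cox_derivatives(beta, x, surv.time, surv.event, ties)
        if abs(score) < tol:
            break
        if info <= 0 or not np.isfinite(info):
            return CoxResult(0.0, 1.0, np.nan, np.nan, False, n_events)
        beta += score / info
        if not np.isfinite(beta) or abs(beta) > beta_max:
            return CoxResult(0.0, 1.0, np.nan, np.nan, False, n_events)
    else:
        return CoxResult(0.0, 1.0, np.nan, np.nan, False, n_events)
    if abs(beta) > beta_max:
        return CoxResult(0.0, 1.0, np.nan, np.nan, False, n_events)
    _, _, info = _cox_derivatives(beta, x, surv.time, surv.event, ties)
    se = float(1.0 / np.sqrt(info)) if info > 0 else np.nan
    z = beta / se if np.isfinite(se) and se > 0 else np.nan
    return CoxResult(float(beta), float(np.exp(beta)), se, float(z), True,
                     n_events)


def prognostic_map(model: SomModel, surv: SurvivalTable,
                   min_overlap: int = 10, ties: str = "breslow") -> PhenotypeMap:
    """Per-unit log hazard ratio (per SD of the metagene value)."""
    shared = model.sample_ids.intersection(surv.sample_id)
    if len(shared) < min_overlap:
        raise ConfigurationError(
            f"only {len(shared)} samples shared between map and survival "
            f"(need >= {min_overlap})")
    sub = surv.reindex(shared)
    cols = model.sample_ids.get_indexer(shared)
    k = model.grid_k
    log_hr = np.zeros(k * k)
    zval = np.full(k * k, np.nan)
    valid = np.zeros(k * k, dtype=bool)
    for u in range(k * k):
        vals = model.codebook[u, cols]
        sd = vals.std()
        if sd == 0:
            continue
        res = cox_fit((vals - vals.mean()) / sd, sub, ties=ties)
        if res.valid:
            log_hr[u] = res.beta
            zval[u] = res.z
            valid[u] = True
    return PhenotypeMap(log_hr.reshape(k, k), "log_hr",
                        valid.reshape(k, k), zval.reshape(k, k))


def km_logrank(groups: Dict[str, Sequence[str]], surv: SurvivalTable):
    """Kaplan-Meier curves per group plus the multi-sample log-rank test.

    Returns (curves, chi2, p) where curves maps group -> DataFrame with
    columns time, survival (the product-limit estimate).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    if len(groups) < 2:
        raise ConfigurationError("need at least two groups")
    times, events, labels = [], [], []
    curves = {}
    for g, samples in groups.items():
        if len(samples) == 0:
            raise ConfigurationError(f"group {g!r} is empty")
        sub = surv.reindex(samples)
        kmf = KaplanMeierFitter()
        kmf.fit(sub.time, sub.event, label=str(g))
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame({"time": sf.index.to_numpy(),
                                  "survival": sf.iloc[:, 0].to_numpy()})
        times.append(sub.time)
        events.append(sub.event)
        labels.extend([g] * len(sub))
    result = multivariate_logrank_test(np.concatenate(times), labels,
                                       np.concatenate(events))
    return curves, float(result.test_statistic), float(result.p_value)


def covariate_map(model: SomModel, x: pd.Series) -> PhenotypeMap:
    """Per-unit Pearson correlation between metagene values and a
    continuous covariate (age, TLR, ...)."""
    shared = model.sample_ids.intersection(x.index)
    if len(shared) < 3:
        raise ConfigurationError("need >= 3 paired samples")
    xv = x.loc[shared].to_numpy(dtype=float)
    cols = model.sample_ids.get_indexer(shared)
    cb = model.codebook[:, cols]
    k = model.grid_k
    x_sd = xv.std()
    valid = np.zeros(k * k, dtype=bool)
    r = np.zeros(k * k)
    if x_sd > 0:
        xc = (xv - xv.mean()) / x_sd
        cb_c = cb - cb.mean(axis=1, keepdims=True)
        cb_sd = cb_c.std(axis=1)
        ok = cb_sd > 0
        r[ok] = (cb_c[ok] @ xc) / (len(xv) * cb_sd[ok])
        valid = ok
    return PhenotypeMap(r.reshape(k, k), "pearson_r", valid.reshape(k, k))


def female_difference_map(model: SomModel, sex: pd.Series,
                          top_quantile: float = 0.75) -> PhenotypeMap:
    """Female difference score per unit, in percent-of-percent.

    For each unit, samples whose portrait value lies strictly above the
    nearest-rank `top_quantile` of that unit's values across samples are
    "overexpressing"; the score is
    100 * (pct_female_selected - pct_female_all) / pct_female_all.
    Units selecting no sample (e.g. constant metagene) are invalid.
    """
    shared = model.sample_ids.intersection(sex.index)
    sx = sex.loc[shared]
    if not {"F", "M"} <= set(sx.unique()):
        raise ConfigurationError("both sexes must be present")
    is_f = (sx == "F").to_numpy()
    pct_all = 100.0 * is_f.mean()
    cols = model.sample_ids.get_indexer(shared)
    k = model.grid_k
    score = np.zeros(k * k)
    valid = np.zeros(k * k, dtype=bool)
    for u in range(k * k):
        vals = model.codebook[u, cols]
        thr = nearest_rank_quantile(vals, top_quantile)
        sel = vals > thr
        if not sel.any():
            continue
        pct_sel = 100.0 * is_f[sel].mean()
        score[u] = 100.0 * (pct_sel - pct_all) / pct_all
        valid[u] = True
    return PhenotypeMap(score.reshape(k, k), "female_diff",
                        valid.reshape(k, k))
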