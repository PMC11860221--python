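"""Multi-mediator path models for the PGS-occupational status association.

Quantifies how much of the association between a polygenic score and
occupational status runs through measured traits (cognitive ability,
scholastic motivation, occupational aspiration, internalizing and
externalizing behaviour, ...) using the product-of-coefficients method:

    M_k = a_k * PGS + controls
    Y   = c' * PGS + sum_k b_k * M_k + controls

with indirect effects a_k * b_k, the total effect from the reduced
regression of Y on the PGS, and the exact least-squares identity
total = c' + sum_k a_k * b_k on every complete-case fit. Inference is by
family-clustered bootstrap (percentile CIs and two-sided p-values). For a
saturated linear path model these per-equation OLS estimates coincide with
the covariance-structure (SEM) point estimates.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .decomposition import (
    _design_matrix,
    _family_groups,
    _z,
    bootstrap_family_indices,
)

logger = logging.getLogger("statusgen")


def significance_stars(p: float) -> str:
    """Star coding: '' for p > 0.05, '*' for 0.01 <= p < 0.05,
    '**' for 0.001 <= p < 0.01, '***' for p < 0.001."""
    if not np.isfinite(p) or p > 0.05:
        return ""
    if p >= 0.01:
        return "*"
    if p >= 0.001:
        return "**"
    return "***"


@dataclass
class PathEstimate:
    estimate: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    p_value: float = np.nan

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


@dataclass
class MediationResult:
    """All paths of one multi-mediator fit on one (wave's) sample."""

    a: dict  # mediator -> PathEstimate (PGS -> mediator)
    b: dict  # mediator -> PathEstimate (mediator -> outcome | others)
    c_prime: PathEstimate
    total: PathEstimate
    indirect: dict  # mediator -> PathEstimate (a_k * b_k)
    proportion_mediated: dict  # mediator -> float
    proportion_mediated_total: float
    n: int
    wave: object = None
    unstable: bool = False
    suppression: bool = False
    notes: list = field(default_factory=list)

    def identity_residual(self) -> float:
        """total - (c' + sum indirect); exactly 0 for least-squares fits."""
        return self.total.estimate - (
            self.c_prime.estimate
            + sum(p.estimate for p in self.indirect.values())
        )


def _point_paths(y, s, M, X):
    """All path coefficients by least squares. y, s standardized; M is the
    n x K standardized mediator matrix; X the control design matrix."""
    K = M.shape[1]
    Xs = np.column_stack([X, s])
    a = np.empty(K)
    for k in range(K):
        coef, *_ = np.linalg.lstsq(Xs, M[:, k], rcond=None)
        a[k] = coef[-1]
    full = np.column_stack([X, M, s])
    coef, *_ = np.linalg.lstsq(full, y, rcond=None)
    b = coef[X.shape[1] : X.shape[1] + K]
    c_prime = coef[-1]
    coef, *_ = np.linalg.lstsq(Xs, y, rcond=None)
    total = coef[-1]
    return a, b, c_prime, total


def _boot_pvalue(draws: np.ndarray) -> float:
    """Two-sided percentile-bootstrap p-value for H0: parameter = 0."""
    draws = draws[np.isfinite(draws)]
    if draws.size == 0:
        return np.nan
    frac_le = (np.count_nonzero(draws <= 0) + 0.5) / (draws.size + 1)
    frac_ge = (np.count_nonzero(draws >= 0) + 0.5) / (draws.size + 1)
    return float(min(1.0, 2.0 * min(frac_le, frac_ge)))


def fit_mediation(
    data: pd.DataFrame,
    outcome: str = "phenotype",
    pgs: str = "observed_pgs",
    mediators=(),
    controls=(),
    family: str | None = "family_id",
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    wave=None,
) -> MediationResult:
    """Fit the multi-mediator model with cluster-bootstrap inference.

    All variables are standardized internally on the complete-case sample.
    ``family=None`` bootstraps individual rows instead of family clusters.
    Negative (suppression) indirect effects are reported as-is with a note.
    """
    if rng is None:
        rng = np.random.default_rng()
    mediators = list(mediators)
    controls = tuple(controls)
    cols = [outcome, pgs, *mediators, *controls]
    if family is not None:
        cols.append(family)
    df = data.dropna(subset=cols)
    n_dropped = len(data) - len(df)
    if n_dropped:
        logger.info("mediation: dropped %d incomplete rows", n_dropped)
    if len(df) < len(mediators) + len(controls) + 3:
        raise DegenerateInputError("too few complete cases for the path model")

    y = _z(df[outcome].to_numpy(dtype=float))
    s = _z(df[pgs].to_numpy(dtype=float))
    M = np.column_stack([_z(df[m].to_numpy(dtype=float)) for m in mediators])
    X = _design_matrix(df, controls)
    a, b, c_prime, total = _point_paths(y, s, M, X)

    if family is not None:
        fam = df[family].to_numpy()
    else:
        fam = np.arange(len(df))
    order, starts, counts = _family_groups(fam)
    K = len(mediators)
    draws = np.empty((n_boot, 2 * K + 2 + K))  # a_k, b_k, c', total, indirect_k
    ym, sm_, Mm = y, s, M
    for i in range(n_boot):
        rows, _ = bootstrap_family_indices(order, starts, counts, rng)
        try:
            ab, bb, cb, tb = _point_paths(
                ym[rows], sm_[rows], Mm[rows], X[rows]
            )
            draws[i] = np.concatenate([ab, bb, [cb, tb], ab * bb])
        except np.linalg.LinAlgError:
            draws[i] = np.nan

    def _path(idx, est):
        d = draws[:, idx]
        d = d[np.isfinite(d)]
        lo, hi = (np.percentile(d, [2.5, 97.5]) if d.size else (np.nan, np.nan))
        return PathEstimate(float(est), float(lo), float(hi), _boot_pvalue(d))

    a_d = {m: _path(k, a[k]) for k, m in enumerate(mediators)}
    b_d = {m: _path(K + k, b[k]) for k, m in enumerate(mediators)}
    c_d = _path(2 * K, c_prime)
    t_d = _path(2 * K + 1, total)
    ind = {m: _path(2 * K + 2 + k, a[k] * b[k]) for k, m in enumerate(mediators)}

    total_se = np.nanstd(draws[:, 2 * K + 1])
    unstable = bool(abs(total) < 2.0 * total_se) if np.isfinite(total_se) else False
    notes = []
    if unstable:
        notes.append("total effect within 2 SE of zero; proportions unstable")
        _warnings.warn(notes[-1], stacklevel=2)
    prop = {m: float(a[k] * b[k] / total) for k, m in enumerate(mediators)}
    suppression = any(
        np.sign(a[k] * b[k]) != np.sign(total) and a[k] * b[k] != 0
        for k in range(K)
    )
    if suppression:
        notes.append(
            "indirect effect(s) with sign opposite to the total effect "
            "(suppression); signed proportions reported"
        )
    return MediationResult(
        a=a_d,
        b=b_d,
        c_prime=c_d,
        total=t_d,
        indirect=ind,
        proportion_mediated=prop,
        proportion_mediated_total=float(np.dot(a, b) / total),
        n=len(df),
        wave=wave,
        unstable=unstable,
        suppression=suppression,
        notes=notes,
    )


def life_course_mediation(
    persons: pd.DataFrame,
    panel: pd.DataFrame,
    mediators,
    pgs: str = "observed_pgs",
    controls=(),
    wave_col: str = "wave",
    status_col: str = "status",
    min_n: int = 100,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    **kw,
) -> list:
    """One mediation fit per career wave on that wave's complete cases."""
    if rng is None:
        rng = np.random.default_rng()
    results = []
    for w in sorted(panel[wave_col].unique()):
        wave_rows = panel.loc[panel[wave_col] == w, ["person_id", status_col]]
        merged = persons.merge(wave_rows, on="person_id", how="inner")
        n_complete = merged.dropna(
            subset=[status_col, pgs, *mediators, *controls]
        ).shape[0]
        if n_complete < min_n:
            logger.warning(
                "wave %s skipped: only %d complete cases (< %d)", w, n_complete, min_n
            )
            continue
        res = fit_mediation(
            merged,
            outcome=status_col,
            pgs=pgs,
            mediators=mediators,
            controls=controls,
            n_boot=n_boot,
            rng=rng,
            wave=w,
            **kw,
        )
        logger.info("wave %s: n = %d", w, res.n)
        results.append(res)
    return results


@dataclass
class ParentalControlComparison:
    without_control: MediationResult
    with_control: MediationResult
    proportion_changes: dict  # mediator -> with - without


def mediation_with_parental_control(
    data: pd.DataFrame,
    parental_status: str = "parental_status",
    controls=(),
    **kw,
) -> ParentalControlComparison:
    """Fit the mediation model with and without parental status among the
    controls, to gauge how much passive gene-environment correlation moves
    the per-mediator proportions."""
    base = fit_mediation(data, controls=controls, **kw)
    ctl = fit_mediation(
        data, controls=tuple(controls) + (parental_status,), **kw
    )
    changes = {
        m: ctl.proportion_mediated[m] - base.proportion_mediated[m]
        for m in base.proportion_mediated
    }
    return ParentalControlComparison(
        without_control=base, with_control=ctl, proportion_changes=changes
    )


def results_table(results) -> pd.DataFrame:
    """Long-format table (wave, path, estimate, ci_low, ci_high, p, stars)."""
    rows = []
    for res in results:
        def add(path, est: PathEstimate):
            rows.append(
                {
                    "wave": res.wave,
                    "path": path,
                    "estimate": est.estimate,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "p": est.p_value,
                    "stars": est.stars,
                    "n": res.n,
                }
            )

        for m, est in res.a.items():
            add(f"a[{m}]", est)
        for m, est in res.b.items():
            add(f"b[{m}]", est)
        for m, est in res.indirect.items():
            add(f"indirect[{m}]", est)
        add("c_prime", res.c_prime)
        add("total", res.total)
        rows.append(
            {
                "wave": res.wave,
                "path": "proportion_mediated_total",
                "estimate": res.proportion_mediated_total,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "p": np.nan,
                "stars": "",
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)
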