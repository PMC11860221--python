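"""Population vs family-based PGS effects and their decomposition.

Population GWAS-based PGS effects on occupational status mix direct genetic
effects with genetic nurture (indirect parental effects) and
assortative-mating inflation. This module estimates the standardized PGS
effect under four designs — population, within-sibship (family fixed
effects), adoption (adoptees only, severing the nurture path) and parental
control (adjusting for parental status) — and forms the attenuation ratio
beta_reduced / beta_PGS with a family-cluster bootstrap CI. It also
computes the attenuation expected from assortative mating alone (exact
equilibrium moment recursion plus a forward-simulation oracle), the spousal
PGS correlation against its phenotypic-assortment benchmark, and the
additive decomposition of the population effect into direct, indirect and
assortative-mating shares.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateInputError, InvalidParameterError
from .simulate import mate_assortatively

logger = logging.getLogger("statusgen")

DESIGNS = ("population", "within_sibship", "adoption", "parental_control")


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class RegressionResult:
    """A standardized PGS effect under one design."""

    beta_pgs: float
    se: float
    incremental_r2: float
    n: int
    design: str
    covariates: tuple = ()
    n_dropped: int = 0
    warnings: list = field(default_factory=list)
    # recipe used by the cluster bootstrap to recompute beta on resampled data
    refit: object = field(default=None, repr=False, compare=False)


@dataclass
class AttenuationEstimate:
    """beta_reduced / beta_PGS with a family-bootstrap percentile CI."""

    ratio: float
    ci_low: float
    ci_high: float
    n_boot: int
    design: str = ""
    warning: str | None = None

    @property
    def attenuation_pct(self) -> float:
        return 100.0 * (1.0 - self.ratio)


@dataclass(frozen=True)
class EffectDecomposition:
    """Additive split of the population PGS effect (percent)."""

    indirect_pct: float
    am_pct: float
    direct_pct: float

    def __post_init__(self):
        total = self.indirect_pct + self.am_pct + self.direct_pct
        if abs(total - 100.0) > 1e-9:
            raise InvalidParameterError(f"components sum to {total}, not 100")


@dataclass
class PopulationDecomposition:
    """Per-design direct shares plus the residual-gap bookkeeping."""

    indirect_attenuations: tuple
    direct_shares: tuple
    direct_range: tuple  # (min, max)
    am_range: tuple | None = None
    within_family_attenuation: float | None = None
    residual_gap_range: tuple | None = None
    decompositions: tuple = ()


# ---------------------------------------------------------------------------
# numpy fitting primitives (shared by the user-facing fits and the bootstrap)
# ---------------------------------------------------------------------------


def _z(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("zero-variance variable")
    return (x - x.mean()) / sd


def _resid(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _design_matrix(df: pd.DataFrame, covariates) -> np.ndarray:
    cols = [np.ones(len(df))]
    for c in covariates:
        v = df[c]
        if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(v, drop_first=True, dtype=float)
            cols.extend(dummies[c2].to_numpy() for c2 in dummies)
        else:
            cols.append(v.to_numpy(dtype=float))
    return np.column_stack(cols)


def _get(d, col) -> np.ndarray:
    """Column as a numpy array from a DataFrame or a plain mapping of
    arrays (the bootstrap fast path)."""
    v = d[col]
    return v.to_numpy() if hasattr(v, "to_numpy") else np.asarray(v)


def _numeric_complete(d, cols):
    """Float arrays for ``cols`` restricted to jointly complete rows."""
    arrays = [_get(d, c).astype(float) for c in cols]
    mask = np.ones(arrays[0].shape[0], dtype=bool)
    for a in arrays:
        mask &= ~np.isnan(a)
    return [a[mask] for a in arrays], mask


def _pop_beta(d, outcome: str, pgs: str, covariates) -> float:
    (y, s, *covs), _ = _numeric_complete(d, [outcome, pgs, *covariates])
    y, s = _z(y), _z(s)
    if covs:
        X = np.column_stack([np.ones_like(y), *covs])
        y, s = _resid(y, X), _resid(s, X)
    return float((s @ y) / (s @ s))


def _sib_beta(d, outcome: str, pgs: str, family: str) -> float:
    (y, s), mask = _numeric_complete(d, [outcome, pgs])
    fam = _get(d, family)[mask]
    _, inv, counts = np.unique(fam, return_inverse=True, return_counts=True)
    keep = counts[inv] >= 2
    y, s, inv = y[keep], s[keep], inv[keep]
    if y.size == 0:
        raise DegenerateInputError("no family with >= 2 complete siblings")
    y, s = _z(y), _z(s)
    counts = np.bincount(inv)
    y_dm = y - (np.bincount(inv, weights=y)[inv] / counts[inv])
    s_dm = s - (np.bincount(inv, weights=s)[inv] / counts[inv])
    denom = s_dm @ s_dm
    if denom == 0:
        raise DegenerateInputError("no within-family PGS variance")
    return float((s_dm @ y_dm) / denom)


def _ado_beta(d, outcome: str, pgs: str, covariates, flag: str) -> float:
    adopt = _get(d, flag).astype(bool)
    sub = {c: _get(d, c)[adopt] for c in (outcome, pgs, *covariates)}
    if not adopt.any():
        raise DegenerateInputError("no adoptees in the data")
    return _pop_beta(sub, outcome, pgs, covariates)


def _parental_beta(d, outcome: str, pgs: str, parental: str, covariates) -> float:
    (y, s, p, *covs), _ = _numeric_complete(
        d, [outcome, pgs, parental, *covariates]
    )
    y, s = _z(y), _z(s)
    X = np.column_stack([np.ones_like(y), *covs, _z(p)])
    y, s = _resid(y, X), _resid(s, X)
    return float((s @ y) / (s @ s))


def _complete(data: pd.DataFrame, cols, design: str):
    sub = data.dropna(subset=list(cols))
    dropped = len(data) - len(sub)
    if dropped:
        logger.info("%s fit: dropped %d incomplete rows", design, dropped)
    return sub, dropped


# ---------------------------------------------------------------------------
# design fits
# ---------------------------------------------------------------------------


def fit_population(
    data: pd.DataFrame,
    outcome: str = "phenotype",
    pgs: str = "observed_pgs",
    covariates=(),
) -> RegressionResult:
    """Population OLS of the standardized outcome on the standardized PGS,
    residualizing both on the covariates first; incremental R-squared is the
    gain of the full model over the covariate-only baseline."""
    covariates = tuple(covariates)
    df, dropped = _complete(data, (outcome, pgs) + covariates, "population")
    y = _z(df[outcome].to_numpy(dtype=float))
    s = _z(df[pgs].to_numpy(dtype=float))
    X = _design_matrix(df, covariates)
    y_r, s_r = _resid(y, X), _resid(s, X)
    r2_base = 1.0 - (y_r**2).sum() / (y**2).sum()
    fit = sm.OLS(y_r, sm.add_constant(s_r)).fit()
    beta = float(fit.params[1])
    inc_r2 = (1.0 - r2_base) * float(np.corrcoef(y_r, s_r)[0, 1] ** 2)
    return RegressionResult(
        beta_pgs=beta,
        se=float(fit.bse[1]),
        incremental_r2=inc_r2,
        n=len(df),
        design="population",
        covariates=covariates,
        n_dropped=dropped,
        refit=lambda d, o=outcome, p=pgs, c=covariates: _pop_beta(d, o, p, c),
    )


def fit_within_sibship(
    data: pd.DataFrame,
    outcome: str = "phenotype",
    pgs: str = "observed_pgs",
    family: str = "family_id",
) -> RegressionResult:
    """Family fixed-effects fit: outcome and PGS standardized on the full
    sibling sample first, then family-demeaned OLS with family-clustered
    standard errors. Singleton families are dropped."""
    df, dropped = _complete(data, (outcome, pgs, family), "within_sibship")
    sizes = df.groupby(family)[outcome].transform("size")
    n_singleton = int((sizes < 2).sum())
    if n_singleton:
        logger.info("within_sibship: dropped %d singleton-family rows", n_singleton)
    df = df[sizes >= 2]
    if df.empty:
        raise DegenerateInputError("no family with >= 2 complete siblings")
    y = _z(df[outcome].to_numpy(dtype=float))
    s = _z(df[pgs].to_numpy(dtype=float))
    fam = df[family].to_numpy()
    y_dm = y - pd.Series(y).groupby(fam).transform("mean").to_numpy()
    s_dm = s - pd.Series(s).groupby(fam).transform("mean").to_numpy()
    fit = sm.OLS(y_dm, s_dm[:, None]).fit(cov_type="cluster", cov_kwds={"groups": fam})
    beta = float(fit.params[0])
    r2 = float(np.corrcoef(y_dm, s_dm)[0, 1] ** 2) if s_dm.std() > 0 else 0.0
    return RegressionResult(
        beta_pgs=beta,
        se=float(fit.bse[0]),
        incremental_r2=r2,
        n=len(df),
        design="within_sibship",
        n_dropped=dropped + n_singleton,
        refit=lambda d, o=outcome, p=pgs, f=family: _sib_beta(d, o, p, f),
    )


def fit_adoption(
    data: pd.DataFrame,
    outcome: str = "phenotype",
    pgs: str = "observed_pgs",
    covariates=(),
    adoptee_flag: str = "is_adoptee",
) -> RegressionResult:
    """Population-style fit restricted to adoptees, whose rearing environment
    is decoupled from their own genotype."""
    adoptees = data[data[adoptee_flag].astype(bool)]
    if adoptees.empty:
        raise DegenerateInputError("no adoptees in the data")
    res = fit_population(adoptees, outcome, pgs, covariates)
    res.design = "adoption"
    if res.n < 30:
        msg = f"only {res.n} adoptees; estimate will be unstable"
        res.warnings.append(msg)
        _warnings.warn(msg, stacklevel=2)
    res.refit = lambda d, o=outcome, p=pgs, c=covariates, fl=adoptee_flag: (
        _ado_beta(d, o, p, c, fl)
    )
    return res


def fit_parental_control(
    data: pd.DataFrame,
    outcome: str = "phenotype",
    pgs: str = "observed_pgs",
    parental_status: str = "parental_status",
    covariates=(),
) -> RegressionResult:
    """Population fit with parental occupational status as an additional
    control, absorbing the passive gene-environment (nurture) path."""
    covariates = tuple(covariates)
    cols = (outcome, pgs, parental_status) + covariates
    df, dropped = _complete(data, cols, "parental_control")
    s = df[pgs].to_numpy(dtype=float)
    p = df[parental_status].to_numpy(dtype=float)
    if s.std() > 0 and p.std() > 0 and abs(np.corrcoef(s, p)[0, 1]) > 0.999:
        raise DegenerateInputError("parental status is collinear with the PGS")
    y = _z(df[outcome].to_numpy(dtype=float))
    s = _z(s)
    X = np.column_stack([_design_matrix(df, covariates), _z(p)])
    y_r, s_r = _resid(y, X), _resid(s, X)
    fit = sm.OLS(y_r, sm.add_constant(s_r)).fit()
    return RegressionResult(
        beta_pgs=float(fit.params[1]),
        se=float(fit.bse[1]),
        incremental_r2=float(np.corrcoef(y_r, s_r)[0, 1] ** 2)
        * (1.0 - (1.0 - (y_r**2).sum() / (y**2).sum())),
        n=len(df),
        design="parental_control",
        covariates=covariates,
        n_dropped=dropped,
        refit=lambda d, o=outcome, g=pgs, ps=parental_status, c=covariates: (
            _parental_beta(d, o, g, ps, c)
        ),
    )


# ---------------------------------------------------------------------------
# attenuation ratios with family bootstrap
# ---------------------------------------------------------------------------


def _family_groups(fam: np.ndarray):
    order = np.argsort(fam, kind="stable")
    sorted_fam = fam[order]
    uniq, starts = np.unique(sorted_fam, return_index=True)
    counts = np.diff(np.append(starts, sorted_fam.size))
    return order, starts, counts


def bootstrap_family_indices(order, starts, counts, rng):
    """One bootstrap replicate: resample whole families with replacement,
    returning row indices and fresh family labels (a family drawn twice
    counts as two clusters)."""
    n_fam = starts.size
    pick = rng.integers(0, n_fam, n_fam)
    c = counts[pick]
    total = int(c.sum())
    offsets = np.repeat(np.cumsum(c) - c, c)
    rows = order[np.arange(total) - offsets + np.repeat(starts[pick], c)]
    new_fam = np.repeat(np.arange(n_fam), c)
    return rows, new_fam


def attenuation_ratio(
    reduced: RegressionResult,
    population: RegressionResult,
    data: pd.DataFrame,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    family: str = "family_id",
) -> AttenuationEstimate:
    """Ratio beta_reduced / beta_PGS with a 95% percentile CI from a
    bootstrap that resamples families (clusters), refitting both designs in
    every replicate so sibling pairs stay intact. The replicate refits run
    on plain numpy-array views; categorical covariates are not supported in
    the bootstrap path."""
    if rng is None:
        rng = np.random.default_rng()
    if reduced.refit is None or population.refit is None:
        raise InvalidParameterError("results lack refit recipes for the bootstrap")
    ratio = reduced.beta_pgs / population.beta_pgs
    warning = None
    if abs(population.beta_pgs) < 2.0 * population.se:
        warning = "population beta within 2 SE of zero; ratio is unstable"
        _warnings.warn(warning, stacklevel=2)
    fam = data[family].to_numpy()
    order, starts, counts = _family_groups(fam)
    arrays = {
        c: data[c].to_numpy()
        for c in data.columns
        if c != family and data[c].dtype.kind in "fib"
    }
    ratios = np.empty(n_boot)
    for b in range(n_boot):
        rows, new_fam = bootstrap_family_indices(order, starts, counts, rng)
        d_b = {c: a[rows] for c, a in arrays.items()}
        d_b[family] = new_fam
        try:
            ratios[b] = reduced.refit(d_b) / population.refit(d_b)
        except (DegenerateInputError, np.linalg.LinAlgError):
            ratios[b] = np.nan
    good = ratios[np.isfinite(ratios)]
    lo, hi = np.percentile(good, [2.5, 97.5]) if good.size else (np.nan, np.nan)
    return AttenuationEstimate(
        ratio=float(ratio),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        design=reduced.design,
        warning=warning,
    )


# ---------------------------------------------------------------------------
# expected attenuation from assortative mating alone
# ---------------------------------------------------------------------------


def expected_am_attenuation(
    h2_pgs_share: float,
    r_mate: float,
    h2_total: float = 0.6,
    max_iter: int = 500,
    tol: float = 1e-13,
) -> float:
    """Within-family / population slope ratio expected under equilibrium
    phenotypic assortment with no indirect effects.

    The additive score splits into the part S captured by the PGS
    (Var share ``h2_pgs_share``) and the uncaptured residual U. Matching on
    the phenotype induces, at equilibrium, a positive correlation between S
    and U. The population slope of Y on S then picks up Cov(S, U) while the
    within-sibship slope does not (sibling score differences are pure
    segregation noise, independent across the two parts), so

        ratio = V_S / (V_S + Cov(S, U))

    with the equilibrium moments obtained by iterating the exact
    Gaussian-copula covariance recursions to their fixed point. r_mate = 0
    returns exactly 1.
    """
    if not 0.0 < h2_pgs_share <= 1.0:
        raise InvalidParameterError("h2_pgs_share must lie in (0, 1]")
    if not 0.0 <= r_mate < 1.0:
        raise InvalidParameterError("r_mate must lie in [0, 1)")
    if not 0.0 < h2_total <= 1.0:
        raise InvalidParameterError("h2_total must lie in (0, 1]")
    if r_mate == 0.0:
        return 1.0
    k, va0 = h2_pgs_share, 1.0
    ve = va0 * (1.0 - h2_total) / h2_total
    vs, vu, c = k * va0, (1.0 - k) * va0, 0.0
    for _ in range(max_iter):
        vy = vs + vu + 2.0 * c + ve
        cs = r_mate * (vs + c) ** 2 / vy
        cu = r_mate * (vu + c) ** 2 / vy
        csu = r_mate * (vs + c) * (vu + c) / vy
        vs_n = 0.5 * (vs + cs) + 0.5 * k * va0
        vu_n = 0.5 * (vu + cu) + 0.5 * (1.0 - k) * va0
        c_n = 0.5 * (c + csu)
        if max(abs(vs_n - vs), abs(vu_n - vu), abs(c_n - c)) < tol:
            vs, vu, c = vs_n, vu_n, c_n
            break
        vs, vu, c = vs_n, vu_n, c_n
    return float(vs / (vs + c))


def simulate_am_attenuation(
    h2_pgs_share: float,
    r_mate: float,
    h2_total: float = 0.6,
    n_pairs: int = 100_000,
    n_generations: int = 16,
    seed: int = 0,
) -> float:
    """Forward-simulation oracle for :func:`expected_am_attenuation`.

    Simulates the captured / uncaptured score parts explicitly through
    ``n_generations`` rounds of copula matching, then estimates the
    within-sibship and population standardized slopes of the phenotype on
    the captured part S from a final generation of sibling pairs.
    """
    if not 0.0 < h2_pgs_share <= 1.0:
        raise InvalidParameterError("h2_pgs_share must lie in (0, 1]")
    rng = np.random.default_rng([seed % (2**31), 97])
    k, va0 = h2_pgs_share, 1.0
    ve = va0 * (1.0 - h2_total) / h2_total
    sd_s, sd_u, sd_e = np.sqrt(k * va0), np.sqrt((1 - k) * va0), np.sqrt(ve)
    seg_s, seg_u = np.sqrt(0.5 * k * va0), np.sqrt(0.5 * (1 - k) * va0)

    Sf, Uf = rng.normal(0, sd_s, n_pairs), rng.normal(0, sd_u, n_pairs)
    Sm, Um = rng.normal(0, sd_s, n_pairs), rng.normal(0, sd_u, n_pairs)
    for g in range(n_generations - 1):
        Yf = Sf + Uf + rng.normal(0, sd_e, n_pairs)
        Ym = Sm + Um + rng.normal(0, sd_e, n_pairs)
        perm = mate_assortatively(Yf, Ym, r_mate, rng)
        Sm, Um = Sm[perm], Um[perm]
        mid_s, mid_u = 0.5 * (Sf + Sm), 0.5 * (Uf + Um)
        if g < n_generations - 2:
            Sf = mid_s + rng.normal(0, seg_s, n_pairs)
            Uf = mid_u + rng.normal(0, seg_u, n_pairs)
            Sm = mid_s + rng.normal(0, seg_s, n_pairs)
            Um = mid_u + rng.normal(0, seg_u, n_pairs)
        else:
            s1 = mid_s + rng.normal(0, seg_s, n_pairs)
            s2 = mid_s + rng.normal(0, seg_s, n_pairs)
            u1 = mid_u + rng.normal(0, seg_u, n_pairs)
            u2 = mid_u + rng.normal(0, seg_u, n_pairs)
            y1 = s1 + u1 + rng.normal(0, sd_e, n_pairs)
            y2 = s2 + u2 + rng.normal(0, sd_e, n_pairs)
    s_all = np.concatenate([s1, s2])
    y_all = np.concatenate([y1, y2])
    sd_S, sd_Y = s_all.std(), y_all.std()
    beta_pop = float(np.cov(s_all, y_all)[0, 1] / s_all.var()) * sd_S / sd_Y
    ds, dy = s1 - s2, y1 - y2
    beta_within = float((ds * dy).sum() / (ds**2).sum()) * sd_S / sd_Y
    return beta_within / beta_pop


# ---------------------------------------------------------------------------
# spousal PGS correlation
# ---------------------------------------------------------------------------


@dataclass
class SpousalCorrelation:
    observed: float
    observed_ci: tuple
    expected: float
    expected_ci: tuple
    r_phenotype: float
    n_couples: int


def spousal_pgs_correlation(
    data: pd.DataFrame,
    pgs: str = "observed_pgs",
    phenotype: str = "phenotype",
    n_boot: int = 500,
    rng: np.random.Generator | None = None,
) -> SpousalCorrelation:
    """Observed spousal PGS correlation vs the value expected under
    single-round phenotypic assortment, r_pheno * rho_f * rho_m, where rho
    is the PGS-phenotype correlation per sex. Multi-generation equilibrium
    assortment drives the observed value above the expectation because the
    genetic spousal correlation accumulates across generations."""
    if rng is None:
        rng = np.random.default_rng()
    df = data.dropna(subset=[pgs, phenotype, "spouse_id"])
    females = df[df["sex"] == "F"].set_index("person_id")
    males = df[df["sex"] == "M"].set_index("person_id")
    females = females[females["spouse_id"].isin(males.index)]
    partners = males.loc[females["spouse_id"].to_numpy()]
    n = len(females)
    if n < 30:
        raise DegenerateInputError(f"only {n} complete couples (need >= 30)")
    gf, gm = females[pgs].to_numpy(), partners[pgs].to_numpy()
    yf, ym = females[phenotype].to_numpy(), partners[phenotype].to_numpy()

    def _stats(idx):
        r_obs = np.corrcoef(gf[idx], gm[idx])[0, 1]
        r_ph = np.corrcoef(yf[idx], ym[idx])[0, 1]
        rho_f = np.corrcoef(gf[idx], yf[idx])[0, 1]
        rho_m = np.corrcoef(gm[idx], ym[idx])[0, 1]
        return r_obs, r_ph * rho_f * rho_m, r_ph

    obs, exp, r_ph = _stats(np.arange(n))
    boot = np.array([_stats(rng.integers(0, n, n))[:2] for _ in range(n_boot)])
    lo_o, hi_o = np.percentile(boot[:, 0], [2.5, 97.5])
    lo_e, hi_e = np.percentile(boot[:, 1], [2.5, 97.5])
    return SpousalCorrelation(
        observed=float(obs),
        observed_ci=(float(lo_o), float(hi_o)),
        expected=float(exp),
        expected_ci=(float(lo_e), float(hi_e)),
        r_phenotype=float(r_ph),
        n_couples=n,
    )


# ---------------------------------------------------------------------------
# additive decomposition of the population effect
# ---------------------------------------------------------------------------


def decompose_population_effect(
    indirect_attenuations,
    am_attenuation_range=None,
    within_family_attenuation: float | None = None,
) -> PopulationDecomposition:
    """Direct-effect shares implied by indirect-effect attenuations.

    Under the additivity assumption each design's direct share is
    100 - indirect attenuation. When an assortative-mating attenuation range
    and the observed within-family attenuation are supplied, the residual
    gap between (indirect + AM) and the observed within-family reduction is
    reported rather than silently absorbed.
    """
    ind = tuple(float(x) for x in indirect_attenuations)
    for x in ind:
        if not 0.0 <= x <= 100.0:
            raise InvalidParameterError(f"attenuation {x} outside [0, 100]")
    direct = tuple(100.0 - x for x in ind)
    am_range = None
    decomps: list[EffectDecomposition] = []
    gap_range = None
    if am_attenuation_range is not None:
        am_lo, am_hi = (float(x) for x in am_attenuation_range)
        if not 0.0 <= am_lo <= am_hi <= 100.0:
            raise InvalidParameterError("invalid AM attenuation range")
        am_range = (am_lo, am_hi)
        for x in ind:
            for am in am_range:
                if x + am > 100.0:
                    raise InvalidParameterError(
                        f"indirect {x} + AM {am} exceeds 100"
                    )
                decomps.append(
                    EffectDecomposition(
                        indirect_pct=x, am_pct=am, direct_pct=100.0 - x - am
                    )
                )
        if within_family_attenuation is not None:
            gaps = [
                within_family_attenuation - (x + am)
                for x in ind
                for am in am_range
            ]
            gap_range = (min(gaps), max(gaps))
    return PopulationDecomposition(
        indirect_attenuations=ind,
        direct_shares=direct,
        direct_range=(min(direct), max(direct)),
        am_range=am_range,
        within_family_attenuation=within_family_attenuation,
        residual_gap_range=gap_range,
        decompositions=tuple(decomps),
    )
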