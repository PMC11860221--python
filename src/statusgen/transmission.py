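"""Genetic confounding of status transmission and status-health links;
career-trajectory profiles.

The parent-offspring occupational status correlation partly reflects common
genetic inheritance. A mediation model routes the parent -> offspring path
through the offspring's PGS; because the observed PGS captures only part of
the common-variant signal (R^2_PGS < h^2_SNP), the mediated share is then
rescaled by the reliability ratio h^2_SNP / R^2_PGS — the linear
measurement-error correction under which the observed score is the latent
common-variant score attenuated by independent noise, so both mediation
paths scale by sqrt(h^2/R^2) and their product by h^2/R^2.

The same logic quantifies genetic confounding of the status-health
association: the PGS-health regression is re-fit with parental status as a
control, and the percentage drop in the PGS coefficient is reported per
health outcome and wave.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidParameterError
from .decomposition import (
    _design_matrix,
    _family_groups,
    _resid,
    _z,
    bootstrap_family_indices,
)

logger = logging.getLogger("statusgen")


# ---------------------------------------------------------------------------
# intergenerational correlation and its genetic share
# ---------------------------------------------------------------------------


@dataclass
class CorrelationEstimate:
    r: float
    ci_low: float
    ci_high: float
    n: int


def intergenerational_correlation(
    data: pd.DataFrame,
    parent_col: str = "paternal_status",
    offspring_col: str = "phenotype",
    family: str | None = "family_id",
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> CorrelationEstimate:
    """Pearson correlation of parental and offspring status with a
    family-cluster bootstrap CI."""
    if rng is None:
        rng = np.random.default_rng()
    df = data.dropna(subset=[parent_col, offspring_col])
    if len(df) < 3:
        raise DegenerateInputError("too few complete parent-offspring pairs")
    p = df[parent_col].to_numpy(dtype=float)
    o = df[offspring_col].to_numpy(dtype=float)
    fam = df[family].to_numpy() if family else np.arange(len(df))
    order, starts, counts = _family_groups(fam)
    r = float(np.corrcoef(p, o)[0, 1])
    boot = np.empty(n_boot)
    for i in range(n_boot):
        rows, _ = bootstrap_family_indices(order, starts, counts, rng)
        boot[i] = np.corrcoef(p[rows], o[rows])[0, 1]
    lo, hi = np.percentile(boot[np.isfinite(boot)], [2.5, 97.5])
    return CorrelationEstimate(r=r, ci_low=float(lo), ci_high=float(hi), n=len(df))


@dataclass
class ConfoundingShare:
    share_pct: float
    ci_low: float
    ci_high: float
    r_intergen: float
    path_a: float  # parent status -> offspring PGS
    path_b: float  # offspring PGS -> offspring status | parent status
    n: int
    unstable: bool = False


def _share(p, o, s):
    """Mediated share of corr(parent, offspring) through the PGS, all
    variables standardized: a = slope of PGS on parent; b = partial slope of
    offspring on PGS given parent; share = a*b / r."""
    r = np.corrcoef(p, o)[0, 1]
    a = (p * s).sum() / (p**2).sum()
    X = np.column_stack([np.ones_like(p), p])
    s_r = _resid(s, X)
    o_r = _resid(o, X)
    b = (s_r * o_r).sum() / (s_r**2).sum()
    return r, a, b, 100.0 * a * b / r


def genetic_confounding_share(
    data: pd.DataFrame,
    parent_col: str = "paternal_status",
    offspring_col: str = "phenotype",
    pgs: str = "observed_pgs",
    family: str | None = "family_id",
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> ConfoundingShare:
    """Share (percent) of the intergenerational status correlation mediated
    by the offspring PGS, with a cluster-bootstrap CI."""
    if rng is None:
        rng = np.random.default_rng()
    df = data.dropna(subset=[parent_col, offspring_col, pgs])
    p = _z(df[parent_col].to_numpy(dtype=float))
    o = _z(df[offspring_col].to_numpy(dtype=float))
    s = _z(df[pgs].to_numpy(dtype=float))
    r, a, b, share = _share(p, o, s)
    fam = df[family].to_numpy() if family else np.arange(len(df))
    order, starts, counts = _family_groups(fam)
    boot = np.empty(n_boot)
    boot_r = np.empty(n_boot)
    for i in range(n_boot):
        rows, _ = bootstrap_family_indices(order, starts, counts, rng)
        boot_r[i], _, _, boot[i] = _share(p[rows], o[rows], s[rows])
    good = boot[np.isfinite(boot)]
    lo, hi = np.percentile(good, [2.5, 97.5])
    unstable = abs(r) < 2.0 * np.nanstd(boot_r)
    if unstable:
        _warnings.warn(
            "intergenerational correlation within 2 SE of zero; "
            "mediated share is undefined",
            stacklevel=2,
        )
    return ConfoundingShare(
        share_pct=float(share),
        ci_low=float(lo),
        ci_high=float(hi),
        r_intergen=float(r),
        path_a=float(a),
        path_b=float(b),
        n=len(df),
        unstable=bool(unstable),
    )


# ---------------------------------------------------------------------------
# SNP-heritability rescaling
# ---------------------------------------------------------------------------


@dataclass
class ConfoundingDecomposition:
    """Intergenerational correlation split into a (rescaled) common-variant
    genetic share and its complement."""

    pgs_share_pct: float
    k_rescale: float
    rescaled_share_pct: float
    other_share_pct: float
    h2_snp: float
    r2_pgs: float
    capped: bool = False
    r_intergen: float | None = None
    wave: object = None

    def __post_init__(self):
        assert abs(self.rescaled_share_pct + self.other_share_pct - 100.0) < 1e-9


def rescale_to_snp_h2(
    pgs_share_pct: float,
    r2_pgs: float,
    h2_snp: float,
    r_intergen: float | None = None,
    wave=None,
) -> ConfoundingDecomposition:
    """Rescale a PGS-mediated share to the full common-variant signal.

    The observed PGS is modelled as the latent common-variant score
    attenuated by independent measurement noise with reliability
    r2_pgs / h2_snp; both mediation paths then shrink by the square root of
    that reliability, so the mediated share recovers the latent-score value
    when multiplied by k = h2_snp / r2_pgs. Shares above 100 are capped and
    flagged.
    """
    if not 0.0 < r2_pgs <= h2_snp <= 1.0:
        raise InvalidParameterError("need 0 < r2_pgs <= h2_snp <= 1")
    k = h2_snp / r2_pgs
    raw = pgs_share_pct * k
    capped = raw > 100.0
    rescaled = min(raw, 100.0)
    if capped:
        logger.warning(
            "rescaled share %.1f%% exceeds 100%%; capped (k = %.2f)", raw, k
        )
    return ConfoundingDecomposition(
        pgs_share_pct=float(pgs_share_pct),
        k_rescale=float(k),
        rescaled_share_pct=float(rescaled),
        other_share_pct=float(100.0 - rescaled),
        h2_snp=float(h2_snp),
        r2_pgs=float(r2_pgs),
        capped=bool(capped),
        r_intergen=r_intergen,
        wave=wave,
    )


# ---------------------------------------------------------------------------
# status-health confounding
# ---------------------------------------------------------------------------


@dataclass
class HealthAttenuation:
    outcome: str
    wave: object
    beta_without: float
    beta_with: float
    n: int
    unstable: bool = False

    @property
    def attenuation_pct(self) -> float:
        return 100.0 * (1.0 - self.beta_with / self.beta_without)


def health_confounding(
    persons: pd.DataFrame,
    health: pd.DataFrame,
    pgs: str = "observed_pgs",
    parental_status: str = "parental_status",
    covariates=(),
    outcomes=("general_health", "mental_health"),
    wave_col: str = "wave",
) -> tuple:
    """PGS -> health regressions with and without parental status.

    Per wave and outcome the ordinal health rating is treated as metric,
    standardized, and regressed on the standardized PGS (plus covariates);
    adding parental status gives the attenuated coefficient. Cells whose
    baseline coefficient is within 2 SE of zero are flagged and excluded
    from the across-wave averages.
    """
    import statsmodels.api as sm

    covariates = tuple(covariates)
    cells: list[HealthAttenuation] = []
    for outcome in outcomes:
        for w in sorted(health[wave_col].unique()):
            hw = health.loc[health[wave_col] == w, ["person_id", outcome]]
            df = persons.merge(hw, on="person_id", how="inner").dropna(
                subset=[outcome, pgs, parental_status, *covariates]
            )
            if len(df) < 10:
                continue
            y = _z(df[outcome].to_numpy(dtype=float))
            s = _z(df[pgs].to_numpy(dtype=float))
            X = _design_matrix(df, covariates)
            y_r, s_r = _resid(y, X), _resid(s, X)
            fit0 = sm.OLS(y_r, sm.add_constant(s_r)).fit()
            beta0, se0 = float(fit0.params[1]), float(fit0.bse[1])
            Xp = np.column_stack([X, _z(df[parental_status].to_numpy(dtype=float))])
            y_p, s_p = _resid(y, Xp), _resid(s, Xp)
            beta1 = float((s_p * y_p).sum() / (s_p**2).sum())
            unstable = abs(beta0) < 2.0 * se0
            if unstable:
                logger.warning(
                    "health cell (%s, wave %s): baseline beta within 2 SE of "
                    "zero; excluded from averages", outcome, w,
                )
            cells.append(
                HealthAttenuation(
                    outcome=outcome,
                    wave=w,
                    beta_without=beta0,
                    beta_with=beta1,
                    n=len(df),
                    unstable=unstable,
                )
            )
    table = pd.DataFrame(
        {
            "outcome": [c.outcome for c in cells],
            "wave": [c.wave for c in cells],
            "beta_without": [c.beta_without for c in cells],
            "beta_with": [c.beta_with for c in cells],
            "attenuation_pct": [c.attenuation_pct for c in cells],
            "n": [c.n for c in cells],
            "unstable": [c.unstable for c in cells],
        }
    )
    averages = {}
    for outcome in outcomes:
        ok = table[(table["outcome"] == outcome) & (~table["unstable"])]
        averages[outcome] = (
            float(ok["attenuation_pct"].mean()) if len(ok) else np.nan
        )
    return table, averages


# ---------------------------------------------------------------------------
# career trajectories
# ---------------------------------------------------------------------------


def percentile_within_wave(
    panel: pd.DataFrame, wave_col: str = "wave", status_col: str = "status"
) -> pd.Series:
    """Status converted to percentile rank within each time point,
    (rank - 0.5) / n * 100, whose mean is exactly 50 for complete cells
    without ties."""
    def _pct(x: pd.Series) -> pd.Series:
        return (x.rank(method="average") - 0.5) / x.notna().sum() * 100.0

    return panel.groupby(wave_col)[status_col].transform(_pct)


def career_trajectory_profile(
    panel: pd.DataFrame,
    persons: pd.DataFrame,
    pgs: str = "observed_pgs",
    parental_education: str = "parental_education",
    sex: str = "sex",
    n_quantiles: int = 5,
    wave_col: str = "wave",
    status_col: str = "status",
) -> pd.DataFrame:
    """Mean status percentile per (wave, PGS quantile, parental education,
    sex) cell with a normal-approximation 95% CI. Parental education bands
    are Low / Medium / High; empty cells are absent, not zero."""
    df = panel.merge(
        persons[["person_id", pgs, parental_education, sex]], on="person_id"
    ).dropna(subset=[status_col, pgs])
    df["percentile"] = percentile_within_wave(df, wave_col, status_col)
    df["pgs_quantile"] = pd.qcut(
        df[pgs], n_quantiles, labels=range(1, n_quantiles + 1)
    )
    grouped = (
        df.groupby([wave_col, "pgs_quantile", parental_education, sex],
                   observed=True)["percentile"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_percentile", "count": "n"})
    )
    half = 1.96 * grouped["std"] / np.sqrt(grouped["n"].clip(lower=1))
    grouped["ci_low"] = grouped["mean_percentile"] - half
    grouped["ci_high"] = grouped["mean_percentile"] + half
    return grouped.drop(columns="std")


def plot_trajectories(profile: pd.DataFrame, path, wave_col: str = "wave") -> None:
    """Small-multiple plot of mean percentile trajectories by PGS quantile,
    one panel per (parental education, sex) stratum."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    edus = [e for e in ("Low", "Medium", "High")
            if e in set(profile["parental_education"])]
    sexes = sorted(profile["sex"].unique())
    fig, axes = plt.subplots(
        len(sexes), max(len(edus), 1), figsize=(3.2 * max(len(edus), 1), 2.8 * len(sexes)),
        sharey=True, squeeze=False,
    )
    for i, sx in enumerate(sexes):
        for j, edu in enumerate(edus):
            ax = axes[i][j]
            sub = profile[(profile["sex"] == sx)
                          & (profile["parental_education"] == edu)]
            for q, grp in sub.groupby("pgs_quantile", observed=True):
                grp = grp.sort_values(wave_col)
                ax.plot(grp[wave_col], grp["mean_percentile"], label=f"Q{q}")
                ax.fill_between(grp[wave_col], grp["ci_low"], grp["ci_high"],
                                alpha=0.2)
            ax.set_title(f"{edu} / {sx}", fontsize=9)
            ax.axhline(50, ls=":", lw=0.5, color="grey")
    axes[0][0].legend(fontsize=7, title="PGS quintile")
    for ax in axes[-1]:
        ax.set_xlabel("wave")
    for row in axes:
        row[0].set_ylabel("mean percentile")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
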