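"""Dose/time reducibility analysis on pairwise sKL scores.

For a drug with the full 3-dose x 4-time design, every unordered pair of
its 12 treatments gives one observation: the sKL score, the unordered
dose pair (a 6-level factor: Low-Low, Low-Middle, Low-High,
Middle-Middle, Middle-High, High-High) and the absolute time difference
in days.  Three model variants are fitted and compared:

    sKL = b1 * X_Dose + b2 * X_Time    (dose_and_time)
    sKL = b1 * X_Dose                  (dose_only)
    sKL = b1 * X_Time                  (time_only)

by adjusted R^2, AIC, and BIC.  When a time-free variant wins under all
three criteria the design's time axis is flagged as reducible — fewer
time points (hence fewer animals) could cover the drug's response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from toxitopic.analysis import SimilarityMatrix
from toxitopic.preprocess import DOSE_LEVELS, parse_treatment_key

logger = logging.getLogger(__name__)

VARIANTS = ("dose_and_time", "dose_only", "time_only")
TIME_FREE_VARIANTS = ("dose_only",)
DOSE_FREE_VARIANTS = ("time_only",)

_DOSE_RANK = {d: i for i, d in enumerate(DOSE_LEVELS)}
DOSE_PAIR_LEVELS = tuple(
    f"{a.capitalize()}-{b.capitalize()}"
    for i, a in enumerate(DOSE_LEVELS)
    for b in DOSE_LEVELS[i:]
)


def dose_pair_label(dose_i: str, dose_j: str) -> str:
    """Order-insensitive 6-level dose-pair label, e.g. 'Low-High'."""
    a, b = sorted((dose_i.lower(), dose_j.lower()), key=lambda d: _DOSE_RANK[d])
    return f"{a.capitalize()}-{b.capitalize()}"


@dataclass
class PairDesign:
    """Unordered feature pairs with sKL response and dose/time predictors."""

    table: pd.DataFrame  # feature_i, feature_j, skl, dose_pair, time_diff
    scope: str

    def __post_init__(self) -> None:
        required = {"feature_i", "feature_j", "skl", "dose_pair", "time_diff"}
        if not required <= set(self.table.columns):
            raise ValueError(f"pair design must have columns {sorted(required)}")
        if (self.table["feature_i"] >= self.table["feature_j"]).any():
            raise ValueError("pairs must be unordered with feature_i < feature_j")
        bad = set(self.table["dose_pair"]) - set(DOSE_PAIR_LEVELS)
        if bad:
            raise ValueError(f"unknown dose-pair levels: {sorted(bad)}")
        if (self.table["time_diff"] < 0).any():
            raise ValueError("time differences must be non-negative")

    @property
    def n_pairs(self) -> int:
        return len(self.table)


def build_pair_design(sim: SimilarityMatrix, scope: str) -> PairDesign:
    """All unordered pairs of in-scope features with their predictors.

    ``scope`` is a drug name (features are that drug's treatment keys in
    a treatment-level similarity matrix) or ``"time_dose_model"``
    (features are the 12 dose-time authors, keys like ``middle|7d``).
    """
    if scope == "time_dose_model":
        keys = [(f, *f.split("|")) for f in sim.feature_ids]
        parsed = {f: (dose, float(t.rstrip("d"))) for f, dose, t in keys}
        in_scope = list(sim.feature_ids)
    else:
        in_scope = []
        parsed = {}
        for f in sim.feature_ids:
            drug, dose, time = parse_treatment_key(f)
            if drug == scope:
                in_scope.append(f)
                parsed[f] = (dose, time)
    if len(in_scope) < 2:
        raise ValueError(f"scope {scope!r} has fewer than 2 features")

    in_scope = sorted(in_scope)
    idx = {f: sim.feature_ids.index(f) for f in in_scope}
    rows = []
    for a in range(len(in_scope)):
        for b in range(a + 1, len(in_scope)):
            fi, fj = in_scope[a], in_scope[b]
            dose_i, time_i = parsed[fi]
            dose_j, time_j = parsed[fj]
            rows.append(
                (
                    fi,
                    fj,
                    float(sim.scores[idx[fi], idx[fj]]),
                    dose_pair_label(dose_i, dose_j),
                    abs(time_i - time_j),
                )
            )
    table = pd.DataFrame(
        rows, columns=["feature_i", "feature_j", "skl", "dose_pair", "time_diff"]
    )
    return PairDesign(table=table, scope=scope)


@dataclass
class GLMFit:
    """One fitted sKL model variant with its comparison criteria."""

    variant: str
    coef: pd.Series
    llf: float
    r_squared: float
    adj_r_squared: float
    aic: float
    bic: float
    nobs: int
    n_params: int
    family: str = "gaussian"
    scope: str = ""
    dropped_levels: list[str] = field(default_factory=list)


def _design_matrix(design: PairDesign, variant: str) -> tuple[pd.DataFrame, list[str]]:
    df = design.table
    dropped: list[str] = []
    parts = []
    if variant in ("dose_and_time", "dose_only"):
        observed = [lv for lv in DOSE_PAIR_LEVELS if lv in set(df["dose_pair"])]
        dropped = [lv for lv in DOSE_PAIR_LEVELS if lv not in observed]
        if dropped:
            logger.warning("dose-pair levels absent from design, dropped: %s", dropped)
        dummies = pd.DataFrame(
            {lv: (df["dose_pair"] == lv).astype(float) for lv in observed}
        )
        parts.append(dummies)  # full dummy coding; factor absorbs the intercept
    if variant == "time_only":
        parts.append(pd.DataFrame({"const": np.ones(len(df))}))
    if variant in ("dose_and_time", "time_only"):
        parts.append(pd.DataFrame({"time_diff": df["time_diff"].astype(float)}))
    X = pd.concat(parts, axis=1)
    return X, dropped


def fit_skl_glm(design: PairDesign, variant: str, family: str = "gaussian") -> GLMFit:
    """Fit one model variant to the pairwise sKL scores.

    Dose-containing variants use full dummy coding of the 6 dose-pair
    levels with no separate intercept (the factor spans it); the
    time-only variant gets an explicit intercept.  ``family`` is
    ``"gaussian"`` (identity link, ordinary least squares — the default,
    consistent with reporting adjusted R^2) or ``"gamma"`` (log link,
    for the strictly positive sKL response; its pseudo-R^2 is
    deviance-based and labeled by the family field).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    y = design.table["skl"].astype(float)
    X, dropped = _design_matrix(design, variant)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"design has {n} rows but the {variant} variant needs > {p}")
    if np.isclose(y.var(ddof=0), 0.0):
        raise ValueError("zero-variance sKL response; nothing to model")

    if family == "gaussian":
        res = sm.OLS(y, X).fit()
        resid = y - res.fittedvalues
        ssr = float(resid @ resid)
        sst = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ssr / sst
        llf = float(res.llf)
    elif family == "gamma":
        res = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log())).fit()
        null = sm.GLM(
            y, np.ones((n, 1)), family=sm.families.Gamma(link=sm.families.links.Log())
        ).fit()
        r2 = 1.0 - res.deviance / null.deviance  # deviance-based pseudo-R^2
        llf = float(res.llf)
    else:
        raise ValueError(f"unknown family {family!r}")

    # p_eff: free coefficients beyond the (implicit or explicit) intercept
    p_eff = p - 1
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p_eff - 1)
    aic = 2 * p - 2 * llf
    bic = p * np.log(n) - 2 * llf
    return GLMFit(
        variant=variant,
        coef=res.params,
        llf=llf,
        r_squared=float(r2),
        adj_r_squared=float(adj_r2),
        aic=float(aic),
        bic=float(bic),
        nobs=n,
        n_params=p,
        family=family,
        scope=design.scope,
        dropped_levels=dropped,
    )


@dataclass
class GLMComparison:
    """Criterion-by-criterion comparison of the three sKL model variants."""

    scope: str
    fits: dict[str, GLMFit]
    best: dict[str, str]  # criterion -> variant
    verdict: str

    def to_row(self) -> pd.Series:
        """Flat summary row: criterion x variant values plus the verdict."""
        data: dict[str, float | str] = {"scope": self.scope}
        for criterion, attr in (
            ("adj_r2", "adj_r_squared"),
            ("aic", "aic"),
            ("bic", "bic"),
        ):
            for v in VARIANTS:
                data[f"{criterion}_{v}"] = getattr(self.fits[v], attr)
            data[f"best_{criterion}"] = self.best[criterion]
        data["verdict"] = self.verdict
        return pd.Series(data)


def compare_glm_variants(fits: dict[str, GLMFit] | list[GLMFit]) -> GLMComparison:
    """Flag the best variant per criterion and emit the reducibility verdict.

    Best = max adjusted R^2, min AIC, min BIC (ties broken toward fewer
    parameters, then fixed variant order).  Verdict: ``"time reducible"``
    when a time-free variant is best under all three criteria,
    ``"dose reducible"`` symmetrically, else ``"not reducible"``.
    """
    if isinstance(fits, list):
        fits = {f.variant: f for f in fits}
    missing = set(VARIANTS) - set(fits)
    if missing:
        raise ValueError(f"missing fitted variants: {sorted(missing)}")
    nobs = {f.nobs for f in fits.values()}
    scopes = {f.scope for f in fits.values()}
    if len(nobs) > 1 or len(scopes) > 1:
        raise ValueError("variants were fitted on different designs")

    def pick(values: dict[str, float], maximize: bool) -> str:
        sign = -1.0 if maximize else 1.0
        order = {v: i for i, v in enumerate(VARIANTS)}
        return min(
            VARIANTS, key=lambda v: (sign * values[v], fits[v].n_params, order[v])
        )

    best = {
        "adj_r2": pick({v: f.adj_r_squared for v, f in fits.items()}, maximize=True),
        "aic": pick({v: f.aic for v, f in fits.items()}, maximize=False),
        "bic": pick({v: f.bic for v, f in fits.items()}, maximize=False),
    }
    winners = set(best.values())
    if len(winners) == 1 and winners <= set(TIME_FREE_VARIANTS):
        verdict = "time reducible"
    elif len(winners) == 1 and winners <= set(DOSE_FREE_VARIANTS):
        verdict = "dose reducible"
    else:
        verdict = "not reducible"
    return GLMComparison(
        scope=next(iter(scopes)), fits=dict(fits), best=best, verdict=verdict
    )


def reduction_report(
    sim: SimilarityMatrix, scopes: list[str], family: str = "gaussian"
) -> pd.DataFrame:
    """Fit and compare all three variants for each scope; one row per scope."""
    rows = []
    for scope in scopes:
        design = build_pair_design(sim, scope)
        fits = {v: fit_skl_glm(design, v, family=family) for v in VARIANTS}
        rows.append(compare_glm_variants(fits).to_row())
    return pd.DataFrame(rows)
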