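"""Mixed-effects association of pathogen load with community covariates.

For a chosen covariate (total commensal colonization, evenness, Faith PD or
weighted mpd) a fixed lattice of random-effect structures is fitted by REML
— from no random effects up to random intercepts and slopes for experiment
and microbox (box nested in experiment, one community per box) — and the
models within 4 AIC units of the minimum form the best set.

The commensal covariate is centered before fitting so that the intercept
reads as the expected pathogen load at mid-level commensal colonization;
evenness and the diversity metrics enter raw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .metrics import StrainTree, pielou_evenness, weighted_mpd, faith_pd
from .records import ScreenDataset, _tukey_fence, partition_ambiguous, total_commensal

__all__ = [
    "RANDOM_STRUCTURES",
    "ModelSpec",
    "FitResult",
    "ModelSelection",
    "enumerate_models",
    "fit_model",
    "select_models",
    "sensitivity_subsets",
    "plant_covariates",
    "associate",
]

# (label, experiment intercept, experiment slope, box intercept, box slope);
# a slope always comes with its intercept and a box term with the experiment
# term, giving the full estimable lattice for two nested grouping factors.
RANDOM_STRUCTURES: tuple[tuple[str, bool, bool, bool, bool], ...] = (
    ("none",                 False, False, False, False),
    ("exp_int",              True,  False, False, False),
    ("exp_int_slope",        True,  True,  False, False),
    ("exp_int+box_int",      True,  False, True,  False),
    ("exp_int_slope+box_int", True, True,  True,  False),
    ("exp_int+box_int_slope", True, False, True,  True),
    ("exp_int_slope+box_int_slope", True, True, True, True),
)

COVARIATES = ("commensal", "evenness", "faith_pd", "weighted_mpd")


@dataclass(frozen=True)
class ModelSpec:
    covariate: str
    random_structure: str

    def __post_init__(self) -> None:
        if self.covariate not in COVARIATES:
            raise ValueError(f"unknown covariate {self.covariate!r}")
        if self.random_structure not in {s[0] for s in RANDOM_STRUCTURES}:
            raise ValueError(f"unknown random structure {self.random_structure!r}")

    @property
    def flags(self) -> tuple[bool, bool, bool, bool]:
        for label, *f in RANDOM_STRUCTURES:
            if label == self.random_structure:
                return tuple(f)  # type: ignore[return-value]
        raise AssertionError


@dataclass
class FitResult:
    model: ModelSpec
    beta_hat: float
    se_beta: float
    p_value: float
    intercept: float
    random_sd: dict[str, float]
    residual_sd: float
    aic: float
    n_obs: int
    converged: bool
    singular: bool = False


@dataclass
class ModelSelection:
    fits: list[FitResult]
    best: list[FitResult] = field(default_factory=list)

    @property
    def best_fit(self) -> FitResult:
        return min(self.best, key=lambda f: f.aic)


def enumerate_models(covariate: str) -> list[ModelSpec]:
    """The fixed, deterministic model lattice for one covariate."""
    return [ModelSpec(covariate, label) for label, *_ in RANDOM_STRUCTURES]


def _reml_ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
    """REML fit of a fixed-effects-only linear model.

    Returns (beta, cov_beta, sigma2_reml, reml_loglike).  The restricted
    log-likelihood is
    ``-0.5 [(n-p) ln 2*pi + (n-p) ln s2 + ln|X'X| + (n-p)]`` with
    ``s2 = RSS/(n-p)``, the same criterion a gls/lmer REML fit maximizes, so
    AIC values are comparable across the lattice.
    """
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    s2 = rss / (n - p)
    xtx = X.T @ X
    cov = s2 * np.linalg.inv(xtx)
    _, logdet = np.linalg.slogdet(xtx)
    llf = -0.5 * ((n - p) * np.log(2 * np.pi) + (n - p) * np.log(s2) + logdet + (n - p))
    return beta, cov, s2, llf


def fit_model(spec: ModelSpec, data: pd.DataFrame, center: bool | None = None) -> FitResult:
    """REML fit of one lattice model.

    ``data`` needs columns ``y``, ``x``, ``experiment``, ``box_id``.  The
    covariate is centered when ``center`` is true (default: only for the
    commensal covariate).  Two-sided t test on the slope with residual
    degrees of freedom ``n - 2``.
    """
    df = data.dropna(subset=["y", "x"]).copy()
    if center is None:
        center = spec.covariate == "commensal"
    if center:
        df["x"] = df["x"] - df["x"].mean()
    n = len(df)
    if n < 4:
        raise ValueError("too few observations")
    exp_i, exp_s, box_i, box_s = spec.flags

    if not exp_i:
        y = df["y"].to_numpy(float)
        X = np.column_stack([np.ones(n), df["x"].to_numpy(float)])
        beta, cov, s2, llf = _reml_ols(y, X)
        aic = -2.0 * llf + 2.0 * (2 + 1)
        se = float(np.sqrt(cov[1, 1]))
        t = beta[1] / se
        p = 2.0 * stats.t.sf(abs(t), n - 2)
        return FitResult(spec, float(beta[1]), se, float(p), float(beta[0]),
                         {}, float(np.sqrt(s2)), float(aic), n, True)

    vc: dict[str, str] = {}
    if box_i:
        vc["box"] = "0 + C(box_id)"
    if box_s:
        vc["box_slope"] = "0 + C(box_id):x"
    re_formula = "1 + x" if exp_s else "1"
    model = smf.mixedlm("y ~ x", df, groups="experiment",
                        re_formula=re_formula, vc_formula=vc or None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=True, method="lbfgs", maxiter=200)
            if not res.converged:
                res = model.fit(reml=True, method="powell", maxiter=400)
        except (np.linalg.LinAlgError, ValueError):
            return FitResult(spec, np.nan, np.nan, np.nan, np.nan, {}, np.nan,
                             np.inf, n, False)
    converged = bool(res.converged) and np.isfinite(res.llf)
    sigma = float(np.sqrt(res.scale))
    random_sd = {}
    cov_re = np.atleast_2d(np.asarray(res.cov_re))
    if cov_re.size:
        random_sd["exp_int"] = float(np.sqrt(max(cov_re[0, 0], 0.0)))
        if exp_s and cov_re.shape[0] > 1:
            random_sd["exp_slope"] = float(np.sqrt(max(cov_re[1, 1], 0.0)))
    for name, v in (res.vcomp is not None and zip(model.exog_vc.names, res.vcomp) or []):
        random_sd[name] = float(np.sqrt(max(v, 0.0)))
    singular = any(sd < 1e-6 for sd in random_sd.values())
    # parameter count: 2 fixed + residual + variance/covariance parameters
    n_vc = len(vc)
    n_re = 3 if exp_s else 1
    k = 2 + 1 + n_re + n_vc
    aic = -2.0 * float(res.llf) + 2.0 * k
    beta = float(res.fe_params["x"])
    se = float(res.bse_fe["x"])
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return FitResult(spec, beta, se, float(p), float(res.fe_params["Intercept"]),
                     random_sd, sigma, float(aic), n, converged, singular)


def select_models(fits: list[FitResult], delta: float = 4.0) -> ModelSelection:
    """Best set = converged fits within ``delta`` AIC of the minimum."""
    ok = [f for f in fits if f.converged and np.isfinite(f.aic)]
    if not ok:
        raise ValueError("no converged fits to select from")
    amin = min(f.aic for f in ok)
    best = [f for f in ok if f.aic - amin < delta]
    return ModelSelection(fits=list(fits), best=best)


def plant_covariates(dataset: ScreenDataset, tree: StrainTree | None = None) -> pd.DataFrame:
    """Per-plant analysis table for the association stage.

    ``y`` is the log10 pathogen load; covariate columns are computed from
    each plant's own end-point abundances (ambiguous counts partitioned for
    evenness/mpd), Faith PD from the inoculated membership.  Requires the
    linear scale; the caller picks the covariate column and renames it to
    ``x``.
    """
    if dataset.scale != "linear":
        raise ValueError("plant_covariates expects linear-scale CFU values")
    members = dataset.communities.membership() if dataset.communities else {}
    fpd_cache: dict[str, float] = {}
    rows = []
    for r in dataset.community_records():
        tot = total_commensal(r)
        part = partition_ambiguous(r)
        j = pielou_evenness(part.strain_cfu)
        mpd = weighted_mpd(tree, part.strain_cfu) if tree is not None else np.nan
        fpd = np.nan
        if tree is not None and r.treatment in members:
            if r.treatment not in fpd_cache:
                fpd_cache[r.treatment] = faith_pd(tree, members[r.treatment])
            fpd = fpd_cache[r.treatment]
        rows.append((r.experiment, r.box_id, r.treatment, r.plant_id,
                     np.log10(r.pathogen_cfu),
                     np.log10(tot) if tot else np.nan,
                     np.nan if j is None else j,
                     fpd, np.nan if mpd is None else mpd,
                     r.has_below_detection, r.has_ambiguous))
    table = pd.DataFrame(rows, columns=[
        "experiment", "box_id", "community_id", "plant_id", "y",
        "commensal", "evenness", "faith_pd", "weighted_mpd",
        "has_below_detection", "has_ambiguous"])
    # Tukey fences on the log scale, per treatment group (the rule applies
    # after the log transform; on the linear scale it would flag the whole
    # high tail of the skewed CFU distribution)
    table["outlier"] = False
    for _, idx in table.groupby(["experiment", "community_id"]).groups.items():
        y = table.loc[idx, "y"].to_numpy()
        lo, hi = _tukey_fence(y)
        table.loc[idx, "outlier"] = ~((y >= lo) & (y <= hi))
    return table


def sensitivity_subsets(table: pd.DataFrame, covariate: str) -> dict[str, pd.DataFrame]:
    """Main and stricter analysis subsets for one covariate.

    Outlier flags alone do not drop plants (exclusion needs a recorded
    experimental reason, handled upstream).  Abundance-based covariates
    (evenness, weighted mpd) require unambiguous counts in the main set.
    The strict sensitivity set additionally drops plants of communities
    with strains below the level of detection.
    """
    base = table
    if covariate in ("evenness", "weighted_mpd"):
        main = base[~base["has_ambiguous"]]
    else:
        main = base
    strict = main[~main["has_below_detection"]]
    return {"main": main.copy(), "strict": strict.copy()}


def associate(table: pd.DataFrame, covariate: str, subset: str = "main") -> ModelSelection:
    """Fit the full lattice for one covariate on one subset and select by AIC."""
    sub = sensitivity_subsets(table, covariate)[subset]
    data = sub.rename(columns={covariate: "x"})[
        ["y", "x", "experiment", "box_id"]]
    fits = [fit_model(spec, data) for spec in enumerate_models(covariate)]
    return select_models(fits)
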