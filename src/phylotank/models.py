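"""OLS model fitting, AICc selection, and partial R² for diversity metrics.

Each standardized diversity metric (species richness, NRI, NTI) is
regressed on habitat size and predation.  The candidate family is every
subset of the role's terms that respects marginality (the quadratic size
term only enters with the linear term; the size x predator interaction only
with both main effects):

* experiments: size, size², predator (binary), size x predator;
* survey:      size, size², predator biomass (continuous), size x predator
               biomass, plus detritus mass as a covariate.

Habitat size is centered log10 capacity (centering tames the collinearity
of size with size²).  Candidates are ranked by the corrected Akaike
information criterion

    AICc = -2 ln L + 2k + 2k(k+1)/(n-k-1)

with Gaussian likelihood at the ML variance (SSE/n) and k counting the
intercept, slopes, and residual variance.  The chosen model has the lowest
AICc, except that when several candidates sit within 2 AICc units of the
minimum the one with the fewest terms wins (parsimony tie-break).

Per-term partial R² on the chosen model is the proportional SSE reduction
when the term is added to the otherwise-complete model, dropping dependents
along with their parent term (removing a main effect removes its quadratic
and interactions too).

Model assumptions are checked on the full model (Shapiro-Wilk on residuals,
Breusch-Pagan for heteroscedasticity, both at alpha = 0.05); on failure the
response can be Box-Cox (positive responses) or Yeo-Johnson transformed,
with lambda picked by profile maximum likelihood on a fixed grid
(-2..2, step 0.01), before standardization.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan

logger = logging.getLogger("phylotank")

LAMBDA_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.01), 2)
ALPHA_DIAG = 0.05

#: term -> terms that must leave the model with it (marginality)
DEPENDENTS = {
    "size": ("size2", "size_x_predator"),
    "predator": ("size_x_predator",),
    "size2": (),
    "size_x_predator": (),
    "detritus": (),
}

ROLE_TERMS = {
    "survey": ("size", "size2", "predator", "size_x_predator", "detritus"),
    "colonization": ("size", "size2", "predator", "size_x_predator"),
    "extinction": ("size", "size2", "predator", "size_x_predator"),
}

#: terms whose marginality prerequisites, if any, are listed
REQUIRES = {
    "size2": ("size",),
    "size_x_predator": ("size", "predator"),
}


# ---------------------------------------------------------------------------
# Design and response preparation
# ---------------------------------------------------------------------------


def build_design(meta, role: str) -> pd.DataFrame:
    """Design-matrix columns for a dataset role from bromeliad metadata.

    size = centered log10 capacity; size2 = size²; predator = 0/1 treatment
    (experiments) or standardized damselfly biomass (survey);
    size_x_predator = product; detritus = standardized detrital mass
    (survey only).
    """
    t = meta.table
    size = t["log_size"].to_numpy(dtype=float)
    size = size - size.mean()
    cols = {"size": size, "size2": size**2}
    if role == "survey":
        pb = t["predator_biomass"].to_numpy(dtype=float)
        cols["predator"] = (pb - pb.mean()) / pb.std(ddof=1)
        det = t["detritus_mass"].to_numpy(dtype=float)
        cols["detritus"] = (det - det.mean()) / det.std(ddof=1)
    else:
        cols["predator"] = t["predator_present"].to_numpy(dtype=bool).astype(float)
    cols["size_x_predator"] = cols["size"] * cols["predator"]
    return pd.DataFrame(cols, index=t.index)


def standardize(y: np.ndarray | pd.Series) -> np.ndarray:
    """Center to mean 0 and scale to sample SD 1 (so coefficients are
    comparable across response metrics)."""
    y = np.asarray(y, dtype=float)
    if np.sum(np.isfinite(y)) < 2:
        raise ValueError("standardize needs >= 2 non-missing values")
    mu, sd = np.nanmean(y), np.nanstd(y, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant response")
    return (y - mu) / sd


@dataclass
class TransformResult:
    y: np.ndarray
    method: str  # "none" | "box_cox" | "yeo_johnson"
    lam: float | None
    diagnostics: dict


def _profile_lambda(y: np.ndarray, llf) -> float:
    vals = np.array([llf(l, y) for l in LAMBDA_GRID])
    return float(LAMBDA_GRID[int(np.nanargmax(vals))])


def _apply_box_cox(y: np.ndarray, lam: float) -> np.ndarray:
    return np.log(y) if lam == 0 else (y**lam - 1) / lam


def residual_diagnostics(y: np.ndarray, design: pd.DataFrame) -> dict:
    """Shapiro-Wilk and Breusch-Pagan p-values on the full model."""
    X = sm.add_constant(design.to_numpy(dtype=float))
    fit = sm.OLS(y, X).fit()
    sw_p = float(stats.shapiro(fit.resid).pvalue)
    bp_p = float(het_breuschpagan(fit.resid, X)[1])
    return {"shapiro_p": sw_p, "breusch_pagan_p": bp_p,
            "pass": sw_p > ALPHA_DIAG and bp_p > ALPHA_DIAG}


def transform_response(
    y: np.ndarray | pd.Series,
    design: pd.DataFrame | None = None,
    method: str = "auto",
    shift: float = 0.0,
) -> TransformResult:
    """Optionally normalize a response by Box-Cox or Yeo-Johnson.

    ``method="auto"`` transforms only when the full-model diagnostics fail,
    choosing Box-Cox for strictly positive responses and Yeo-Johnson
    otherwise.  Lambda maximizes the profile log-likelihood on the fixed
    grid.
    """
    y = np.asarray(y, dtype=float) + shift
    diag = residual_diagnostics(y, design) if design is not None else {}
    if method == "none" or (method == "auto" and diag.get("pass", True)):
        return TransformResult(y, "none", None, diag)
    if method == "auto":
        method = "box_cox" if np.all(y > 0) else "yeo_johnson"
    if method == "box_cox":
        if np.any(y <= 0):
            raise ValueError("box_cox requires positive data (use shift)")
        lam = _profile_lambda(y, stats.boxcox_llf)
        return TransformResult(_apply_box_cox(y, lam), "box_cox", lam, diag)
    if method == "yeo_johnson":
        lam = _profile_lambda(y, stats.yeojohnson_llf)
        return TransformResult(stats.yeojohnson(y, lmbda=lam), "yeo_johnson",
                               lam, diag)
    raise ValueError(f"unknown transform method {method!r}")


# ---------------------------------------------------------------------------
# Candidate family and AICc selection
# ---------------------------------------------------------------------------


def candidate_terms(terms: tuple[str, ...]) -> list[tuple[str, ...]]:
    """All subsets of ``terms`` respecting marginality, smallest first."""
    out = []
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(terms, r):
            cs = set(combo)
            if all(set(REQUIRES.get(t, ())) <= cs for t in combo):
                out.append(combo)
    return out


def aicc(llf: float, k: int, n: int) -> float:
    """AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1); infinite when n <= k + 1."""
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _fit(design: pd.DataFrame, y: np.ndarray, terms: tuple[str, ...]):
    X = sm.add_constant(design[list(terms)].to_numpy(dtype=float)) \
        if terms else np.ones((len(y), 1))
    return sm.OLS(y, X).fit()


@dataclass
class ModelSelectionResult:
    candidates: pd.DataFrame  # terms, n_terms, k, loglik, aicc, delta_aicc
    chosen_terms: tuple[str, ...]
    coefficients: dict[str, float]
    term_pvalues: dict[str, float]
    partial_r2: dict[str, float]
    n: int
    fit: object = field(repr=False)


def fit_candidates(
    design: pd.DataFrame,
    y: np.ndarray | pd.Series,
    terms: tuple[str, ...] | None = None,
    role: str | None = None,
) -> ModelSelectionResult:
    """Fit every marginality-respecting candidate and select by AICc.

    Rows with missing response (degenerate SES) are dropped pairwise with
    the design.  Candidates whose sample size cannot support the parameter
    count are dropped with a log entry.  Ties within 2 AICc of the minimum
    go to the model with the fewest terms ("fewest variables" parsimony),
    then to the lower AICc.
    """
    if terms is None:
        if role is None:
            raise ValueError("supply terms or role")
        terms = ROLE_TERMS[role]
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y)
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("fit_candidates: dropped %d rows with missing response",
                    n_dropped)
    y = y[mask]
    design = design.loc[mask]
    n = len(y)

    rows = []
    fits = {}
    for combo in candidate_terms(terms):
        k = len(combo) + 2  # intercept + slopes + residual variance
        if n - k - 1 <= 0:
            logger.info("fit_candidates: candidate %s dropped (n=%d too small)",
                        combo, n)
            continue
        fit = _fit(design, y, combo)
        if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
            raise ValueError(f"rank-deficient design for terms {combo}")
        rows.append({"terms": combo, "n_terms": len(combo), "k": k,
                     "loglik": float(fit.llf), "aicc": aicc(fit.llf, k, n)})
        fits[combo] = fit
    if not rows:
        raise ValueError("no fittable candidates (n too small)")
    cand = pd.DataFrame(rows)
    cand["delta_aicc"] = cand["aicc"] - cand["aicc"].min()
    chosen = select_by_aicc(cand)
    fit = fits[chosen]
    names = ("const",) + chosen
    coefs = dict(zip(names, map(float, fit.params)))
    pvals = dict(zip(names, map(float, fit.pvalues)))
    pr2 = partial_r2(design, y, chosen)
    return ModelSelectionResult(
        cand.sort_values("aicc").reset_index(drop=True), chosen, coefs,
        pvals, pr2, n, fit,
    )


def select_by_aicc(candidates: pd.DataFrame) -> tuple[str, ...]:
    """Selection rule on a candidate table (columns terms, n_terms, aicc):
    lowest AICc, but among all candidates within 2 AICc units of the
    minimum the one with the fewest terms wins; remaining ties go to the
    lower AICc."""
    cand = candidates.copy()
    cand["delta_aicc"] = cand["aicc"] - cand["aicc"].min()
    within = cand[cand["delta_aicc"] <= 2.0]
    best = within.sort_values(["n_terms", "aicc"]).iloc[0]
    return tuple(best["terms"])


def partial_r2(
    design: pd.DataFrame, y: np.ndarray, chosen: tuple[str, ...]
) -> dict[str, float]:
    """Per-term partial R²: (SSE_without - SSE_with) / SSE_without,
    where "without" drops the term and its marginality dependents."""
    y = np.asarray(y, dtype=float)
    full = _fit(design, y, chosen)
    sse_full = float(full.ssr)
    out = {}
    for t in chosen:
        dropped = {t, *DEPENDENTS.get(t, ())}
        reduced = tuple(u for u in chosen if u not in dropped)
        sse_red = float(_fit(design, y, reduced).ssr)
        out[t] = (sse_red - sse_full) / sse_red if sse_red > 0 else np.nan
    return out
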