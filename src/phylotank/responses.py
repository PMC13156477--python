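"""Species-level response indices from the two assembly experiments.

Each index is a z-score comparing an observed summary of where a species'
individuals ended up against a null model of random assembly:

colonization experiment
    * ``size_preference`` — mean log10 habitat size of the species'
      colonists vs. each colonist choosing a bromeliad independently and
      uniformly at random.  Positive z: found in larger plants than chance.
    * ``predator_avoidance`` — fraction of colonists in predator-free
      bromeliads vs. a binomial null with p = (# predator-free)/(# plants).
      Positive z: avoidance.

extinction experiment (introduced counts known)
    * ``size_sensitivity`` — mean log10 size over surviving individuals vs.
      a null that fixes the species' survivor total and draws which of its
      introduced individuals survive uniformly without replacement
      (multivariate hypergeometric across bromeliads).  Positive z:
      survivors concentrated in larger plants.
    * ``predator_sensitivity`` — fraction of survivors in predator-free
      bromeliads under the same fixed-survivor-count null.  Positive z:
      better survival away from predators.

Closed forms exist for all four nulls and are the default; a Monte-Carlo
path (``method="montecarlo"``) draws the same nulls explicitly and is used
for cross-checking.  Species with fewer than two contributing individuals
are skipped; null standard deviations of zero (all plants predator-free,
species introduced at a single site, all-or-none survival) are flagged
degenerate.  Significance is two-sided at |z| >= 1.96 with no
multiple-testing correction (a Benjamini-Hochberg option is available but
off by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import BromeliadMeta, CommunityTable

logger = logging.getLogger("phylotank")

Z_THRESHOLD = 1.96

INDEX_KINDS = (
    "size_preference",
    "predator_avoidance",
    "size_sensitivity",
    "predator_sensitivity",
)


@dataclass
class ResponseIndex:
    species: str
    index_kind: str
    observed: float
    null_mean: float
    null_sd: float
    z: float
    significant: bool
    n_events: int
    flag: str  # "ok" | "skipped_min_events" | "degenerate_null"


def _finish(rows: list[ResponseIndex]) -> pd.DataFrame:
    skipped = sum(r.flag == "skipped_min_events" for r in rows)
    degen = sum(r.flag == "degenerate_null" for r in rows)
    if skipped:
        logger.info("response indices: %d species skipped (< 2 events)", skipped)
    if degen:
        logger.info("response indices: %d species with degenerate null", degen)
    return pd.DataFrame([r.__dict__ for r in rows])


def _row(species, kind, obs, mu, sd, n, flag="ok") -> ResponseIndex:
    if flag != "ok" or not np.isfinite(sd) or sd == 0:
        if flag == "ok":
            flag = "degenerate_null"
        return ResponseIndex(species, kind, obs, mu, np.nan if flag ==
                             "skipped_min_events" else sd, np.nan, False, n, flag)
    z = (obs - mu) / sd
    return ResponseIndex(species, kind, obs, mu, sd, z,
                         bool(abs(z) >= Z_THRESHOLD), n, flag)


# ---------------------------------------------------------------------------
# Colonization indices
# ---------------------------------------------------------------------------


def size_preference(
    table: CommunityTable,
    meta: BromeliadMeta,
    method: str = "exact",
    n_null: int = 9999,
    rng: np.random.Generator | None = None,
    min_events: int = 2,
) -> pd.DataFrame:
    """Habitat-size preference z-score per colonizing species."""
    logs = meta.log_size(table.bromeliads)
    B = len(logs)
    mu = float(logs.mean())
    var1 = float(logs.var())  # population variance of a single uniform draw
    rows: list[ResponseIndex] = []
    for s in table.species:
        counts = table.counts[s].to_numpy(dtype=int)
        n = int(counts.sum())
        if n < min_events:
            rows.append(_row(s, "size_preference", np.nan, mu, np.nan, n,
                             "skipped_min_events"))
            continue
        obs = float((counts @ logs) / n)
        if method == "exact":
            sd = float(np.sqrt(var1 / n))
        elif method == "montecarlo":
            if rng is None:
                rng = np.random.default_rng()
            draws = rng.integers(0, B, size=(n_null, n))
            sims = logs[draws].mean(axis=1)
            mu_s, sd = float(sims.mean()), float(sims.std(ddof=1))
            rows.append(_row(s, "size_preference", obs, mu_s, sd, n))
            continue
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append(_row(s, "size_preference", obs, mu, sd, n))
    return _finish(rows)


def predator_avoidance(
    table: CommunityTable,
    meta: BromeliadMeta,
    method: str = "exact",
    n_null: int = 9999,
    rng: np.random.Generator | None = None,
    min_events: int = 2,
) -> pd.DataFrame:
    """Predator-avoidance z-score per colonizing species.

    Observed statistic: fraction of colonists in predator-absent plants;
    null proportion binomial with p = (# predator-free)/(# plants).
    """
    pred = meta.predator_present(table.bromeliads)
    B = len(pred)
    p_free = float((~pred).sum() / B)
    rows: list[ResponseIndex] = []
    for s in table.species:
        counts = table.counts[s].to_numpy(dtype=int)
        n = int(counts.sum())
        if n < min_events:
            rows.append(_row(s, "predator_avoidance", np.nan, p_free, np.nan,
                             n, "skipped_min_events"))
            continue
        obs = float(counts[~pred].sum() / n)
        if method == "exact":
            sd = float(np.sqrt(p_free * (1 - p_free) / n))
            rows.append(_row(s, "predator_avoidance", obs, p_free, sd, n))
        elif method == "montecarlo":
            if rng is None:
                rng = np.random.default_rng()
            sims = rng.binomial(n, p_free, size=n_null) / n
            rows.append(_row(s, "predator_avoidance", obs, float(sims.mean()),
                             float(sims.std(ddof=1)), n))
        else:
            raise ValueError(f"unknown method {method!r}")
    return _finish(rows)


# ---------------------------------------------------------------------------
# Extinction indices
# ---------------------------------------------------------------------------


def _survivor_null_moments(
    intro: np.ndarray, values: np.ndarray, k: int
) -> tuple[float, float]:
    """Mean and SD of the mean ``values`` over k survivors drawn uniformly
    without replacement from the introduced individuals (finite-population
    sampling; individual i carries the value of its bromeliad)."""
    N = int(intro.sum())
    mu_pop = float((intro @ values) / N)
    var_pop = float((intro @ (values - mu_pop) ** 2) / N)
    if N <= 1:
        return mu_pop, 0.0
    var_mean = var_pop / k * (N - k) / (N - 1)
    return mu_pop, float(np.sqrt(max(var_mean, 0.0)))


def _extinction_index(
    table: CommunityTable,
    meta: BromeliadMeta,
    kind: str,
    method: str,
    n_null: int,
    rng: np.random.Generator | None,
) -> pd.DataFrame:
    if table.role != "extinction" or table.introduced is None:
        raise ValueError("extinction indices require an extinction table with "
                         "introduced counts")
    if kind == "size_sensitivity":
        values = meta.log_size(table.bromeliads)
    else:
        values = (~meta.predator_present(table.bromeliads)).astype(float)
    rows: list[ResponseIndex] = []
    for s in table.species:
        intro = table.introduced[s].to_numpy(dtype=int)
        surv = table.counts[s].to_numpy(dtype=int)
        N, k = int(intro.sum()), int(surv.sum())
        if N < 2 or k < 1 or k >= N:
            # no survivors, no deaths, or a single introduced individual:
            # the fixed-survivor-count null is degenerate
            flag = "degenerate_null" if N >= 2 else "skipped_min_events"
            rows.append(_row(s, kind, np.nan, np.nan, np.nan, k, flag))
            continue
        obs = float((surv @ values) / k)
        if method == "exact":
            mu, sd = _survivor_null_moments(intro, values, k)
            rows.append(_row(s, kind, obs, mu, sd, k))
        elif method == "montecarlo":
            if rng is None:
                rng = np.random.default_rng()
            individuals = np.repeat(values, intro)
            sims = np.empty(n_null)
            for r in range(n_null):
                sims[r] = rng.choice(individuals, size=k, replace=False).mean()
            rows.append(_row(s, kind, obs, float(sims.mean()),
                             float(sims.std(ddof=1)), k))
        else:
            raise ValueError(f"unknown method {method!r}")
    return _finish(rows)


def size_sensitivity(
    table: CommunityTable,
    meta: BromeliadMeta,
    method: str = "exact",
    n_null: int = 9999,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Habitat-size survival sensitivity z-score per introduced species."""
    return _extinction_index(table, meta, "size_sensitivity", method, n_null, rng)


def predator_sensitivity(
    table: CommunityTable,
    meta: BromeliadMeta,
    method: str = "exact",
    n_null: int = 9999,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Predator survival sensitivity z-score per introduced species."""
    return _extinction_index(table, meta, "predator_sensitivity", method, n_null, rng)


# ---------------------------------------------------------------------------
# Convenience
# ---------------------------------------------------------------------------


def compute_response_indices(
    colonization: tuple[CommunityTable, BromeliadMeta] | None = None,
    extinction: tuple[CommunityTable, BromeliadMeta] | None = None,
    method: str = "exact",
    n_null: int = 9999,
    rng: np.random.Generator | None = None,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """All four indices in one long-format table.

    With ``bh_correction`` the significance column is recomputed from
    Benjamini-Hochberg-adjusted two-sided normal p-values within each
    index kind (off by default, mirroring uncorrected |z| >= 1.96 use).
    """
    frames = []
    if colonization is not None:
        t, m = colonization
        frames.append(size_preference(t, m, method, n_null, rng))
        frames.append(predator_avoidance(t, m, method, n_null, rng))
    if extinction is not None:
        t, m = extinction
        frames.append(size_sensitivity(t, m, method, n_null, rng))
        frames.append(predator_sensitivity(t, m, method, n_null, rng))
    if not frames:
        raise ValueError("no experiment data supplied")
    out = pd.concat(frames, ignore_index=True)
    if bh_correction:
        out["p_value"] = 2 * stats.norm.sf(np.abs(out["z"]))
        out["significant"] = False
        for kind, grp in out.groupby("index_kind"):
            ok = grp["p_value"].notna()
            if ok.sum() == 0:
                continue
            p = grp.loc[ok, "p_value"].to_numpy()
            order = np.argsort(p)
            m = len(p)
            thresh = 0.05 * (np.arange(1, m + 1)) / m
            passed = p[order] <= thresh
            cutoff = p[order][: passed.nonzero()[0].max() + 1].max() if passed.any() else -1
            out.loc[grp.index[ok], "significant"] = p <= cutoff
    return out
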