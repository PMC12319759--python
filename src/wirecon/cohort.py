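"""Participant-level statistics and stochasticity experiments.

Covers: outlier trimming on fitted parameters, the extreme-score-group
contrast (top vs bottom decile of the polygenic-type score), the continuous
score-parameter GLM with nuisance covariates, the repeated-simulation
stochasticity contrast between two parameter regimes, and the
parameter-randomisation sweep against a degree-preserving rewired null.

Sign convention: every contrast is reported as (group "high" - group "low"),
so a softer distance penalty in the high group yields positive effect sizes
for probability variability, embedding dissimilarity, and global efficiency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, InvalidSpecError
from .evaluation import fingerprint, maslov_sneppen, tf_dissimilarity
from .gnm import GNMParams, derive_seed, simulate
from .graphs import SpatialGraph
from .metrics import global_efficiency

__all__ = [
    "remove_outliers",
    "extreme_group_contrast",
    "pgs_glm",
    "StochasticityReport",
    "stochasticity_experiment",
    "randomisation_sweep",
]


def remove_outliers(table: pd.DataFrame, k_sd: float = 2.0) -> pd.DataFrame:
    """Drop rows whose eta or gamma lies outside mean +/- k_sd * SD.

    Bounds are computed once on the input table (single pass, not iterated).
    """
    if k_sd <= 0:
        raise InvalidSpecError("k_sd must be > 0")
    keep = np.ones(len(table), dtype=bool)
    for col in ("eta", "gamma"):
        x = table[col].to_numpy(dtype=float)
        lo, hi = x.mean() - k_sd * x.std(ddof=1), x.mean() + k_sd * x.std(ddof=1)
        keep &= (x >= lo) & (x <= hi)
    out = table.loc[keep].reset_index(drop=True)
    if out.empty:
        raise InvalidInputError("outlier removal left an empty table")
    return out


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    n1, n2 = len(a), len(b)
    pooled = np.sqrt(
        ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    )
    return float((a.mean() - b.mean()) / pooled) if pooled > 0 else 0.0


def _ttest(a: np.ndarray, b: np.ndarray) -> dict[str, float]:
    """Classic equal-variance two-sample t-test of (a - b), plus Cohen's d.

    Degenerate case (both samples constant and equal, e.g. two identical
    paired regimes) reports a null contrast (t = 0, p = 1, d = 0).
    """
    t, p = stats.ttest_ind(a, b, equal_var=True)
    if np.isnan(t):
        t, p = 0.0, 1.0
    return {
        "t": float(t),
        "df": len(a) + len(b) - 2,
        "p": float(p),
        "d": _cohens_d(a, b),
    }


def extreme_group_contrast(
    table: pd.DataFrame, fraction: float = 0.10
) -> pd.DataFrame:
    """Top vs bottom score-decile contrast of fitted eta and gamma.

    Group size is ceil(fraction * n).  Returns one row per parameter with the
    classic two-sample t (df = n1 + n2 - 2), p, and pooled-SD Cohen's d, all
    oriented as top-group minus bottom-group.
    """
    if not 0 < fraction < 0.5:
        raise InvalidSpecError("fraction must be in (0, 0.5)")
    n = len(table)
    g = math.ceil(fraction * n)
    if g < 2:
        raise InvalidInputError("need at least 2 participants per group")
    ranked = table.sort_values("pgs", kind="mergesort")
    bottom, top = ranked.iloc[:g], ranked.iloc[-g:]
    rows = []
    for col in ("eta", "gamma"):
        res = _ttest(top[col].to_numpy(float), bottom[col].to_numpy(float))
        rows.append({"parameter": col, "n_per_group": g, **res})
    return pd.DataFrame(rows)


def pgs_glm(table: pd.DataFrame, covariates: tuple[str, ...] = ("mean_fd", "sex", "age"),
            n_tests: int = 2) -> pd.DataFrame:
    """Standardized linear association of each fitted parameter with the score.

    Fits z(parameter) ~ z(pgs) + covariates by OLS for eta and gamma and
    reports the fully standardized slope on the score, its p-value, and the
    Bonferroni-corrected p (factor = number of parameters tested).
    """
    import statsmodels.api as sm

    missing = [c for c in covariates if c not in table.columns]
    if missing:
        raise InvalidInputError(f"missing covariates: {missing}")

    def z(x: np.ndarray) -> np.ndarray:
        return (x - x.mean()) / x.std(ddof=0)

    cols = [z(table["pgs"].to_numpy(float))]
    names = ["pgs"]
    for c in covariates:
        v = table[c]
        if v.dtype == object or str(v.dtype) == "category":
            dummies = pd.get_dummies(v, prefix=c, drop_first=True)
            for dc in dummies.columns:
                cols.append(dummies[dc].to_numpy(float))
                names.append(dc)
        else:
            cols.append(v.to_numpy(float))
            names.append(c)
    X = np.column_stack(cols)
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        collinear = []
        for k in range(design.shape[1] - 1, 0, -1):
            reduced = np.delete(design, k, axis=1)
            if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(design):
                collinear.append((["const"] + names)[k])
        raise InvalidInputError(f"rank-deficient design; collinear: {collinear}")
    rows = []
    for col in ("eta", "gamma"):
        y = z(table[col].to_numpy(float))
        fit = sm.OLS(y, design).fit()
        beta, p = float(fit.params[1]), float(fit.pvalues[1])
        rows.append(
            {"parameter": col, "beta": beta, "p": p,
             "p_bonf": min(1.0, n_tests * p)}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StochasticityReport:
    """Distributions and contrasts from the repeated-simulation experiment.

    ``distributions[group][measure]`` holds the raw per-simulation (global
    efficiency), per-pair (embedding / topological dissimilarity) or per-node
    (probability CV) values; ``contrasts`` has one row per measure with t, p
    and Cohen's d oriented as high - low.
    """

    distributions: dict[str, dict[str, np.ndarray]]
    contrasts: pd.DataFrame


def _probability_cv(pair_probs: np.ndarray) -> np.ndarray:
    """Per-pair CV across simulations of iteration-averaged wiring probability.

    ``pair_probs`` is (sims, pairs).  Pairs that were never candidates (mean
    probability 0, e.g. seed edges) are excluded.  A more stochastic wiring
    regime lets simulation trajectories diverge, so each pair's accumulated
    probability varies more from run to run.
    """
    mean = pair_probs.mean(axis=0)
    sd = pair_probs.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return cv[np.isfinite(cv)]


def _pair_indices(n_sims: int, max_pairs: int, rng: np.random.Generator):
    pairs = [(i, j) for i in range(n_sims) for j in range(i + 1, n_sims)]
    if len(pairs) > max_pairs:
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[k] for k in idx]
    return pairs


def _jaccard_distance(a: frozenset, b: frozenset) -> float:
    union = len(a | b)
    return 1.0 - (len(a & b) / union if union else 1.0)


def _group_measures(
    seed: SpatialGraph,
    target_edges: int,
    params: GNMParams,
    n_sims: int,
    rng_seed: int,
    rule: str,
    max_pairs: int,
    include_topology: bool,
) -> dict[str, np.ndarray]:
    pair_probs = []
    edge_sets = []
    fingerprints = []
    efficiency = np.zeros(n_sims)
    for s in range(n_sims):
        trace = simulate(
            seed, target_edges, rule, params,
            derive_seed(rng_seed, "stoch", s), record="pairs",
        )
        pair_probs.append(trace.mean_pair_probability)
        edge_sets.append(frozenset(trace.added_edges))
        if include_topology:
            fingerprints.append(fingerprint(trace.final))
        efficiency[s] = global_efficiency(trace.final)
    rng = np.random.default_rng(derive_seed(rng_seed, "pairs"))
    pairs = _pair_indices(n_sims, max_pairs, rng)
    embedding = np.array(
        [_jaccard_distance(edge_sets[i], edge_sets[j]) for i, j in pairs]
    )
    out = {
        "probability_cv": _probability_cv(np.stack(pair_probs)),
        "embedding_dissimilarity": embedding,
        "global_efficiency": efficiency,
    }
    if include_topology:
        out["topological_dissimilarity"] = np.array(
            [tf_dissimilarity(fingerprints[i], fingerprints[j]) for i, j in pairs]
        )
    return out


def stochasticity_experiment(
    params_low: GNMParams,
    params_high: GNMParams,
    seed: SpatialGraph,
    target_edges: int,
    n_sims: int = 200,
    rng_seed: int = 0,
    rule: str = "neighbours",
    max_pairs: int = 1000,
    include_topology: bool = True,
) -> StochasticityReport:
    """Contrast the stochasticity of two wiring regimes over repeated runs.

    For each group, ``n_sims`` networks are simulated from the shared seed.
    Measures collected: per-pair CV across simulations of the
    iteration-averaged wiring probability, mean pairwise Jaccard distance
    between added-edge sets (embedding dissimilarity, over up to
    ``max_pairs`` random simulation pairs), per-simulation global efficiency,
    and (optionally) pairwise topological-fingerprint dissimilarity.
    Contrasts are t, p and Cohen's d of high - low.
    """
    if n_sims < 2:
        raise InvalidSpecError("n_sims must be >= 2")
    # common random numbers: simulation k shares its RNG stream across the
    # two regimes, so group contrasts are paired comparisons of the same
    # draws under different wiring parameters (variance reduction for the
    # direction of small effects)
    groups = {
        "low": _group_measures(seed, target_edges, params_low, n_sims,
                               rng_seed, rule, max_pairs, include_topology),
        "high": _group_measures(seed, target_edges, params_high, n_sims,
                                rng_seed, rule, max_pairs, include_topology),
    }
    measures = ["probability_cv", "embedding_dissimilarity", "global_efficiency"]
    if include_topology:
        measures.insert(2, "topological_dissimilarity")
    rows = []
    for measure in measures:
        hi = groups["high"][measure]
        lo = groups["low"][measure]
        hi, lo = hi[np.isfinite(hi)], lo[np.isfinite(lo)]
        rows.append({"measure": measure, **_ttest(hi, lo)})
    return StochasticityReport(distributions=groups,
                               contrasts=pd.DataFrame(rows))


def randomisation_sweep(
    optimal: GNMParams,
    fractions,
    seed: SpatialGraph,
    target: SpatialGraph,
    n_sims: int = 100,
    rng_seed: int = 0,
    rule: str = "neighbours",
) -> pd.DataFrame:
    """Progressively randomise wiring by scaling both exponents.

    For each fraction f, the model runs with (round(f*eta, 3), round(f*gamma,
    3)); f = 0 is pure random edge addition.  Per fraction the mean simulated
    global efficiency and the mean topological-fingerprint dissimilarity to a
    Maslov-Sneppen-rewired copy of the target are returned.
    """
    fractions = list(fractions)
    if any(not 0 <= f <= 1 for f in fractions):
        raise InvalidSpecError("fractions must lie in [0, 1]")
    rows = []
    for f in fractions:
        params = GNMParams(round(f * optimal.eta, 3), round(f * optimal.gamma, 3),
                           epsilon=optimal.epsilon)
        eff = np.zeros(n_sims)
        dis = np.zeros(n_sims)
        for s in range(n_sims):
            trace = simulate(
                seed, target.n_edges, rule, params,
                derive_seed(rng_seed, "sweep", f, s),
            )
            eff[s] = global_efficiency(trace.final)
            rewired = maslov_sneppen(target, derive_seed(rng_seed, "ms", f, s))
            dis[s] = tf_dissimilarity(fingerprint(trace.final),
                                      fingerprint(rewired))
        rows.append(
            {
                "fraction": f,
                "eta": params.eta,
                "gamma": params.gamma,
                "mean_global_efficiency": float(eff.mean()),
                "mean_tf_dissimilarity_to_rewired": float(dis.mean()),
            }
        )
    return pd.DataFrame(rows)
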