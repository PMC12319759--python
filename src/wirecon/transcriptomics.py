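"""Partial-least-squares decoding of nodal wiring terms against regional
gene expression.

For each participant, a PLS regression relates the region x gene expression
matrix (predictors) to a nodal vector of parameterised wiring cost or value
(response).  Gene loadings on the first component are tested against a
permutation null built by shuffling the response across regions; genes
surviving in the required set of participants are averaged and ranked.

The PLS itself is scikit-learn's NIPALS implementation; this module fixes the
sign convention (component-1 scores correlate positively with the response)
so loadings are comparable across participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .errors import DegenerateResponseError, InvalidInputError, InvalidSpecError

__all__ = [
    "PLSGeneResult",
    "pls_fit",
    "permutation_pvalues",
    "aggregate_ranking",
]


@dataclass(frozen=True)
class PLSGeneResult:
    """Per-gene component-1 loadings, optional permutation p-values, and
    per-component fraction of response variance explained."""

    genes: tuple[str, ...]
    loadings: np.ndarray  # genes, signed component-1 loadings
    variance_explained: np.ndarray  # per component, fraction of y variance
    p_values: np.ndarray | None = None

    def table(self) -> pd.DataFrame:
        data = {"gene": self.genes, "loading": self.loadings}
        if self.p_values is not None:
            data["p"] = self.p_values
        return pd.DataFrame(data)


def _fit_loadings(X: np.ndarray, y: np.ndarray, n_components: int):
    """Component-1 gene loadings with the positive-score sign convention."""
    pls = PLSRegression(n_components=n_components, scale=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns on near-null y
        pls.fit(X, y)
    loadings = pls.x_loadings_.copy()
    scores = pls.x_scores_
    var_exp = np.zeros(n_components)
    yc = y - y.mean()
    for k in range(n_components):
        t = scores[:, k]
        if t.std() > 0 and yc.std() > 0:
            var_exp[k] = float(np.corrcoef(t, yc)[0, 1] ** 2)
        sign = np.sign(np.corrcoef(t, yc)[0, 1]) if t.std() > 0 else 1.0
        if sign < 0:
            loadings[:, k] *= -1
    return loadings, var_exp


def pls_fit(X: pd.DataFrame, y: np.ndarray, n_components: int = 3) -> PLSGeneResult:
    """PLS regression of a nodal response on a region x gene matrix.

    Columns of X and y are centred and scaled; gene loadings are reported on
    the first component with scores sign-fixed to correlate positively with y.
    """
    y = np.asarray(y, dtype=float)
    Xv = X.to_numpy(dtype=float)
    if Xv.shape[0] != y.size:
        raise InvalidInputError("rows of X must match length of y")
    if y.std() == 0:
        raise DegenerateResponseError("response has zero variance")
    if n_components > min(Xv.shape[0] - 1, Xv.shape[1]):
        raise InvalidSpecError("n_components too large for the data")
    loadings, var_exp = _fit_loadings(Xv, y, n_components)
    return PLSGeneResult(
        genes=tuple(X.columns),
        loadings=loadings[:, 0],
        variance_explained=var_exp,
    )


def permutation_pvalues(
    X: pd.DataFrame,
    y: np.ndarray,
    n_components: int = 3,
    n_perm: int = 1000,
    rng_seed: int = 0,
) -> PLSGeneResult:
    """Permutation p-values for component-1 gene loadings.

    y is shuffled across regions ``n_perm`` times; for each gene,
    p = (1 + #{|null loading| >= |observed|}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise InvalidSpecError("n_perm must be >= 100")
    base = pls_fit(X, y, n_components)
    observed = np.abs(base.loadings)
    Xv = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(rng_seed)
    exceed = np.zeros(Xv.shape[1], dtype=np.int64)
    for _ in range(n_perm):
        yp = rng.permutation(y)
        null_loadings, _ = _fit_loadings(Xv, yp, n_components)
        exceed += np.abs(null_loadings[:, 0]) >= observed
    p = (1.0 + exceed) / (n_perm + 1.0)
    return PLSGeneResult(
        genes=base.genes,
        loadings=base.loadings,
        variance_explained=base.variance_explained,
        p_values=p,
    )


def aggregate_ranking(
    results: list[PLSGeneResult],
    alpha: float = 0.05,
    mode: str = "all",
) -> pd.DataFrame:
    """Cross-participant ranked gene list.

    ``mode="all"`` keeps genes significant (p < alpha) in *every* participant;
    ``mode="any"`` in at least one.  Surviving genes get their component-1
    loadings averaged across participants and are ordered by descending mean
    loading (ties broken lexicographically by gene id).  An empty list is a
    valid outcome and is returned with a warning.
    """
    if not results:
        raise InvalidInputError("need at least one participant result")
    if mode not in ("all", "any"):
        raise InvalidSpecError("mode must be 'all' or 'any'")
    genes = results[0].genes
    if any(r.genes != genes for r in results):
        raise InvalidInputError("participants disagree on gene identity/order")
    if any(r.p_values is None for r in results):
        raise InvalidInputError("all results need permutation p-values")
    pmat = np.stack([r.p_values for r in results])  # participants x genes
    sig = pmat < alpha
    keep = sig.all(axis=0) if mode == "all" else sig.any(axis=0)
    if not keep.any():
        warnings.warn("no genes survive in the requested participant set",
                      stacklevel=2)
        return pd.DataFrame(columns=["gene", "mean_loading"])
    loadings = np.stack([r.loadings for r in results]).mean(axis=0)
    out = pd.DataFrame(
        {"gene": np.array(genes)[keep], "mean_loading": loadings[keep]}
    )
    return (
        out.sort_values(["mean_loading", "gene"], ascending=[False, True],
                        kind="mergesort")
        .reset_index(drop=True)
    )
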