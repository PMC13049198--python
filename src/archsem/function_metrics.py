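"""Functional similarity, GO-transfer accuracy, and consistency metrics.

Functional similarity S_F between two architectures is the plain Jaccard
of their ancestor-closed GO term sets within one sub-ontology.  Against a
neighborhood, the comparison set is the union of the members' term sets.

Annotation transfer treats that union P as a prediction of the target's
terms T and scores it with precision, recall and the Matthews correlation
coefficient over a fixed term universe (by default the set of terms
annotated to at least one DA in the ontology; the contingency's TN cell is
|universe| − |T ∪ P|).  Per-target scores are macro-averaged; targets with
undefined values (empty neighborhoods, empty unions) are excluded from the
means and counted, never imputed as zero.

Neighborhood *consistency* is measured two ways over sharing
neighborhoods: the mean number of distinct terms in the neighborhood
union, and the mean pairwise S_F over all member pairs.  A supplementary
OLS regression quantifies how much of the target–neighbor S_F variance is
explained by architecture length or term-set size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus_io import AnnotationMap, DAKey
from .neighborhoods import Neighborhood

logger = logging.getLogger("archsem")


@dataclass
class TransferScores:
    """Macro-averaged annotation-transfer accuracy over a target set."""

    precision: float
    recall: float
    mcc: float
    n_targets: int
    n_excluded: int
    per_target: pd.DataFrame | None = None


def functional_similarity(f1: Iterable[str], f2: Iterable[str]) -> float:
    """Jaccard of two GO term sets; two empty sets score 0 (degenerate)."""
    s1, s2 = frozenset(f1), frozenset(f2)
    union = s1 | s2
    if not union:
        logger.debug("functional_similarity: both term sets empty")
        return 0.0
    return len(s1 & s2) / len(union)


def neighborhood_terms(members: Sequence[DAKey], ann: AnnotationMap) -> frozenset[str]:
    """Union of the term sets of the member DAs."""
    out: set[str] = set()
    for m in members:
        out.update(ann.get(m))
    return frozenset(out)


def neighborhood_similarity(
    target, hood: Neighborhood | Sequence[DAKey], ann: AnnotationMap
) -> float:
    """S_F between a target and the union annotation of a neighborhood.

    Accepts a full Neighborhood or any member subset (e.g. the sharing or
    non-sharing split).  Raises on an empty neighborhood: callers exclude
    such targets from means.
    """
    members = hood.members if isinstance(hood, Neighborhood) else tuple(hood)
    if not members:
        raise ValueError("empty neighborhood: similarity undefined")
    tkey = target.domains if hasattr(target, "domains") else tuple(target)
    return functional_similarity(ann.get(tkey), neighborhood_terms(members, ann))


def term_universe(ann: AnnotationMap) -> frozenset[str]:
    """Terms annotated to ≥1 DA: the default MCC contingency universe."""
    out: set[str] = set()
    for terms in ann.terms_for.values():
        out.update(terms)
    return frozenset(out)


def _contingency_scores(T: frozenset, P: frozenset, n_vocab: int):
    tp = len(T & P)
    fp = len(P - T)
    fn = len(T - P)
    tn = n_vocab - len(T | P)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return precision, recall, mcc


def transfer_scores(
    hoods: Mapping[DAKey, Neighborhood],
    ann: AnnotationMap,
    subset: str = "sharing",
    vocab: Iterable[str] | None = None,
) -> TransferScores:
    """Macro-averaged precision/recall/MCC of neighbor-union GO transfer.

    ``subset`` selects which members predict: "sharing", "nonsharing", or
    "full".  Targets whose selected member set is empty are excluded (and
    counted).  ``vocab`` overrides the term universe (default: all terms
    annotated to ≥1 DA in this ontology).
    """
    if subset not in ("sharing", "nonsharing", "full"):
        raise ValueError(f"unknown subset {subset!r}")
    universe = frozenset(vocab) if vocab is not None else term_universe(ann)
    if not universe:
        raise ValueError("empty term universe")
    n_vocab = len(universe)
    rows = []
    n_excluded = 0
    for tkey, hood in hoods.items():
        members = {
            "sharing": hood.sharing,
            "nonsharing": hood.nonsharing,
            "full": hood.members,
        }[subset]
        T = ann.get(tkey)
        if not members or not T:
            n_excluded += 1
            continue
        P = neighborhood_terms(members, ann)
        p, r, m = _contingency_scores(T, P, n_vocab)
        rows.append(("-".join(tkey), p, r, m))
    if not rows:
        return TransferScores(float("nan"), float("nan"), float("nan"), 0, n_excluded)
    df = pd.DataFrame(rows, columns=["target", "precision", "recall", "mcc"])
    return TransferScores(
        precision=float(df["precision"].mean()),
        recall=float(df["recall"].mean()),
        mcc=float(df["mcc"].mean()),
        n_targets=len(df),
        n_excluded=n_excluded,
        per_target=df,
    )


def mean_neighborhood_similarity(
    hoods: Mapping[DAKey, Neighborhood],
    ann: AnnotationMap,
    subset: str = "full",
) -> tuple[float, int, int]:
    """Mean S_F(A, neighborhood) over targets; returns (mean, n, n_excluded)."""
    vals = []
    n_excluded = 0
    for tkey, hood in hoods.items():
        members = {
            "sharing": hood.sharing,
            "nonsharing": hood.nonsharing,
            "full": hood.members,
        }[subset]
        if not members:
            n_excluded += 1
            continue
        vals.append(neighborhood_similarity(tkey, members, ann))
    mean = float(np.mean(vals)) if vals else float("nan")
    return mean, len(vals), n_excluded


@dataclass
class ConsistencyMetrics:
    """Within-neighborhood focus of sharing k-neighborhoods."""

    mean_distinct_terms: float
    mean_pairwise_similarity: float
    n_distinct: int
    n_pairwise: int
    n_excluded_distinct: int = 0
    n_excluded_pairwise: int = 0


def consistency_metrics(
    hoods: Mapping[DAKey, Neighborhood], ann: AnnotationMap
) -> ConsistencyMetrics:
    """Distinct-term counts and mean pairwise S_F in sharing neighborhoods.

    The distinct-term metric needs ≥1 sharing member; the pairwise metric
    needs ≥2 (all unordered pairs are averaged per target, then across
    targets).  Hoods failing a precondition are excluded per metric.
    """
    distinct_vals, pair_vals = [], []
    ex_d = ex_p = 0
    for tkey, hood in hoods.items():
        members = hood.sharing
        if len(members) >= 1:
            distinct_vals.append(len(neighborhood_terms(members, ann)))
        else:
            ex_d += 1
        if len(members) >= 2:
            sims = [
                functional_similarity(ann.get(members[i]), ann.get(members[j]))
                for i in range(len(members))
                for j in range(i + 1, len(members))
            ]
            pair_vals.append(float(np.mean(sims)))
        else:
            ex_p += 1
    return ConsistencyMetrics(
        mean_distinct_terms=float(np.mean(distinct_vals)) if distinct_vals else float("nan"),
        mean_pairwise_similarity=float(np.mean(pair_vals)) if pair_vals else float("nan"),
        n_distinct=len(distinct_vals),
        n_pairwise=len(pair_vals),
        n_excluded_distinct=ex_d,
        n_excluded_pairwise=ex_p,
    )


@dataclass
class RegressionResult:
    """OLS of target–neighbor S_F on a covariate."""

    r_squared: float
    params: pd.Series | None
    n: int


def length_dependence(
    response: Sequence[float], covariates: np.ndarray | Sequence[float]
) -> RegressionResult:
    """Ordinary least squares of S_F values on one or more covariates.

    Returns the coefficient table and R².  A constant covariate leaves R²
    undefined (reported as NaN).
    """
    import statsmodels.api as sm

    y = np.asarray(response, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(np.ptp(X, axis=0) == 0):
        logger.warning("length_dependence: constant covariate; R² undefined")
        return RegressionResult(r_squared=float("nan"), params=None, n=y.size)
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    return RegressionResult(
        r_squared=float(fit.rsquared), params=fit.params, n=int(fit.nobs)
    )


def target_neighbor_pairs(
    hoods: Mapping[DAKey, Neighborhood], ann: AnnotationMap
) -> pd.DataFrame:
    """Flat table of sharing target–neighbor pairs with S_F and covariates."""
    rows = []
    for tkey, hood in hoods.items():
        for mkey in hood.sharing:
            rows.append(
                (
                    "-".join(tkey),
                    "-".join(mkey),
                    functional_similarity(ann.get(tkey), ann.get(mkey)),
                    len(tkey),
                    len(mkey),
                    len(ann.get(tkey)),
                    len(ann.get(mkey)),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "target",
            "neighbor",
            "similarity",
            "target_length",
            "neighbor_length",
            "target_terms",
            "neighbor_terms",
        ],
    )
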