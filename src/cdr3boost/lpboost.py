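"""1-norm soft-margin boosting (LPBoost) solved by column generation.

The classifier is a convex combination of signed p-mer term-frequency
features. With H the m x n matrix of weak-learner outputs and y_i in
{-1, +1} the sample labels, the primal LP is

    max_{a, xi, rho}  rho - D * sum_i xi_i
    s.t.  y_i (H_i a) + xi_i >= rho        i = 1..m
          sum_j a_j = 1,  a_j >= 0,  xi_i >= 0

and its dual is

    min_{u, beta}  beta
    s.t.  sum_i u_i y_i H_ij <= beta       j = 1..n
          sum_i u_i = 1,  0 <= u_i <= D.

D > 1/m is the per-sample misclassification penalty cap. Column generation
keeps a restricted set of columns, repeatedly solving the restricted master
and adding the weak learner most violating the dual constraint
(argmax_j sum_i u_i y_i H_ij) until no violation exceeds beta within
tolerance — at which point the restricted optimum is the global optimum.

The feature dictionary is *signed*: each p-mer u contributes the columns
(+u) and (-u) with outputs +f_u and -f_u, so the nonnegative weights a can
express negative effective coefficients a(+u) - a(-u).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linprog

from .features import index_to_pmer, pmer_to_index

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 500
#: Default soft-margin fraction nu; D = 1 / (nu * m) unless given explicitly.
#: With many highly correlated subsample rows per repertoire the effective
#: sample count is the number of mice, so a large slack fraction guards
#: against fitting subsample noise and keeps solutions sparse.
DEFAULT_NU = 0.8


class SolverError(RuntimeError):
    """The LP solver failed on a restricted master problem."""


def penalty_from_nu(m: int, nu: float = DEFAULT_NU) -> float:
    """Misclassification cap D = 1/(nu*m), clipped into (1/m, 1].

    nu is the asymptotic fraction of margin errors tolerated; expressing D
    this way keeps its meaning stable as the number of training rows m
    changes (e.g. mice-as-rows vs subsamples-as-rows).
    """
    if not 0 < nu <= 1:
        raise ValueError(f"nu must be in (0, 1], got {nu}")
    return float(min(1.0, max(1.0 / (nu * m), np.nextafter(1.0 / m, 1.0))))


@dataclass
class RestrictedSolution:
    """Optimal primal/dual variables of one restricted master solve."""

    a: np.ndarray  # weights over the restricted columns, sum 1
    rho: float
    xi: np.ndarray
    u: np.ndarray
    beta: float
    D: float

    @property
    def duality_gap(self) -> float:
        """|rho - D*sum(xi) - beta|; ~0 at optimality (strong duality)."""
        return abs(self.rho - self.D * self.xi.sum() - self.beta)


def solve_restricted_master(
    H_sub: np.ndarray, y: np.ndarray, D: float
) -> RestrictedSolution:
    """Solve the boosting LP restricted to the given columns.

    The LP is solved in its dual form (m+1 variables, one constraint per
    column); the primal weights are the constraint marginals and (rho, xi)
    follow in closed form from the resulting margins: rho is the
    ceil(1/D)-th smallest margin and xi_i = max(0, rho - margin_i).
    """
    H_sub = np.asarray(H_sub, dtype=float)
    y = np.asarray(y, dtype=float)
    m, k = H_sub.shape
    if k < 1:
        raise ValueError("restricted master needs at least one column")
    if D <= 0:
        raise ValueError(f"D must be positive, got {D}")
    if not set(np.unique(y)) <= {-1.0, 1.0}:
        raise ValueError("labels must be in {-1, +1}")

    # variables: u_1..u_m, beta
    c = np.zeros(m + 1)
    c[-1] = 1.0
    A_ub = np.column_stack([(H_sub * y[:, None]).T, -np.ones(k)])
    b_ub = np.zeros(k)
    A_eq = np.concatenate([np.ones(m), [0.0]])[None, :]
    b_eq = [1.0]
    bounds = [(0.0, D)] * m + [(None, None)]
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
        method="highs",
    )
    if not res.success:
        raise SolverError(f"restricted master failed: {res.message}")

    u = np.clip(res.x[:m], 0.0, D)
    beta = float(res.fun)
    a = np.clip(-res.ineqlin.marginals, 0.0, None)
    s = a.sum()
    if s <= 0:
        raise SolverError("degenerate restricted master: zero weight vector")
    a = a / s

    margins = y * (H_sub @ a)
    j = int(min(m, max(1, np.ceil(1.0 / D - 1e-12))))
    rho = float(np.sort(margins)[j - 1])
    xi = np.maximum(rho - margins, 0.0)
    return RestrictedSolution(a=a, rho=rho, xi=xi, u=u, beta=beta, D=D)


def most_violated_column(
    u: np.ndarray, y: np.ndarray, F: np.ndarray
) -> tuple[tuple[int, int], float]:
    """The signed feature maximizing the dual score sum_i u_i y_i H_ij.

    F is the m x n_pmers unsigned feature matrix; the signed dictionary
    orders all (+) columns by p-mer rank, then all (-) columns, and ties
    are broken by that order. Returns ((pmer_index, sign), score); the
    score is always >= 0 by sign symmetry.
    """
    if F.shape[1] < 1:
        raise ValueError("empty weak-learner dictionary")
    v = (np.asarray(u) * np.asarray(y)) @ F
    j_plus = int(np.argmax(v))
    j_minus = int(np.argmax(-v))
    if v[j_plus] >= -v[j_minus]:
        return (j_plus, +1), float(v[j_plus])
    return (j_minus, -1), float(-v[j_minus])


@dataclass
class LPBoostModel:
    """A trained 1-norm soft-margin boosting classifier.

    ``columns`` are (pmer_index, sign) pairs of the restricted dictionary in
    the order they were generated; ``a`` the corresponding weights. The
    decision rule is sign(sum_j a_j * sign_j * f[pmer_j] - theta), where
    theta is the midpoint of the class-wise mean training scores and f the
    (normalized) p-mer term-frequency vector of a sample.
    """

    p: int
    columns: list[tuple[int, int]]
    a: np.ndarray
    rho: float
    beta: float
    D: float
    theta: float
    xi: np.ndarray
    u: np.ndarray
    converged: bool
    n_iter: int
    duality_gap: float
    active_history: list[int] = field(default_factory=list)

    @property
    def active_columns(self) -> list[tuple[str, int, float]]:
        """(p-mer, sign, weight) for columns with non-zero weight."""
        return [
            (index_to_pmer(j, self.p), s, float(w))
            for (j, s), w in zip(self.columns, self.a)
            if w > 1e-9
        ]

    def effective_coefficients(self) -> dict[str, float]:
        """Per-p-mer net coefficient a(+) - a(-) over active columns."""
        coef: dict[str, float] = {}
        for pmer, s, w in self.active_columns:
            coef[pmer] = coef.get(pmer, 0.0) + s * w
        return {k: v for k, v in coef.items() if abs(v) > 1e-9}

    def decision_scores(self, F: np.ndarray) -> np.ndarray:
        """Unthresholded scores sum_j a_j h_j(x) for rows of F."""
        F = np.atleast_2d(F)
        scores = np.zeros(F.shape[0])
        for (j, s), w in zip(self.columns, self.a):
            if w > 0:
                scores += w * s * F[:, j]
        return scores


def predict(model: LPBoostModel, F: np.ndarray) -> np.ndarray:
    """Class labels for feature rows; ties at the threshold go to +1."""
    scores = model.decision_scores(F)
    return np.where(scores - model.theta >= 0, 1, -1)


def lpboost_train(
    F: np.ndarray,
    y: np.ndarray,
    D: float | None = None,
    nu: float = DEFAULT_NU,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    p: int = 3,
) -> LPBoostModel:
    """Train LPBoost by column generation over the signed p-mer dictionary.

    F is the m x 20**p matrix of per-sample term frequencies; y the labels.
    If D is None it is set to 1/(nu*m). Starting from uniform sample
    weights u = 1/m and beta = 0, the loop adds the most violated signed
    column and re-solves the restricted master until no dual score exceeds
    beta + tol (the global-optimality certificate) or max_iter is reached.
    """
    F = np.asarray(F, dtype=float)
    y = np.asarray(y, dtype=float)
    m = F.shape[0]
    if m < 2 or len(set(np.unique(y))) < 2:
        raise ValueError("training needs >= 2 samples with both labels present")
    if D is None:
        D = penalty_from_nu(m, nu)
    elif D * m < 1.0:
        # dual needs sum(u)=1 with u_i <= D, so D must exceed 1/m
        clipped = float(np.nextafter(1.0 / m, 1.0))
        logger.warning("D=%g is below 1/m=%g; clipping to feasibility", D, 1.0 / m)
        D = clipped

    u = np.full(m, 1.0 / m)
    beta = 0.0
    columns: list[tuple[int, int]] = []
    col_set: set[tuple[int, int]] = set()
    sol: RestrictedSolution | None = None
    converged = False
    active_history: list[int] = []
    n_iter = 0

    while n_iter < max_iter:
        n_iter += 1
        col, score = most_violated_column(u, y, F)
        if columns and score <= beta + tol:
            converged = True
            break
        if col in col_set:
            # numerically stalled: the optimal certificate holds within
            # solver precision even though score > beta + tol marginally
            converged = True
            logger.debug("column generation stalled on duplicate column %s", col)
            break
        columns.append(col)
        col_set.add(col)
        H_sub = np.column_stack([s * F[:, j] for j, s in columns])
        sol = solve_restricted_master(H_sub, y, D)
        u, beta = sol.u, sol.beta
        active_history.append(int((sol.a > 1e-9).sum()))

    if sol is None:
        raise SolverError("column generation produced no restricted solve")
    if not converged:
        logger.warning("LPBoost reached max_iter=%d without certificate", max_iter)

    scores = np.zeros(m)
    for (j, s), w in zip(columns, sol.a):
        scores += w * s * F[:, j]
    theta = float((scores[y > 0].mean() + scores[y < 0].mean()) / 2.0)

    return LPBoostModel(
        p=p,
        columns=columns,
        a=sol.a,
        rho=sol.rho,
        beta=sol.beta,
        D=D,
        theta=theta,
        xi=sol.xi,
        u=sol.u,
        converged=converged,
        n_iter=n_iter,
        duality_gap=sol.duality_gap,
        active_history=active_history,
    )


def solve_full_lp(F: np.ndarray, y: np.ndarray, D: float) -> float:
    """Directly solve the primal over the *entire* signed dictionary.

    Intended as an independent check of the column-generation optimum on
    small instances; returns the optimal objective rho - D*sum(xi).
    """
    F = np.asarray(F, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = F.shape
    H = np.concatenate([F, -F], axis=1)  # signed dictionary
    n2 = 2 * n
    # variables: a (n2), xi (m), rho; minimize -rho + D*sum(xi)
    c = np.concatenate([np.zeros(n2), np.full(m, D), [-1.0]])
    # -y_i H_i a - xi_i + rho <= 0
    A_ub = np.column_stack([-(y[:, None] * H), -np.eye(m), np.ones(m)])
    b_ub = np.zeros(m)
    A_eq = np.concatenate([np.ones(n2), np.zeros(m), [0.0]])[None, :]
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=[1.0],
        bounds=[(0, None)] * (n2 + m) + [(None, None)],
        method="highs",
    )
    if not res.success:
        raise SolverError(f"full LP failed: {res.message}")
    return float(-res.fun)


def write_model(model: LPBoostModel, path: str | Path) -> None:
    """Serialize a model as TSV: a header block then active columns."""
    lines = [
        f"# rho\t{model.rho!r}",
        f"# beta\t{model.beta!r}",
        f"# D\t{model.D!r}",
        f"# theta\t{model.theta!r}",
        f"# p\t{model.p}",
        f"# converged\t{int(model.converged)}",
        f"# n_iter\t{model.n_iter}",
        "feature_pmer\tsign\tweight",
    ]
    for pmer, s, w in model.active_columns:
        lines.append(f"{pmer}\t{'+' if s > 0 else '-'}\t{w!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_model(path: str | Path) -> LPBoostModel:
    """Read a model written by :func:`write_model`.

    Only the decision-relevant fields (columns, weights, theta, p) and the
    recorded scalars round-trip; solver internals (u, xi) are not stored.
    """
    header: dict[str, str] = {}
    columns: list[tuple[int, int]] = []
    weights: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# "):
                key, val = line[2:].split("\t")
                header[key] = val
            elif line and not line.startswith("feature_pmer"):
                pmer, sign, w = line.split("\t")
                columns.append((pmer_to_index(pmer), +1 if sign == "+" else -1))
                weights.append(float(w))
    m0 = np.empty(0)
    return LPBoostModel(
        p=int(header["p"]),
        columns=columns,
        a=np.asarray(weights),
        rho=float(header["rho"]),
        beta=float(header["beta"]),
        D=float(header["D"]),
        theta=float(header["theta"]),
        xi=m0,
        u=m0,
        converged=bool(int(header["converged"])),
        n_iter=int(header["n_iter"]),
        duality_gap=0.0,
    )


def split_repertoire_sequences(
    sequences: list[str], rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """Randomly split unique sequences into two disjoint halves."""
    perm = rng.permutation(len(sequences))
    half = len(sequences) // 2
    seqs = np.asarray(sequences, dtype=object)
    return list(seqs[perm[:half]]), list(seqs[perm[half:]])


def select_D(
    cohort,
    grid: list[float] | None = None,
    seed: int = 0,
    **loo_kwargs,
):
    """Choose the penalty D by the disjoint-split validation protocol.

    Each mouse's unique sequences are split uniformly at random into two
    disjoint halves sharing no sequences. For every grid value a
    leave-one-mouse-out run is scored on half 1 only; the best-accuracy
    value is returned (ties favour the smaller D), to be applied by the
    caller to held-back half 2.

    Returns a ``SelectDResult`` with the chosen D, both half-cohorts and
    the per-grid accuracies.
    """
    from .evaluation import SelectDResult, loo_classify  # deferred: avoids cycle
    from .repertoires import Cohort, Repertoire

    rng = np.random.default_rng(seed)
    half1, half2 = [], []
    for rep in cohort.labelled():
        if len(rep) < 2:
            raise ValueError(f"mouse {rep.mouse_id} has fewer than 2 sequences")
        s1, s2 = split_repertoire_sequences(rep.sequences(), rng)
        counts = rep.counts()
        kw = dict(label=rep.label, timepoint=rep.timepoint)
        from .repertoires import Cdr3

        half1.append(Repertoire(rep.mouse_id, clones=[Cdr3(s, counts[s]) for s in s1], **kw))
        half2.append(Repertoire(rep.mouse_id, clones=[Cdr3(s, counts[s]) for s in s2], **kw))
    c1, c2 = Cohort(half1), Cohort(half2)

    if grid is None:
        grid = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
    accuracies = {}
    for d in grid:
        result = loo_classify(c1, D=d, seed=seed, **loo_kwargs)
        accuracies[d] = result.accuracy
    best = max(sorted(accuracies), key=lambda d: (accuracies[d], -d))
    return SelectDResult(best_D=best, half1=c1, half2=c2, accuracies=accuracies)
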