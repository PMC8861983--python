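"""Doubly repeated-measures linear mixed model for 3D implant migration.

The model treats both the follow-up visit and the migration axis as repeated
measures: each subject contributes one response per observed
(visit, axis) cell, and the within-subject covariance over the cell grid is
estimated by REML under an unstructured, separable (Kronecker) or diagonal
structure (:mod:`rsamix.covariance`).  Fixed effects are specified by a
formula over treatment group, visit, axis and optional covariates; missing
cells simply drop out of the subject's likelihood contribution, so no
imputation is needed.  Small-sample F-tests use the Kenward-Roger adjustment
(:mod:`rsamix.inference`), which makes the joint group test reduce exactly
to classical results (two-sample t, Hotelling T^2) in balanced complete
cases.

The marginal log-likelihood of subject i with observed cells o_i is
N(y_i; X_i beta, V[o_i, o_i]); REML profiles beta and maximizes over the
covariance parameters with an analytic-gradient quasi-Newton method on the
log-Cholesky scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from patsy import build_design_matrices, dmatrix
from scipy import optimize, stats

from .config import AXES
from .covariance import get_structure, nearest_pd

__all__ = [
    "build_model_frame",
    "fit_mv_lmm",
    "LmmFit",
    "ConvergenceError",
    "test_3d_group_effect",
    "slice_by_axis",
    "simplify_model",
    "lsmeans",
    "standardize_by_axis",
    "hotelling_two_sample",
    "hotelling_two_sample_batch",
]

DEFAULT_FORMULA = "value ~ group * week * axis"


class ConvergenceError(RuntimeError):
    """REML optimization failed; carries the last gradient norm."""

    def __init__(self, msg: str, grad_norm: float):
        super().__init__(msg)
        self.grad_norm = grad_norm


# ---------------------------------------------------------------------------
# model frame
# ---------------------------------------------------------------------------

def build_model_frame(
    observations: pd.DataFrame,
    exclude: Iterable | None = None,
    axes: Sequence[str] = AXES,
    group_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long subject x visit x axis table from wide per-visit observations.

    Parameters
    ----------
    observations
        Wide table with columns ``subject``, ``group``, ``week``, one column
        per migration axis, and optionally ``bmd_class``.
    exclude
        Subject ids to drop (a cohort view, e.g. the without-outliers
        cohort); never mutates the input.
    group_order
        Category order for the treatment factor; the first level is the
        reference.  Defaults to placing ``placebo``/``control`` first when
        present, otherwise sorted order.

    Missing cells (NaN) are dropped, not imputed.
    """
    obs = observations.copy()
    if exclude:
        obs = obs[~obs["subject"].isin(set(exclude))]
    id_vars = [c for c in ("subject", "group", "week", "bmd_class") if c in obs]
    missing = {"subject", "group", "week"} - set(id_vars)
    if missing:
        raise ValueError(f"observations lack required columns: {sorted(missing)}")
    frame = obs.melt(
        id_vars=id_vars, value_vars=list(axes), var_name="axis", value_name="value"
    ).dropna(subset=["value"])
    if frame.duplicated(["subject", "week", "axis"]).any():
        raise ValueError("duplicate (subject, week, axis) cells in observations")

    groups = list(pd.unique(obs["group"]))
    if group_order is None:
        ref = [g for g in groups if str(g).lower() in ("placebo", "control")]
        group_order = (ref + sorted(g for g in groups if g not in ref)) if ref else sorted(groups)
    frame["group"] = pd.Categorical(frame["group"], categories=group_order)
    weeks = sorted(frame["week"].unique())
    frame["week"] = pd.Categorical(frame["week"], categories=weeks, ordered=True)
    frame["axis"] = pd.Categorical(
        frame["axis"], categories=[a for a in axes if a in set(frame["axis"])]
    )
    if "bmd_class" in frame:
        frame["bmd_class"] = pd.Categorical(frame["bmd_class"])
    return frame.sort_values(["subject", "week", "axis"]).reset_index(drop=True)


def standardize_by_axis(frame: pd.DataFrame) -> pd.DataFrame:
    """Divide each axis's responses by its pooled SD.

    Puts millimetre and degree axes on a common dimensionless scale for the
    blended "3D migration" least-squares means display.
    """
    out = frame.copy()
    sd = out.groupby("axis", observed=True)["value"].transform("std")
    out["value"] = out["value"] / sd.replace(0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# REML fitting
# ---------------------------------------------------------------------------

@dataclass
class _Pattern:
    """Subjects sharing one missingness pattern over the cell grid."""

    cells: np.ndarray          # observed cell indices, sorted
    X: np.ndarray              # (n_subj, k, p)
    y: np.ndarray              # (n_subj, k)
    subjects: list


def _group_patterns(frame, X, cell_index) -> list[_Pattern]:
    patterns: dict[tuple, list] = {}
    for sid, idx in frame.groupby("subject", observed=True, sort=True).indices.items():
        cells = cell_index[idx]
        order = np.argsort(cells)
        idx = np.asarray(idx)[order]
        key = tuple(cells[order])
        patterns.setdefault(key, []).append((sid, idx))
    out = []
    for key, members in patterns.items():
        Xs = np.stack([X[idx] for _, idx in members])
        ys = np.stack([frame["value"].to_numpy(float)[idx] for _, idx in members])
        out.append(_Pattern(np.array(key), Xs, ys, [sid for sid, _ in members]))
    return out


def _moment_start(patterns: list[_Pattern], n_cells: int, p: int) -> np.ndarray:
    """Pairwise-complete covariance of OLS residuals as a starting value."""
    X = np.vstack([pat.X.reshape(-1, p) for pat in patterns])
    y = np.concatenate([pat.y.ravel() for pat in patterns])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    S = np.zeros((n_cells, n_cells))
    C = np.zeros((n_cells, n_cells))
    for pat in patterns:
        r = pat.y - pat.X @ beta
        ix = np.ix_(pat.cells, pat.cells)
        S[ix] += r.T @ r
        C[ix] += len(pat.subjects)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(C > 0, S / np.maximum(C, 1), 0.0)
    # cells never observed: give them the average observed variance
    d = np.diag(S).copy()
    d[d <= 0] = max(d[d > 0].mean() if np.any(d > 0) else 1.0, 1e-6)
    np.fill_diagonal(S, d)
    return nearest_pd(S)


class LmmFit:
    """A converged REML fit of the doubly repeated-measures model.

    Attributes
    ----------
    beta, beta_names : fixed-effect estimates and their column names.
    vcov : GLS covariance of ``beta`` (inverse weighted cross-product).
    V : estimated within-subject covariance over the full cell grid.
    T, A : Kronecker factors (``None`` unless the structure is separable).
    loglik : restricted log-likelihood at the optimum (additive constant
        ``-n/2 log(2 pi)`` omitted).
    """

    def __init__(self, frame, formula, design_info, structure, theta,
                 patterns, beta, vcov, loglik, grad_norm, n_iter, trace):
        self.frame = frame
        self.formula = formula
        self.design_info = design_info
        self.structure = structure
        self.theta = theta
        self.patterns = patterns
        self.beta = beta
        self.vcov = vcov
        self.loglik = loglik
        self.grad_norm = grad_norm
        self.n_iter = n_iter
        self.objective_trace = trace
        self.V = structure.build(theta)
        self.T, self.A = (
            structure.factors(theta) if hasattr(structure, "factors") else (None, None)
        )
        self.weeks = list(frame["week"].cat.categories)
        self.axes = list(frame["axis"].cat.categories)
        self._kr_cache = None

    # -- descriptive -----------------------------------------------------
    @property
    def beta_names(self) -> list[str]:
        return list(self.design_info.column_names)

    @property
    def term_names(self) -> list[str]:
        return [t for t in self.design_info.term_names if t != "Intercept"]

    def params(self) -> pd.Series:
        return pd.Series(self.beta, index=self.beta_names)

    def n_subjects(self) -> int:
        return sum(len(p.subjects) for p in self.patterns)

    def n_obs(self) -> int:
        return len(self.frame)

    # -- inference helpers (delegating to rsamix.inference) ---------------
    def _kr(self):
        from .inference import KrWorkspace

        if self._kr_cache is None:
            self._kr_cache = KrWorkspace(self)
        return self._kr_cache

    @property
    def vcov_adj(self) -> np.ndarray:
        """Kenward-Roger adjusted covariance of the fixed effects."""
        return self._kr().phi_adj

    def test_contrast(self, L: np.ndarray):
        """KR-adjusted F-test of the linear hypothesis L beta = 0."""
        from .inference import kenward_roger_test

        return kenward_roger_test(self, L)

    def contrast_for_terms(self, terms: Sequence[str]) -> np.ndarray:
        """Rows selecting all design columns belonging to the given terms."""
        slices = self.design_info.term_name_slices
        cols: list[int] = []
        for t in terms:
            if t not in slices:
                raise KeyError(f"term {t!r} not in model ({self.term_names})")
            cols.extend(range(*slices[t].indices(len(self.beta))))
        if not cols:
            raise ValueError("no columns selected")
        L = np.zeros((len(cols), len(self.beta)))
        L[np.arange(len(cols)), cols] = 1.0
        return L

    def test_terms(self, terms: Sequence[str]):
        return self.test_contrast(self.contrast_for_terms(terms))

    def design_rows(self, data: pd.DataFrame) -> np.ndarray:
        (m,) = build_design_matrices([self.design_info], data)
        return np.asarray(m)

    def summary(self) -> str:
        lines = [
            f"Doubly repeated-measures LMM ({self.structure.name} covariance)",
            f"formula: {self.formula}",
            f"subjects: {self.n_subjects()}  cells: {self.n_obs()}  "
            f"REML loglik: {self.loglik:.3f}",
        ]
        se = np.sqrt(np.diag(self.vcov))
        for name, b, s in zip(self.beta_names, self.beta, se):
            lines.append(f"  {name:45s} {b:10.4f} (SE {s:.4f})")
        return "\n".join(lines)


def _reml_obj_grad(theta, structure, patterns, p, want_grad=True):
    V, dVs = (
        structure.build_with_grad(theta) if want_grad else (structure.build(theta), None)
    )
    n_free = structure.n_free
    logdet = 0.0
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    cache = []
    for pat in patterns:
        S = V[np.ix_(pat.cells, pat.cells)]
        try:
            cF = np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            return np.inf, np.full(n_free, np.nan), None
        n_i = len(pat.subjects)
        logdet += 2.0 * n_i * np.log(np.diag(cF)).sum()
        Sinv = np.linalg.inv(S)
        U = np.einsum("kl,nlp->nkp", Sinv, pat.X)       # Sigma^-1 X_i
        XtViX += np.einsum("nkp,nkq->pq", pat.X, U)
        XtViy += np.einsum("nkp,nk->p", U, pat.y)
        cache.append((pat, Sinv, U))
    try:
        cXtViX = np.linalg.cholesky(XtViX)
    except np.linalg.LinAlgError:
        return np.inf, np.full(n_free, np.nan), None
    beta = np.linalg.solve(XtViX, XtViy)
    C = np.linalg.inv(XtViX)
    logdet_fix = 2.0 * np.log(np.diag(cXtViX)).sum()
    quad = 0.0
    resid_cache = []
    for pat, Sinv, U in cache:
        r = pat.y - pat.X @ beta
        e = np.einsum("kl,nl->nk", Sinv, r)             # Sigma^-1 r_i
        quad += np.einsum("nk,nk->", r, e)
        resid_cache.append((pat, Sinv, U, e))
    neg2ll = logdet + logdet_fix + quad
    obj = 0.5 * neg2ll
    if not want_grad:
        return obj, None, (beta, C)
    grad = np.zeros(n_free)
    for j, dV in enumerate(dVs):
        g = 0.0
        for pat, Sinv, U, e in resid_cache:
            dS = dV[np.ix_(pat.cells, pat.cells)]
            n_i = len(pat.subjects)
            g += n_i * np.einsum("kl,lk->", Sinv, dS)
            M = np.einsum("nkp,pq->nkq", U, C)
            g -= np.einsum("nkq,kl,nlq->", M, dS, U)
            g -= np.einsum("nk,kl,nl->", e, dS, e)
        grad[j] = 0.5 * g
    return obj, grad, (beta, C)


def fit_mv_lmm(
    frame: pd.DataFrame,
    formula: str = DEFAULT_FORMULA,
    cov_structure: str = "kronecker_un",
    max_iter: int = 500,
    grad_tol: float = 1e-6,
    fail_tol: float = 1e-3,
) -> LmmFit:
    """Fit the multivariate migration model by REML.

    Parameters
    ----------
    frame
        Long model frame from :func:`build_model_frame` (categorical
        ``group``/``week``/``axis``, numeric ``value``; missing cells simply
        absent).
    formula
        patsy formula for the fixed effects (response must be ``value``).
    cov_structure
        ``"kronecker_un"`` (default, visit factor x axis factor),
        ``"unstructured"``/``"full_un"`` or ``"diagonal"``.
    grad_tol, fail_tol
        Target and hard-failure thresholds on the max-norm of the REML
        gradient; exceeding ``fail_tol`` after ``max_iter`` iterations
        raises :class:`ConvergenceError`.
    """
    frame = frame.reset_index(drop=True)
    for col in ("group", "week", "axis"):
        if col in frame and not isinstance(frame[col].dtype, pd.CategoricalDtype):
            raise TypeError(f"column {col!r} must be categorical; use build_model_frame")
    groups = frame["group"].cat.categories if "group" in frame else []
    if "group" in frame:
        counts = frame.groupby("group", observed=False)["subject"].nunique()
        if (counts < 2).any() and "group" in formula:
            raise ValueError("need at least 2 subjects per treatment group")

    rhs = formula.split("~", 1)[1]
    design = dmatrix(rhs, frame, return_type="dataframe")
    X = np.asarray(design)
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effects design is rank deficient")

    weeks = list(frame["week"].cat.categories)
    axes = list(frame["axis"].cat.categories)
    week_idx = frame["week"].cat.codes.to_numpy()
    axis_idx = frame["axis"].cat.codes.to_numpy()
    cell_index = week_idx * len(axes) + axis_idx

    structure = get_structure(cov_structure, len(weeks), len(axes))
    patterns = _group_patterns(frame, X, cell_index)
    S0 = _moment_start(patterns, structure.n_cells, p)
    theta0 = structure.start(S0)

    trace: list[float] = []
    last = {}

    def fun(theta):
        obj, grad, aux = _reml_obj_grad(theta, structure, patterns, p)
        if np.isfinite(obj):
            last["aux"] = aux
            last["theta"] = theta.copy()
        return obj, (grad if grad is not None else np.zeros_like(theta))

    def cb(theta):
        obj, _, _ = _reml_obj_grad(theta, structure, patterns, p, want_grad=False)
        trace.append(-obj)

    res = optimize.minimize(
        fun, theta0, jac=True, method="L-BFGS-B", callback=cb,
        options={"maxiter": max_iter, "maxcor": 30, "ftol": 1e-15,
                 "gtol": grad_tol / 10.0},
    )
    theta = res.x
    obj, grad, aux = _reml_obj_grad(theta, structure, patterns, p)
    gnorm = float(np.max(np.abs(grad)))
    if not np.isfinite(obj) or aux is None:
        raise ConvergenceError("REML objective not finite at final iterate", gnorm)
    if gnorm > fail_tol:
        raise ConvergenceError(
            f"REML did not converge in {max_iter} iterations "
            f"(max |gradient| = {gnorm:.3g})",
            gnorm,
        )
    if gnorm > grad_tol * 100:
        warnings.warn(
            f"REML gradient norm {gnorm:.3g} above target {grad_tol:.0e}",
            stacklevel=2,
        )
    beta, C = aux
    return LmmFit(
        frame, formula, design.design_info, structure, theta, patterns,
        beta, C, -obj, gnorm, res.nit, trace,
    )


# ---------------------------------------------------------------------------
# model-level tests and summaries
# ---------------------------------------------------------------------------

def _terms_involving(fit: LmmFit, factor: str) -> list[str]:
    return [t for t in fit.term_names if factor in _term_factors(t)]


def _term_factors(term: str) -> set[str]:
    return {f.strip() for f in term.split(":")}


def test_3d_group_effect(fit: LmmFit, factor: str = "group"):
    """Joint KR F-test of every retained fixed-effect term involving the
    treatment group — the single "3D migration" comparison."""
    terms = _terms_involving(fit, factor)
    if not terms:
        raise ValueError(f"model contains no terms involving {factor!r}")
    return fit.test_terms(terms)


def _margin_grid(fit: LmmFit, margins: Sequence[str]) -> pd.DataFrame:
    """All margin-level combinations crossed with equal-weight averages of
    the remaining model factors."""
    frame = fit.frame
    factor_cols = [
        c for c in ("group", "week", "axis", "bmd_class")
        if c in frame and c in fit.formula
    ]
    levels = {c: list(frame[c].cat.categories) for c in factor_cols}
    margin_levels = [(m, levels[m]) for m in margins]
    rest = [c for c in factor_cols if c not in margins]
    grids = []
    import itertools

    for combo in itertools.product(*(lv for _, lv in margin_levels)):
        rows = []
        for rest_combo in itertools.product(*(levels[c] for c in rest)):
            row = dict(zip(margins, combo))
            row.update(dict(zip(rest, rest_combo)))
            rows.append(row)
        g = pd.DataFrame(rows)
        for c in factor_cols:
            g[c] = pd.Categorical(g[c], categories=levels[c])
        grids.append((dict(zip(margins, combo)), g))
    return grids


def lsmeans(
    fit: LmmFit, margins: Sequence[str] = ("group", "week"), level: float = 0.95
) -> pd.DataFrame:
    """Least-squares (estimated marginal) means over the requested margins.

    Non-margin factors are averaged with equal weights over their levels.
    Confidence intervals use the KR-adjusted covariance with per-contrast
    KR denominator degrees of freedom.
    """
    from .inference import kr_contrast_ci

    out = []
    for combo, grid in _margin_grid(fit, margins):
        l = fit.design_rows(grid).mean(axis=0)
        est, se, df, lo, hi = kr_contrast_ci(fit, l, level)
        out.append({**combo, "estimate": est, "se": se, "df": df,
                    "ci_lower": lo, "ci_upper": hi})
    return pd.DataFrame(out)


def slice_by_axis(
    fit: LmmFit, factor: str = "group", level: float = 0.95,
    per_week: bool = False,
) -> pd.DataFrame:
    """Treatment-effect slices: the group difference within each migration
    axis, averaged over visits with equal weights (or per visit).

    Returns one row per axis (x week) with the LS-mean difference, its KR
    confidence interval and the KR F-test of the slice.
    """
    from .inference import kenward_roger_test, kr_contrast_ci

    frame = fit.frame
    glev = list(frame[factor].cat.categories)
    if len(glev) != 2:
        raise ValueError("slices require exactly two treatment groups")
    rows = []
    weeks = fit.weeks if per_week else [None]
    for ax in fit.axes:
        for wk in weeks:
            margins = {"axis": ax, factor: glev[1]}
            if wk is not None:
                margins["week"] = wk
            sel = [factor, "axis"] + (["week"] if wk is not None else [])
            grids = {g: None for g in glev}
            for g in glev:
                combos = _margin_grid(fit, sel)
                want = {**{"axis": ax, factor: g}, **({"week": wk} if wk is not None else {})}
                for combo, grid in combos:
                    if combo == want:
                        grids[g] = grid
            l = fit.design_rows(grids[glev[1]]).mean(axis=0) - fit.design_rows(
                grids[glev[0]]
            ).mean(axis=0)
            est, se, df, lo, hi = kr_contrast_ci(fit, l, level)
            test = kenward_roger_test(fit, l[None, :])
            row = {"axis": ax, "estimate": est, "se": se,
                   "ci_lower": lo, "ci_upper": hi,
                   "F": test.F, "num_df": test.num_df,
                   "denom_df": test.denom_df, "p": test.p}
            if wk is not None:
                row["week"] = wk
            rows.append(row)
    return pd.DataFrame(rows)


def simplify_model(fit: LmmFit, alpha_keep: float = 0.05) -> LmmFit:
    """Backward elimination of non-significant interaction terms.

    Tests each currently removable interaction (one not contained in a
    retained higher-order interaction) with the KR F-test and drops the one
    with the largest p >= ``alpha_keep``; repeats until none qualifies.
    Main effects are never dropped.  Deterministic: largest p first, ties
    broken by term name.
    """
    current = fit
    while True:
        terms = current.term_names
        inters = [t for t in terms if len(_term_factors(t)) > 1]
        removable = [
            t for t in inters
            if not any(
                _term_factors(t) < _term_factors(u) for u in inters if u != t
            )
        ]
        if not removable:
            return current
        pvals = []
        for t in removable:
            res = current.test_terms([t])
            pvals.append((res.p, t))
        pvals.sort(key=lambda x: (-x[0], x[1]))
        worst_p, worst = pvals[0]
        if worst_p < alpha_keep:
            return current
        kept = [t for t in terms if t != worst]
        formula = "value ~ " + (" + ".join(kept) if kept else "1")
        current = fit_mv_lmm(
            current.frame, formula, cov_structure=current.structure.name
        )


# ---------------------------------------------------------------------------
# closed-form balanced path (used inside Monte Carlo sweeps)
# ---------------------------------------------------------------------------

def hotelling_two_sample(y1: np.ndarray, y2: np.ndarray):
    """Two-sample Hotelling T^2 test via its exact F transform.

    For a balanced, complete, single-visit dataset this is identical to the
    REML multivariate model's joint KR group test (a property verified in
    the test suite), and serves as the closed-form fast path inside the
    Monte Carlo power sweep.

    Returns ``(F, num_df, denom_df, p)``.
    """
    y1 = np.atleast_2d(np.asarray(y1, float))
    y2 = np.atleast_2d(np.asarray(y2, float))
    F, p = _hotelling_core(y1[None], y2[None])
    n1, n2, k = len(y1), len(y2), y1.shape[1]
    return float(F[0]), k, n1 + n2 - k - 1, float(p[0])


def hotelling_two_sample_batch(y1: np.ndarray, y2: np.ndarray) -> np.ndarray:
    """Vectorized Hotelling T^2 p-values over a batch of simulated datasets.

    ``y1``, ``y2``: arrays of shape (batch, n_subjects, n_axes).
    """
    _, p = _hotelling_core(y1, y2)
    return p


def _hotelling_core(y1, y2):
    n1, n2 = y1.shape[1], y2.shape[1]
    k = y1.shape[2]
    N = n1 + n2
    d = y1.mean(axis=1) - y2.mean(axis=1)
    c1 = y1 - y1.mean(axis=1, keepdims=True)
    c2 = y2 - y2.mean(axis=1, keepdims=True)
    S = (
        np.einsum("bni,bnj->bij", c1, c1) + np.einsum("bni,bnj->bij", c2, c2)
    ) / (N - 2)
    sol = np.linalg.solve(S, d[..., None])[..., 0]
    t2 = (n1 * n2 / N) * np.einsum("bi,bi->b", d, sol)
    df2 = N - k - 1
    F = t2 * df2 / ((N - 2) * k)
    return F, stats.f.sf(F, k, df2)
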