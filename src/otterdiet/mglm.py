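"""Model-based multivariate analysis of binary diet matrices.

Diet composition is a sample x prey-group matrix of presences.  Rather than
summarising it into distances, each prey group gets its own binomial GLM
with a complementary log-log link, ``g(p) = log(-log(1 - p))``, sharing one
design matrix across groups.  Community-level hypotheses are tested with the
sum over groups of likelihood-ratio deviances; its null distribution comes
from a parametric bootstrap that simulates every group from the reduced
model's fitted probabilities and refits both models.  Per-group p-values are
adjusted by Westfall-Young free step-down resampling over the same
simulated statistics, preserving the correlation structure among groups.

The public surface follows the statsmodels convention: build a
:class:`DietCompositionModel` from a response matrix and a covariate table,
``fit()`` it, and query the returned :class:`DietCompositionResults` for
coefficients, ``summary()``, term tests (:meth:`~DietCompositionResults.lr_test`)
and a sequential :meth:`~DietCompositionResults.anova` table.  Model search
uses :func:`stepwise_aic` on the multivariate AIC (the sum of per-group
AICs).

All fitting goes through one batched IRLS that solves every response column
simultaneously, which is what makes resampling-based inference with
thousands of refits cheap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_MU_EPS = 1e-10
_ETA_LO, _ETA_HI = -30.0, 3.2  # cloglog: mu(3.2) is within 1e-10 of 1
_DEV_TOL = 1e-8
_MAX_ITER = 100

#: interaction terms used in the global diet model, alongside the mains
DEFAULT_TERMS = (
    "sex", "size_class", "smi", "year", "season", "coast_distance",
    "habitat", "pct_urban", "lat", "lon",
    "sex:size_class", "coast_distance:sex", "coast_distance:size_class",
    "habitat:sex", "habitat:size_class", "lat:lon",
)


class DesignError(ValueError):
    pass


# -- design matrices -------------------------------------------------------

def _encode_variable(cov: pd.DataFrame, var: str) -> tuple[np.ndarray, list[str]]:
    if var not in cov.columns:
        raise DesignError(f"covariate {var!r} not in table")
    col = cov[var]
    if pd.api.types.is_numeric_dtype(col) and not isinstance(
        col.dtype, pd.CategoricalDtype
    ):
        return col.to_numpy(dtype=float)[:, None], [var]
    # treatment coding, lexically sorted levels, first level as reference
    levels = sorted(map(str, col.dropna().unique()))
    vals = col.astype(str).to_numpy()
    cols = [(vals == lev).astype(float) for lev in levels[1:]]
    names = [f"{var}[T.{lev}]" for lev in levels[1:]]
    if not cols:
        raise DesignError(f"covariate {var!r} has a single level")
    return np.column_stack(cols), names


def build_design(
    cov: pd.DataFrame, terms: Sequence[str]
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Intercept + treatment-coded term blocks; returns X, names, term->columns."""
    blocks = [np.ones((len(cov), 1))]
    names = ["Intercept"]
    term_cols: dict[str, list[int]] = {}
    pos = 1
    for term in terms:
        parts = term.split(":")
        mats, labs = zip(*(_encode_variable(cov, p) for p in parts))
        mat, lab = mats[0], list(labs[0])
        for m2, l2 in zip(mats[1:], labs[1:]):
            mat = np.concatenate(
                [mat[:, [i]] * m2 for i in range(mat.shape[1])], axis=1
            )
            lab = [f"{a}:{b}" for a in lab for b in l2]
        blocks.append(mat)
        names.extend(lab)
        term_cols[term] = list(range(pos, pos + mat.shape[1]))
        pos += mat.shape[1]
    X = np.concatenate(blocks, axis=1)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the aliased columns via pivoted QR diagnostics
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.argsort(diag)[: X.shape[1] - rank]]
        raise DesignError(f"design matrix is rank deficient; aliased columns: {bad}")
    return X, names, term_cols


# -- batched IRLS ----------------------------------------------------------

def _cloglog(p: np.ndarray) -> np.ndarray:
    return np.log(-np.log1p(-p))


def _binomial_deviance(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Per-column deviance of binary responses (saturated log-lik is 0)."""
    return -2.0 * (y * np.log(mu) + (1.0 - y) * np.log1p(-mu)).sum(axis=0)


def irls_cloglog(
    X: np.ndarray,
    Y: np.ndarray,
    max_iter: int = _MAX_ITER,
    tol: float = _DEV_TOL,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit binomial cloglog GLMs for every column of ``Y`` at once.

    Returns ``(beta (p, m), deviance (m,), mu (n, m), converged (m,))``.
    Columns with a constant response (complete separation of the intercept)
    are flagged non-converged, as are columns that exhaust ``max_iter``.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, m = Y.shape
    p = X.shape[1]
    colsum = Y.sum(axis=0)
    degenerate = (colsum == 0) | (colsum == n)

    mu = np.clip((Y + 0.5) / 2.0, _MU_EPS, 1 - _MU_EPS)
    eta = _cloglog(mu)
    dev = np.full(m, np.inf)
    beta = np.zeros((p, m))
    converged = np.zeros(m, dtype=bool)
    for _ in range(max_iter):
        eta_c = np.clip(eta, _ETA_LO, _ETA_HI)
        ee = np.exp(eta_c)
        dmu = np.exp(eta_c - ee)  # d mu / d eta, always > 0 on the clip range
        mu = np.clip(-np.expm1(-ee), _MU_EPS, 1 - _MU_EPS)
        w = dmu * dmu / (mu * (1.0 - mu))
        z = eta_c + (Y - mu) / dmu
        xtwx = np.einsum("np,nm,nq->mpq", X, w, X, optimize=True)
        xtwz = np.einsum("np,nm,nm->mp", X, w, z, optimize=True)
        try:
            beta = np.linalg.solve(xtwx, xtwz[:, :, None])[:, :, 0].T
        except np.linalg.LinAlgError:
            beta = np.stack(
                [np.linalg.lstsq(xtwx[j], xtwz[j], rcond=None)[0] for j in range(m)],
                axis=1,
            )
        eta = X @ beta
        mu_new = np.clip(-np.expm1(-np.exp(np.clip(eta, _ETA_LO, _ETA_HI))),
                         _MU_EPS, 1 - _MU_EPS)
        dev_new = _binomial_deviance(Y, mu_new)
        converged = np.abs(dev - dev_new) < tol
        dev = dev_new
        if converged.all():
            break
    mu = np.clip(-np.expm1(-np.exp(np.clip(eta, _ETA_LO, _ETA_HI))),
                 _MU_EPS, 1 - _MU_EPS)
    converged = converged & ~degenerate
    return beta, dev, mu, converged


@dataclass
class CloglogFit:
    """A single-column binomial cloglog fit."""

    params: pd.Series
    fittedvalues: np.ndarray
    deviance: float
    aic: float
    converged: bool


def fit_binomial_cloglog(
    y: Sequence[int] | np.ndarray,
    X: np.ndarray,
    names: Sequence[str] | None = None,
) -> CloglogFit:
    """Fit one binomial GLM with a complementary log-log link by IRLS.

    ``AIC = deviance + 2 * n_coefficients``.  A non-converged fit (e.g.
    under complete separation) is returned flagged, never silently.
    """
    X = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("design matrix is rank deficient")
    beta, dev, mu, conv = irls_cloglog(X, np.asarray(y, dtype=float))
    if not conv[0]:
        warnings.warn("cloglog IRLS did not converge; fit is flagged", stacklevel=2)
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    return CloglogFit(
        params=pd.Series(beta[:, 0], index=list(names)),
        fittedvalues=mu[:, 0],
        deviance=float(dev[0]),
        aic=float(dev[0] + 2 * X.shape[1]),
        converged=bool(conv[0]),
    )


# -- term tests ------------------------------------------------------------

@dataclass
class TermTest:
    """Resampled likelihood-ratio test of one model term."""

    term: str
    df: int
    community_deviance: float
    p_value: float
    group_deviance: pd.Series
    group_p_adjusted: pd.Series
    n_resamples: int
    seed: int | None


def _westfall_young(d_obs: np.ndarray, d_sim: np.ndarray, B: int) -> np.ndarray:
    """Free step-down adjusted p-values from simulated per-group statistics."""
    order = np.argsort(-d_obs)
    padj = np.empty_like(d_obs)
    running_max = np.full(d_sim.shape[1], -np.inf)
    for k in range(len(order) - 1, -1, -1):  # least significant upward
        g = order[k]
        running_max = np.maximum(running_max, d_sim[g])
        padj[g] = (1.0 + np.sum(running_max >= d_obs[g])) / (B + 1.0)
    running = 0.0
    for g in order:  # enforce monotone step-down ordering
        running = max(running, padj[g])
        padj[g] = running
    return padj


def _bootstrap_term(
    Y: np.ndarray,
    X_full: np.ndarray,
    X_red: np.ndarray,
    mu_red: np.ndarray,
    n_resamples: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated (community, per-group) LR statistics under the reduced model."""
    n, G = Y.shape
    B = n_resamples
    u = rng.random((n, G, B))
    Ysim = (u < mu_red[:, :, None]).astype(float).reshape(n, G * B)
    _, dev_full, _, _ = irls_cloglog(X_full, Ysim)
    _, dev_red, _, _ = irls_cloglog(X_red, Ysim)
    d = np.maximum(dev_red - dev_full, 0.0).reshape(G, B)
    return d.sum(axis=0), d


# -- the model / results pair ---------------------------------------------

class DietCompositionModel:
    """Multivariate binomial cloglog GLM over a binary prey-group matrix.

    Parameters
    ----------
    response
        Binary sample x group DataFrame.
    covariates
        Per-sample covariate table aligned on the same index.  Rows with any
        missing modelled covariate are dropped with a logged count.
    terms
        Model terms; interactions as ``"a:b"``.  Categorical variables are
        treatment-coded with lexically sorted levels.
    """

    def __init__(
        self,
        response: pd.DataFrame,
        covariates: pd.DataFrame,
        terms: Sequence[str] = DEFAULT_TERMS,
    ):
        covariates = covariates.loc[response.index]
        used_vars = sorted({v for t in terms for v in t.split(":")})
        ok = covariates[used_vars].notna().all(axis=1) if used_vars else pd.Series(
            True, index=covariates.index
        )
        self.n_dropped = int((~ok).sum())
        if self.n_dropped:
            logger.info(
                "dropping %d rows with missing covariates", self.n_dropped
            )
        self.response = response.loc[ok].astype(float)
        self.covariates = covariates.loc[ok]
        self.terms = list(terms)
        self.X, self.exog_names, self.term_columns = build_design(
            self.covariates, self.terms
        )

    @classmethod
    def from_frames(
        cls,
        response: pd.DataFrame,
        covariates: pd.DataFrame,
        terms: Sequence[str] = DEFAULT_TERMS,
    ) -> "DietCompositionModel":
        return cls(response, covariates, terms)

    @property
    def groups(self) -> list[str]:
        return list(self.response.columns)

    def reduced_design(self, term: str) -> np.ndarray:
        if term not in self.term_columns:
            raise DesignError(f"term {term!r} not in model")
        drop = set(self.term_columns[term])
        keep = [i for i in range(self.X.shape[1]) if i not in drop]
        return self.X[:, keep]

    def fit(self) -> "DietCompositionResults":
        Y = self.response.to_numpy()
        beta, dev, mu, conv = irls_cloglog(self.X, Y)
        return DietCompositionResults(self, beta, dev, mu, conv)


class DietCompositionResults:
    """Fitted multivariate binomial model: estimates, diagnostics, tests."""

    def __init__(self, model, beta, dev, mu, converged):
        self.model = model
        self.params = pd.DataFrame(
            beta, index=model.exog_names, columns=model.groups
        )
        self.deviances = pd.Series(dev, index=model.groups, name="deviance")
        self.fittedvalues = pd.DataFrame(
            mu, index=model.response.index, columns=model.groups
        )
        self.converged = pd.Series(converged, index=model.groups, name="converged")

    @property
    def community_deviance(self) -> float:
        return float(self.deviances.sum())

    @property
    def group_aic(self) -> pd.Series:
        k = self.model.X.shape[1]
        return self.deviances + 2 * k

    @property
    def aic(self) -> float:
        """Multivariate AIC: the sum of per-group AICs."""
        return float(self.group_aic.sum())

    def lr_test(
        self, term: str, n_resamples: int = 999, seed: int | None = None
    ) -> TermTest:
        """Likelihood-ratio test of one term with parametric-bootstrap inference.

        The observed statistic is the community deviance
        ``sum_g [dev_g(reduced) - dev_g(full)]``.  Each bootstrap draw
        simulates every group from the reduced model's fitted probabilities,
        refits both models and recomputes the statistic; the multivariate
        p-value uses the add-one convention and per-group p-values are
        Westfall-Young step-down adjusted over the same draws.
        """
        if n_resamples < 99:
            warnings.warn(
                f"n_resamples={n_resamples} gives coarse p-value resolution",
                stacklevel=2,
            )
        model = self.model
        Y = model.response.to_numpy()
        X_red = model.reduced_design(term)
        _, dev_red, mu_red, _ = irls_cloglog(X_red, Y)
        d_obs = np.maximum(dev_red - self.deviances.to_numpy(), 0.0)
        rng = np.random.default_rng(seed)
        sim_comm, sim_group = _bootstrap_term(
            Y, model.X, X_red, mu_red, n_resamples, rng
        )
        stat = float(d_obs.sum())
        p = float((1.0 + np.sum(sim_comm >= stat)) / (n_resamples + 1.0))
        padj = _westfall_young(d_obs, sim_group, n_resamples)
        return TermTest(
            term=term,
            df=len(model.term_columns[term]),
            community_deviance=stat,
            p_value=p,
            group_deviance=pd.Series(d_obs, index=model.groups),
            group_p_adjusted=pd.Series(padj, index=model.groups),
            n_resamples=n_resamples,
            seed=seed,
        )

    def anova(
        self,
        terms: Sequence[str] | None = None,
        n_resamples: int = 999,
        seed: int | None = None,
    ) -> "AnovaTable":
        """Sequential (type-I) term-addition table with resampled p-values.

        Terms are added in the listed order; each is tested against the model
        containing all preceding terms, bootstrapping from that reduced fit.
        """
        model = self.model
        terms = list(terms) if terms is not None else list(model.terms)
        ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
        children = ss.spawn(len(terms))
        rows = []
        tests: dict[str, TermTest] = {}
        for k, term in enumerate(terms):
            sub = DietCompositionModel(
                model.response, model.covariates, terms[: k + 1]
            )
            res = sub.fit()
            test = res.lr_test(
                term,
                n_resamples=n_resamples,
                seed=int(children[k].generate_state(1)[0] % (2**31)),
            )
            tests[term] = test
            rows.append(
                {
                    "term": term,
                    "df": test.df,
                    "deviance": test.community_deviance,
                    "p_value": test.p_value,
                }
            )
        return AnovaTable(pd.DataFrame(rows), tests, n_resamples, seed)

    def summary(self) -> str:
        model = self.model
        lines = [
            "Multivariate binomial GLM (cloglog link)",
            "=" * 72,
            f"Samples: {len(model.response)}    Prey groups: {len(model.groups)}"
            f"    Dropped rows: {model.n_dropped}",
            f"Terms: {', '.join(model.terms) if model.terms else '(intercept only)'}",
            f"Community deviance: {self.community_deviance:.4f}"
            f"    Multivariate AIC: {self.aic:.4f}",
            "-" * 72,
            f"{'group':<24}{'deviance':>12}{'AIC':>12}{'converged':>12}",
        ]
        for g in model.groups:
            lines.append(
                f"{g:<24}{self.deviances[g]:>12.4f}{self.group_aic[g]:>12.4f}"
                f"{str(bool(self.converged[g])):>12}"
            )
        lines.append("=" * 72)
        return "\n".join(lines)


@dataclass
class AnovaTable:
    """Per-term deviance/p table plus the underlying per-group tests."""

    table: pd.DataFrame
    tests: Mapping[str, TermTest]
    n_resamples: int
    seed: int | None

    def group_table(self, alpha: float = 0.05) -> pd.DataFrame:
        rows = []
        for term, test in self.tests.items():
            for g in test.group_deviance.index:
                rows.append(
                    {
                        "term": term,
                        "group": g,
                        "deviance": test.group_deviance[g],
                        "p_adjusted": test.group_p_adjusted[g],
                        "significant": test.group_p_adjusted[g] <= alpha,
                    }
                )
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        return self.table.to_string(index=False)


# -- model selection -------------------------------------------------------

def _hierarchy_ok(terms: set[str]) -> bool:
    """Interaction terms must appear alongside all their main effects."""
    for t in terms:
        if ":" in t and not all(p in terms for p in t.split(":")):
            return False
    return True


def stepwise_aic(
    response: pd.DataFrame,
    covariates: pd.DataFrame,
    candidate_terms: Sequence[str],
    direction: str = "both",
    start_terms: Sequence[str] | None = None,
) -> list[str]:
    """Greedy AIC search over terms, respecting interaction hierarchy.

    Starts from the global model (all candidates) and repeatedly applies the
    single add/drop move that most lowers the multivariate AIC (the sum of
    per-group AICs), stopping when no move improves it.  Interaction terms
    are only allowed alongside their main effects, and a main effect cannot
    leave while one of its interactions stays.
    """
    if direction not in ("both", "backward", "forward"):
        raise ValueError(f"unknown direction {direction!r}")
    candidates = list(candidate_terms)
    if start_terms is None:
        current = (
            [] if direction == "forward" else list(candidates)
        )
    else:
        current = list(start_terms)

    def aic_of(terms: Sequence[str]) -> float:
        return DietCompositionModel(response, covariates, terms).fit().aic

    best_aic = aic_of(current)
    improved = True
    while improved:
        improved = False
        moves: list[tuple[float, list[str]]] = []
        if direction in ("both", "backward"):
            for t in current:
                trial = [u for u in current if u != t]
                if _hierarchy_ok(set(trial)):
                    moves.append((aic_of(trial), trial))
        if direction in ("both", "forward"):
            for t in candidates:
                if t in current:
                    continue
                trial = current + [t]
                if _hierarchy_ok(set(trial)):
                    moves.append((aic_of(trial), trial))
        if moves:
            trial_aic, trial = min(moves, key=lambda m: m[0])
            if trial_aic < best_aic - 1e-9:
                best_aic, current, improved = trial_aic, trial, True
    return current


def manyglm_fit(
    response: pd.DataFrame,
    covariates: pd.DataFrame,
    terms: Sequence[str] = DEFAULT_TERMS,
) -> DietCompositionResults:
    """One independent binomial cloglog fit per response column (shared design)."""
    return DietCompositionModel(response, covariates, terms).fit()
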