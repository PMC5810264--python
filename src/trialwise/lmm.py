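"""Single-trial mixed-model stage.

Linear mixed models with crossed random effects for participants and items,
sliding-difference contrasts for factors, pruning of zero-variance random
terms, stepwise fixed-effect reduction by likelihood-ratio tests, nested
follow-up models, and remef-style partial effects.

The solver backend is statsmodels: ``MixedLM`` for gaussian responses (crossed
random effects are realized through the variance-component formulation, with
independent variances per random term, i.e. no random-effect correlations) and
``BinomialBayesMixedGLM`` (variational Bayes) for binomial responses.  The
gaussian backend does not provide Satterthwaite degrees of freedom; p-values
use the normal approximation and every fit records that flag.  Binomial fits
report posterior-based z statistics; their marginal log-likelihood, AIC and
BIC are not available and are reported as NaN.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec

__all__ = [
    "ModelSpec",
    "ModelFit",
    "ModelComparison",
    "sliding_difference_contrasts",
    "build_fixed_design",
    "fit_model",
    "likelihood_ratio_test",
    "prune_singular_random_terms",
    "reduce_fixed_effects",
    "nested_followup",
    "partial_effects",
    "rescale_amplitudes",
]

log = logging.getLogger("trialwise.lmm")


# ---------------------------------------------------------------------------
# Contrast coding and design matrices

def sliding_difference_contrasts(n_levels: int) -> np.ndarray:
    """Successive-difference coding matrix (n_levels x n_levels-1).

    Column j encodes level[j+1] - level[j]; with an intercept, the intercept
    estimates the unweighted grand mean of the cell means.  Columns sum to 0.
    """
    if n_levels < 2:
        raise ValueError("need at least 2 levels")
    k = n_levels
    c = np.zeros((k, k - 1))
    for j in range(k - 1):
        c[:, j] = (np.arange(k) >= j + 1) - (k - (j + 1)) / k
    return c


def _factor_levels(series: pd.Series) -> list[str] | None:
    """Declared or observed level order for factor-like columns, else None."""
    if isinstance(series.dtype, pd.CategoricalDtype):
        return [str(l) for l in series.cat.categories]
    if series.dtype == object or series.dtype == bool:
        return sorted(map(str, pd.unique(series.dropna())))
    return None


def _encode_column(data: pd.DataFrame, name: str,
                   factors: dict[str, list[str]]) -> pd.DataFrame:
    """One predictor column -> its design columns (contrasts or identity)."""
    if name == "1":
        return pd.DataFrame({"1": np.ones(len(data))})
    if name not in data.columns:
        raise KeyError(f"unknown model column {name!r}")
    s = data[name]
    levels = factors.get(name) or _factor_levels(s)
    if levels is None:
        return pd.DataFrame({name: pd.to_numeric(s).to_numpy(float)})
    if len(levels) < 2:
        raise ValueError(f"factor {name!r} has fewer than 2 levels")
    cmat = sliding_difference_contrasts(len(levels))
    codes = pd.Categorical(s.astype(str), categories=levels).codes
    if (codes < 0).any():
        bad = sorted(set(s.astype(str)) - set(levels))
        raise ValueError(f"column {name!r} contains undeclared level(s) {bad}")
    cols = {
        f"{name}[{levels[j + 1]}-{levels[j]}]": cmat[codes, j]
        for j in range(len(levels) - 1)
    }
    return pd.DataFrame(cols)


def _encode_term(data: pd.DataFrame, term: str,
                 factors: dict[str, list[str]]) -> pd.DataFrame:
    """A term is a ':'-joined product of predictor columns."""
    parts = term.split(":")
    block = _encode_column(data, parts[0], factors)
    for p in parts[1:]:
        nxt = _encode_column(data, p, factors)
        block = pd.DataFrame(
            {
                f"{a}:{b}": block[a].to_numpy() * nxt[b].to_numpy()
                for a in block.columns
                for b in nxt.columns
            }
        )
    return block


def expand_terms(terms: Sequence[str]) -> list[str]:
    """Expand '*' shorthand: "a*b" -> a, b, a:b (all orders)."""
    out: list[str] = []
    for t in terms:
        if "*" in t:
            parts = [p.strip() for p in t.split("*")]
            from itertools import combinations
            for r in range(1, len(parts) + 1):
                for combo in combinations(parts, r):
                    name = ":".join(combo)
                    if name not in out:
                        out.append(name)
        elif t.strip() not in out:
            out.append(t.strip())
    return out


def build_fixed_design(
    data: pd.DataFrame, terms: Sequence[str],
    factors: dict[str, list[str]] | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Fixed-effect design matrix with intercept; returns (X, term->columns)."""
    factors = factors or {}
    X = pd.DataFrame({"Intercept": np.ones(len(data))})
    column_terms: dict[str, list[str]] = {"Intercept": ["Intercept"]}
    for term in expand_terms(terms):
        block = _encode_term(data, term, factors)
        for col in block.columns:
            X[col] = block[col].to_numpy()
        column_terms[term] = list(block.columns)
    return X, column_terms


# ---------------------------------------------------------------------------
# Model specification and fit containers

@dataclass
class ModelSpec:
    """Response, fixed terms, random terms per grouping, family.

    ``random`` maps a grouping column (participant_id, item_id, ...) to its
    random terms; "1" is the random intercept.  Factors not inferable from
    dtype can be declared with explicit level order in ``factors``.
    """

    response: str
    fixed: list[str]
    random: dict[str, list[str]] = field(default_factory=dict)
    family: str = "gaussian"
    factors: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        self.fixed = expand_terms(self.fixed)
        for g, terms in self.random.items():
            seen = []
            for t in terms:
                if t not in seen:
                    seen.append(t)
            self.random[g] = seen

    @classmethod
    def from_formula(cls, formula: str, family: str = "gaussian",
                     factors: dict[str, list[str]] | None = None) -> "ModelSpec":
        """Mini-grammar: ``resp ~ a * b + c | participant: 1 + a | item: 1``."""
        parts = [p.strip() for p in formula.split("|")]
        lhs, rhs = parts[0].split("~")
        fixed = [t.strip() for t in rhs.split("+") if t.strip()]
        random: dict[str, list[str]] = {}
        for p in parts[1:]:
            grp, terms = p.split(":")
            random[grp.strip()] = [t.strip() for t in terms.split("+") if t.strip()]
        return cls(response=lhs.strip(), fixed=fixed, random=random,
                   family=family, factors=factors or {})


@dataclass
class ModelComparison:
    delta_chi2: float
    df: int
    p: float
    delta_aic: float
    delta_bic: float
    preferred: str
    removed_term: str | None = None


@dataclass
class ModelFit:
    """Fixed effects, variance components, BLUPs and fit indices."""

    spec: ModelSpec
    fixed_effects: pd.DataFrame            # index: design columns; b, se, stat, p
    column_terms: dict[str, list[str]]
    random_sd: pd.DataFrame                # grouping, term, sd
    resid_sd: float
    blups: pd.DataFrame                    # grouping, term, level, blup
    llf: float
    reml: bool
    aic: float
    bic: float
    n_obs: int
    converged: bool
    singular: bool
    singular_terms: list[tuple[str, str]]
    df_method: str                         # "normal" (no Satterthwaite backend)
    # arrays retained for partial-effects computation
    _X: pd.DataFrame = field(repr=False, default=None)
    _y: np.ndarray = field(repr=False, default=None)
    _random_contrib: np.ndarray = field(repr=False, default=None)

    @property
    def reml_deviance(self) -> float:
        return -2.0 * self.llf if self.reml else float("nan")

    def term_pvalue(self, term: str) -> float:
        """Joint Wald p-value for all design columns of a term."""
        cols = self.column_terms[term]
        b = self.fixed_effects.loc[cols, "b"].to_numpy()
        se = self.fixed_effects.loc[cols, "se"].to_numpy()
        # columns are treated as independent (diagonal Wald); adequate for
        # the orthogonal contrasts used here
        chi2 = float(np.sum((b / se) ** 2))
        return float(stats.chi2.sf(chi2, df=len(cols)))


# ---------------------------------------------------------------------------
# Random-effect design construction

def _random_blocks(
    data: pd.DataFrame, random: dict[str, list[str]],
    factors: dict[str, list[str]],
) -> list[tuple[str, str, list[str], np.ndarray]]:
    """(grouping, term, column labels, n x q design) per random component.

    Crossed groupings are handled by expanding each grouping's levels into
    indicator columns multiplied with the term's design columns; one variance
    parameter per (grouping, term).
    """
    blocks = []
    for grouping, terms in random.items():
        if grouping not in data.columns:
            raise KeyError(f"unknown grouping column {grouping!r}")
        lv = [str(l) for l in pd.unique(data[grouping])]
        onehot = (
            data[grouping].astype(str).to_numpy()[:, None] == np.array(lv)[None, :]
        ).astype(float)
        for term in terms:
            tcols = _encode_term(data, term, factors)
            mats, names = [], []
            for tc in tcols.columns:
                mats.append(onehot * tcols[tc].to_numpy()[:, None])
                names.extend([f"{l}|{tc}" for l in lv])
            blocks.append((grouping, term, names, np.hstack(mats)))
    return blocks


# ---------------------------------------------------------------------------
# Fitting

def fit_model(
    spec: ModelSpec, data: pd.DataFrame, reml: bool = True
) -> ModelFit:
    """Fit the specified mixed model; listwise NaN drop on used columns."""
    used = {spec.response}
    for t in spec.fixed:
        used.update(p for p in t.split(":") if p != "1")
    for g, terms in spec.random.items():
        used.add(g)
        for t in terms:
            used.update(p for p in t.split(":") if p != "1")
    missing = sorted(used - set(data.columns))
    if missing:
        raise KeyError(f"data is missing column(s): {missing}")
    data = data.dropna(subset=sorted(used)).reset_index(drop=True)
    if len(data) == 0:
        raise ValueError("no complete observations after NaN drop")

    y = pd.to_numeric(data[spec.response]).to_numpy(float)
    X, column_terms = build_fixed_design(data, spec.fixed, spec.factors)
    if spec.family == "binomial" and not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("binomial response must be coded 0/1")
    blocks = _random_blocks(data, spec.random, spec.factors)

    if spec.family == "gaussian" and float(np.var(y)) == 0.0:
        return _degenerate_fit(spec, y, X, column_terms, blocks, reml)
    if spec.family == "gaussian":
        return _fit_gaussian(spec, y, X, column_terms, blocks, data, reml)
    return _fit_binomial(spec, y, X, column_terms, blocks)


# "zero variance" pruning threshold: a component is singular when its
# variance is below 1e-6 x the residual variance (SD ratio 1e-3); the
# optimizer parks null components at tiny nonzero values rather than 0
_SINGULAR_TOL = 1e-3


def _fit_gaussian(spec, y, X, column_terms, blocks, data, reml) -> ModelFit:
    n = len(y)
    if blocks:
        groups = np.zeros(n)  # single-group trick enables crossed groupings
        names = [f"{g}:{t}" for g, t, _, _ in blocks]
        colnames = [[cn] for _, _, cn, _ in blocks]
        mats = [[m] for _, _, _, m in blocks]
        vc = VCSpec(names, colnames, mats)
        model = MixedLM(y, X.to_numpy(), groups=groups, exog_vc=vc)
    else:
        model = None

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if model is None:
            # pure fixed-effects model: OLS is the exact gaussian fit
            import statsmodels.api as sm
            res = sm.OLS(y, X.to_numpy()).fit()
            resid_sd = float(np.sqrt(res.ssr / n))
            llf = float(res.llf)
            k = X.shape[1] + 1
            fe = pd.DataFrame(
                {"b": res.params, "se": res.bse, "stat": res.tvalues,
                 "p": 2 * stats.norm.sf(np.abs(res.tvalues))},
                index=X.columns,
            )
            return ModelFit(
                spec=spec, fixed_effects=fe, column_terms=column_terms,
                random_sd=pd.DataFrame(columns=["grouping", "term", "sd"]),
                resid_sd=resid_sd,
                blups=pd.DataFrame(columns=["grouping", "term", "level", "blup"]),
                llf=llf, reml=False, aic=-2 * llf + 2 * k,
                bic=-2 * llf + k * np.log(n), n_obs=n, converged=True,
                singular=False, singular_terms=[], df_method="normal",
                _X=X, _y=y, _random_contrib=np.zeros(n),
            )
        try:
            # powell is markedly more reliable than gradient methods on the
            # profiled variance surface (lbfgs stalls in flat regions)
            res = model.fit(reml=reml, method=["powell", "nm", "lbfgs"],
                            maxiter=2000)
            converged = bool(res.converged)
        except Exception as err:  # non-convergence with diagnostics
            raise RuntimeError(
                f"mixed-model fit failed for {spec.response!r}: {err}"
            ) from err

    p_fix = X.shape[1]
    fe_params = np.asarray(res.params[:p_fix])
    fe_bse = np.asarray(res.bse[:p_fix])
    zvals = fe_params / fe_bse
    fe = pd.DataFrame(
        {"b": fe_params, "se": fe_bse, "stat": zvals,
         "p": 2 * stats.norm.sf(np.abs(zvals))},
        index=X.columns,
    )
    resid_var = float(res.scale)
    resid_sd = float(np.sqrt(resid_var))
    vcomp = np.asarray(res.vcomp, dtype=float)
    rows = [
        {"grouping": g, "term": t, "sd": float(np.sqrt(max(v, 0.0)))}
        for (g, t, _, _), v in zip(blocks, vcomp)
    ]
    random_sd = pd.DataFrame(rows, columns=["grouping", "term", "sd"])
    singular_terms = [
        (r["grouping"], r["term"])
        for r in rows
        if r["sd"] < _SINGULAR_TOL * max(resid_sd, 1e-12)
    ]

    blups, contrib = _compute_blups(
        y - X.to_numpy() @ fe_params, blocks, vcomp, resid_var
    )
    llf = float(res.llf)
    k = p_fix + len(blocks) + 1
    fit = ModelFit(
        spec=spec, fixed_effects=fe, column_terms=column_terms,
        random_sd=random_sd, resid_sd=resid_sd, blups=blups,
        llf=llf, reml=reml, aic=-2 * llf + 2 * k, bic=-2 * llf + k * np.log(n),
        n_obs=n, converged=converged, singular=bool(singular_terms),
        singular_terms=singular_terms, df_method="normal",
        _X=X, _y=y, _random_contrib=contrib,
    )
    log.info(
        "gaussian fit (%s): llf=%.2f, p-values via normal approximation "
        "(no Satterthwaite backend)", "REML" if reml else "ML", llf,
    )
    return fit


def _compute_blups(resid_fixed, blocks, variances, resid_var):
    """BLUPs u = G Z' V^-1 (y - Xb) via the Woodbury identity.

    Zero-variance components contribute u = 0 and are dropped from the solve.
    Returns (tidy BLUP table, per-observation random contribution Z u).
    """
    n = resid_fixed.shape[0]
    active = [(i, b) for i, b in enumerate(blocks) if variances[i] > 0]
    if not active:
        empty = pd.DataFrame(columns=["grouping", "term", "level", "blup"])
        return empty, np.zeros(n)
    Z = np.hstack([b[3] for _, b in active])
    gdiag = np.concatenate(
        [np.full(b[3].shape[1], variances[i]) for i, b in active]
    )
    A = np.diag(resid_var / gdiag) + Z.T @ Z
    zr = Z.T @ resid_fixed
    u = gdiag * (zr - Z.T @ (Z @ np.linalg.solve(A, zr))) / resid_var
    contrib = Z @ u

    rows, off = [], 0
    for i, (g, t, names, mat) in active:
        q = mat.shape[1]
        for name, val in zip(names, u[off : off + q]):
            level, _, tcol = name.partition("|")
            rows.append(
                {"grouping": g, "term": t, "level": level, "blup": float(val)}
            )
        off += q
    return pd.DataFrame(rows), contrib


def _degenerate_fit(spec, y, X, column_terms, blocks, reml) -> ModelFit:
    """Constant response: intercept = the constant, everything else zero."""
    fe = pd.DataFrame(
        {"b": 0.0, "se": 0.0, "stat": 0.0, "p": 1.0}, index=X.columns
    )
    fe.loc["Intercept", "b"] = float(y[0])
    random_sd = pd.DataFrame(
        [{"grouping": g, "term": t, "sd": 0.0} for g, t, _, _ in blocks],
        columns=["grouping", "term", "sd"],
    )
    return ModelFit(
        spec=spec, fixed_effects=fe, column_terms=column_terms,
        random_sd=random_sd, resid_sd=0.0,
        blups=pd.DataFrame(columns=["grouping", "term", "level", "blup"]),
        llf=float("inf"), reml=reml, aic=float("-inf"), bic=float("-inf"),
        n_obs=len(y), converged=True,
        singular=bool(blocks),
        singular_terms=[(g, t) for g, t, _, _ in blocks],
        df_method="normal",
        _X=X, _y=y, _random_contrib=np.zeros(len(y)),
    )


def _fit_binomial(spec, y, X, column_terms, blocks) -> ModelFit:
    n = len(y)
    if blocks:
        exog_vc = np.hstack([m for _, _, _, m in blocks])
        ident = np.concatenate(
            [np.full(m.shape[1], i) for i, (_, _, _, m) in enumerate(blocks)]
        )
    else:
        exog_vc = np.zeros((n, 0))
        ident = np.zeros(0, dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = BinomialBayesMixedGLM(
            y, X.to_numpy(), exog_vc, ident.astype(int),
            vcp_p=2.0, fe_p=2.0,
        )
        res = model.fit_vb()

    p_fix = X.shape[1]
    b = np.asarray(res.fe_mean)
    se = np.asarray(res.fe_sd)
    z = b / se
    fe = pd.DataFrame(
        {"b": b, "se": se, "stat": z, "p": 2 * stats.norm.sf(np.abs(z))},
        index=X.columns,
    )
    sds = np.exp(np.asarray(res.vcp_mean))
    random_sd = pd.DataFrame(
        [
            {"grouping": g, "term": t, "sd": float(sds[i])}
            for i, (g, t, _, _) in enumerate(blocks)
        ],
        columns=["grouping", "term", "sd"],
    )
    singular_terms = [
        (r["grouping"], r["term"])
        for _, r in random_sd.iterrows()
        if r["sd"] < 1e-3
    ]
    u = np.asarray(res.vc_mean) if blocks else np.zeros(0)
    rows, off = [], 0
    for g, t, names, mat in blocks:
        q = mat.shape[1]
        for name, val in zip(names, u[off : off + q]):
            level, _, _tcol = name.partition("|")
            rows.append(
                {"grouping": g, "term": t, "level": level, "blup": float(val)}
            )
        off += q
    contrib = exog_vc @ u if blocks else np.zeros(n)
    log.info("binomial fit via variational Bayes; logLik/AIC/BIC unavailable")
    return ModelFit(
        spec=spec, fixed_effects=fe, column_terms=column_terms,
        random_sd=random_sd, resid_sd=float("nan"),
        blups=pd.DataFrame(rows, columns=["grouping", "term", "level", "blup"]),
        llf=float("nan"), reml=False, aic=float("nan"), bic=float("nan"),
        n_obs=n, converged=True, singular=bool(singular_terms),
        singular_terms=singular_terms, df_method="normal",
        _X=X, _y=y, _random_contrib=contrib,
    )


# ---------------------------------------------------------------------------
# Model comparison and reduction

def likelihood_ratio_test(fit_big: ModelFit, fit_small: ModelFit,
                          removed_term: str | None = None) -> ModelComparison:
    """LRT of nested ML fits: Delta chi2 = 2 (llf_big - llf_small)."""
    if fit_big.reml or fit_small.reml:
        raise ValueError("likelihood-ratio tests require ML fits (reml=False)")
    chi2 = 2.0 * (fit_big.llf - fit_small.llf)
    df = len(fit_big.fixed_effects) - len(fit_small.fixed_effects)
    if df <= 0:
        raise ValueError("models are not properly nested")
    p = float(stats.chi2.sf(max(chi2, 0.0), df=df))
    d_aic = fit_small.aic - fit_big.aic
    d_bic = fit_small.bic - fit_big.bic
    preferred = "small" if p >= 0.05 else "big"
    return ModelComparison(
        delta_chi2=float(chi2), df=df, p=p, delta_aic=float(d_aic),
        delta_bic=float(d_bic), preferred=preferred, removed_term=removed_term,
    )


def prune_singular_random_terms(
    spec: ModelSpec, data: pd.DataFrame, max_iter: int = 10
) -> tuple[ModelSpec, list[str], ModelFit]:
    """Drop random terms estimated at (numerically) zero variance.

    Slopes are removed before their grouping's intercept; removal proceeds one
    term at a time (smallest SD first) with a refit after each removal, until
    the fit is non-singular or only random intercepts remain.  Deterministic:
    no randomness is involved.  Returns (reduced spec, removal log, final fit).
    """
    spec = replace(spec, random={g: list(t) for g, t in spec.random.items()})
    removed: list[str] = []
    for _ in range(max_iter):
        fit = fit_model(spec, data, reml=(spec.family == "gaussian"))
        if not fit.singular:
            return spec, removed, fit
        candidates = []
        for g, t in fit.singular_terms:
            others = [x for x in spec.random.get(g, []) if x != "1"]
            if t == "1" and others:
                continue  # intercept only removable after its slopes
            sd = float(
                fit.random_sd.query("grouping == @g and term == @t")["sd"].iloc[0]
            )
            candidates.append((sd, g, t))
        if not candidates:
            return spec, removed, fit
        _, g, t = min(candidates)
        spec.random[g].remove(t)
        if not spec.random[g]:
            del spec.random[g]
        removed.append(f"{g}:{t}")
        log.info("pruned singular random term %s:%s", g, t)
    return spec, removed, fit_model(spec, data, reml=(spec.family == "gaussian"))


def _removable_terms(fixed: list[str]) -> list[str]:
    """Terms not contained in any retained higher-order interaction."""
    sets = {t: set(t.split(":")) for t in fixed}
    out = []
    for t, s in sets.items():
        if t == "Intercept":
            continue
        if not any(s < s2 for t2, s2 in sets.items() if t2 != t):
            out.append(t)
    return out


def reduce_fixed_effects(
    spec: ModelSpec, data: pd.DataFrame, alpha: float = 0.05
) -> tuple[ModelFit, list[ModelComparison]]:
    """Stepwise backward reduction of the fixed-effects structure.

    At each step the least significant removable term (largest Wald p; ties
    broken in favor of higher-order interactions) is dropped and the smaller
    model is compared with the larger one by a likelihood-ratio test on ML
    fits; removal stops once the smaller model fits significantly worse
    (LRT p < alpha).  For binomial fits the decision uses the Wald test
    (no marginal likelihood is available) and the LRT fields are NaN.
    """
    ml = spec.family == "gaussian"
    trail: list[ModelComparison] = []
    current = replace(spec, fixed=list(spec.fixed))
    fit = fit_model(current, data, reml=False if ml else True)

    while True:
        removable = _removable_terms(current.fixed)
        if not removable:
            break
        scored = sorted(
            removable,
            key=lambda t: (fit.term_pvalue(t), t.count(":")),
            reverse=True,
        )
        worst = scored[0]
        if fit.term_pvalue(worst) < alpha:
            break
        smaller = replace(
            current, fixed=[t for t in current.fixed if t != worst]
        )
        fit_small = fit_model(smaller, data, reml=False if ml else True)
        if ml:
            cmp_ = likelihood_ratio_test(fit, fit_small, removed_term=worst)
            if cmp_.p < alpha:
                cmp_.preferred = "big"
                trail.append(cmp_)
                break
        else:
            cmp_ = ModelComparison(
                delta_chi2=float("nan"), df=len(fit.fixed_effects)
                - len(fit_small.fixed_effects), p=fit.term_pvalue(worst),
                delta_aic=float("nan"), delta_bic=float("nan"),
                preferred="small", removed_term=worst,
            )
        trail.append(cmp_)
        current, fit = smaller, fit_small

    if ml:
        # report the final model under REML for variance components
        fit = fit_model(current, data, reml=True)
    return fit, trail


def nested_followup(
    spec: ModelSpec, data: pd.DataFrame, inner_factor: str, outer_factor: str
) -> pd.DataFrame:
    """Effects of ``inner_factor`` at each level of ``outer_factor``.

    Refits a model specified identically to the original except that the
    inner main effect and the inner x outer interaction are replaced by
    per-outer-level inner contrasts.  Returns one row per (outer level,
    inner contrast) with b, se, stat, p.
    """
    for f in (inner_factor, outer_factor):
        if not any(f in t.split(":") for t in spec.fixed):
            raise ValueError(f"factor {f!r} not among the model's fixed terms")
    outer_levels = spec.factors.get(outer_factor) or _factor_levels(
        data[outer_factor]
    )
    if outer_levels is None:
        raise ValueError(f"{outer_factor!r} is not a factor")
    for lvl in outer_levels:
        if not (data[outer_factor].astype(str) == lvl).any():
            raise ValueError(f"no data at {outer_factor}={lvl!r}")

    used = {spec.response}
    for t in spec.fixed:
        used.update(t.split(":"))
    for g, ts in spec.random.items():
        used.add(g)
        for t in ts:
            used.update(p for p in t.split(":") if p != "1")
    data = data.dropna(subset=sorted(used & set(data.columns))).reset_index(
        drop=True
    )

    drop = {
        t for t in spec.fixed
        if set(t.split(":")) in ({inner_factor}, {inner_factor, outer_factor})
    }
    X, column_terms = build_fixed_design(
        data, [t for t in spec.fixed if t not in drop], spec.factors
    )
    inner_block = _encode_term(data, inner_factor, spec.factors)
    nested_cols = []
    for lvl in outer_levels:
        ind = (data[outer_factor].astype(str) == lvl).to_numpy(float)
        for c in inner_block.columns:
            name = f"{outer_factor}[{lvl}]:{c}"
            X[name] = ind * inner_block[c].to_numpy()
            nested_cols.append((lvl, c, name))
    column_terms["nested"] = [n for _, _, n in nested_cols]

    nested_spec = replace(
        spec, fixed=[t for t in spec.fixed if t not in drop]
    )
    fit = _refit_with_design(nested_spec, data, X, column_terms)
    rows = [
        {
            "outer_level": lvl,
            "inner_contrast": c,
            "b": fit.fixed_effects.loc[name, "b"],
            "se": fit.fixed_effects.loc[name, "se"],
            "stat": fit.fixed_effects.loc[name, "stat"],
            "p": fit.fixed_effects.loc[name, "p"],
        }
        for lvl, c, name in nested_cols
    ]
    return pd.DataFrame(rows)


def _refit_with_design(spec, data, X, column_terms) -> ModelFit:
    """Fit with an explicitly constructed fixed design (same backends)."""
    y = pd.to_numeric(data[spec.response]).to_numpy(float)
    blocks = _random_blocks(data, spec.random, spec.factors)
    if spec.family == "gaussian":
        if float(np.var(y)) == 0.0:
            return _degenerate_fit(spec, y, X, column_terms, blocks, True)
        return _fit_gaussian(spec, y, X, column_terms, blocks, data, True)
    return _fit_binomial(spec, y, X, column_terms, blocks)


# ---------------------------------------------------------------------------
# Partial effects and utilities

def partial_effects(
    fit: ModelFit,
    keep_fixed: Sequence[str] | None = None,
    remove_random: bool = False,
) -> np.ndarray:
    """Observed response minus the removed fitted contributions (remef-style).

    ``keep_fixed`` lists the fixed terms whose contributions stay in the
    returned values (default: all).  With ``keep_fixed=[]`` and
    ``remove_random=True`` the result is the model residuals.
    """
    keep = set(fit.column_terms) if keep_fixed is None else set(keep_fixed)
    unknown = keep - set(fit.column_terms)
    if unknown:
        raise KeyError(f"unknown term(s): {sorted(unknown)}")
    out = fit._y.astype(float).copy()
    for term, cols in fit.column_terms.items():
        if term in keep:
            continue
        b = fit.fixed_effects.loc[cols, "b"].to_numpy()
        out -= fit._X[cols].to_numpy() @ b
    if remove_random:
        out -= fit._random_contrib
    return out


def rescale_amplitudes(
    table: pd.DataFrame, column: str, factor: float = 10.0
) -> pd.DataFrame:
    """Divide an amplitude column by ``factor`` (default 10, so downstream
    slopes read per 10 uV)."""
    out = table.copy()
    out[column] = pd.to_numeric(out[column]) / factor
    return out
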