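"""Mixed-model selection for song traits versus noise: AICc, weights, ER.

The question is whether a song trait (source amplitude or minimum
frequency) tracks environmental noise at one or more time scales.  A
candidate set of linear mixed-effects models is enumerated over the noise
measures (optionally with quadratic terms, pairwise interactions among
noise measures, and a recordist-distance covariate), each model is fitted
by maximum likelihood with a by-bird random intercept (optionally a
by-bird random slope on a noise measure), and the set is ranked by AICc:

    AICc = -2 logL + 2k + 2k(k+1) / (n - k - 1)

with k counting every estimated parameter (fixed effects + random-effect
(co)variances + residual variance) and n the number of songs.  Akaike
weights, evidence ratios against the intercept-only null, and per-term
total weights (parameter importance) summarise the support.

ML rather than REML likelihoods are used throughout: REML likelihoods are
not comparable across models with different fixed effects.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "ModelSpec",
    "ModelSetConfig",
    "FitResult",
    "ModelSetResult",
    "aicc",
    "akaike_weights",
    "evidence_ratio",
    "parameter_importance",
    "build_model_set",
    "default_amplitude_config",
    "default_minfreq_config",
    "fit_mixed_model",
    "fit_model_set",
    "rank_models",
    "covariation_test",
    "residual_diagnostics",
    "ResidualDiagnostics",
]

logger = logging.getLogger(__name__)

NOISE_TERMS = ("instantaneous", "bout_background", "territory")

_LABELS = {
    "distance": "Distance",
    "instantaneous": "Instantaneous",
    "bout_background": "Bout Background",
    "territory": "Territory",
    "song_amplitude": "Song Amplitude",
}


def _term_label(term: str) -> str:
    if term.endswith("^2"):
        return _LABELS.get(term[:-2], term[:-2]) + "^2"
    if ":" in term:
        a, b = term.split(":")
        return f"{_LABELS.get(a, a)} x {_LABELS.get(b, b)}"
    return _LABELS.get(term, term)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: response, fixed terms, random structure.

    Fixed terms are column-derived names: base covariates (``distance``,
    ``instantaneous``, ...), quadratics (``instantaneous^2``) and pairwise
    interactions (``instantaneous:territory``).  The intercept is always
    present and not listed.  ``random`` is ``"intercept"`` (by-bird random
    intercept) or ``"slope"`` (random intercept + by-bird random slope on
    ``slope_term``, unstructured covariance).
    """

    response: str
    fixed_terms: tuple[str, ...] = ()
    random: str = "intercept"
    slope_term: str = "bout_background"

    def __post_init__(self) -> None:
        if self.random not in ("intercept", "slope"):
            raise ValueError(f"unknown random structure {self.random!r}")

    @property
    def name(self) -> str:
        if not self.fixed_terms:
            return "Intercept only (null) model"
        return " + ".join(_term_label(t) for t in self.fixed_terms)

    def contains(self, term: str) -> bool:
        return term in self.fixed_terms


@dataclass
class FitResult:
    """A fitted candidate model with the quantities model selection needs."""

    spec: ModelSpec
    log_likelihood: float
    k: int
    n: int
    aicc: float
    coefficients: pd.Series
    std_errors: pd.Series
    converged: bool = True
    singular: bool = False
    fitted_values: Optional[np.ndarray] = None
    residuals: Optional[np.ndarray] = None

    @property
    def usable(self) -> bool:
        return self.converged and not self.singular


@dataclass
class ModelSetResult:
    """Ranked candidate set: AICc table, weights, ER, term importance."""

    fits: list[FitResult]  # ranked, best first
    table: pd.DataFrame  # columns: model, K, AICc, dAICc, weight
    weights: np.ndarray
    null_name: str
    excluded: list[FitResult] = field(default_factory=list)

    @property
    def top(self) -> FitResult:
        return self.fits[0]

    def weight_of(self, name: str) -> float:
        m = self.table["model"] == name
        if not m.any():
            raise KeyError(f"no model named {name!r} in the set")
        return float(self.table.loc[m, "weight"].iloc[0])

    def evidence_ratio_vs_null(self, name: str) -> float:
        return evidence_ratio(self.weight_of(name), self.weight_of(self.null_name))

    def importance(self, term: str) -> float:
        return parameter_importance(self, term)


# ---------------------------------------------------------------------------
# information-theoretic arithmetic
# ---------------------------------------------------------------------------

def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Akaike information criterion with the small-sample correction."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return float(-2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1))


def akaike_weights(aicc_values: Iterable[float]) -> np.ndarray:
    """Akaike weights: relative likelihoods normalised over the set."""
    a = np.asarray(list(aicc_values), dtype=float)
    if a.size == 0:
        raise ValueError("empty model set")
    rel = np.exp(-0.5 * (a - a.min()))
    return rel / rel.sum()


def evidence_ratio(w_model: float, w_null: float) -> float:
    """Support for a model over the null: the ratio of their weights."""
    if w_null == 0.0:
        return float("inf")
    return float(w_model / w_null)


def parameter_importance(model_set: ModelSetResult, term: str) -> float:
    """Total Akaike weight of all models containing ``term``."""
    present = [f.spec.contains(term) for f in model_set.fits]
    if not any(f.spec.contains(term) for f in model_set.fits + model_set.excluded):
        warnings.warn(f"term {term!r} appears in no candidate model")
        all_terms = {t for f in model_set.fits for t in f.spec.fixed_terms}
        if term.split("^")[0].split(":")[0] not in {
            t.split("^")[0].split(":")[0] for t in all_terms
        } | set(NOISE_TERMS) | {"distance", "song_amplitude"}:
            raise KeyError(f"unknown term {term!r}")
        return 0.0
    return float(np.sum(model_set.weights[np.asarray(present)]))


# ---------------------------------------------------------------------------
# candidate-set enumeration
# ---------------------------------------------------------------------------

@dataclass
class ModelSetConfig:
    """Declarative description of a candidate set.

    The base enumeration is the power set of ``noise_terms`` (capped at
    ``max_noise_terms`` simultaneous measures).  With ``quadratics`` each
    selected measure appears as linear, quadratic, or linear+quadratic
    (quadratic-only forms are permitted).  With ``interactions`` pairwise
    products between two linearly-present noise measures are added as a
    variant.  With ``include_distance`` every model is generated both with
    and without the distance covariate.  ``explicit_models`` bypasses the
    enumeration entirely.
    """

    response: str
    noise_terms: tuple[str, ...] = NOISE_TERMS
    include_distance: bool = False
    quadratics: bool = False
    interactions: bool = False
    max_noise_terms: Optional[int] = None
    random: str = "intercept"
    slope_term: str = "bout_background"
    explicit_models: Optional[tuple[tuple[str, ...], ...]] = None


def default_amplitude_config() -> ModelSetConfig:
    """Candidate set for song amplitude: all three noise measures with
    quadratics, pairwise interactions, and an optional distance term."""
    return ModelSetConfig(
        response="song_amplitude",
        include_distance=True,
        quadratics=True,
        interactions=True,
        max_noise_terms=2,
        random="intercept",
    )


def default_minfreq_config(random: str = "intercept") -> ModelSetConfig:
    """Candidate set for song minimum frequency: noise measures with
    quadratics and pairwise interactions, no distance term."""
    return ModelSetConfig(
        response="min_freq",
        include_distance=False,
        quadratics=True,
        interactions=True,
        max_noise_terms=2,
        random=random,
    )


def build_model_set(config: ModelSetConfig) -> list[ModelSpec]:
    """Enumerate the candidate :class:`ModelSpec` set for a config.

    Always includes the intercept-only null model.
    """
    if config.explicit_models is not None:
        specs = [
            ModelSpec(config.response, tuple(terms), config.random, config.slope_term)
            for terms in config.explicit_models
        ]
        if not any(not s.fixed_terms for s in specs):
            specs.insert(0, ModelSpec(config.response, (), config.random, config.slope_term))
        return specs

    if not config.noise_terms:
        raise ValueError("empty term pool")
    cap = config.max_noise_terms or len(config.noise_terms)

    noise_variants: list[tuple[str, ...]] = [()]
    for r in range(1, cap + 1):
        for subset in itertools.combinations(config.noise_terms, r):
            states = [("lin", "quad", "both")] if config.quadratics else [("lin",)]
            states = states[0]
            for combo in itertools.product(states, repeat=r):
                terms: list[str] = []
                for t, st in zip(subset, combo):
                    if st in ("lin", "both"):
                        terms.append(t)
                    if st in ("quad", "both"):
                        terms.append(f"{t}^2")
                noise_variants.append(tuple(terms))
                if (
                    config.interactions
                    and r == 2
                    and all(st in ("lin", "both") for st in combo)
                ):
                    noise_variants.append(tuple(terms) + (f"{subset[0]}:{subset[1]}",))

    specs = []
    distance_options = (False, True) if config.include_distance else (False,)
    for with_d in distance_options:
        for nv in noise_variants:
            terms = (("distance",) if with_d else ()) + nv
            specs.append(
                ModelSpec(config.response, terms, config.random, config.slope_term)
            )
    # drop the duplicate empty-with-distance? ("distance" alone is a real model)
    seen = set()
    out = []
    for s in specs:
        if s.fixed_terms not in seen:
            seen.add(s.fixed_terms)
            out.append(s)
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _design_column(df: pd.DataFrame, term: str) -> np.ndarray:
    if term.endswith("^2"):
        return df[term[:-2]].to_numpy(dtype=float) ** 2
    if ":" in term:
        a, b = term.split(":")
        return df[a].to_numpy(dtype=float) * df[b].to_numpy(dtype=float)
    return df[term].to_numpy(dtype=float)


def fit_mixed_model(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit one candidate linear mixed model by maximum likelihood.

    ``data`` needs the response column, every base covariate named in the
    fixed terms, and a ``bird_id`` grouping column with >= 2 birds.
    Non-convergence and boundary (singular) variance estimates are flagged
    on the result rather than raised; :func:`rank_models` excludes flagged
    fits from the ranking with a warning.
    """
    required = {spec.response, "bird_id"} | {
        t.split("^")[0].split(":")[0] for t in spec.fixed_terms
    } | {b for t in spec.fixed_terms if ":" in t for b in t.split(":")}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"data table missing columns: {sorted(missing)}")
    if data["bird_id"].nunique() < 2:
        raise ValueError("mixed model requires >= 2 birds")

    endog = data[spec.response].to_numpy(dtype=float)
    names = ["Intercept"] + list(spec.fixed_terms)
    exog = np.column_stack(
        [np.ones(len(data))] + [_design_column(data, t) for t in spec.fixed_terms]
    )
    groups = data["bird_id"].to_numpy()

    if spec.random == "slope":
        exog_re = np.column_stack(
            [np.ones(len(data)), data[spec.slope_term].to_numpy(dtype=float)]
        )
        n_vc = 3  # var(intercept), var(slope), their covariance
    else:
        exog_re = np.ones((len(data), 1))
        n_vc = 1

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(endog, exog, groups=groups, exog_re=exog_re)
        try:
            res = model.fit(reml=False, maxiter=500)
            if not res.converged or not np.isfinite(res.llf):
                res = model.fit(reml=False, method="powell", maxiter=1000)
        except (np.linalg.LinAlgError, ValueError):
            return FitResult(
                spec=spec,
                log_likelihood=-np.inf,
                k=len(names) + n_vc + 1,
                n=len(data),
                aicc=np.inf,
                coefficients=pd.Series(dtype=float),
                std_errors=pd.Series(dtype=float),
                converged=False,
            )

        k = len(names) + n_vc + 1  # fixed effects + RE (co)variances + residual
        llf = float(res.llf)
        converged = bool(res.converged) and np.isfinite(llf)
        n = len(data)
        coefs = pd.Series(np.asarray(res.fe_params, dtype=float), index=names)
        ses = pd.Series(np.asarray(res.bse_fe, dtype=float), index=names)
        cov_re = np.atleast_2d(np.asarray(res.cov_re, dtype=float))
        singular = bool(np.any(np.diag(cov_re) < 1e-10 * max(res.scale, 1e-12)))
        if singular:
            # random effects unpredictable at the boundary; fixed part only
            fitted = exog @ np.asarray(res.fe_params, dtype=float)
        else:
            fitted = np.asarray(res.fittedvalues, dtype=float)
    return FitResult(
        spec=spec,
        log_likelihood=llf,
        k=k,
        n=n,
        aicc=aicc(llf, k, n) if np.isfinite(llf) else np.inf,
        coefficients=coefs,
        std_errors=ses,
        converged=converged,
        singular=singular,
        fitted_values=fitted,
        residuals=endog - fitted,
    )


def fit_model_set(data: pd.DataFrame, config: ModelSetConfig) -> ModelSetResult:
    """Enumerate, fit, and rank a candidate set on one data table."""
    specs = build_model_set(config)
    fits = [fit_mixed_model(data, s) for s in specs]
    return rank_models(fits)


def rank_models(fits: Sequence[FitResult]) -> ModelSetResult:
    """Rank fitted candidates by AICc and attach weights and deltas.

    Non-converged or singular fits are excluded from the ranking (with a
    logged warning); weights are normalised over the usable set.
    """
    usable = [f for f in fits if f.usable]
    excluded = [f for f in fits if not f.usable]
    for f in excluded:
        logger.warning(
            "model %r excluded from ranking (converged=%s, singular=%s)",
            f.spec.name, f.converged, f.singular,
        )
    if not usable:
        raise ValueError("no usable fits in the candidate set")
    order = np.argsort([f.aicc for f in usable], kind="stable")
    ranked = [usable[i] for i in order]
    aiccs = np.array([f.aicc for f in ranked])
    w = akaike_weights(aiccs)
    table = pd.DataFrame(
        {
            "model": [f.spec.name for f in ranked],
            "K": [f.k for f in ranked],
            "AICc": aiccs,
            "dAICc": aiccs - aiccs[0],
            "weight": w,
        }
    )
    null_name = ModelSpec(ranked[0].spec.response, ()).name
    return ModelSetResult(
        fits=ranked, table=table, weights=w, null_name=null_name, excluded=excluded
    )


def covariation_test(
    minfreq_table: pd.DataFrame, amplitude_table: pd.DataFrame
) -> ModelSetResult:
    """Does minimum frequency covary with song amplitude?

    Joins the two per-song tables on ``song_id``, fits
    ``min_freq ~ song_amplitude`` and the intercept-only null (both with a
    by-bird random intercept), and returns their AICc comparison.
    """
    joined = minfreq_table.merge(
        amplitude_table[["song_id", "song_amplitude"]], on="song_id", how="inner"
    ).dropna(subset=["min_freq", "song_amplitude"])
    if joined.empty:
        raise ValueError("no songs shared between the two tables")
    specs = [
        ModelSpec("min_freq", ()),
        ModelSpec("min_freq", ("song_amplitude",)),
    ]
    fits = [fit_mixed_model(joined, s) for s in specs]
    return rank_models(fits)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

@dataclass
class ResidualDiagnostics:
    """Plot-ready residual summaries for one fitted model."""

    fitted: np.ndarray
    residuals: np.ndarray
    trend_slope: float  # OLS slope of residual vs fitted (should be ~0)
    spread_ratio: float  # |resid| spread, upper vs lower fitted half
    normality_stat: float  # D'Agostino-Pearson K^2
    normality_p: float


def residual_diagnostics(fit: FitResult) -> ResidualDiagnostics:
    """Heteroscedasticity and normality summaries for a converged fit.

    ``spread_ratio`` compares the mean absolute residual in the upper half
    of fitted values with the lower half; values well above 1 indicate
    variance growing with the mean.
    """
    if not fit.converged or fit.residuals is None:
        raise ValueError("diagnostics require a converged fit with residuals")
    fitted, resid = fit.fitted_values, fit.residuals
    slope = float(np.polyfit(fitted, resid, 1)[0]) if np.ptp(fitted) > 0 else 0.0
    med = np.median(fitted)
    lower = np.abs(resid[fitted <= med])
    upper = np.abs(resid[fitted > med])
    if lower.size == 0 or upper.size == 0 or lower.mean() == 0:
        ratio = 1.0
    else:
        ratio = float(upper.mean() / lower.mean())
    k2, p = stats.normaltest(resid)
    return ResidualDiagnostics(
        fitted=fitted,
        residuals=resid,
        trend_slope=slope,
        spread_ratio=ratio,
        normality_stat=float(k2),
        normality_p=float(p),
    )
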