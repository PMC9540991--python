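"""Stepwise AIC model building, Akaike weights and averaged effect sizes.

Models are built by forward stepwise addition over a candidate list: at each
step the term that lowers AIC the most enters, and the search stops when no
addition improves AIC.  Interactions between a species habitat-affiliation
flag and a landscape covariate are considered only from an a-priori
whitelist, may enter only once the flag's main effect is present, and are
parameterized as the pair of conditional slopes (``flag:cov`` and
``!flag:cov``), replacing the covariate's main effect — so each slope is
tested against zero within its species group.  Two covariates declared as a
correlated (mutually exclusive) pair never co-occur in one model.

After the stepwise search, each selected covariate is replaced one-by-one by
its declared correlated alternatives; every substitution within 2 AIC of the
best model is retained, and predictions are averaged across the retained
models with Akaike weights on the log-time scale (geometric-mean
semantics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .survival import FitError, FitResult, fit_exponential_frailty, predict_mean_time

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """Search space for stepwise model building.

    ``candidates`` are main-effect covariate names; ``interactions`` are
    (flag, covariate) pairs allowed to interact; ``exclusive_pairs`` lists
    covariates never admitted together, and doubles as the substitution map
    in the post-search replacement step.  Pairs of candidates whose absolute
    sample correlation exceeds ``corr_threshold`` are treated as exclusive
    automatically.
    """

    candidates: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()
    exclusive_pairs: tuple[frozenset, ...] = ()
    corr_threshold: float = 0.7
    base_terms: tuple[str, ...] = ()


@dataclass
class ModelSet:
    """Candidate models retained after selection, with Akaike weights."""

    models: list[FitResult]
    delta_aic: np.ndarray
    weights: np.ndarray

    @property
    def best(self) -> FitResult:
        return self.models[int(np.argmin([m.aic for m in self.models]))]


def akaike_weights(aics: Sequence[float]) -> np.ndarray:
    """w_m = exp(-Delta_m / 2) normalized; Delta relative to the minimum AIC."""
    a = np.asarray(aics, dtype=float)
    if len(a) == 0 or not np.all(np.isfinite(a)):
        raise ValueError("AICs must be a nonempty finite sequence")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def _interaction_terms(flag: str, cov: str) -> tuple[str, str]:
    return (f"{flag}:{cov}", f"!{flag}:{cov}")


def _covariates_in(terms: Sequence[str]) -> set[str]:
    """Bare covariate names appearing anywhere in the term list."""
    out = set()
    for term in terms:
        for factor in term.split(":"):
            out.add(factor.lstrip("!"))
    return out


def _exclusions(table: pd.DataFrame, config: SelectionConfig) -> set[frozenset]:
    pairs = {frozenset(p) for p in config.exclusive_pairs}
    cand = [c for c in config.candidates if c in table.columns]
    for i, a in enumerate(cand):
        for b in cand[i + 1:]:
            va, vb = table[a], table[b]
            if va.std() == 0 or vb.std() == 0:
                continue
            if abs(np.corrcoef(va, vb)[0, 1]) > config.corr_threshold:
                pairs.add(frozenset((a, b)))
    return pairs


def _blocked(cov: str, present: set[str], exclusions: set[frozenset]) -> bool:
    return any(
        cov in pair and (pair - {cov}) & present
        for pair in exclusions
    )


def stepwise_build(
    table: pd.DataFrame,
    config: SelectionConfig,
    **fit_kwargs,
) -> ModelSet:
    """Forward stepwise AIC search followed by correlated-variable substitution.

    Returns the best model plus every single-substitution alternative within
    2 AIC of it.  Candidates whose fit fails are logged and skipped.
    """
    exclusions = _exclusions(table, config)

    def fit(terms: Sequence[str]) -> FitResult | None:
        try:
            return fit_exponential_frailty(table, terms, **fit_kwargs)
        except FitError as exc:
            logger.warning("skipping candidate %s: %s", list(terms), exc)
            return None

    terms = list(config.base_terms)
    current = fit(terms)
    if current is None:
        raise FitError("the base model could not be fitted")

    while True:
        present = _covariates_in(terms)
        moves: list[tuple[list[str], FitResult]] = []

        for cov in config.candidates:
            if cov in terms or _blocked(cov, present, exclusions):
                continue
            m = fit(terms + [cov])
            if m is not None:
                moves.append((terms + [cov], m))

        for flag, cov in config.interactions:
            pair = _interaction_terms(flag, cov)
            if pair[0] in terms or flag not in terms:
                continue  # flag main effect must already be present
            if cov not in present and _blocked(cov, present, exclusions):
                continue
            new = [t for t in terms if t != cov] + list(pair)
            m = fit(new)
            if m is not None:
                moves.append((new, m))

        if not moves:
            break
        best_terms, best_fit = min(moves, key=lambda tm: tm[1].aic)
        if best_fit.aic >= current.aic:
            break
        terms, current = best_terms, best_fit

    models = [current]
    seen = {tuple(sorted(terms))}
    for pair in exclusions:
        pair = tuple(pair)
        for a, b in ((pair[0], pair[1]), (pair[1], pair[0])):
            if a not in _covariates_in(terms) or b in _covariates_in(terms):
                continue
            substituted = [_swap_term(t, a, b) for t in terms]
            key = tuple(sorted(substituted))
            if key in seen:
                continue
            seen.add(key)
            m = fit(substituted)
            if m is not None and m.aic < current.aic + 2.0:
                models.append(m)

    aics = [m.aic for m in models]
    order = np.argsort(aics)
    models = [models[i] for i in order]
    aics = np.asarray(aics)[order]
    return ModelSet(models=models, delta_aic=aics - aics.min(), weights=akaike_weights(aics))


def _swap_term(term: str, a: str, b: str) -> str:
    """Replace covariate ``a`` by ``b`` inside a (possibly interaction) term."""
    factors = []
    for factor in term.split(":"):
        neg = factor.startswith("!")
        name = factor.lstrip("!")
        if name == a:
            name = b
        factors.append(("!" if neg else "") + name)
    return ":".join(factors)


@dataclass(frozen=True)
class EffectSize:
    """Top-vs-bottom-quintile contrast of model-averaged predicted times."""

    focal: str
    time_low: float    # geometric mean predicted time, bottom 20% of landscapes
    time_high: float   # geometric mean predicted time, top 20%
    n_low: int
    n_high: int

    @property
    def ratio(self) -> float:
        return self.time_high / self.time_low


def averaged_effect_sizes(
    modelset: ModelSet,
    table: pd.DataFrame,
    focal: str,
    zone_columns: Sequence[str],
    fixed: dict[str, float] | None = None,
    group: dict[str, float] | None = None,
    quantile: float = 0.2,
    max_rows: int | None = None,
    seed: int = 0,
) -> EffectSize:
    """Effect of realistic landscape variation on predicted arrival time.

    Whole rows of the zone-covariate block are resampled from the observed
    table (preserving their covariation); covariates in ``fixed`` are pinned
    (e.g. distance at 1.00 = 100 km), species flags set per ``group`` and
    every other covariate held at its observed median.  Predictions from
    each model are combined on the log-time scale with Akaike weights and
    the geometric mean predicted time is contrasted between rows in the top
    and bottom ``quantile`` of the focal covariate.
    """
    if focal not in zone_columns:
        raise ValueError("the focal covariate must be one of the zone columns")
    zone = table[list(zone_columns)].reset_index(drop=True)
    if max_rows is not None and len(zone) > max_rows:
        rng = np.random.default_rng(seed)
        zone = zone.iloc[rng.choice(len(zone), max_rows, replace=False)].reset_index(drop=True)
    if zone[focal].nunique() < 2:
        raise ValueError(f"focal covariate {focal!r} is constant: degenerate scenario")

    needed = set()
    for m in modelset.models:
        needed |= _covariates_in(m.terms)
    scenario = pd.DataFrame(index=zone.index)
    for col in needed:
        if col in zone_columns:
            scenario[col] = zone[col].to_numpy()
        elif fixed and col in fixed:
            scenario[col] = fixed[col]
        elif group and col in group:
            scenario[col] = group[col]
        else:
            scenario[col] = float(table[col].median())

    log_pred = np.zeros(len(scenario))
    for w, m in zip(modelset.weights, modelset.models):
        log_pred += w * np.log(predict_mean_time(m, scenario))

    x = zone[focal].to_numpy(dtype=float)
    lo_cut = np.quantile(x, quantile)
    hi_cut = np.quantile(x, 1.0 - quantile)
    low = x <= lo_cut
    high = x >= hi_cut
    return EffectSize(
        focal=focal,
        time_low=float(np.exp(log_pred[low].mean())),
        time_high=float(np.exp(log_pred[high].mean())),
        n_low=int(low.sum()),
        n_high=int(high.sum()),
    )
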