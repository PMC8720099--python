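"""Predictor selection rules and three-set variance partitioning.

The comparison design fits one additive model per predictor subset of the
climate/habitat/soil triple (7 models) and decomposes the full model's
explained deviance by inclusion-exclusion into three pure, three
pairwise-shared and one triple-shared component.  Shared components may be
negative (suppression: the overlap explains less jointly than separately)
and are reported as-is.  Subset models are fitted with every term's
smoothing parameter frozen at its value from the full three-predictor fit,
so all 7 models share one set of model parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .gam import GamFit, fit_gam

__all__ = [
    "CollinearityReport",
    "VPResult",
    "LinearFitSummary",
    "collinearity_screen",
    "select_by_aic",
    "variance_partition",
    "stepwise_linear",
    "filter_soil_models",
]


@dataclass(frozen=True)
class CollinearityReport:
    pairs: tuple[tuple[str, str, float], ...]   # (name_a, name_b, r), |r| > threshold
    zero_variance: tuple[str, ...]
    threshold: float

    def __bool__(self) -> bool:
        return bool(self.pairs)


def collinearity_screen(candidates: Mapping[str, Sequence[float]],
                        threshold: float = 0.6) -> CollinearityReport:
    """All unordered predictor pairs whose |Pearson r| exceeds the threshold
    (the predictor combination is changed when r > 0.6).  Zero-variance
    vectors cannot enter a correlation and are reported separately."""
    arrs = {k: np.asarray(v, dtype=float) for k, v in candidates.items()}
    lengths = {a.size for a in arrs.values()}
    if len(lengths) > 1:
        raise ValueError("candidate vectors differ in length")
    if lengths and next(iter(lengths)) < 3:
        raise ValueError("need n >= 3 for a meaningful correlation")
    degenerate = tuple(sorted(k for k, a in arrs.items() if np.std(a) == 0))
    usable = sorted(k for k in arrs if k not in degenerate)
    pairs = []
    for a, b in combinations(usable, 2):
        r = float(np.corrcoef(arrs[a], arrs[b])[0, 1])
        if abs(r) > threshold:
            pairs.append((a, b, r))
    return CollinearityReport(tuple(pairs), degenerate, threshold)


def select_by_aic(response, variants: Mapping[str, Sequence[float]],
                  gamma: float = 1.0) -> str:
    """Among alternative statistics of one environmental factor (e.g. mean /
    max / sd temperature), pick the one whose univariate additive model has
    the lowest AIC.  Ties break deterministically by name order."""
    if not variants:
        raise ValueError("no variants supplied")
    best_name, best_aic = None, np.inf
    errors = {}
    for name in sorted(variants):
        try:
            fit = fit_gam(response, {name: variants[name]}, gamma=gamma)
        except Exception as exc:  # noqa: BLE001 - report all failures at end
            errors[name] = exc
            continue
        if fit.aic < best_aic:
            best_name, best_aic = name, fit.aic
    if best_name is None:
        raise ValueError(f"all candidate fits failed: {errors}")
    return best_name


@dataclass(frozen=True)
class VPResult:
    """Seven-component partition of the full model's explained deviance.

    pure: exclusively explained by climate (a), habitat (b), soil (c);
    pairwise_shared: climate&habitat (d), habitat&soil (e), climate&soil (f);
    triple_shared: g.  Components sum to the full model's deviance exactly
    and may individually be negative.
    """

    pure: dict
    pairwise_shared: dict
    triple_shared: float
    full_deviance: float
    subset_deviance: dict

    def components(self) -> dict:
        return {**{k: v for k, v in self.pure.items()},
                **{k: v for k, v in self.pairwise_shared.items()},
                "g": self.triple_shared}

    def total(self) -> float:
        return sum(self.pure.values()) + sum(self.pairwise_shared.values()) \
            + self.triple_shared


def variance_partition(response,
                       climate, habitat, soil,
                       names: tuple[str, str, str] = ("climate", "habitat", "soil"),
                       gamma: float = 1.0,
                       freeze: str = "smoothing") -> VPResult:
    """Three-set variance partitioning over 7 additive models.

    The full model (all three predictors) is fitted with GCV; the six subset
    models are then refitted with each term's smoothing parameter frozen at
    the full-model value (``freeze='smoothing'``, the default) or re-chosen
    by GCV per subset (``freeze='none'``).  With D(S) the explained deviance
    of subset S and A/B/C = climate/habitat/soil:

        a = D(ABC) - D(BC)            pure climate
        b = D(ABC) - D(AC)            pure habitat
        c = D(ABC) - D(AB)            pure soil
        d = D(AC) + D(BC) - D(C) - D(ABC)    climate & habitat
        e = D(AB) + D(AC) - D(A) - D(ABC)    habitat & soil
        f = D(AB) + D(BC) - D(B) - D(ABC)    climate & soil
        g = D(ABC) - a - b - c - d - e - f
    """
    if freeze not in ("smoothing", "none"):
        raise ValueError(f"unknown freeze mode {freeze!r}")
    nm_a, nm_b, nm_c = names
    data = {nm_a: np.asarray(climate, dtype=float),
            nm_b: np.asarray(habitat, dtype=float),
            nm_c: np.asarray(soil, dtype=float)}
    full = fit_gam(response, data, gamma=gamma)
    frozen = full.lambdas if freeze == "smoothing" else None

    def dev(*keys: str) -> float:
        sub = {k: data[k] for k in keys}
        lams = {k: frozen[k] for k in keys} if frozen is not None else None
        return fit_gam(response, sub, lambdas=lams, gamma=gamma).explained_deviance

    D_abc = full.explained_deviance
    D_ab, D_ac, D_bc = dev(nm_a, nm_b), dev(nm_a, nm_c), dev(nm_b, nm_c)
    D_a, D_b, D_c = dev(nm_a), dev(nm_b), dev(nm_c)

    a = D_abc - D_bc
    b = D_abc - D_ac
    c = D_abc - D_ab
    d = D_ac + D_bc - D_c - D_abc
    e = D_ab + D_ac - D_a - D_abc
    f = D_ab + D_bc - D_b - D_abc
    g = D_abc - a - b - c - d - e - f
    return VPResult(
        pure={"a": a, "b": b, "c": c},
        pairwise_shared={"d": d, "e": e, "f": f},
        triple_shared=g,
        full_deviance=D_abc,
        subset_deviance={
            nm_a: D_a, nm_b: D_b, nm_c: D_c,
            f"{nm_a}+{nm_b}": D_ab, f"{nm_a}+{nm_c}": D_ac,
            f"{nm_b}+{nm_c}": D_bc, f"{nm_a}+{nm_b}+{nm_c}": D_abc,
        },
    )


# ---------------------------------------------------------------------------
# stepwise multiple linear regression (soil surface models)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearFitSummary:
    name: str
    terms: tuple[str, ...]
    coefficients: dict
    r2: float
    adj_r2: float
    aic: float
    n: int


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    return beta, rss


def _ols_aic(y: np.ndarray, X: np.ndarray) -> float:
    n = y.size
    _, rss = _ols(y, X)
    sigma2 = max(rss / n, 1e-300)
    return n * np.log(sigma2) + 2.0 * (X.shape[1] + 1)


def stepwise_linear(response, candidates: Mapping[str, Sequence[float]],
                    name: str = "model") -> LinearFitSummary:
    """Bidirectional (forward and backward) AIC stepwise multiple linear
    regression starting from the intercept-only model."""
    y = np.asarray(response, dtype=float)
    cols = {k: np.asarray(v, dtype=float) for k, v in candidates.items()}
    n = y.size
    if n <= len(cols) + 1:
        raise ValueError(f"n = {n} too small for {len(cols)} candidates")
    for k, v in cols.items():
        if v.size != n:
            raise ValueError(f"candidate {k!r} length mismatch")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite values in candidate {k!r}")

    def design(terms: Sequence[str]) -> np.ndarray:
        return np.column_stack([np.ones(n)] + [cols[t] for t in terms])

    tss = float(np.sum((y - y.mean()) ** 2))
    selected: list[str] = []
    current_aic = _ols_aic(y, design(selected))
    while True:
        # an (essentially) perfect fit makes log(RSS) comparisons meaningless
        _, rss_cur = _ols(y, design(selected))
        if rss_cur <= 1e-12 * max(tss, 1e-300):
            break
        moves: list[tuple[float, str, str]] = []
        for t in sorted(set(cols) - set(selected)):
            moves.append((_ols_aic(y, design(selected + [t])), "add", t))
        for t in selected:
            rest = [s for s in selected if s != t]
            moves.append((_ols_aic(y, design(rest)), "drop", t))
        if not moves:
            break
        best_aic, action, term = min(moves)
        if best_aic >= current_aic - 1e-10:
            break
        if action == "add":
            selected.append(term)
        else:
            selected.remove(term)
        current_aic = best_aic

    X = design(selected)
    beta, rss = _ols(y, X)
    p = len(selected)
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    adj = 1.0 - (rss / max(n - p - 1, 1)) / (tss / (n - 1)) if tss > 0 else 1.0
    coefs = {"intercept": float(beta[0]),
             **{t: float(b) for t, b in zip(selected, beta[1:])}}
    return LinearFitSummary(name=name, terms=tuple(selected), coefficients=coefs,
                            r2=r2, adj_r2=adj, aic=current_aic, n=n)


def filter_soil_models(fits: Sequence[LinearFitSummary],
                       min_adj_r2: float = 0.45) -> list[LinearFitSummary]:
    """Retain only soil-surface models explaining more than the threshold
    (adjusted R^2 strictly greater than 0.45 by default); only such models'
    spatial predictions are carried forward as soil predictors."""
    return [f for f in fits if f.adj_r2 > min_adj_r2]
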