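"""Linear gloss-prediction model with a synthetic observer.

Perceived gloss is modelled as a linear function of the four highlight
statistics (number, mean size, percentage area, strength). A synthetic
observer generates noisy responses from known weights on the full design
grid so that the fitting path can be validated by parameter recovery;
fits report standardized and raw coefficients, R-squared and per-feature
rank correlations, globally and per factor subset.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .highlight_stats import ContrastMeasures, HighlightStatistics, ValidityFlags

__all__ = [
    "FEATURES",
    "SMOOTHNESS_LEVELS",
    "ALPHA_LEVELS",
    "SHAPES",
    "INTENSITY_LEVELS",
    "Condition",
    "StimulusRecord",
    "ObserverParams",
    "ModelFit",
    "enumerate_design",
    "design_trials",
    "adjustment_color_block",
    "adjustment_white_block",
    "adjustment_total_settings",
    "fit_linear",
    "synth_observer",
    "subset_analysis",
]

FEATURES = ("number", "mean_size", "pct_area", "strength")

SMOOTHNESS_LEVELS = (0.2, 0.3, 0.4, 0.5, 0.6)
ALPHA_LEVELS = (0.0, 0.04, 0.08, 0.12, 0.16, 0.32, 0.6)
SHAPES = ("blob1", "blob2", "blob3", "sphere", "cylinder")
INTENSITY_LEVELS = (0.5, 1.5)


@dataclass(frozen=True)
class Condition:
    shape: str
    smoothness: float
    alpha: float
    intensity: float


@dataclass
class StimulusRecord:
    condition: Condition
    statistics: HighlightStatistics | None = None
    contrasts: ContrastMeasures | None = None
    flags: ValidityFlags | None = None
    response: float | None = None

    @property
    def valid(self) -> bool:
        return self.flags is None or not self.flags.invalid

    def feature_vector(self) -> np.ndarray:
        if self.statistics is None:
            raise ValueError("record has no statistics")
        s = self.statistics
        return np.array([s.number, s.mean_size, s.pct_area, s.strength])


@dataclass(frozen=True)
class ObserverParams:
    """Generative observer: linear in the standardized features plus
    Gaussian noise."""

    intercept: float = 0.4
    weights: tuple[float, float, float, float] = (0.02, 0.03, -0.08, 0.06)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.weights) != len(FEATURES):
            raise ValueError("one weight per feature required")


@dataclass
class ModelFit:
    intercept: float
    weights: dict[str, float]
    raw_intercept: float
    raw_weights: dict[str, float]
    stderr: dict[str, float]
    r_squared: float
    spearman: dict[str, float]
    pearson: dict[str, float]
    n_used: int


# ---------------------------------------------------------------------------
# design enumeration


def enumerate_design(
    smoothness_levels=SMOOTHNESS_LEVELS,
    alpha_levels=ALPHA_LEVELS,
    shapes=SHAPES,
    intensity_levels=INTENSITY_LEVELS,
) -> list[Condition]:
    """Cartesian product of the factor levels, deterministic order."""
    return [
        Condition(shape=sh, smoothness=sm, alpha=al, intensity=it)
        for sm, al, sh, it in itertools.product(
            smoothness_levels, alpha_levels, shapes, intensity_levels
        )
    ]


def design_trials(conditions: list[Condition], repetitions: int = 4) -> list[Condition]:
    """Condition list repeated ``repetitions`` times (one entry per trial)."""
    return [c for c in conditions for _ in range(repetitions)]


def adjustment_color_block(
    shapes=SHAPES, smoothness_levels=SMOOTHNESS_LEVELS, repetitions: int = 4
) -> list[Condition]:
    """One single-criterion adjustment block: shapes x smoothness x reps,
    all at the high light intensity."""
    conds = enumerate_design(
        smoothness_levels=smoothness_levels,
        alpha_levels=(math.nan,),  # spread is the dependent variable here
        shapes=shapes,
        intensity_levels=(1.5,),
    )
    return design_trials(conds, repetitions)


def adjustment_white_block(
    shapes=SHAPES,
    smoothness_levels=SMOOTHNESS_LEVELS,
    intensity_levels=INTENSITY_LEVELS,
    repetitions: int = 4,
) -> list[Condition]:
    """The white-light adjustment block, which adds the intensity factor."""
    conds = enumerate_design(
        smoothness_levels=smoothness_levels,
        alpha_levels=(math.nan,),
        shapes=shapes,
        intensity_levels=intensity_levels,
    )
    return design_trials(conds, repetitions)


def adjustment_total_settings(n_subjects: int = 4) -> int:
    """Total adjustment settings: three single-criterion blocks plus one
    white-light block per subject."""
    per_subject = 3 * len(adjustment_color_block()) + len(adjustment_white_block())
    return per_subject * n_subjects


# ---------------------------------------------------------------------------
# fitting


def _feature_matrix(records: list[StimulusRecord]) -> np.ndarray:
    return np.array([r.feature_vector() for r in records])


def _fit_records(records: list[StimulusRecord]) -> list[StimulusRecord]:
    return [
        r
        for r in records
        if r.valid
        and r.response is not None
        and r.statistics is not None
        and not np.any(np.isnan(r.feature_vector()))
    ]


def fit_linear(records: list[StimulusRecord]) -> ModelFit:
    """OLS of response on the four statistics.

    Features are standardized internally so the reported weights are
    comparable across features; raw-scale coefficients are derived from
    them. Exactly collinear features raise an error naming the pair.
    """
    used = _fit_records(records)
    n = len(used)
    if n < 6:
        raise ValueError(f"need at least 6 valid records, got {n}")
    X = _feature_matrix(used)
    y = np.array([r.response for r in used], dtype=np.float64)

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    for j, name in enumerate(FEATURES):
        if sd[j] <= 1e-12 * (abs(mu[j]) + 1.0):
            raise ValueError(f"feature '{name}' is constant (collinear with intercept)")
    Z = (X - mu) / sd
    corr = np.corrcoef(Z, rowvar=False)
    for i in range(len(FEATURES)):
        for j in range(i + 1, len(FEATURES)):
            if abs(corr[i, j]) > 1.0 - 1e-12:
                raise ValueError(
                    f"features '{FEATURES[i]}' and '{FEATURES[j]}' are exactly collinear"
                )

    A = np.column_stack([np.ones(n), Z])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    # a response with no variance explains nothing by convention
    r2 = 1.0 - sse / sst if sst > 1e-12 * max(1.0, float(y @ y)) else 0.0

    dof = n - A.shape[1]
    sigma2 = sse / dof if dof > 0 else math.nan
    cov = sigma2 * np.linalg.pinv(A.T @ A)
    se = np.sqrt(np.diag(cov))

    weights = dict(zip(FEATURES, beta[1:]))
    raw_weights = {f: beta[1 + j] / sd[j] for j, f in enumerate(FEATURES)}
    raw_intercept = float(beta[0] - sum(beta[1 + j] * mu[j] / sd[j] for j in range(4)))

    spearman, pearson = {}, {}
    y_constant = np.ptp(y) == 0
    for j, f in enumerate(FEATURES):
        if y_constant:
            spearman[f] = pearson[f] = math.nan
            continue
        spearman[f] = float(stats.spearmanr(X[:, j], y).statistic)
        pearson[f] = float(stats.pearsonr(X[:, j], y).statistic)

    return ModelFit(
        intercept=float(beta[0]),
        weights={k: float(v) for k, v in weights.items()},
        raw_intercept=raw_intercept,
        raw_weights={k: float(v) for k, v in raw_weights.items()},
        stderr=dict(zip(FEATURES, map(float, se[1:]))),
        r_squared=float(r2),
        spearman=spearman,
        pearson=pearson,
        n_used=n,
    )


# ---------------------------------------------------------------------------
# synthetic observer


def synth_observer(
    records: list[StimulusRecord], params: ObserverParams
) -> list[StimulusRecord]:
    """Assign noisy linear responses to the valid records.

    Features are standardized across the valid records (the same set a
    subsequent fit would use), so the generative weights live on the same
    scale as the fitted standardized weights. Deterministic per seed.
    """
    out = [replace(r) for r in records]
    idx = [
        i
        for i, r in enumerate(out)
        if r.valid
        and r.statistics is not None
        and not np.any(np.isnan(r.feature_vector()))
    ]
    if not idx:
        return out
    X = _feature_matrix([out[i] for i in idx])
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    rng = np.random.default_rng(params.seed)
    noise = rng.normal(0.0, params.noise_sd, size=len(idx))
    responses = params.intercept + Z @ np.asarray(params.weights) + noise
    for k, i in enumerate(idx):
        out[i].response = float(responses[k])
    return out


# ---------------------------------------------------------------------------
# subset analysis


def subset_analysis(
    records: list[StimulusRecord], split_factors: tuple[str, ...] = ()
) -> dict[tuple, ModelFit | str]:
    """One fit per level combination of ``split_factors``.

    Factors are attribute names of Condition ('shape', 'smoothness',
    'alpha', 'intensity'). An empty tuple reproduces the single global
    fit under the key (). Subsets too small (or degenerate) to fit are
    recorded as the string 'unfittable'.
    """
    groups: dict[tuple, list[StimulusRecord]] = {}
    for r in records:
        key = tuple(getattr(r.condition, f) for f in split_factors)
        groups.setdefault(key, []).append(r)
    out: dict[tuple, ModelFit | str] = {}
    for key in sorted(groups):
        try:
            out[key] = fit_linear(groups[key])
        except (ValueError, np.linalg.LinAlgError):
            out[key] = "unfittable"
    return out
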