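"""Forward-validation protocol and prediction-performance statistics.

Accuracy is the Pearson correlation r(y*, y_hat) between pre-corrected
phenotypes and model predictions in the validation set; RRMSE the root-mean-
squared prediction error relative to the phenotypic SD; the bias slope the
OLS coefficient of y* on y_hat (>1 deflated, <1 inflated predictions);
model R^2 the squared correlation within the reference set. Accuracies of
competing models fitted to the same phenotypes are compared with the
Hotelling-Williams test for dependent correlations. The forward split
trains on older generations and validates on the youngest, mimicking
deployment in a breeding program.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationSplit",
    "EvalResult",
    "forward_split",
    "accuracy",
    "rrmse",
    "bias_slope",
    "model_r2",
    "bootstrap_se",
    "hotelling_williams_test",
    "component_correlation_table",
]


@dataclass
class ValidationSplit:
    """Disjoint reference/validation individual sets from generation labels."""

    reference_ids: list
    validation_ids: list
    rule: str = ""

    def __post_init__(self):
        if set(self.reference_ids) & set(self.validation_ids):
            raise ValueError("reference and validation sets overlap")


def forward_split(generations, validation_generation, ids=None) -> ValidationSplit:
    """Individuals of ``validation_generation`` validate; all others train."""
    gen = np.asarray(generations)
    if ids is None:
        ids = np.arange(len(gen))
    ids = np.asarray(ids, dtype=object)
    if len(ids) != len(gen):
        raise ValueError("ids and generations must have equal length")
    mask = gen == validation_generation
    if not mask.any():
        raise ValueError(f"no individuals in generation {validation_generation!r}")
    if mask.all():
        raise ValueError("reference set is empty: all individuals in the "
                         "validation generation")
    return ValidationSplit(
        reference_ids=list(ids[~mask]),
        validation_ids=list(ids[mask]),
        rule=f"generation:{validation_generation}",
    )


def _check_pair(y_star, y_hat, min_n=3):
    a = np.asarray(y_star, dtype=float)
    b = np.asarray(y_hat, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if len(a) < min_n:
        raise ValueError(f"need at least {min_n} pairs")
    return a, b


def accuracy(y_star, y_hat) -> float:
    """Pearson correlation between phenotypes and predictions."""
    a, b = _check_pair(y_star, y_hat)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(stats.pearsonr(a, b).statistic)


def rrmse(y_star, y_hat, sigma_p: float | None = None) -> float:
    """Root-mean-squared prediction error relative to the phenotypic SD.

    ``sigma_p`` defaults to the sample SD (ddof=1) of ``y_star`` — the
    validation-set phenotypic standard deviation.
    """
    a, b = _check_pair(y_star, y_hat, min_n=2)
    if sigma_p is None:
        sigma_p = float(np.std(a, ddof=1))
    if sigma_p <= 0:
        raise ValueError("sigma_p must be positive")
    return float(np.sqrt(np.mean((a - b) ** 2)) / sigma_p)


def bias_slope(y_star, y_hat) -> float:
    """OLS slope of phenotypes on predictions; 1 = dispersion-unbiased,
    above 1 deflated, below 1 inflated predictions."""
    a, b = _check_pair(y_star, y_hat)
    vb = np.var(b, ddof=1)
    if vb == 0:
        raise ValueError("slope undefined: predictions are constant")
    return float(np.cov(a, b, ddof=1)[0, 1] / vb)


def model_r2(y_star_reference, y_hat_reference) -> float:
    """Squared correlation between phenotypes and fitted values in the
    reference set (equals OLS R^2 for the simple regression)."""
    return accuracy(y_star_reference, y_hat_reference) ** 2


def bootstrap_se(y_star, y_hat, n_boot: int = 10_000, seed: int = 0) -> float:
    """SD of the accuracy over paired bootstrap resamples.

    Resamples with an undefined correlation (a constant vector) are redrawn
    and counted in the log. Deterministic given the seed.
    """
    a, b = _check_pair(y_star, y_hat, min_n=10)
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    n = len(a)
    rs = np.empty(n_boot)
    filled = 0
    redrawn = 0
    while filled < n_boot:
        todo = n_boot - filled
        idx = rng.integers(0, n, size=(todo, n))
        xs, ys = a[idx], b[idx]
        xc = xs - xs.mean(axis=1, keepdims=True)
        yc = ys - ys.mean(axis=1, keepdims=True)
        den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
        ok = den > 0
        r = np.divide((xc * yc).sum(axis=1), den, out=np.zeros(todo), where=ok)
        good = np.flatnonzero(ok)
        rs[filled:filled + len(good)] = r[good]
        filled += len(good)
        redrawn += todo - len(good)
    if redrawn:
        logger.info("bootstrap_se: redrew %d degenerate resamples", redrawn)
    return float(rs.std(ddof=1))


def hotelling_williams_test(r12: float, r13: float, r23: float, n: int):
    """Williams' t for comparing two dependent correlations sharing variable 1.

    Tests r12 = r13 given the correlation r23 between the two predictors,
    using |R| = 1 - r12^2 - r13^2 - r23^2 + 2 r12 r13 r23 and
    rbar = (r12 + r13)/2; the statistic is referred to a t distribution with
    n - 3 degrees of freedom, two-sided.

    Returns ``(t, p, df)``.
    """
    for r in (r12, r13, r23):
        if not -1 < r < 1:
            raise ValueError("correlations must lie strictly in (-1, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    detR = 1.0 - r12**2 - r13**2 - r23**2 + 2.0 * r12 * r13 * r23
    if detR <= 0:
        raise ValueError("correlation triple is not positive definite")
    rbar = 0.5 * (r12 + r13)
    df = n - 3
    denom = 2.0 * detR * (n - 1) / df + rbar**2 * (1.0 - r23) ** 3
    t = (r12 - r13) * np.sqrt((n - 1) * (1.0 + r23) / denom)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p), df


def component_correlation_table(components: dict, y_star) -> pd.DataFrame:
    """Pairwise Pearson correlations among component predictions and y*.

    ``components`` maps labels (e.g. ``"g"``, ``"t"``, ``"tc"``, ``"gt"``)
    to validation-set effect vectors. A constant vector yields NaN entries
    rather than an error (its correlations are undefined).
    """
    y = np.asarray(y_star, dtype=float)
    cols = {**{k: np.asarray(v, dtype=float) for k, v in components.items()},
            "y_star": y}
    labels = list(cols)
    for k, v in cols.items():
        if v.shape != y.shape:
            raise ValueError(f"component {k!r} length mismatch")
    mat = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for i, ki in enumerate(labels):
        for kj in labels[i + 1:]:
            a, b = cols[ki], cols[kj]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                r = np.nan
            else:
                r = float(stats.pearsonr(a, b).statistic)
            mat.loc[ki, kj] = mat.loc[kj, ki] = r
    return mat


@dataclass
class EvalResult:
    """Validation-set statistics for one fitted model."""

    accuracy: float
    accuracy_se: float
    rrmse: float
    bias_slope: float
    model_r2_reference: float | None = None
    component_correlations: pd.DataFrame | None = None
    n_validation: int = 0
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "accuracy_se": self.accuracy_se,
            "rrmse": self.rrmse,
            "bias_slope": self.bias_slope,
            "model_r2_reference": self.model_r2_reference,
            "n_validation": self.n_validation,
        }
        if self.component_correlations is not None:
            d["component_correlations"] = {
                k: dict(v) for k, v in self.component_correlations.items()
            }
        d.update(self.extras)
        return d


def evaluate_forward(
    y_star,
    y_hat,
    validation_mask,
    components: dict | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
) -> EvalResult:
    """Assemble the full validation report for one model.

    ``validation_mask`` flags validation individuals within the vectors;
    reference individuals provide the model-R^2; component vectors, when
    given, are subset to the validation individuals for the correlation
    table.
    """
    y_star = np.asarray(y_star, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    mask = np.asarray(validation_mask, dtype=bool)
    yv, pv = y_star[mask], y_hat[mask]
    acc = accuracy(yv, pv)
    res = EvalResult(
        accuracy=acc,
        accuracy_se=bootstrap_se(yv, pv, n_boot=n_boot, seed=seed),
        rrmse=rrmse(yv, pv),
        bias_slope=bias_slope(yv, pv),
        n_validation=int(mask.sum()),
    )
    if (~mask).any():
        res.model_r2_reference = model_r2(y_star[~mask], y_hat[~mask])
    if components:
        res.component_correlations = component_correlation_table(
            {k: np.asarray(v)[mask] for k, v in components.items()}, yv
        )
    return res
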