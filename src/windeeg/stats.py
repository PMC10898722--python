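"""Band-ablation feature importance and the group-level statistics.

* one-tailed one-sample t-tests of accuracy against chance (0.5) and of
  importance against 0, with Holm-Bonferroni step-down correction;
* one-way repeated-measures ANOVA with the Greenhouse-Geisser sphericity
  correction (epsilon from the sample covariance of conditions);
* feature importance of each frequency band as the decrease in RBF-SVM
  accuracy when the band's six columns are removed from both training and
  test data, re-run under the same seeds as the full-feature protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import scipy.stats

from .classify import LabeledTrialSet, ProtocolResult, run_protocol
from .exceptions import InvalidParameterError, NumericalError
from .features import BAND_NAMES

IMPORTANCE_FAMILY = "svm_rbf"


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


class RmAnovaResult(NamedTuple):
    F: float
    df1: float
    df2: float
    epsilon: float
    p: float


@dataclass
class GroupStats:
    """Group-level battery over one value-per-participant-per-condition matrix."""

    condition_names: tuple[str, ...]
    means: dict[str, float]
    sds: dict[str, float]
    t_tests: dict[str, TTestResult]
    p_holm: dict[str, float]
    anova: RmAnovaResult | None
    mu0: float = 0.5


@dataclass
class ImportanceResult:
    """Per-band accuracy drops (full minus ablated) for one participant."""

    drops: dict[str, float]
    full_accuracy: float
    ablated_accuracy: dict[str, float] = field(default_factory=dict)


def one_sample_t_one_tailed(values: np.ndarray, mu0: float) -> TTestResult:
    """Upper-tail one-sample t-test: H1 mean > mu0."""
    x = np.asarray(values, float)
    n = len(x)
    if n < 2:
        raise InvalidParameterError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise NumericalError("zero variance; t statistic undefined")
    t = (x.mean() - mu0) / (sd / np.sqrt(n))
    df = n - 1
    p = float(scipy.stats.t.sf(t, df))
    return TTestResult(t=float(t), df=df, p=p)


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values (original order)."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        candidate = min((m - rank) * p[idx], 1.0)
        running_max = max(running_max, candidate)
        adjusted[idx] = running_max
    return adjusted


def rm_anova_gg(matrix: np.ndarray) -> RmAnovaResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``matrix`` is subjects x conditions with no missing cells. The F
    statistic uses the within-subject decomposition; epsilon comes from the
    sample (biased, 1/n) covariance of the conditions and the corrected
    p-value from the F distribution at (eps*df1, eps*df2).
    """
    x = np.asarray(matrix, float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise InvalidParameterError("need >= 3 subjects and >= 2 conditions")
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("matrix contains missing cells")
    n, k = x.shape

    grand = x.mean()
    subj_means = x.mean(axis=1, keepdims=True)
    cond_means = x.mean(axis=0, keepdims=True)
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    resid = x - subj_means - cond_means + grand
    ss_err = (resid**2).sum()
    df1, df2 = k - 1, (n - 1) * (k - 1)
    if ss_err <= 0:
        raise NumericalError("zero residual variance; F undefined")
    f_stat = (ss_cond / df1) / (ss_err / df2)

    # Greenhouse-Geisser epsilon via the double-centred sample covariance
    s = np.cov(x, rowvar=False, bias=True)
    s = np.atleast_2d(s)
    centred = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
    eigvals = np.linalg.eigvalsh(centred)
    eigvals = np.clip(eigvals, 0.0, None)
    denom = (k - 1) * (eigvals**2).sum()
    if denom <= 0:
        raise NumericalError("degenerate condition covariance; epsilon undefined")
    epsilon = float(eigvals.sum() ** 2 / denom)
    epsilon = float(np.clip(epsilon, 1.0 / (k - 1), 1.0))

    p = float(scipy.stats.f.sf(f_stat, epsilon * df1, epsilon * df2))
    return RmAnovaResult(F=float(f_stat), df1=df1, df2=df2, epsilon=epsilon, p=p)


def band_feature_names(band: str, feature_names: tuple[str, ...]) -> tuple[str, ...]:
    """The feature columns belonging to one frequency band."""
    if band not in BAND_NAMES:
        raise InvalidParameterError(
            f"unknown band {band!r}; expected one of {BAND_NAMES}"
        )
    return tuple(n for n in feature_names if n.endswith(f"_{band}"))


def band_ablation_importance(
    labeled: LabeledTrialSet,
    seed: int = 0,
    tuning_budget: int = 50,
    n_repetitions: int = 5,
    full_result: ProtocolResult | None = None,
) -> ImportanceResult:
    """Accuracy drop of the RBF SVM when each band's features are removed.

    The ablated protocols re-run with the same master seed as the full run,
    so identical undersampling draws and tuning streams are used and the
    drop reflects the removed features, not sampling noise.
    """
    if full_result is None:
        full_result = run_protocol(
            labeled,
            families=(IMPORTANCE_FAMILY,),
            n_repetitions=n_repetitions,
            seed=seed,
            tuning_budget=tuning_budget,
        )
    full_acc = full_result.per_family_mean[IMPORTANCE_FAMILY]
    drops: dict[str, float] = {}
    ablated: dict[str, float] = {}
    for band in BAND_NAMES:
        reduced = labeled.drop_features(band_feature_names(band, labeled.feature_names))
        result = run_protocol(
            reduced,
            families=(IMPORTANCE_FAMILY,),
            n_repetitions=n_repetitions,
            seed=seed,
            tuning_budget=tuning_budget,
        )
        ablated[band] = result.per_family_mean[IMPORTANCE_FAMILY]
        drops[band] = full_acc - ablated[band]
    return ImportanceResult(
        drops=drops, full_accuracy=full_acc, ablated_accuracy=ablated
    )


def group_statistics(
    values_by_condition: dict[str, np.ndarray], mu0: float = 0.5
) -> GroupStats:
    """t-tests (vs ``mu0``, one-tailed, Holm-corrected) + RM-ANOVA across conditions.

    ``values_by_condition`` maps condition name (classifier family or band)
    to one value per participant, participants aligned across conditions.
    """
    names = tuple(values_by_condition)
    arrays = [np.asarray(values_by_condition[n], float) for n in names]
    lengths = {len(a) for a in arrays}
    if len(lengths) != 1:
        raise InvalidParameterError("conditions have unequal participant counts")

    t_tests = {n: one_sample_t_one_tailed(a, mu0) for n, a in zip(names, arrays)}
    adjusted = holm_adjust(np.array([t_tests[n].p for n in names]))
    p_holm = dict(zip(names, adjusted.tolist()))

    anova = None
    if len(names) >= 2 and lengths.pop() >= 3:
        anova = rm_anova_gg(np.column_stack(arrays))
    return GroupStats(
        condition_names=names,
        means={n: float(a.mean()) for n, a in zip(names, arrays)},
        sds={n: float(a.std(ddof=1)) for n, a in zip(names, arrays)},
        t_tests=t_tests,
        p_holm=p_holm,
        anova=anova,
        mu0=mu0,
    )
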