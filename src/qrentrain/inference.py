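"""Statistical machinery: surrogate pairing, mixed models, Holm, networks.

Two questions are asked of the per-pair entrainment records:

1. Is question-response (dis)similarity different from what the two
   interlocutors' intrinsic movement styles would produce by chance?  The
   chance baseline is a *pseudo-pair* dataset: within each dyad the
   question-response correspondences are shuffled by a uniformly sampled
   derangement, so every question is paired with a response other than its
   own while no pairing ever crosses dyads.  Real and pseudo records are
   then compared with a likelihood-ratio test between nested random-
   intercept models (null: intercept only; full: + condition).

2. Does entrainment co-vary with the dyad's empathy-quotient difference?
   Same model comparison with the EQ difference as the fixed effect.

All models are linear mixed models with a single random intercept for the
combined dyad-and-responder identifier, fit by maximum likelihood (REML
log-likelihoods are not comparable across fixed-effects structures, so ML
is required for the LRTs).  Family-wise error over the two kinematic tests
is controlled with Holm's step-down correction; the prosodic test forms its
own singleton family.  A post hoc partial-correlation network relates the
three entrainment measures pairwise while controlling the third.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from .errors import DegenerateModelError, ValidationError
from .scoring import QAPair

logger = logging.getLogger(__name__)

__all__ = [
    "LmmResult",
    "PartialCorrelationNet",
    "MixedFitHandle",
    "shuffle_pairs",
    "fit_random_intercept_model",
    "likelihood_ratio_test",
    "holm_adjust",
    "surrogate_test",
    "eq_association_test",
    "run_surrogate_suite",
    "run_eq_suite",
    "partial_correlations",
    "KINEMATIC_FAMILY",
]

# Holm families: the two kinematic tests form one family; prosody is its own.
KINEMATIC_FAMILY = ("head_distance", "hand_distance")


@dataclass
class LmmResult:
    """A nested-model comparison for one dependent variable."""

    dependent: str
    fixed_effect: str
    chi2: float
    df: int
    p_raw: float
    beta: float
    se: float
    t: float
    p_adjusted: float | None = None
    n_obs: int = 0
    singular: bool = False

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValidationError("df must be >= 1")
        if self.chi2 < 0:
            raise ValidationError("chi-square statistic cannot be negative")
        if self.p_adjusted is not None and self.p_adjusted < self.p_raw - 1e-12:
            raise ValidationError("adjusted p cannot fall below raw p")


@dataclass
class PartialCorrelationNet:
    """Pairwise partial correlations among the three entrainment measures."""

    variables: tuple[str, str, str]
    partial_r: np.ndarray  # 3x3, unit diagonal, symmetric
    n_obs: int = 0

    def __post_init__(self) -> None:
        self.partial_r = np.asarray(self.partial_r, dtype=float)
        if self.partial_r.shape != (3, 3):
            raise ValidationError("partial_r must be 3x3")
        if not np.allclose(np.diag(self.partial_r), 1.0):
            raise ValidationError("partial_r diagonal must be 1")
        if not np.allclose(self.partial_r, self.partial_r.T):
            raise ValidationError("partial_r must be symmetric")
        if np.nanmax(np.abs(self.partial_r)) > 1 + 1e-9:
            raise ValidationError("partial correlations must lie in [-1, 1]")


def _sample_derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random derangement by rejection sampling (~e tries)."""
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def shuffle_pairs(
    pairs: Sequence[QAPair],
    seed: int | np.random.Generator = 0,
) -> list[QAPair]:
    """Build the pseudo-pair surrogate set.

    Within each dyad, responses are reassigned to questions by a uniformly
    sampled derangement: no question keeps its own response, and no pairing
    crosses dyads, so any dyad-level intrinsic similarity is preserved while
    pair-specific coupling is destroyed.  Dyads with a single pair admit no
    derangement and are excluded (logged).  Deterministic under a fixed seed.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    by_dyad: dict[str, list[QAPair]] = {}
    for p in pairs:
        by_dyad.setdefault(p.dyad_id, []).append(p)
    out: list[QAPair] = []
    for dyad_id in sorted(by_dyad):
        group = by_dyad[dyad_id]
        if len(group) < 2:
            logger.info("dyad %s has a single pair; no derangement exists, "
                        "excluded from the surrogate set", dyad_id)
            continue
        perm = _sample_derangement(len(group), rng)
        for i, j in enumerate(perm):
            q = group[i].question
            r = group[j].response
            out.append(QAPair(
                pair_id=f"{q.segment_id}+{r.segment_id}",
                question=q, response=r, dyad_id=dyad_id, surrogate=True,
            ))
    return out


@dataclass
class MixedFitHandle:
    """A fitted random-intercept model (ML)."""

    llf: float
    n_params: int
    n_obs: int
    dependent: str
    fixed_effect: str | None
    beta: float = np.nan
    se: float = np.nan
    t: float = np.nan
    singular: bool = False
    converged: bool = True


def fit_random_intercept_model(
    records: pd.DataFrame,
    dependent: str,
    fixed_effect: str | None = None,
    group_key: str = "group",
) -> MixedFitHandle:
    """ML fit of ``dependent ~ 1 [+ fixed_effect] + (1 | group)``.

    The grouping factor is a single identifier combining dyad and responder
    (nested random effects for dyad and participant are deliberately not
    used; a single combined intercept is the stable parameterization).
    """
    df = records.dropna(subset=[dependent]
                        + ([fixed_effect] if fixed_effect else []))
    y = df[dependent].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValidationError(f"non-finite values in dependent {dependent!r}")
    groups = df[group_key].to_numpy()
    if pd.unique(groups).size < 2:
        raise DegenerateModelError("need at least 2 groups")
    exog = np.ones((len(df), 1))
    if fixed_effect is not None:
        x = df[fixed_effect]
        if x.dtype == object or isinstance(x.dtype, pd.CategoricalDtype):
            levels = pd.unique(x)
            if len(levels) != 2:
                raise ValidationError(
                    f"fixed effect {fixed_effect!r} must be numeric or a "
                    f"2-level factor (got {len(levels)} levels)"
                )
            x = (x == sorted(map(str, levels))[1]).astype(float)
        x = np.asarray(x, dtype=float)
        if np.ptp(x) == 0:
            raise DegenerateModelError(
                f"fixed effect {fixed_effect!r} has zero variance"
            )
        exog = np.column_stack([exog[:, 0], x])
    model = MixedLM(y, exog, groups=groups)
    with warnings.catch_warnings():
        # boundary fits (zero random-effect variance) are flagged on the
        # handle instead of spamming per-fit warnings
        warnings.simplefilter("ignore")
        fit = model.fit(reml=False, method="bfgs", maxiter=500)
    singular = bool(np.asarray(fit.cov_re).min() < 1e-8)
    if singular:
        logger.warning("random-intercept variance is near zero for %s",
                       dependent)
    handle = MixedFitHandle(
        llf=float(fit.llf),
        # params: fixed effects + residual variance + random-intercept var
        n_params=exog.shape[1] + 2,
        n_obs=len(df),
        dependent=dependent,
        fixed_effect=fixed_effect,
        singular=singular,
        converged=bool(fit.converged),
    )
    if fixed_effect is not None:
        handle.beta = float(fit.fe_params[1])
        handle.se = float(fit.bse_fe[1])
        handle.t = handle.beta / handle.se
    return handle


def likelihood_ratio_test(
    null: MixedFitHandle, full: MixedFitHandle
) -> LmmResult:
    """Chi-square LRT of nested ML fits: 2(ll_full - ll_null), clipped at 0."""
    if null.dependent != full.dependent or null.n_obs != full.n_obs:
        raise DegenerateModelError(
            "LRT requires the same dependent and observations in both fits"
        )
    df = full.n_params - null.n_params
    if df < 1:
        raise DegenerateModelError("full model must add parameters")
    chi2 = max(0.0, 2.0 * (full.llf - null.llf))
    return LmmResult(
        dependent=full.dependent,
        fixed_effect=full.fixed_effect or "",
        chi2=chi2,
        df=df,
        p_raw=float(stats.chi2.sf(chi2, df)),
        beta=full.beta,
        se=full.se,
        t=full.t,
        n_obs=full.n_obs,
        singular=full.singular or null.singular,
    )


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def _prepare_conditions(
    real_records: pd.DataFrame, pseudo_records: pd.DataFrame
) -> pd.DataFrame:
    real = real_records.copy()
    pseudo = pseudo_records.copy()
    real["condition"] = "real"
    pseudo["condition"] = "pseudo"
    combined = pd.concat([real, pseudo], ignore_index=True)
    # code real=0, pseudo=1: a positive beta means pseudo pairs are more
    # distant (less similar) than real pairs
    combined["condition_code"] = (combined["condition"] == "pseudo").astype(
        float)
    return combined


def surrogate_test(
    real_records: pd.DataFrame,
    pseudo_records: pd.DataFrame,
    dependent: str,
    group_key: str = "group",
) -> LmmResult:
    """Real-vs-pseudo LRT for one entrainment measure.

    Positive ``beta`` (condition coded real=0, pseudo=1) means pseudo pairs
    are more dissimilar than real pairs, i.e. adjacency-specific
    entrainment beyond the dyad's intrinsic similarity.
    """
    combined = _prepare_conditions(real_records, pseudo_records)
    null = fit_random_intercept_model(combined, dependent, None, group_key)
    full = fit_random_intercept_model(combined, dependent, "condition_code",
                                      group_key)
    result = likelihood_ratio_test(null, full)
    result.fixed_effect = "condition"
    return result


def eq_association_test(
    real_records: pd.DataFrame,
    dependent: str,
    group_key: str = "group",
) -> LmmResult:
    """LRT for the dyad EQ-difference fixed effect on one measure."""
    if real_records["eq_diff"].isna().any():
        raise ValidationError("eq_diff must be present on all records")
    null_df = real_records.dropna(subset=[dependent])
    null = fit_random_intercept_model(null_df, dependent, None, group_key)
    full = fit_random_intercept_model(null_df, dependent, "eq_diff",
                                      group_key)
    return likelihood_ratio_test(null, full)


def _apply_holm_families(results: dict[str, LmmResult]) -> None:
    family = [d for d in KINEMATIC_FAMILY if d in results]
    if family:
        adjusted = holm_adjust([results[d].p_raw for d in family])
        for d, p in zip(family, adjusted):
            results[d].p_adjusted = float(p)
    for d, r in results.items():
        if d not in family:
            r.p_adjusted = r.p_raw  # singleton family


def run_surrogate_suite(
    real_records: pd.DataFrame,
    pseudo_records: pd.DataFrame,
    dependents: Sequence[str] = ("head_distance", "hand_distance", "f0_diff"),
    group_key: str = "group",
) -> dict[str, LmmResult]:
    """Chance-level tests for all measures, with Holm over the kinematics."""
    results = {
        dep: surrogate_test(real_records, pseudo_records, dep, group_key)
        for dep in dependents
    }
    _apply_holm_families(results)
    return results


def run_eq_suite(
    real_records: pd.DataFrame,
    dependents: Sequence[str] = ("head_distance", "hand_distance", "f0_diff"),
    group_key: str = "group",
) -> dict[str, LmmResult]:
    """EQ-difference association tests, with Holm over the kinematics."""
    results = {
        dep: eq_association_test(real_records, dep, group_key)
        for dep in dependents
    }
    _apply_holm_families(results)
    return results


def partial_correlations(
    records: pd.DataFrame,
    variables: tuple[str, str, str] = ("head_distance", "hand_distance",
                                      "f0_diff"),
) -> PartialCorrelationNet:
    """Pairwise partial correlations, each controlling the third variable.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)), computed
    on complete cases over all three measures.
    """
    df = records.loc[:, list(variables)].dropna()
    if len(df) < 4:
        raise ValidationError("need at least 4 complete cases")
    r = np.corrcoef(df.to_numpy(dtype=float), rowvar=False)
    out = np.eye(3)
    for a in range(3):
        for b in range(a + 1, 3):
            c = 3 - a - b
            denom = (1 - r[a, c] ** 2) * (1 - r[b, c] ** 2)
            if denom <= 1e-12:
                raise DegenerateModelError(
                    f"partial correlation of {variables[a]} and "
                    f"{variables[b]} is undefined: the third variable is "
                    "perfectly correlated with one of them"
                )
            out[a, b] = out[b, a] = (
                (r[a, b] - r[a, c] * r[b, c]) / np.sqrt(denom)
            )
    return PartialCorrelationNet(variables=tuple(variables), partial_r=out,
                                 n_obs=len(df))
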