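"""Statistical analysis of a coral-skeleton passive-dissolution experiment.

The experiment immerses bare coral skeletons (no living tissue) in still
seawater for a fixed exposure, either acidified (pH 7.8, the level projected
for 2100) or at present-day pH 8.2, and records the change in dry weight.
This module provides:

* per-sample summaries — weight loss normalized by initial weight, and the
  areal dissolution rate in g CaCO3 cm^-2 d^-1;
* group comparisons — one-way ANOVA and the Tukey honest-significant-
  difference post-hoc test, grouped by growth form / genus / treatment;
* the exponential surface-area–dissolution curve
  ``loss(SA) = -k_amp * exp(k_exp * SA)`` fitted by Gauss–Newton least
  squares, exposed as a Model/Results pair;
* :class:`DissolutionExperiment`, a model object wrapping a full sample table
  whose :meth:`~DissolutionExperiment.fit` runs the complete analysis.

Sign convention: losses are stored as ``w1 - w0``, so dissolution is
negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .units import ArealMassRate

__all__ = [
    "SAMPLE_COLUMNS",
    "GROWTH_FORMS",
    "POROSITY_CLASSES",
    "TREATMENTS",
    "normalized_loss",
    "areal_dissolution_rate",
    "mean_areal_rate",
    "group_summary",
    "one_way_anova",
    "AnovaResult",
    "tukey_hsd",
    "ExponentialLossModel",
    "ExponentialLossResults",
    "fit_exponential_loss",
    "DissolutionExperiment",
    "DissolutionResults",
    "FitError",
    "ConvergenceError",
]

# canonical sample-table schema; units are baked into the column names so a
# g-vs-kg slip cannot survive a round trip through CSV
SAMPLE_COLUMNS = [
    "sample_id",
    "genus",
    "growth_form",
    "porosity_class",
    "treatment",
    "w0_g",
    "w1_g",
    "surface_area_cm2",
    "volume_ml",
    "duration_d",
]

GROWTH_FORMS = ("submassive", "branching", "encrusting", "foliose")
POROSITY_CLASSES = ("perforate", "imperforate")
TREATMENTS = ("acidified", "control")


class FitError(ValueError):
    """Raised when the exponential loss fit cannot be set up."""


class ConvergenceError(FitError):
    """Gauss–Newton failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_params: tuple[float, float]):
        super().__init__(message)
        self.last_params = last_params


# ---------------------------------------------------------------------------
# per-sample summaries
# ---------------------------------------------------------------------------

def normalized_loss(samples: pd.DataFrame) -> pd.Series:
    """Weight change divided by initial weight, ``(w1 - w0) / w0`` (negative when dissolving)."""
    w0 = samples["w0_g"].to_numpy(dtype=float)
    if (w0 <= 0).any():
        bad = samples.index[w0 <= 0].tolist()
        raise ValueError(f"w0_g must be > 0 (rows {bad})")
    return (samples["w1_g"] - samples["w0_g"]) / samples["w0_g"]


def areal_dissolution_rate(samples: pd.DataFrame) -> pd.Series:
    """Per-sample areal rate ``(w1 - w0) / (surface_area * duration)`` in g cm^-2 d^-1."""
    sa = samples["surface_area_cm2"].to_numpy(dtype=float)
    dur = samples["duration_d"].to_numpy(dtype=float)
    if (sa <= 0).any() or (dur <= 0).any():
        raise ValueError("surface_area_cm2 and duration_d must be > 0")
    return (samples["w1_g"] - samples["w0_g"]) / (samples["surface_area_cm2"] * samples["duration_d"])


def mean_areal_rate(samples: pd.DataFrame) -> ArealMassRate:
    """Group-mean areal dissolution rate as a unit-tagged flux (g cm^-2 d^-1)."""
    return ArealMassRate(float(areal_dissolution_rate(samples).mean()), "g", "cm2", "d")


def group_summary(
    samples: pd.DataFrame, grouping: Sequence[str] = ("treatment", "genus", "growth_form")
) -> pd.DataFrame:
    """Per-group n, mean and sd of normalized loss (one row per group)."""
    if len(samples) == 0:
        raise ValueError("empty sample table")
    df = samples.copy()
    df["normalized_loss"] = normalized_loss(samples)
    out = (
        df.groupby(list(grouping), observed=True)["normalized_loss"]
        .agg(n="size", mean_normalized_loss="mean", sd_normalized_loss=lambda x: x.std(ddof=1))
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    """Classical one-way ANOVA decomposition."""

    F: float
    df_between: int
    df_within: int
    p: float
    ss_between: float
    ss_within: float
    degenerate: bool = False  # SSW == 0: all within-group spread vanished

    def __iter__(self):
        return iter((self.F, self.df_between, self.df_within, self.p))


def _split_groups(values, groups) -> list[np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    return [values[groups == g] for g in pd.unique(groups)]


def one_way_anova(values: Sequence[float], groups: Sequence) -> AnovaResult:
    """One-way fixed-effects ANOVA: F = (SSB/df1) / (SSW/df2), p from the F upper tail.

    With zero within-group variance everywhere the ratio degenerates:
    F is reported as ``inf`` with p = 0 and ``degenerate=True`` (or F = 0,
    p = 1 when the between-group spread also vanishes).
    """
    cells = _split_groups(values, groups)
    k = len(cells)
    n = sum(len(c) for c in cells)
    if k < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    df1, df2 = k - 1, n - k
    if df2 < 2:
        raise ValueError("ANOVA needs at least 2 residual degrees of freedom")
    grand = np.concatenate(cells).mean()
    ssb = sum(len(c) * (c.mean() - grand) ** 2 for c in cells)
    ssw = sum(((c - c.mean()) ** 2).sum() for c in cells)
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, df1, df2, 1.0, 0.0, 0.0, degenerate=True)
        return AnovaResult(math.inf, df1, df2, 0.0, float(ssb), 0.0, degenerate=True)
    f = (ssb / df1) / (ssw / df2)
    p = float(stats.f.sf(f, df1, df2))
    return AnovaResult(float(f), df1, df2, p, float(ssb), float(ssw))


def tukey_hsd(
    values: Sequence[float], groups: Sequence, alpha: float = 0.05
) -> pd.DataFrame:
    """Tukey honest-significant-difference pairwise comparisons.

    Uses the pooled within-group variance and the studentized-range
    distribution with ``k`` groups and ``n - k`` degrees of freedom
    (Tukey–Kramer for unequal group sizes).  Returns one row per pair with
    the mean difference, adjusted p and a significance flag at ``alpha``.
    """
    cells = _split_groups(values, groups)
    labels = list(pd.unique(np.asarray(groups)))
    anova = one_way_anova(values, groups)
    k = len(cells)
    msw = anova.ss_within / anova.df_within
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = cells[i].mean() - cells[j].mean()
            if msw == 0.0:
                p = 1.0 if diff == 0.0 else 0.0
            else:
                se = math.sqrt(msw / 2.0 * (1.0 / len(cells[i]) + 1.0 / len(cells[j])))
                q = abs(diff) / se
                p = float(stats.studentized_range.sf(q, k, anova.df_within))
            rows.append(
                {
                    "group1": labels[i],
                    "group2": labels[j],
                    "mean_diff": float(diff),
                    "p_adj": p,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exponential surface-area–dissolution model
# ---------------------------------------------------------------------------

class ExponentialLossModel:
    """Exponential surface-area–dissolution model ``loss = -k_amp * exp(k_exp * SA)``.

    Larger colonies of perforate corals expose disproportionately more
    internal surface to seawater, so the absolute CaCO3 loss grows
    exponentially with measured (wax-dip) surface area.  ``k_amp`` is the
    amplitude in g (> 0); ``k_exp`` the exponent coefficient in cm^-2.

    Parameters
    ----------
    surface_area : array-like, cm^2, strictly positive
    loss : array-like, g; typically <= 0 (dissolution)
    """

    def __init__(self, surface_area, loss):
        self.surface_area = np.asarray(surface_area, dtype=float)
        self.loss = np.asarray(loss, dtype=float)
        if self.surface_area.shape != self.loss.shape:
            raise FitError("surface_area and loss must have equal length")
        if self.surface_area.size < 3:
            raise FitError("need at least 3 observations")
        if (self.surface_area <= 0).any():
            raise FitError("surface areas must be strictly positive")
        if np.allclose(self.surface_area, self.surface_area[0]):
            raise FitError("surface areas must not all be equal")

    @classmethod
    def from_dataframe(cls, samples: pd.DataFrame) -> "ExponentialLossModel":
        return cls(samples["surface_area_cm2"], samples["w1_g"] - samples["w0_g"])

    def predict(self, params: tuple[float, float], sa=None) -> np.ndarray:
        k_amp, k_exp = params
        s = self.surface_area if sa is None else np.asarray(sa, dtype=float)
        return -k_amp * np.exp(k_exp * s)

    def _jacobian(self, params: tuple[float, float]) -> np.ndarray:
        k_amp, k_exp = params
        e = np.exp(k_exp * self.surface_area)
        return np.column_stack([-e, -k_amp * self.surface_area * e])

    def _initial_params(self) -> tuple[float, float]:
        # ordinary regression of ln(-loss) on SA over strictly negative losses;
        # weight-gaining samples stay in the nonlinear fit but cannot seed the log fit
        neg = self.loss < 0
        if neg.sum() < 2:
            raise FitError("need at least 2 strictly negative losses for log-initialization")
        sa, y = self.surface_area[neg], np.log(-self.loss[neg])
        slope, intercept = np.polyfit(sa, y, 1)
        return math.exp(intercept), slope

    def fit(self, max_iter: int = 200, tol: float = 1e-10) -> "ExponentialLossResults":
        """Gauss–Newton least squares with step halving.

        Converges when the largest relative parameter change drops below
        ``tol``; raises :class:`ConvergenceError` (carrying the last iterate)
        after ``max_iter`` iterations.
        """
        theta = np.array(self._initial_params())
        sse = float(((self.loss - self.predict(theta)) ** 2).sum())
        for _ in range(max_iter):
            r = self.loss - self.predict(theta)
            jac = self._jacobian(theta)
            try:
                delta, *_ = np.linalg.lstsq(jac, r, rcond=None)
            except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
                raise ConvergenceError(f"normal equations singular: {exc}", tuple(theta)) from exc
            if not np.all(np.isfinite(delta)):
                raise ConvergenceError("non-finite Gauss–Newton step", tuple(theta))
            # halve the step until the SSE decreases and the amplitude stays positive
            lam = 1.0
            for _h in range(60):
                cand = theta + lam * delta
                if cand[0] > 0:
                    cand_sse = float(((self.loss - self.predict(cand)) ** 2).sum())
                    if cand_sse <= sse or np.allclose(lam * delta, 0.0):
                        break
                lam *= 0.5
            else:
                raise ConvergenceError("step halving failed to reduce SSE", tuple(theta))
            rel = np.max(np.abs(lam * delta) / np.maximum(np.abs(theta), 1e-300))
            theta, sse = cand, cand_sse
            if rel < tol:
                return self._results(theta, sse)
        raise ConvergenceError(f"no convergence after {max_iter} iterations", tuple(theta))

    def _results(self, theta: np.ndarray, sse: float) -> "ExponentialLossResults":
        n = self.surface_area.size
        jac = self._jacobian(theta)
        dof = n - 2
        s2 = sse / dof if dof > 0 else np.nan
        try:
            cov = s2 * np.linalg.inv(jac.T @ jac)
        except np.linalg.LinAlgError:
            cov = np.full((2, 2), np.nan)
        return ExponentialLossResults(
            model=self,
            params=np.asarray(theta, dtype=float),
            cov_params=cov,
            rss=float(sse),
            nobs=int(n),
        )


@dataclass
class ExponentialLossResults:
    """Fit results for :class:`ExponentialLossModel`."""

    model: ExponentialLossModel
    params: np.ndarray  # (k_amp, k_exp)
    cov_params: np.ndarray
    rss: float
    nobs: int

    @property
    def k_amp(self) -> float:
        return float(self.params[0])

    @property
    def k_exp(self) -> float:
        return float(self.params[1])

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def df_resid(self) -> int:
        return self.nobs - 2

    def predict(self, sa) -> np.ndarray:
        return self.model.predict(tuple(self.params), sa)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """t-based confidence intervals, rows (k_amp, k_exp) x (lower, upper)."""
        tcrit = stats.t.ppf(1 - alpha / 2, self.df_resid)
        half = tcrit * self.bse
        return np.column_stack([self.params - half, self.params + half])

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Exponential surface-area dissolution fit",
            "  loss(SA) = -k_amp * exp(k_exp * SA)",
            f"  n = {self.nobs}, RSS = {self.rss:.6g}",
            f"  k_amp = {self.k_amp:.6g} g      se {self.bse[0]:.3g}  "
            f"95% CI [{ci[0, 0]:.6g}, {ci[0, 1]:.6g}]",
            f"  k_exp = {self.k_exp:.6g} cm^-2  se {self.bse[1]:.3g}  "
            f"95% CI [{ci[1, 0]:.6g}, {ci[1, 1]:.6g}]",
        ]
        return "\n".join(lines)


def fit_exponential_loss(
    surface_areas, losses, max_iter: int = 200, tol: float = 1e-10
) -> ExponentialLossResults:
    """Convenience wrapper: build :class:`ExponentialLossModel` and fit it."""
    return ExponentialLossModel(surface_areas, losses).fit(max_iter=max_iter, tol=tol)


# ---------------------------------------------------------------------------
# whole-experiment model object
# ---------------------------------------------------------------------------

class DissolutionExperiment:
    """Model object for a full dissolution-experiment sample table.

    ``fit()`` computes group summaries, the omnibus ANOVA over the acidified
    groups (the four perforate growth forms plus the imperforate genus by
    default), the Tukey post-hoc table, the exponential surface-area fit on
    the perforate acidified subset, and the mean areal dissolution rate.
    """

    def __init__(self, samples: pd.DataFrame):
        missing = set(SAMPLE_COLUMNS) - set(samples.columns)
        if missing:
            raise ValueError(f"sample table missing columns: {sorted(missing)}")
        self.samples = samples.reset_index(drop=True)

    @classmethod
    def from_dataframe(cls, samples: pd.DataFrame) -> "DissolutionExperiment":
        return cls(samples)

    def _acidified_labels(self) -> tuple[pd.DataFrame, pd.Series]:
        acid = self.samples[self.samples["treatment"] == "acidified"]
        labels = np.where(
            acid["porosity_class"] == "perforate",
            acid["genus"].str.cat(acid["growth_form"], sep="-"),
            acid["genus"],
        )
        return acid, pd.Series(labels, index=acid.index)

    def fit(self, alpha: float = 0.05, fit_curve: bool = True) -> "DissolutionResults":
        acid, labels = self._acidified_labels()
        nl = normalized_loss(acid)
        anova = one_way_anova(nl.to_numpy(), labels.to_numpy())
        tukey = tukey_hsd(nl.to_numpy(), labels.to_numpy(), alpha=alpha)
        perf_acid = self.samples[
            (self.samples["treatment"] == "acidified")
            & (self.samples["porosity_class"] == "perforate")
        ]
        loss_fit = None
        loss_fit_error = None
        if fit_curve:
            try:
                loss_fit = ExponentialLossModel.from_dataframe(perf_acid).fit()
            except FitError as exc:
                loss_fit_error = str(exc)
        return DissolutionResults(
            experiment=self,
            group_summary=group_summary(self.samples),
            anova=anova,
            tukey=tukey,
            loss_fit=loss_fit,
            loss_fit_error=loss_fit_error,
            perforate_rate=mean_areal_rate(perf_acid) if len(perf_acid) else None,
            alpha=alpha,
        )


@dataclass
class DissolutionResults:
    """Results bundle from :meth:`DissolutionExperiment.fit`."""

    experiment: DissolutionExperiment
    group_summary: pd.DataFrame
    anova: AnovaResult
    tukey: pd.DataFrame
    loss_fit: ExponentialLossResults | None
    loss_fit_error: str | None
    perforate_rate: ArealMassRate | None
    alpha: float = 0.05
    extras: dict = field(default_factory=dict)

    def summary(self) -> str:
        a = self.anova
        lines = [
            "Dissolution experiment analysis",
            "=" * 31,
            f"Samples: {len(self.experiment.samples)}",
            "",
            "Group means of normalized loss ((w1-w0)/w0):",
            self.group_summary.to_string(index=False, float_format=lambda v: f"{v:.5f}"),
            "",
            f"One-way ANOVA (acidified groups): F({a.df_between}, {a.df_within}) = "
            f"{a.F:.3f}, p = {a.p:.4f}" + ("  [degenerate]" if a.degenerate else ""),
            "",
            f"Tukey HSD (alpha = {self.alpha}):",
            self.tukey.to_string(index=False, float_format=lambda v: f"{v:.5f}"),
        ]
        if self.perforate_rate is not None:
            lines += [
                "",
                f"Mean perforate-acidified areal rate: {self.perforate_rate.value:.3g} g cm^-2 d^-1",
            ]
        if self.loss_fit is not None:
            lines += ["", self.loss_fit.summary()]
        elif self.loss_fit_error:
            lines += ["", f"Exponential fit unavailable: {self.loss_fit_error}"]
        return "\n".join(lines)
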