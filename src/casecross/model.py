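"""Conditional logistic regression for time-stratified case-crossover data.

Each matched set contributes a softmax probability of the case day among the
set's days: with design rows ``x_j`` and coefficients ``beta``,

    loglik = sum_sets [ x_case . beta - log sum_{j in set} exp(x_j . beta) ].

Covariates constant within a set (the decedent's race, their block group's
composition or segregation scores) cancel from this likelihood, so modifier
*main* effects are structurally excluded from the design; only their
products with the time-varying exposure are estimable. Building a design
with a set-constant column raises :class:`~casecross.exceptions.RankDeficiencyError`.

The likelihood is maximized by Newton-Raphson with analytic gradient and
Hessian, step-halving, and log-sum-exp stabilization; the covariance of the
estimates is the inverse negative Hessian at the optimum.

:class:`ConditionalLogit` is the low-level model (numpy design matrix in,
:class:`ConditionalLogitResults` out). :class:`CaseCrossoverModel` is the
analysis-level model: it assembles the design the study uses — exposure
window, day-of-week indicators, linear + quadratic temperature (centered),
and optional exposure x modifier interactions — from the long-format frame
produced by :mod:`casecross.referents`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .exceptions import (
    ConvergenceError,
    RankDeficiencyError,
    SeparationError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConditionalLogit",
    "ConditionalLogitResults",
    "ModelSpec",
    "CaseCrossoverModel",
    "restrict_below_threshold",
]

_WEEKDAYS = ("Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday")
# Sunday is the day-of-week reference level.


class ConditionalLogit:
    """Conditional (matched-set) logistic regression.

    Parameters
    ----------
    endog : array (n,)
        Case indicator, exactly one 1 per group.
    exog : array (n, p)
        Design matrix. Must have full column rank after within-group
        centering (set-constant columns are inestimable).
    groups : array (n,)
        Matched-set labels.
    exog_names : list of str, optional
    """

    def __init__(self, endog, exog, groups, exog_names=None, check_rank=True):
        endog = np.asarray(endog, dtype=float)
        exog = np.asarray(exog, dtype=float)
        if exog.ndim == 1:
            exog = exog[:, None]
        groups = np.asarray(groups)
        if not (len(endog) == len(exog) == len(groups)):
            raise ValidationError("endog, exog and groups must have equal length")
        if not np.isfinite(exog).all():
            raise ValidationError("non-finite value in design matrix")
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{j}" for j in range(exog.shape[1])
        ]
        if len(self.exog_names) != exog.shape[1]:
            raise ValidationError("exog_names length does not match design width")

        # sort rows by group so each set is contiguous
        codes, uniques = pd.factorize(groups, sort=False)
        order = np.argsort(codes, kind="stable")
        self._y = endog[order]
        self._X = exog[order]
        self._codes = codes[order]
        self.group_labels = uniques
        self._starts = np.flatnonzero(np.r_[True, np.diff(self._codes) != 0])
        self._sizes = np.diff(np.r_[self._starts, len(self._codes)])
        self.n_sets = len(self._starts)

        per_set_cases = np.add.reduceat(self._y, self._starts)
        if not np.all(per_set_cases == 1):
            raise ValidationError("every matched set must contain exactly one case row")
        if (self._sizes < 2).any():
            raise ValidationError("every matched set needs at least one referent row")
        self._case_rows = np.flatnonzero(self._y == 1)

        # within-set centered design, used for rank checks and scaling
        means = np.add.reduceat(self._X, self._starts, axis=0) / self._sizes[:, None]
        self._Xc = self._X - means[self._codes]
        self._col_scale = self._Xc.std(axis=0)
        if check_rank:
            self._check_rank()

    def _check_rank(self):
        raw_scale = np.maximum(np.abs(self._X).max(axis=0), 1.0)
        constant = self._col_scale <= 1e-12 * raw_scale
        if constant.any():
            names = [n for n, c in zip(self.exog_names, constant) if c]
            raise RankDeficiencyError(
                names,
                "design columns constant within every matched set (inestimable in the "
                f"conditional likelihood): {', '.join(names)}. Modifier main effects "
                "cancel from the likelihood and must be omitted.",
            )
        Z = self._Xc / np.where(self._col_scale > 0, self._col_scale, 1.0)
        _, R, piv = linalg.qr(Z, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag[0] * max(Z.shape) * np.finfo(float).eps * 10 if diag.size else 0.0
        rank = int((diag > tol).sum())
        if rank < Z.shape[1]:
            names = [self.exog_names[j] for j in sorted(piv[rank:])]
            raise RankDeficiencyError(names)

    # ---- likelihood and derivatives -------------------------------------

    def _linpred(self, beta):
        return self._X @ np.asarray(beta, dtype=float)

    def _set_logsumexp(self, eta):
        m = np.maximum.reduceat(eta, self._starts)
        z = np.exp(eta - m[self._codes])
        s = np.add.reduceat(z, self._starts)
        return m + np.log(s), z / s[self._codes]

    def loglike(self, beta) -> float:
        """Conditional log-likelihood at ``beta`` (finite for all finite beta)."""
        eta = self._linpred(beta)
        lse, _ = self._set_logsumexp(eta)
        return float(eta[self._case_rows].sum() - lse.sum())

    def score(self, beta) -> np.ndarray:
        """Analytic gradient of :meth:`loglike`."""
        eta = self._linpred(beta)
        _, p = self._set_logsumexp(eta)
        return self._X[self._case_rows].sum(axis=0) - self._X.T @ p

    def hessian(self, beta) -> np.ndarray:
        """Analytic Hessian of :meth:`loglike` (negative semidefinite)."""
        eta = self._linpred(beta)
        _, p = self._set_logsumexp(eta)
        S = self._X * p[:, None]
        xbar = np.add.reduceat(S, self._starts, axis=0)
        return -(self._X.T @ S - xbar.T @ xbar)

    # ---- fitting --------------------------------------------------------

    def fit(
        self,
        start_params=None,
        tol: float = 1e-8,
        maxiter: int = 50,
        sep_threshold: float = 8.0,
    ) -> "ConditionalLogitResults":
        """Newton-Raphson maximization with step-halving.

        Parameters
        ----------
        start_params : array, optional
            Starting value, default zeros.
        tol : float
            Convergence criterion on the gradient max-norm.
        maxiter : int
        sep_threshold : float
            Declare separation (monotone likelihood) when a coefficient
            exceeds this many within-set standard deviations of its column
            while the gradient is still large.

        Raises
        ------
        SeparationError
            If a coefficient diverges (monotone likelihood).
        ConvergenceError
            If ``maxiter`` is reached without meeting ``tol``.

        Notes
        -----
        Internally the optimization runs on columns standardized by their
        within-set standard deviation — a pure reparameterization that makes
        the gradient tolerance meaningful across covariates of very
        different scales (e.g. exposure x percent interactions). Estimates
        and covariance are returned on the original scale; ``grad_max`` is
        the standardized-space gradient max-norm.
        """
        p = self._X.shape[1]
        s = np.where(self._col_scale > 0, self._col_scale, 1.0)

        def score_z(bz):
            return self.score(bz / s) / s

        def hess_z(bz):
            return self.hessian(bz / s) / np.outer(s, s)

        def ll_z(bz):
            return self.loglike(bz / s)

        bz = np.zeros(p) if start_params is None else np.asarray(start_params, dtype=float) * s
        ll = ll_z(bz)
        niter = 0
        at_floor = False
        for niter in range(1, maxiter + 1):
            g = score_z(bz)
            if np.abs(g).max() < tol:
                niter -= 1
                break
            H = hess_z(bz)
            try:
                step = linalg.solve(-H, g, assume_a="pos")
            except linalg.LinAlgError:
                step = np.linalg.lstsq(-H, g, rcond=None)[0]
            # Newton decrement: predicted likelihood gain of the full step.
            # Below ~1e-12 the gain is under float64 resolution of the
            # log-likelihood and the gradient norm has hit its rounding
            # floor: the optimum is resolved to machine precision.
            if g @ step < 2e-12:
                niter -= 1
                at_floor = True
                break
            shrink = 1.0
            for _ in range(40):
                cand = bz + shrink * step
                ll_new = ll_z(cand)
                if ll_new >= ll - 1e-13:
                    break
                shrink *= 0.5
            else:
                raise ConvergenceError(
                    f"step-halving failed to improve the likelihood at iteration {niter}"
                )
            bz, ll = cand, ll_new

            # a coefficient this many within-set sds from zero (log odds
            # ratio > e^10 per sd) only arises under monotone likelihood
            if np.abs(bz).max() > sep_threshold:
                j = int(np.argmax(np.abs(bz)))
                raise SeparationError(self.exog_names[j])

        if np.abs(bz).max() > sep_threshold:
            raise SeparationError(self.exog_names[int(np.argmax(np.abs(bz)))])
        g = score_z(bz)
        grad_max = float(np.abs(g).max())
        converged = grad_max < tol or at_floor
        if not converged:
            raise ConvergenceError(
                f"no convergence in {maxiter} iterations (gradient max-norm {grad_max:.3g})"
            )
        cov_z = linalg.inv(-hess_z(bz))
        cov = (cov_z + cov_z.T) / 2.0 / np.outer(s, s)
        return ConditionalLogitResults(
            model=self,
            params=bz / s,
            cov_params_arr=cov,
            llf=ll_z(bz),
            niter=niter,
            converged=converged,
            grad_max=grad_max,
        )


@dataclass
class ConditionalLogitResults:
    """Estimates, covariance and diagnostics from a conditional-logit fit."""

    model: ConditionalLogit
    params: np.ndarray
    cov_params_arr: np.ndarray
    llf: float
    niter: int
    converged: bool
    grad_max: float

    @property
    def exog_names(self) -> list[str]:
        return self.model.exog_names

    @property
    def n_sets(self) -> int:
        return self.model.n_sets

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params_arr))

    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(self.cov_params_arr, index=self.exog_names, columns=self.exog_names)

    def _index(self, name_or_idx) -> int:
        if isinstance(name_or_idx, str):
            try:
                return self.exog_names.index(name_or_idx)
            except ValueError:
                raise ValidationError(f"no coefficient named {name_or_idx!r}") from None
        return int(name_or_idx)

    def wald_test(self, coefficient) -> tuple[float, float]:
        """Wald z statistic and two-sided normal p-value for one coefficient."""
        if not self.converged:
            raise ConvergenceError("refusing Wald test on a non-converged fit")
        k = self._index(coefficient)
        se = self.bse[k]
        z = self.params[k] / se if se > 0 else np.inf * np.sign(self.params[k])
        return float(z), float(2.0 * stats.norm.sf(abs(z)))

    def params_series(self) -> pd.Series:
        return pd.Series(self.params, index=self.exog_names, name="coef")

    def summary(self) -> str:
        """Plain-text coefficient table with z tests and 95% CIs."""
        se = self.bse
        z = np.divide(self.params, se, out=np.full_like(self.params, np.nan), where=se > 0)
        pv = 2.0 * stats.norm.sf(np.abs(z))
        lines = [
            "Conditional logistic regression (matched sets)",
            f"  n_sets={self.n_sets}  loglik={self.llf:.4f}  iterations={self.niter}  "
            f"converged={self.converged} (|grad|max={self.grad_max:.2e})",
            "",
            f"{'':28s}{'coef':>12s}{'se':>12s}{'z':>9s}{'P>|z|':>9s}{'[0.025':>11s}{'0.975]':>11s}",
        ]
        for j, name in enumerate(self.exog_names):
            lines.append(
                f"{name:28s}{self.params[j]:12.6f}{se[j]:12.6f}{z[j]:9.3f}{pv[j]:9.4f}"
                f"{self.params[j] - 1.96 * se[j]:11.6f}{self.params[j] + 1.96 * se[j]:11.6f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "coefficients": dict(zip(self.exog_names, map(float, self.params))),
            "standard_errors": dict(zip(self.exog_names, map(float, self.bse))),
            "covariance": [[float(v) for v in row] for row in self.cov_params_arr],
            "loglik": float(self.llf),
            "n_sets": int(self.n_sets),
            "convergence": {
                "converged": bool(self.converged),
                "iterations": int(self.niter),
                "gradient_max_norm": float(self.grad_max),
            },
        }

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


# ---------------------------------------------------------------------------
# analysis-level model


@dataclass(frozen=True)
class ModelSpec:
    """What enters the case-crossover design matrix.

    The exposure window is the regressor of interest; day-of-week indicators
    (Sunday reference) and linear + quadratic terms of the same-window
    temperature adjust for short-term temporal confounding not removed by
    the matched design. ``modifier`` names a set-constant column whose
    *interaction* with the exposure is added; its main effect cancels and is
    never included.

    modifier_kind:
        ``"continuous"`` — a single ``exposure x modifier`` column;
        ``"binary"`` — modifier recoded 0/1 via ``modifier_level`` (the level
        coded 1), one interaction column;
        ``"categorical"`` — one interaction dummy per non-reference level
        (reference = first level in sorted order, or ``modifier_reference``).
    """

    exposure: str = "pm25_window"
    temperature: str = "temp_window"
    dow: str = "dow"
    modifier: str | None = None
    modifier_kind: str = "continuous"
    modifier_level: str | None = None
    modifier_reference: str | None = None
    center_temperature: bool = True
    adjust: bool = True  # include dow + temperature adjustment terms


class CaseCrossoverModel:
    """Case-crossover analysis model on a long-format matched-set frame.

    Parameters
    ----------
    design
        Frame from :func:`casecross.referents.build_matched_sets` with
        columns ``record_id, date, is_case, pm25_window, temp_window, dow``
        plus any modifier columns.
    spec
        A :class:`ModelSpec`; default is the unmodified main model.
    """

    def __init__(self, design: pd.DataFrame, spec: ModelSpec | None = None):
        self.spec = spec or ModelSpec()
        self.design = design
        X, names = self._build_matrix(design, self.spec)
        self.modifier_column = None if self.spec.modifier is None else self.spec.modifier
        self._mod = ConditionalLogit(
            design["is_case"].to_numpy(),
            X,
            design["record_id"].to_numpy(),
            exog_names=names,
        )

    @classmethod
    def from_design(cls, design, modifier=None, modifier_kind="continuous", **spec_kw):
        return cls(design, ModelSpec(modifier=modifier, modifier_kind=modifier_kind, **spec_kw))

    @staticmethod
    def _build_matrix(df: pd.DataFrame, spec: ModelSpec):
        cols = [df[spec.exposure].to_numpy(dtype=float)]
        names = [spec.exposure]
        if spec.adjust:
            dow = df[spec.dow].astype(str)
            for day in _WEEKDAYS:
                cols.append((dow == day).to_numpy(dtype=float))
                names.append(f"dow_{day}")
            temp = df[spec.temperature].to_numpy(dtype=float)
            if spec.center_temperature:
                temp = temp - np.nanmean(temp)
            cols.append(temp)
            names.append("temp_c")
            cols.append(temp**2)
            names.append("temp_c_sq")
        if spec.modifier is not None:
            if spec.modifier not in df.columns:
                raise ValidationError(f"modifier column {spec.modifier!r} not in design")
            expo = df[spec.exposure].to_numpy(dtype=float)
            if spec.modifier_kind == "continuous":
                m = df[spec.modifier].to_numpy(dtype=float)
                cols.append(expo * m)
                names.append(f"{spec.exposure}:{spec.modifier}")
            elif spec.modifier_kind == "binary":
                if spec.modifier_level is None:
                    raise ValidationError("binary modifier needs modifier_level")
                m = (df[spec.modifier].astype(str) == spec.modifier_level).to_numpy(dtype=float)
                cols.append(expo * m)
                names.append(f"{spec.exposure}:{spec.modifier}[{spec.modifier_level}]")
            elif spec.modifier_kind == "categorical":
                levels = sorted(df[spec.modifier].astype(str).unique())
                ref = spec.modifier_reference or levels[0]
                if ref not in levels:
                    raise ValidationError(f"reference level {ref!r} absent from data")
                for lev in levels:
                    if lev == ref:
                        continue
                    m = (df[spec.modifier].astype(str) == lev).to_numpy(dtype=float)
                    cols.append(expo * m)
                    names.append(f"{spec.exposure}:{spec.modifier}[{lev}]")
            else:
                raise ValidationError(f"unknown modifier_kind {spec.modifier_kind!r}")
        return np.column_stack(cols), names

    def fit(self, **kwargs) -> "CaseCrossoverResults":
        res = self._mod.fit(**kwargs)
        return CaseCrossoverResults(
            model=self._mod,
            params=res.params,
            cov_params_arr=res.cov_params_arr,
            llf=res.llf,
            niter=res.niter,
            converged=res.converged,
            grad_max=res.grad_max,
            spec=self.spec,
            design=self.design,
        )


@dataclass
class CaseCrossoverResults(ConditionalLogitResults):
    """Conditional-logit results plus study-scale reporting helpers.

    Reporting methods (percent change per 10 ug/m^3, effects at modifier
    percentiles/categories) live in :mod:`casecross.effects`; the thin
    wrappers here keep the statsmodels-style "everything hangs off the
    results object" ergonomics.
    """

    spec: ModelSpec = field(default=None)
    design: pd.DataFrame = field(default=None, repr=False)

    @property
    def exposure_name(self) -> str:
        return self.spec.exposure

    def interaction_names(self) -> list[str]:
        prefix = f"{self.spec.exposure}:"
        return [n for n in self.exog_names if n.startswith(prefix)]

    def percent_change(self, delta: float = 10.0):
        from .effects import percent_change

        k = self._index(self.exposure_name)
        return percent_change(self.params[k], self.bse[k], delta=delta)

    def effect_at(self, m: float, delta: float = 10.0):
        from .effects import effect_at_modifier

        return effect_at_modifier(self, m, delta=delta)

    def effects_at_percentiles(self, delta: float = 10.0):
        from .effects import effects_at_percentiles

        return effects_at_percentiles(self, delta=delta)

    def categorical_effects(self, delta: float = 10.0):
        from .effects import categorical_effects

        return categorical_effects(self, delta=delta)

    def interaction_pvalue(self) -> float:
        """Wald p-value of the (single) interaction coefficient."""
        names = self.interaction_names()
        if len(names) != 1:
            raise ValidationError(
                "interaction_pvalue needs exactly one interaction column; "
                f"found {names}"
            )
        return self.wald_test(names[0])[1]


def restrict_below_threshold(
    design: pd.DataFrame,
    threshold: float = 35.0,
    column: str = "pm25_day",
) -> tuple[pd.DataFrame, dict]:
    """Restrict a matched-set design to days below a daily-PM2.5 threshold.

    Days (case or referent) whose daily PM2.5 exceeds ``threshold`` are
    removed; a set is dropped entirely if its case day is removed or if no
    referents remain. The default threshold is the 24-hour national ambient
    air-quality standard of 35 ug/m^3.

    Returns the filtered design and a dict of drop counts.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    if column not in design.columns:
        raise ValidationError(f"column {column!r} not in design")
    over = design[column] > threshold
    bad = set(design.loc[over & (design["is_case"] == 1), "record_id"])
    keep = ~over & ~design["record_id"].isin(bad)
    out = design.loc[keep]
    sizes = out.groupby("record_id")["is_case"].size()
    lonely = set(sizes.index[sizes < 2])
    out = out.loc[~out["record_id"].isin(lonely)].reset_index(drop=True)
    log = {
        "days_removed": int(over.sum()),
        "sets_dropped_case_day": len(bad),
        "sets_dropped_no_referents": len(lonely),
        "n_sets": int(out["record_id"].nunique()),
    }
    logger.info("NAAQS restriction: %s", log)
    return out, log
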