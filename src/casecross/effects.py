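"""Reporting transformations: percent change per 10 ug/m^3 and modifier effects.

A fitted per-unit log odds ``beta`` is reported as the percent change in
mortality risk for a ``delta = 10`` ug/m^3 increase in exposure,

    PC = 100 * (exp(delta * beta) - 1),

with the 95% CI obtained by transforming ``beta +/- 1.96 * se``. Effects at
a modifier value ``m`` use the linear combination ``b(m) = b1 + m * b2``
(exposure plus interaction coefficient) with the delta-method standard
error ``se(m) = sqrt(v11 + m^2 v22 + 2 m v12)``; the same machinery gives
per-category effects for the five-level segregation-score interaction, with
the first (black-majority) category as reference.

Continuous modifiers are summarized at their 10th/50th/90th percentiles over
decedents (one value per matched set, nearest-rank convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "EffectEstimate",
    "percent_change",
    "effect_at_modifier",
    "modifier_percentiles",
    "effects_at_percentiles",
    "categorical_effects",
    "forest_plot",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class EffectEstimate:
    """Percent change per ``delta`` ug/m^3, with 95% CI.

    ``label`` identifies what the effect refers to (overall, a modifier
    value, or a segregation category); ``interaction_p`` is the Wald p-value
    of the associated interaction coefficient where one exists.
    """

    label: str
    percent_change: float
    ci_low: float
    ci_high: float
    delta: float = 10.0
    interaction_p: float | None = None

    def __post_init__(self):
        if not (self.ci_low <= self.percent_change <= self.ci_high):
            raise ValidationError("CI does not bracket the point estimate")

    def __str__(self):
        s = (
            f"{self.label}: {self.percent_change:+.2f}% "
            f"(95% CI {self.ci_low:.2f}%; {self.ci_high:.2f}%) per {self.delta:g} ug/m3"
        )
        if self.interaction_p is not None:
            s += f" [interaction p = {self.interaction_p:.3f}]"
        return s


def percent_change(beta: float, se: float, delta: float = 10.0, label: str = "overall",
                   interaction_p: float | None = None) -> EffectEstimate:
    """Percent change in risk per ``delta``-unit exposure increase."""
    if se < 0:
        raise ValidationError("standard error must be non-negative")
    pc = 100.0 * np.expm1(delta * beta)
    lo = 100.0 * np.expm1(delta * (beta - Z95 * se))
    hi = 100.0 * np.expm1(delta * (beta + Z95 * se))
    return EffectEstimate(label, float(pc), float(lo), float(hi), delta, interaction_p)


def _interaction_block(fit, name: str):
    k1 = fit._index(fit.exposure_name)
    k2 = fit._index(name)
    V = fit.cov_params_arr
    return fit.params[k1], fit.params[k2], V[k1, k1], V[k2, k2], V[k1, k2]


def effect_at_modifier(fit, m: float, delta: float = 10.0, label: str | None = None) -> EffectEstimate:
    """Effect of a ``delta`` exposure increase at modifier value ``m``.

    Requires a fit with exactly one continuous/binary interaction term.
    Point estimate from ``b1 + m * b2``; delta-method SE.
    """
    names = fit.interaction_names()
    if len(names) != 1:
        raise ValidationError(
            f"effect_at_modifier needs a single interaction coefficient, found {names}"
        )
    b1, b2, v11, v22, v12 = _interaction_block(fit, names[0])
    b = b1 + m * b2
    var = v11 + m * m * v22 + 2.0 * m * v12
    if var < 0:
        var = 0.0
    _, pv = fit.wald_test(names[0])
    return percent_change(
        b, float(np.sqrt(var)), delta=delta,
        label=label or f"modifier={m:g}", interaction_p=pv,
    )


def modifier_percentiles(values, probs=(10, 50, 90)) -> dict[int, float]:
    """Empirical percentiles of decedent-level modifier values, nearest rank.

    ``values`` holds one value per matched set (decedent). Requires at least
    10 values.
    """
    v = np.sort(np.asarray(values, dtype=float))
    v = v[np.isfinite(v)]
    if len(v) < 10:
        raise ValidationError(f"need >= 10 modifier values, got {len(v)}")
    out = {}
    for p in probs:
        rank = int(np.ceil(p / 100.0 * len(v)))  # nearest-rank: ceil(p*n/100)
        out[int(p)] = float(v[max(rank, 1) - 1])
    return out


def effects_at_percentiles(fit, delta: float = 10.0, probs=(10, 50, 90)) -> list[EffectEstimate]:
    """Effects at the 10th/50th/90th percentile of the fitted modifier.

    Percentiles are taken over decedents: one modifier value per matched set
    from the fit's design frame.
    """
    if fit.spec is None or fit.spec.modifier is None or fit.design is None:
        raise ValidationError("fit carries no modifier design")
    per_set = fit.design.loc[fit.design["is_case"] == 1, fit.spec.modifier]
    pct = modifier_percentiles(per_set.to_numpy(dtype=float), probs=probs)
    return [
        effect_at_modifier(fit, m, delta=delta, label=f"p{p} ({fit.spec.modifier}={m:g})")
        for p, m in pct.items()
    ]


def categorical_effects(fit, delta: float = 10.0) -> list[EffectEstimate]:
    """Per-category effects for a categorical (e.g. 5-level RRS) interaction.

    The reference category's effect is the exposure coefficient alone; each
    other category adds its interaction coefficient, with the delta-method SE
    from the 2x2 covariance block, and reports the per-level Wald interaction
    p-value against the reference.
    """
    names = fit.interaction_names()
    if not names:
        raise ValidationError("fit has no interaction terms")
    k1 = fit._index(fit.exposure_name)
    V = fit.cov_params_arr
    ref_label = (fit.spec.modifier_reference if fit.spec else None)
    if ref_label is None and fit.spec is not None and fit.design is not None:
        levels = sorted(fit.design[fit.spec.modifier].astype(str).unique())
        present = {n.split("[", 1)[1].rstrip("]") for n in names}
        ref_levels = [l for l in levels if l not in present]
        ref_label = ref_levels[0] if len(ref_levels) == 1 else "reference"
    out = [
        percent_change(fit.params[k1], float(np.sqrt(V[k1, k1])), delta=delta,
                       label=f"{ref_label} (reference)")
    ]
    for name in names:
        level = name.split("[", 1)[1].rstrip("]")
        b1, b2, v11, v22, v12 = _interaction_block(fit, name)
        se = float(np.sqrt(max(v11 + v22 + 2.0 * v12, 0.0)))
        _, pv = fit.wald_test(name)
        out.append(percent_change(b1 + b2, se, delta=delta, label=level, interaction_p=pv))
    return out


def forest_plot(effects: list[EffectEstimate], path=None, title=None):
    """Forest-style plot of effect estimates with 95% CIs.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    y = np.arange(len(effects))[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.6 * len(effects) + 1.5))
    for e, yi in zip(effects, y):
        ax.plot([e.ci_low, e.ci_high], [yi, yi], color="k", lw=1.2)
        ax.plot([e.percent_change], [yi], "s", color="k", ms=5)
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels([e.label for e in effects])
    ax.set_xlabel(f"% change in mortality per {effects[0].delta:g} ug/m3 PM2.5 (95% CI)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
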