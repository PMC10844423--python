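"""Response to selection: selection intensity and annual genetic gain.

Annual gain per breeding method, from the breeder's equation divided by
the cycle length ``t`` (years):

* phenotypic selection (PS):  dG = i * h2 * sigma_P / t,
* family selection (FS):      dG = i * h2_family * sigma_Fbar / t  (family
  means take the place of phenotypes),
* genomic selection (GS):     dG = i * r * sigma_A / t, where ``r`` is the
  genomic prediction accuracy.

``i`` is the selection intensity — the standardized mean of the selected
upper tail of a normal distribution, ``i(p) = phi(z_p) / p`` with ``z_p``
the upper-``p`` quantile.  Default cycle lengths reflect a conifer
programme: 15 y for GS (age of reproduction), 30 y for PS (phenotyping
age) and 45 y for FS (phenotyping plus a progeny test).
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .datatypes import ValidationError

DEFAULT_CYCLES = {"GS": 15.0, "PS": 30.0, "FS": 45.0}

_REQUIRED = {
    "GS": ("r", "sigma_a"),
    "PS": ("h2", "sigma_p"),
    "FS": ("h2", "sigma_p"),
}


@dataclass
class GainSpec:
    """Inputs for one method's annual-gain calculation.

    For PS, ``h2``/``sigma_p`` are the individual narrow-sense heritability
    and phenotypic SD; for FS the family-mean heritability and family-mean
    phenotypic SD; for GS, ``r`` is the prediction accuracy and ``sigma_a``
    the additive-genetic SD.  ``trait_mean`` switches the result to percent
    of the trait mean per year.
    """

    selection_proportion: float
    method: str
    h2: float | None = None
    sigma_p: float | None = None
    r: float | None = None
    sigma_a: float | None = None
    cycle_years: float | None = None
    trait_mean: float | None = None

    def __post_init__(self) -> None:
        if self.method not in _REQUIRED:
            raise ValidationError(f"method must be one of {sorted(_REQUIRED)}")
        if not (0.0 < self.selection_proportion <= 1.0):
            raise ValidationError("selection_proportion must lie in (0, 1]")
        if self.cycle_years is None:
            self.cycle_years = DEFAULT_CYCLES[self.method]
        if self.cycle_years <= 0:
            raise ValidationError("cycle_years must be > 0")
        for name in _REQUIRED[self.method]:
            if getattr(self, name) is None:
                raise ValidationError(f"method {self.method} requires field {name!r}")


def selection_intensity(p: float) -> float:
    """Mean of the selected upper fraction ``p`` of a standard normal.

    ``i(p) = phi(Phi^{-1}(1 - p)) / p``; no selection (p = 1) gives 0.
    """
    p = float(p)
    if not (0.0 < p <= 1.0):
        raise ValidationError("selection proportion must lie in (0, 1]")
    if p == 1.0:
        return 0.0
    z = stats.norm.isf(p)
    return float(stats.norm.pdf(z) / p)


def annual_gain(spec: GainSpec) -> float:
    """Annual genetic gain in trait units per year (or %/year)."""
    i = selection_intensity(spec.selection_proportion)
    if spec.method == "GS":
        gain = i * spec.r * spec.sigma_a / spec.cycle_years
    else:
        gain = i * spec.h2 * spec.sigma_p / spec.cycle_years
    if spec.trait_mean is not None:
        if spec.trait_mean == 0:
            raise ValidationError("trait_mean must be nonzero for percent reporting")
        gain = gain / spec.trait_mean * 100.0
    return float(gain)


def compare_methods(
    estimates: dict,
    proportions,
    cycles: dict | None = None,
    percent: bool = False,
) -> pd.DataFrame:
    """Tidy gain table, one row per (trait, method, selection proportion).

    ``estimates`` maps trait -> method -> keyword inputs for
    :class:`GainSpec` (e.g. ``{"height": {"GS": {"r": .4, "sigma_a": 2.},
    "PS": {"h2": .25, "sigma_p": 4.}}}``); methods absent for a trait are
    skipped.  ``percent`` requires a ``trait_mean`` entry per trait-method.
    """
    proportions = list(proportions)
    if not proportions:
        raise ValidationError("empty selection-proportion grid")
    cycles = {**DEFAULT_CYCLES, **(cycles or {})}
    rows = []
    for trait, methods in estimates.items():
        for method, kw in methods.items():
            for p in proportions:
                spec = GainSpec(
                    selection_proportion=p,
                    method=method,
                    cycle_years=kw.get("cycle_years", cycles[method]),
                    **{k: v for k, v in kw.items() if k != "cycle_years"},
                )
                if not percent:
                    spec.trait_mean = None
                rows.append(
                    {
                        "trait": trait,
                        "method": method,
                        "proportion": p,
                        "intensity": selection_intensity(p),
                        "cycle_years": spec.cycle_years,
                        "annual_gain": annual_gain(spec),
                    }
                )
    return pd.DataFrame(rows)
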