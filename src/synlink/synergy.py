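"""Chou–Talalay combination-index quantification of drug synergy.

The median-effect law ``Fa/Fu = (D/Dm)^m`` linearizes to
``log10(Fa/Fu) = m log10(D) - m log10(Dm)``, so ``m`` (sigmoidicity) and
``Dm`` (median-effect dose) are estimated per cell line and drug by
ordinary least squares on the monotherapy dose-response series. For a
combination observation at doses ``(D1, D2)`` with fraction affected
``Fa``, the expected monotherapy dose of drug *i* that would alone produce
the same effect is ``E_i = Dm_i (Fa/Fu)^(1/m_i)``, and the combination
index is

    CI = D1/E1 + D2/E2

CI < 1 indicates synergy, 1 additivity, > 1 antagonism. Very large values
arise from poorly fit monotherapy curves rather than true antagonism, so
emitted CI values are capped at 5 (the raw value is kept for audit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .qc import DoseResponseSeries

__all__ = [
    "MedianEffectFit",
    "CombinationObservation",
    "CIResult",
    "InvalidFitError",
    "CI_CAP",
    "STRONG_SYNERGY_MAX",
    "WEAK_SYNERGY_MIN",
    "fit_median_effect",
    "expected_dose",
    "combination_index",
    "classify_ci",
    "ci_profile",
]

CI_CAP = 5.0
STRONG_SYNERGY_MAX = 0.3
WEAK_SYNERGY_MIN = 0.85


class InvalidFitError(ValueError):
    """Raised when a median-effect fit cannot support expected-dose inversion."""


@dataclass
class MedianEffectFit:
    """Median-effect parameters for one cell line x drug.

    ``valid`` is False (not an error) when the slope is nonpositive or the
    regression is degenerate; such curves cannot be inverted.
    """

    cell_line: str
    drug: str
    m: float
    dm: float
    intercept: float
    r_squared: float
    n_points: int
    valid: bool


@dataclass
class CombinationObservation:
    """One combination dose pair with its observed fraction affected."""

    d1: float
    d2: float
    fa: float

    def __post_init__(self):
        if self.d1 <= 0 or self.d2 <= 0:
            raise ValueError("combination doses must be positive")
        if not 0.0 < self.fa < 1.0:
            raise ValueError(f"fa must lie in (0, 1), got {self.fa}")

    @property
    def fu(self) -> float:
        return 1.0 - self.fa


@dataclass
class CIResult:
    """Combination index at one dose pair; ``ci`` is None when missing."""

    cell_line: str
    drug1: str
    drug2: str
    d1: float
    d2: float
    e1: float | None
    e2: float | None
    ci_raw: float | None
    ci: float | None
    label: str | None
    reason: str | None = None

    @property
    def missing(self) -> bool:
        return self.ci is None


def fit_median_effect(
    series: DoseResponseSeries | None = None,
    *,
    doses=None,
    viability=None,
    cell_line: str = "",
    drug: str = "",
) -> MedianEffectFit:
    """Fit the linearized median-effect model to a monotherapy series.

    Regresses ``log10(Fa/Fu)`` on ``log10(D)``; the slope is ``m`` and
    ``Dm = 10^(-intercept/m)``. Requires at least 3 distinct positive doses
    and viabilities strictly inside (0, 1).
    """
    if series is not None:
        doses = series.doses
        viability = series.viability
        cell_line = series.cell_line
        drug = str(series.drug)
    doses = np.asarray(doses, dtype=float)
    viability = np.asarray(viability, dtype=float)
    if doses.ndim != 1:
        raise ValueError("monotherapy fit needs a one-dimensional dose grid")
    if (doses <= 0).any():
        raise ValueError("doses must be strictly positive")
    if np.unique(doses).size < 3:
        raise ValueError("need at least 3 distinct doses")
    if ((viability <= 0) | (viability >= 1)).any():
        raise ValueError("viabilities must lie strictly inside (0, 1)")

    x = np.log10(doses)
    y = np.log10((1.0 - viability) / viability)
    res = stats.linregress(x, y)
    m = float(res.slope)
    intercept = float(res.intercept)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    valid = np.isfinite(m) and m > 0
    dm = float(10.0 ** (-intercept / m)) if valid else float("nan")
    if valid and not (np.isfinite(dm) and dm > 0):
        valid = False
    return MedianEffectFit(
        cell_line=cell_line,
        drug=drug,
        m=m,
        dm=dm,
        intercept=intercept,
        r_squared=r2,
        n_points=int(doses.size),
        valid=valid,
    )


def expected_dose(fit: MedianEffectFit, fa: float) -> float:
    """Monotherapy dose expected to produce fraction affected ``fa``.

    Inverts the median-effect law: ``E = Dm (Fa/Fu)^(1/m)``; strictly
    increasing in ``fa`` for a valid fit.
    """
    if not fit.valid:
        raise InvalidFitError(
            f"median-effect fit for {fit.cell_line}/{fit.drug} is not invertible"
        )
    if not 0.0 < fa < 1.0:
        raise ValueError(f"fa must lie in (0, 1), got {fa}")
    return fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)


def combination_index(
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    obs: CombinationObservation,
    cap: float = CI_CAP,
) -> CIResult:
    """Combination index for one observed dose pair.

    Both expected doses are evaluated at the single observed combination
    ``Fa``. Invalid monotherapy fits yield a missing CI with a reason, not
    a capped value.
    """
    base = dict(
        cell_line=fit1.cell_line,
        drug1=fit1.drug,
        drug2=fit2.drug,
        d1=obs.d1,
        d2=obs.d2,
    )
    if not (fit1.valid and fit2.valid):
        bad = fit1.drug if not fit1.valid else fit2.drug
        return CIResult(
            **base, e1=None, e2=None, ci_raw=None, ci=None, label=None,
            reason=f"invalid median-effect fit for {bad}",
        )
    e1 = expected_dose(fit1, obs.fa)
    e2 = expected_dose(fit2, obs.fa)
    ci_raw = obs.d1 / e1 + obs.d2 / e2
    ci = min(ci_raw, cap)
    return CIResult(
        **base, e1=e1, e2=e2, ci_raw=ci_raw, ci=ci, label=classify_ci(ci)
    )


def classify_ci(ci: float) -> str:
    """Classify a combination index.

    < 0.3 strong synergy; [0.3, 0.85) synergy; [0.85, 1) weak synergy;
    exactly 1 additive; > 1 antagonism.
    """
    if not np.isfinite(ci) or ci <= 0:
        raise ValueError(f"CI must be positive, got {ci}")
    if ci < STRONG_SYNERGY_MAX:
        return "strong_synergy"
    if ci < WEAK_SYNERGY_MIN:
        return "synergy"
    if ci < 1.0:
        return "weak_synergy"
    if ci == 1.0:
        return "additive"
    return "antagonism"


def ci_profile(
    series: dict,
    cell_line: str,
    pair: tuple[str, str],
    design_pairs: list[tuple[float, float]] | None = None,
    cap: float = CI_CAP,
) -> list[CIResult]:
    """Per-dose-pair CI results for one cell line and drug pair.

    ``series`` is the mapping produced by :func:`synlink.qc.run_qc`. Dose
    pairs without combination data, and pairs whose monotherapy arm is
    absent or uninvertible, yield missing results with a reason — values
    are never fabricated.
    """
    drug1, drug2 = pair
    combo = series.get((cell_line, (drug1, drug2)))
    if design_pairs is None:
        if combo is None:
            raise ValueError(f"no combination series for {cell_line}/{pair}")
        design_pairs = [tuple(d) for d in np.atleast_2d(combo.doses)]

    def _missing(reason: str) -> list[CIResult]:
        return [
            CIResult(
                cell_line=cell_line, drug1=drug1, drug2=drug2, d1=d1, d2=d2,
                e1=None, e2=None, ci_raw=None, ci=None, label=None, reason=reason,
            )
            for d1, d2 in design_pairs
        ]

    mono1 = series.get((cell_line, drug1))
    mono2 = series.get((cell_line, drug2))
    if mono1 is None or mono2 is None:
        absent = drug1 if mono1 is None else drug2
        return _missing(f"monotherapy series absent for {absent}")
    try:
        fit1 = fit_median_effect(mono1, drug=drug1)
        fit2 = fit_median_effect(mono2, drug=drug2)
    except ValueError as exc:
        return _missing(f"monotherapy fit failed: {exc}")

    observed: dict[tuple[float, float], float] = {}
    if combo is not None:
        for d, v in zip(np.atleast_2d(combo.doses), combo.viability):
            observed[(float(d[0]), float(d[1]))] = float(v)

    results = []
    for d1, d2 in design_pairs:
        v = observed.get((float(d1), float(d2)))
        if v is None:
            results.append(
                CIResult(
                    cell_line=cell_line, drug1=drug1, drug2=drug2, d1=d1, d2=d2,
                    e1=None, e2=None, ci_raw=None, ci=None, label=None,
                    reason="combination wells missing",
                )
            )
            continue
        obs = CombinationObservation(d1=float(d1), d2=float(d2), fa=1.0 - v)
        res = combination_index(fit1, fit2, obs, cap=cap)
        res.cell_line = cell_line
        results.append(res)
    return results
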