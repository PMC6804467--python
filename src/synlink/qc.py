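"""Five-stage quality control for raw fluorescence plates.

The pipeline turns raw RFU well tables into normalized dose-response
series, in this order:

1. quadruplicate check — coefficient-of-variation screen within each set
   of replicate wells, replacing deviants by the mean of the others;
2. plate viability filter — plates whose 90th-percentile RFU falls below a
   death threshold (default 2000) are removed as mass cell death;
3. control cleanup — vehicle and negative (10% DMSO) controls are run
   through an iterative flag-and-replace linear regression on well index;
4. normalization — viability = (RFU - negative mean) / (vehicle mean -
   negative mean), clipped away from {0, 1} so log transforms stay finite;
5. dose-response check — the same flag-and-replace loop on viability
   against log10(dose) within each drug series.

Replicate runs of a cell line are averaged at the normalized-viability
level after QC, producing one dose-response series per line and condition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import PLATE_COLUMNS

__all__ = [
    "QCConfig",
    "QCReport",
    "DoseResponseSeries",
    "qc_quadruplicates",
    "plate_viability_filter",
    "studentized_residuals",
    "control_flag_replace",
    "normalize_plate",
    "dose_response_flag_replace",
    "run_qc",
]

logger = logging.getLogger(__name__)


@dataclass
class QCConfig:
    """Tunable thresholds of the QC pipeline."""

    cv_threshold: float = 0.3
    plate_rfu_threshold: float = 2000.0
    resid_threshold: float = 3.0
    max_iter: int = 10
    eps: float = 0.005  # viability clip margin


@dataclass
class DoseResponseSeries:
    """Normalized viability per dose (or dose pair) for one line x condition.

    ``doses`` is (n,) for monotherapy or (n, 2) for combinations, strictly
    positive and sorted ascending (by first dose for pairs); ``viability``
    is clipped to [eps, 1 - eps].
    """

    cell_line: str
    drug: str | tuple[str, str]
    doses: np.ndarray
    viability: np.ndarray
    n_wells: np.ndarray

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        self.n_wells = np.asarray(self.n_wells, dtype=int)
        if (self.doses <= 0).any():
            raise ValueError("doses must be strictly positive")
        key = self.doses if self.doses.ndim == 1 else self.doses[:, 0]
        if (np.diff(key) < 0).any():
            raise ValueError("doses must be sorted ascending")

    @property
    def fa(self) -> np.ndarray:
        """Fraction of cells affected (dead)."""
        return 1.0 - self.viability

    @property
    def fu(self) -> np.ndarray:
        """Fraction of cells unaffected (alive)."""
        return self.viability

    def __len__(self) -> int:
        return len(self.viability)


@dataclass
class QCReport:
    """Audit trail: per-plate retention and every replaced value.

    ``wells`` has one row per replaced well with the stage that replaced it
    (``quadruplicate``, ``control`` or ``dose_response``); ``plates`` has
    one row per input plate with its 90th-percentile RFU and whether it was
    retained.
    """

    plates: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["plate_id", "retained", "p90_rfu", "usable"]
        )
    )
    wells: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["plate_id", "row", "col", "stage", "original", "replacement"]
        )
    )
    warnings: list[str] = field(default_factory=list)

    @property
    def n_plates_removed(self) -> int:
        return int((~self.plates["retained"].astype(bool)).sum())

    def flagged_well_keys(self) -> set[tuple[str, int, int]]:
        return set(
            zip(self.wells["plate_id"], self.wells["row"], self.wells["col"])
        )


# ---------------------------------------------------------------------------
# Stage 1: quadruplicate CV screen
# ---------------------------------------------------------------------------


def qc_quadruplicates(
    values, cv_threshold: float = 0.3
) -> tuple[np.ndarray, np.ndarray]:
    """Screen one quadruplicate of RFU values for deviants.

    If the coefficient of variation (sd/mean) of the four values is within
    the threshold they pass unchanged. Otherwise the single value whose
    removal minimizes the CV of the remaining three is a candidate deviant:
    if the reduced CV passes, that value is replaced by the mean of the
    other three; if no single removal suffices (two or more deviants), all
    four are replaced by their mean.

    Returns ``(cleaned, flags)`` where flags marks replaced positions.
    """
    vals = np.asarray(values, dtype=float)
    if vals.shape != (4,):
        raise ValueError(f"expected exactly 4 values, got shape {vals.shape}")
    if not np.isfinite(vals).all():
        raise ValueError("quadruplicate values must be finite")
    flags = np.zeros(4, dtype=bool)
    mean = vals.mean()
    if mean <= 0:
        return np.full(4, mean), np.ones(4, dtype=bool)
    cv = vals.std(ddof=1) / mean
    if cv <= cv_threshold:
        return vals.copy(), flags
    best_i, best_cv = -1, np.inf
    for i in range(4):
        rest = np.delete(vals, i)
        m = rest.mean()
        c = np.inf if m <= 0 else rest.std(ddof=1) / m
        if c < best_cv:
            best_i, best_cv = i, c
    if best_cv <= cv_threshold:
        cleaned = vals.copy()
        cleaned[best_i] = np.delete(vals, best_i).mean()
        flags[best_i] = True
        return cleaned, flags
    return np.full(4, mean), np.ones(4, dtype=bool)


# ---------------------------------------------------------------------------
# Stage 2: plate viability filter
# ---------------------------------------------------------------------------


def plate_viability_filter(
    rfu_values, threshold_rfu: float = 2000.0
) -> tuple[bool, float]:
    """Dead-plate check on the 90th percentile of a plate's RFU values.

    Uses the linear-interpolation percentile convention. A plate is
    retained iff its 90th percentile is at or above the threshold.
    """
    vals = np.asarray(rfu_values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty plate")
    p90 = float(np.percentile(vals, 90.0, method="linear"))
    return p90 >= threshold_rfu, p90


# ---------------------------------------------------------------------------
# Stages 3 & 5: iterative flag-and-replace regression
# ---------------------------------------------------------------------------


def studentized_residuals(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Externally studentized residuals of a simple linear regression.

    ``r_i = e_i / (s_(i) * sqrt(1 - h_ii))`` with the leave-one-out error
    variance ``s_(i)^2 = (SSE - e_i^2 / (1 - h_ii)) / (n - 3)``. Degenerate
    cases (n <= 3, zero predictor variance, exact fit) return zeros.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n <= 3:
        return np.zeros(n)
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx <= 0:
        # fall back to location model: residuals about the mean
        e = y - y.mean()
        h = np.full(n, 1.0 / n)
        dof = n - 2
    else:
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        e = y - (y.mean() + slope * (x - x.mean()))
        h = 1.0 / n + (x - x.mean()) ** 2 / sxx
        dof = n - 3
    sse = np.sum(e**2)
    # an (up to float error) exact fit has no outliers; don't studentize noise
    if sse <= n * (1e-10**2) * max(1.0, float(np.mean(y**2))):
        return np.zeros(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2_loo = (sse - e**2 / (1.0 - h)) / dof
        s2_loo = np.maximum(s2_loo, 0.0)
        r = e / np.sqrt(s2_loo * (1.0 - h))
    r[~np.isfinite(r)] = 0.0
    return r


def _flag_replace_loop(
    x: np.ndarray,
    y: np.ndarray,
    resid_threshold: float,
    max_iter: int,
    clip: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterate: fit OLS, flag |studentized residual| > threshold, replace the
    worst offender with its fitted value, refit; stop when clean."""
    y = np.asarray(y, dtype=float).copy()
    x = np.asarray(x, dtype=float)
    flags = np.zeros(y.size, dtype=bool)
    for _ in range(max_iter):
        r = studentized_residuals(x, y)
        bad = np.abs(r) > resid_threshold
        if not bad.any():
            break
        worst = int(np.argmax(np.abs(r)))
        sxx = np.sum((x - x.mean()) ** 2)
        mask = np.ones(y.size, dtype=bool)
        mask[worst] = False
        if sxx <= 0:
            fitted = y[mask].mean()  # degenerate covariate: mean replacement
        else:
            # predict the flagged point from the regression on the others
            xm, ym = x[mask], y[mask]
            sxx_m = np.sum((xm - xm.mean()) ** 2)
            if sxx_m <= 0:
                fitted = ym.mean()
            else:
                slope = np.sum((xm - xm.mean()) * (ym - ym.mean())) / sxx_m
                fitted = ym.mean() + slope * (x[worst] - xm.mean())
        if clip is not None:
            fitted = float(np.clip(fitted, *clip))
        if abs(fitted - y[worst]) <= 1e-12 * max(1.0, abs(fitted)):
            # replacement would not change the value (e.g. a clip-saturated
            # endpoint); nothing to fix
            break
        y[worst] = fitted
        flags[worst] = True
    return y, flags


def control_flag_replace(
    values,
    resid_threshold: float = 3.0,
    max_iter: int = 10,
    positions=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Clean a plate's control wells by iterative regression on well index.

    Applied separately to vehicle and negative controls. With fewer than 3
    control wells the values pass through unchanged (logged).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 3:
        logger.warning("fewer than 3 control wells; skipping control QC")
        return vals.copy(), np.zeros(vals.size, dtype=bool)
    x = np.arange(vals.size, dtype=float) if positions is None else np.asarray(
        positions, dtype=float
    )
    if max_iter <= 0:
        return vals.copy(), np.zeros(vals.size, dtype=bool)
    return _flag_replace_loop(x, vals, resid_threshold, max_iter)


def normalize_plate(
    rfu, vehicle_mean: float, negative_mean: float, eps: float = 0.005
) -> np.ndarray:
    """Viability from RFU via control normalization, clipped to [eps, 1-eps]."""
    if vehicle_mean <= negative_mean:
        raise ValueError(
            "vehicle control mean must exceed negative control mean "
            f"(got V={vehicle_mean}, N={negative_mean}); plate unusable"
        )
    v = (np.asarray(rfu, dtype=float) - negative_mean) / (
        vehicle_mean - negative_mean
    )
    return np.clip(v, eps, 1.0 - eps)


def dose_response_flag_replace(
    series: DoseResponseSeries,
    resid_threshold: float = 3.0,
    max_iter: int = 10,
    eps: float = 0.005,
) -> tuple[DoseResponseSeries, np.ndarray]:
    """Flag-and-replace within one dose-response series.

    The regression runs on the median-effect linearized scale —
    ``log10(Fa/Fu)`` against ``log10(dose)`` — under which a clean
    dose-response curve is exactly linear, so clean series are a fixed
    point of the check. Replaced points take their regression-predicted
    value mapped back to viability and clipped to the viability band.
    Series with fewer than 3 points pass through (logged).
    """
    if len(series) < 3:
        logger.warning(
            "series %s/%s has < 3 dose points; skipping dose-response QC",
            series.cell_line,
            series.drug,
        )
        return series, np.zeros(len(series), dtype=bool)
    dose1 = series.doses if series.doses.ndim == 1 else series.doses[:, 0]
    x = np.log10(dose1)
    v = np.clip(series.viability, eps, 1.0 - eps)
    y = np.log10((1.0 - v) / v)
    y_max = math.log10((1.0 - eps) / eps)
    y_clean, flags = _flag_replace_loop(
        x, y, resid_threshold, max_iter, clip=(-y_max, y_max)
    )
    cleaned = np.where(flags, 1.0 / (1.0 + 10.0**y_clean), series.viability)
    cleaned = np.clip(cleaned, eps, 1.0 - eps) if flags.any() else series.viability
    out = DoseResponseSeries(
        cell_line=series.cell_line,
        drug=series.drug,
        doses=series.doses,
        viability=cleaned,
        n_wells=series.n_wells,
    )
    return out, flags


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def _series_sort(doses: np.ndarray):
    key = doses if doses.ndim == 1 else doses[:, 0]
    return np.argsort(key, kind="stable")


def run_qc(
    plates: pd.DataFrame, config: QCConfig | None = None
) -> tuple[dict[tuple[str, str | tuple[str, str]], DoseResponseSeries], QCReport]:
    """Run the full QC pipeline on a long-format well table.

    Returns ``(series, report)`` where ``series`` maps
    ``(cell_line, drug)`` and ``(cell_line, (drug1, drug2))`` keys to
    averaged :class:`DoseResponseSeries`, and ``report`` accounts for every
    plate and replaced well.
    """
    cfg = config or QCConfig()
    missing = set(PLATE_COLUMNS) - set(plates.columns)
    if missing:
        raise ValueError(f"plate table missing columns {sorted(missing)}")
    plates = plates.copy()
    plates["rfu"] = plates["rfu"].astype(float)

    report = QCReport()
    plate_rows = []
    well_rows = []
    # per-plate, per-series viability after stages 1-5
    cleaned_points: list[tuple[str, object, object, float, int]] = []
    # (cell_line, drug-key, dose-key, viability, n_wells)

    for plate_id, pl in plates.groupby("plate_id", sort=False):
        pl = pl.sort_values(["row", "col"]).reset_index()
        rfu = pl["rfu"].to_numpy().copy()
        # flags accumulate here and only count if the plate survives: a
        # removed plate contributes no downstream values, replaced or not
        plate_well_rows: list[tuple] = []

        # -- stage 1: quadruplicates over assay conditions ------------------
        cond_cols = ["role", "drug1", "dose1", "drug2", "dose2"]
        for key, idx in (
            pl.groupby(cond_cols, sort=False, dropna=False).groups.items()
        ):
            role = key[0]
            if role not in ("single_drug", "combination"):
                continue
            idx = np.asarray(idx)
            if idx.size != 4:
                report.warnings.append(
                    f"{plate_id}: condition {key} has {idx.size} wells, "
                    "quadruplicate check skipped"
                )
                continue
            cleaned, flags = qc_quadruplicates(rfu[idx], cfg.cv_threshold)
            for j, i in enumerate(idx):
                if flags[j]:
                    plate_well_rows.append(
                        (
                            plate_id,
                            int(pl.loc[i, "row"]),
                            int(pl.loc[i, "col"]),
                            "quadruplicate",
                            rfu[i],
                            cleaned[j],
                        )
                    )
            rfu[idx] = cleaned

        # -- stage 2: plate viability filter --------------------------------
        retained, p90 = plate_viability_filter(rfu, cfg.plate_rfu_threshold)
        if not retained:
            plate_rows.append((plate_id, False, p90, False))
            continue

        # -- stage 3: control flag-and-replace ------------------------------
        ctrl_means = {}
        usable = True
        for role, name in (
            ("vehicle_control", "vehicle"),
            ("negative_control", "negative"),
        ):
            mask = (pl["role"] == role).to_numpy()
            idx = np.flatnonzero(mask)
            vals = rfu[idx]
            cleaned, flags = control_flag_replace(
                vals, cfg.resid_threshold, cfg.max_iter
            )
            for j, i in enumerate(idx):
                if flags[j]:
                    plate_well_rows.append(
                        (
                            plate_id,
                            int(pl.loc[i, "row"]),
                            int(pl.loc[i, "col"]),
                            "control",
                            rfu[i],
                            cleaned[j],
                        )
                    )
            rfu[idx] = cleaned
            if idx.size == 0:
                report.warnings.append(f"{plate_id}: no {name} controls")
                usable = False
            else:
                ctrl_means[name] = float(cleaned.mean())
        if usable and ctrl_means["vehicle"] <= ctrl_means["negative"]:
            report.warnings.append(
                f"{plate_id}: vehicle mean <= negative mean; plate unusable"
            )
            usable = False
        plate_rows.append((plate_id, usable, p90, usable))
        if not usable:
            continue

        # -- stage 4: normalization -----------------------------------------
        viability = normalize_plate(
            rfu, ctrl_means["vehicle"], ctrl_means["negative"], cfg.eps
        )

        # -- stage 5: dose-response flag-and-replace ------------------------
        # the regression check applies within each single drug; combination
        # points (screened at the quadruplicate stage) pass through, since a
        # combination series with unequal drug slopes is not log-linear even
        # when clean
        cell_line = pl["cell_line"].iloc[0]
        assay = pl[pl["role"].isin(["single_drug", "combination"])]
        for role in ("single_drug", "combination"):
            sub = assay[assay["role"] == role]
            if sub.empty:
                continue
            if role == "single_drug":
                groups = sub.groupby("drug1", sort=False)
            else:
                groups = sub.groupby(["drug1", "drug2"], sort=False)
            for gkey, g in groups:
                if role == "single_drug":
                    drug_key = gkey if not isinstance(gkey, tuple) else gkey[0]
                    point_groups = g.groupby("dose1", sort=True)
                    mkdose = lambda k: float(k)
                else:
                    drug_key = (gkey[0], gkey[1])
                    point_groups = g.groupby(["dose1", "dose2"], sort=True)
                    mkdose = lambda k: (float(k[0]), float(k[1]))
                doses, viab, nw, well_idx = [], [], [], []
                for dkey, gg in point_groups:
                    ii = gg.index.to_numpy()
                    doses.append(mkdose(dkey))
                    viab.append(float(viability[ii].mean()))
                    nw.append(len(ii))
                    well_idx.append(ii)
                darr = np.asarray(doses)
                order = _series_sort(darr)
                series = DoseResponseSeries(
                    cell_line=cell_line,
                    drug=drug_key,
                    doses=darr[order],
                    viability=np.asarray(viab)[order],
                    n_wells=np.asarray(nw)[order],
                )
                if role == "single_drug":
                    cleaned_series, flags = dose_response_flag_replace(
                        series, cfg.resid_threshold, cfg.max_iter, cfg.eps
                    )
                else:
                    cleaned_series = series
                    flags = np.zeros(len(series), dtype=bool)
                for j_sorted, flagged in enumerate(flags):
                    if not flagged:
                        continue
                    for i in well_idx[order[j_sorted]]:
                        plate_well_rows.append(
                            (
                                plate_id,
                                int(pl.loc[i, "row"]),
                                int(pl.loc[i, "col"]),
                                "dose_response",
                                series.viability[j_sorted],
                                cleaned_series.viability[j_sorted],
                            )
                        )
                for j in range(len(cleaned_series)):
                    dose_key = (
                        float(cleaned_series.doses[j])
                        if cleaned_series.doses.ndim == 1
                        else (
                            float(cleaned_series.doses[j, 0]),
                            float(cleaned_series.doses[j, 1]),
                        )
                    )
                    cleaned_points.append(
                        (
                            cell_line,
                            drug_key,
                            dose_key,
                            float(cleaned_series.viability[j]),
                            int(cleaned_series.n_wells[j]),
                        )
                    )
        well_rows.extend(plate_well_rows)

    report.plates = pd.DataFrame(
        plate_rows, columns=["plate_id", "retained", "p90_rfu", "usable"]
    )
    report.wells = pd.DataFrame(
        well_rows,
        columns=["plate_id", "row", "col", "stage", "original", "replacement"],
    )

    # -- average replicate runs at the viability level -----------------------
    out: dict[tuple[str, str | tuple[str, str]], DoseResponseSeries] = {}
    acc: dict[tuple, dict[object, list[tuple[float, int]]]] = {}
    for cell_line, drug_key, dose_key, v, n in cleaned_points:
        acc.setdefault((cell_line, drug_key), {}).setdefault(dose_key, []).append(
            (v, n)
        )
    dropped = set(plates["cell_line"]) - {k[0] for k in acc}
    for line in sorted(dropped):
        report.warnings.append(f"{line}: all plates removed; excluded downstream")
    for (cell_line, drug_key), by_dose in acc.items():
        dose_keys = sorted(by_dose)
        doses = np.asarray(dose_keys)
        viab = np.array([np.mean([v for v, _ in by_dose[d]]) for d in dose_keys])
        nw = np.array([sum(n for _, n in by_dose[d]) for d in dose_keys])
        out[(cell_line, drug_key)] = DoseResponseSeries(
            cell_line=cell_line, drug=drug_key, doses=doses, viability=viab, n_wells=nw
        )
    return out, report
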