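"""Pedigree variance-component heritability of quantitative traits.

The phenotype is modelled as P = G + E with broad-sense heritability
H² = Var(G) / Var(P). For pedigree data the genetic covariance between
individuals i and j is 2 φ(i,j) · Vg, with φ the kinship coefficient, so
each family contributes a multivariate-normal likelihood with covariance
Σ = 2Φ Vg + I Ve. (Vg, Ve) are estimated by maximum likelihood over family
blocks; with no dominance term in the covariance this is the additive
variance-component H² that pedigree software reports for data of this
structure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .pedigree import Pedigree

__all__ = [
    "KinshipMatrix",
    "VarianceComponents",
    "kinship_matrix",
    "fit_variance_components",
    "heritability_by_dose",
]

logger = logging.getLogger(__name__)


@dataclass
class KinshipMatrix:
    """Kinship coefficients φ for every pair of pedigree members.

    Symmetric, block-diagonal by family; φ(i,i) = ½(1 + φ(father, mother))
    (0.5 for non-inbred individuals), φ = 0 between families.
    """

    ids: list[str]
    phi: np.ndarray
    family_of: dict[str, str]

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.shape != (len(self.ids), len(self.ids)):
            raise ValueError("kinship matrix shape mismatch")
        self._row = {iid: i for i, iid in enumerate(self.ids)}

    def get(self, i: str, j: str) -> float:
        return float(self.phi[self._row[i], self._row[j]])

    def submatrix(self, ids: list[str]) -> np.ndarray:
        idx = [self._row[i] for i in ids]
        return self.phi[np.ix_(idx, idx)]


def kinship_matrix(ped: Pedigree) -> KinshipMatrix:
    """Exact recursive kinship coefficients for a pedigree.

    Founders are mutually unrelated; for a non-founder i with parents f, m
    and any j processed before i, φ(i,j) = ½(φ(f,j) + φ(m,j)) and
    φ(i,i) = ½(1 + φ(f,m)).
    """
    order = ped.topological()
    n = len(order)
    ids = [ind.id for ind in order]
    row = {iid: k for k, iid in enumerate(ids)}
    phi = np.zeros((n, n))
    for k, ind in enumerate(order):
        if ind.is_founder:
            phi[k, k] = 0.5
        else:
            f, m = row[ind.father_id], row[ind.mother_id]
            phi[k, k] = 0.5 * (1.0 + phi[f, m])
            for j in range(k):
                phi[k, j] = phi[j, k] = 0.5 * (phi[f, j] + phi[m, j])
    # reorder to the pedigree's own individual order
    perm = [row[iid] for iid in ped.ids]
    phi = phi[np.ix_(perm, perm)]
    return KinshipMatrix(
        ids=ped.ids,
        phi=phi,
        family_of={ind.id: ind.family_id for ind in ped.individuals},
    )


@dataclass
class VarianceComponents:
    """Maximum-likelihood variance decomposition of one trait."""

    vg: float
    ve: float
    loglik: float
    converged: bool
    n_used: int

    @property
    def vp(self) -> float:
        return self.vg + self.ve

    @property
    def h2(self) -> float | None:
        if not self.converged or self.vp <= 0:
            return None
        return self.vg / self.vp


def _make_blocks(kin: KinshipMatrix, values: pd.Series):
    """Build per-group (eigenvalues, rotated ones, rotated trait rows)."""
    by_fam: dict[str, list[str]] = {}
    for iid in values.index:
        by_fam.setdefault(kin.family_of[iid], []).append(iid)
    groups: dict[bytes, dict] = {}
    for fam, ids in by_fam.items():
        k_mat = 2.0 * kin.submatrix(ids)
        key = np.round(k_mat, 12).tobytes()
        g = groups.setdefault(key, {"k": k_mat, "ys": []})
        g["ys"].append(values.loc[ids].to_numpy())
    blocks = []
    n_total = 0
    any_related = False
    n_families = len(by_fam)
    for g in groups.values():
        lam, u = np.linalg.eigh(g["k"])
        y = np.stack(g["ys"])
        ones_rot = u.T @ np.ones(lam.size)
        blocks.append((lam, ones_rot, y @ u))
        n_total += y.size
        off = g["k"] - np.diag(np.diag(g["k"]))
        if np.abs(off).max() > 1e-12:
            any_related = True
    return blocks, n_total, any_related, n_families


def _neg_loglik(blocks, n_total: int, vg: float, ve: float) -> float:
    num = 0.0
    den = 0.0
    for lam, ones_rot, z in blocks:
        d = vg * lam + ve
        num += (z * (ones_rot / d)).sum()
        den += z.shape[0] * (ones_rot**2 / d).sum()
    mu = num / den
    ll = 0.0
    for lam, ones_rot, z in blocks:
        d = vg * lam + ve
        resid = z - mu * ones_rot
        ll += z.shape[0] * np.log(d).sum() + (resid**2 / d).sum()
    return 0.5 * (ll + n_total * math.log(2.0 * math.pi))


def fit_variance_components(
    trait: pd.Series,
    kin: KinshipMatrix,
    n_restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-8,
) -> VarianceComponents:
    """Maximum-likelihood fit of trait ~ N(μ·1, 2Φ Vg + I Ve) by family block.

    Optimizes over log-variances with seeded multi-start L-BFGS-B (boundary
    Vg → 0 checked explicitly), profiling the mean out by GLS. Missing trait
    values drop the individual; if no phenotyped pair is related, Vg is
    unidentifiable and the result carries ``converged=False``.
    """
    values = trait.dropna().astype(float)
    values = values[[iid in kin.family_of for iid in values.index]]
    if values.size < 3:
        raise ValueError("need at least 3 phenotyped individuals")
    if values.var() <= 0:
        raise ValueError("trait has zero variance")
    blocks, n_total, any_related, n_families = _make_blocks(kin, values)
    if not any_related:
        logger.warning("no related phenotyped pairs: Vg unidentifiable")
        return VarianceComponents(
            vg=float("nan"), ve=float(values.var()), loglik=float("nan"),
            converged=False, n_used=int(values.size),
        )

    vp0 = float(values.var())
    rng = np.random.default_rng(seed)

    def objective(params):
        vg, ve = np.exp(params)
        return _neg_loglik(blocks, n_total, vg, ve)

    starts = [(0.5 * vp0, 0.5 * vp0)]
    for _ in range(max(0, n_restarts - 1)):
        h = rng.uniform(0.05, 0.95)
        starts.append((h * vp0, (1.0 - h) * vp0))

    best = None
    lo = math.log(vp0) - 25.0
    hi = math.log(vp0) + 5.0
    for vg0, ve0 in starts:
        res = minimize(
            objective,
            x0=[math.log(vg0), math.log(ve0)],
            method="L-BFGS-B",
            bounds=[(lo, hi), (lo, hi)],
            options={"ftol": tol, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    vg_hat, ve_hat = np.exp(best.x)
    # explicit Vg -> 0 boundary (environment-only model)
    res0 = minimize(
        lambda p: _neg_loglik(blocks, n_total, 0.0, math.exp(p[0])),
        x0=[math.log(vp0)],
        method="L-BFGS-B",
        bounds=[(lo, hi)],
        options={"ftol": tol},
    )
    if res0.fun < best.fun - 1e-9:
        vg_hat, ve_hat = 0.0, float(np.exp(res0.x[0]))
        best = res0
    elif vg_hat < vp0 * 1e-8:
        vg_hat = 0.0
    return VarianceComponents(
        vg=float(vg_hat),
        ve=float(ve_hat),
        loglik=float(-best.fun),
        converged=bool(best.success),
        n_used=int(values.size),
    )


def null_loglik(trait: pd.Series, kin: KinshipMatrix) -> float:
    """Log-likelihood of the no-genetics model (Vg = 0) for comparison."""
    values = trait.dropna().astype(float)
    blocks, n_total, _, _ = _make_blocks(kin, values)
    res = minimize(
        lambda p: _neg_loglik(blocks, n_total, 0.0, math.exp(p[0])),
        x0=[math.log(float(values.var()))],
        method="L-BFGS-B",
    )
    return float(-res.fun)


def heritability_by_dose(
    traits: dict, kin: KinshipMatrix, **fit_kwargs
) -> tuple[pd.DataFrame, object]:
    """Per-dose heritability table and the max-H² dose.

    ``traits`` maps a dose key to a trait Series. Doses whose fit fails are
    reported with missing H². Ties on H² break toward the earlier dose key
    in the mapping's order (logged).
    """
    rows = []
    fits = {}
    for dose, tr in traits.items():
        try:
            vc = fit_variance_components(tr, kin, **fit_kwargs)
        except ValueError as exc:
            logger.warning("dose %s: %s", dose, exc)
            rows.append((dose, np.nan, np.nan, np.nan, np.nan, False))
            continue
        fits[dose] = vc
        rows.append((dose, vc.vg, vc.ve, vc.h2, vc.loglik, vc.converged))
    table = pd.DataFrame(
        rows, columns=["dose", "vg", "ve", "h2", "loglik", "converged"]
    )
    usable = [d for d in traits if d in fits and fits[d].h2 is not None]
    if not usable:
        raise ValueError("no dose produced a fittable heritability")
    best = max(usable, key=lambda d: fits[d].h2)  # max() keeps first on ties
    n_best = sum(1 for d in usable if fits[d].h2 == fits[best].h2)
    if n_best > 1:
        logger.info("H2 tie across %d doses; choosing earliest (%s)", n_best, best)
    return table, best
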