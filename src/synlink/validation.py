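"""End-to-end validation experiments with known ground truth.

Each function runs one self-contained experiment through the public
pipeline — generating synthetic inputs, executing the analysis, and
measuring recovery of the generating truth. They back both the test suite
and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .linkage import genome_scan
from .pedigree import simulate_pedigrees
from .qc import plate_viability_filter, run_qc
from .quantgen import fit_variance_components, kinship_matrix
from .simulate import (
    ArtifactSpec,
    AssayDesign,
    DrugParams,
    GeneticMap,
    TraitModel,
    simulate_genotypes,
    simulate_plates,
    simulate_trait,
)
from .synergy import (
    CombinationObservation,
    ci_profile,
    combination_index,
    fit_median_effect,
)

__all__ = [
    "sham_combination_cis",
    "ci_cap_demo",
    "plate_filter_boundary",
    "median_effect_recovery",
    "ci_noise_recovery",
    "heritability_recovery",
    "linkage_power",
    "linkage_null_calibration",
    "qc_deviant_recall",
]

_VEHICLE = 10000.0
_NEGATIVE = 500.0


def sham_combination_cis(rho: float = 4.0, dm: float = 2.0, m: float = 1.6):
    """CI at every dose pair for one compound relabelled as two drugs.

    Drug B is drug A at potency ratio ``rho``; the combination responds as
    drug A at the pooled effective dose D1 + rho * D2. Loewe additivity
    then forces CI = 1 at every pair.
    """
    doses1 = dm * np.array([0.125, 0.25, 0.5, 1.0, 2.0, 4.0])
    doses2 = doses1 / rho
    v1 = 1.0 / (1.0 + (doses1 / dm) ** m)
    v2 = 1.0 / (1.0 + (doses2 / (dm / rho)) ** m)
    fit1 = fit_median_effect(doses=doses1, viability=v1, drug="a")
    fit2 = fit_median_effect(doses=doses2, viability=v2, drug="b")
    cis = []
    for d1, d2 in zip(doses1 / 2.0, doses2 / 2.0):
        eff = d1 + rho * d2
        fa = 1.0 - 1.0 / (1.0 + (eff / dm) ** m)
        cis.append(combination_index(fit1, fit2, CombinationObservation(d1, d2, fa)).ci)
    return np.asarray(cis)


def ci_cap_demo():
    """A dose pair whose raw CI far exceeds the cap; returns (ci, ci_raw)."""
    from .synergy import MedianEffectFit

    fit = MedianEffectFit("L", "d", m=1.0, dm=1.0, intercept=0.0,
                          r_squared=1.0, n_points=6, valid=True)
    res = combination_index(fit, fit, CombinationObservation(2.0, 2.0, 0.01))
    return res.ci, res.ci_raw


def plate_filter_boundary(n_wells: int = 384, tol: float = 0.25) -> float:
    """Bisection over constant-RFU plates for the retain/remove transition."""
    lo, hi = 0.0, 10000.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        retained, _ = plate_viability_filter(np.full(n_wells, mid))
        if retained:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def median_effect_recovery(m: float = 1.5, dm: float = 4.0):
    """Fit on noise-free log-linear data; returns (m_est, dm_est)."""
    doses = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0])
    viability = 1.0 / (1.0 + (doses / dm) ** m)
    fit = fit_median_effect(doses=doses, viability=viability)
    return fit.m, fit.dm


def ci_noise_recovery(
    n_lines: int = 100,
    noise_fraction: float = 0.03,
    seed: int = 0,
) -> float:
    """Median absolute CI error under RFU noise over a synthetic panel.

    Noise sd is the stated fraction of the plate's dynamic range
    (vehicle minus negative level); the generating CI per line spans the
    configured range via the latent trait.
    """
    rng = np.random.default_rng(seed)
    lines = [f"L{i:03d}" for i in range(n_lines)]
    latent = pd.Series(rng.normal(0.0, 0.35, n_lines), index=lines)
    design = AssayDesign.default()
    dp = {"drugA": DrugParams(4.0, 1.5, 0.2), "drugB": DrugParams(1.0, 2.0, 0.2)}
    noise_sd = noise_fraction * (_VEHICLE - _NEGATIVE)
    plates, truth = simulate_plates(
        lines, latent, design, dp, ArtifactSpec(noise_sd=noise_sd),
        seed=int(rng.integers(2**31 - 1)),
        vehicle_level=_VEHICLE, negative_level=_NEGATIVE,
    )
    series, _ = run_qc(plates)
    true_ci = truth.true_ci.set_index(["cell_line", "dose1", "dose2"])["ci_true"]
    errors = []
    for line in lines:
        for res in ci_profile(series, line, ("drugA", "drugB")):
            if res.missing:
                continue
            errors.append(abs(res.ci - true_ci.loc[(line, res.d1, res.d2)]))
    return float(np.median(errors))


def heritability_recovery(
    h2: float,
    n_families: int = 150,
    n_seeds: int = 20,
    seed: int = 0,
    children=(2, 4),
) -> float:
    """Mean variance-component H² estimate over replicate simulated panels.

    The trait is the latent (polygenic + environmental) synergy trait at
    the generator's heritability; each replicate simulates a fresh pedigree
    and trait and refits from scratch.
    """
    rng = np.random.default_rng(seed)
    ests = []
    for _ in range(n_seeds):
        s = rng.integers(0, 2**31 - 1, size=3)
        ped = simulate_pedigrees(n_families, children, seed=int(s[0]))
        model = TraitModel(
            polygenic_variance=h2, environmental_variance=1.0 - h2
        )
        trait = simulate_trait(ped, None, model, seed=int(s[1]))
        kin = kinship_matrix(ped)
        vc = fit_variance_components(trait, kin, seed=int(s[2]))
        est = vc.h2 if vc.h2 is not None else 0.0
        ests.append(est)
    return float(np.mean(ests))


def _scan_once(seed: int, h2: float, n_families: int, children) -> "object":
    rng = np.random.default_rng(seed)
    s = rng.integers(0, 2**31 - 1, size=3)
    ped = simulate_pedigrees(n_families, children, seed=int(s[0]))
    gmap = GeneticMap.uniform(4, 60, 2.0)
    geno = simulate_genotypes(ped, gmap, seed=int(s[1]))
    if h2 > 0:
        model = TraitModel.from_h2(
            h2, qtl_fraction=1.0, qtl_chromosome=2, qtl_position_cM=60.0
        )
    else:
        model = TraitModel(polygenic_variance=0.0, environmental_variance=1.0)
    trait = simulate_trait(ped, geno, model, seed=int(s[2]), gmap=gmap)
    return genome_scan(trait, ped, geno, gmap)


def linkage_power(
    n_seeds: int = 20,
    qtl_variance: float = 0.3,
    n_families: int = 600,
    children: int = 3,
    seed: int = 0,
) -> float:
    """Fraction of replicate genomes whose top LOD peak lands on the QTL
    chromosome (chromosome 2 of a 4-chromosome genome)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_seeds):
        scan = _scan_once(int(rng.integers(2**31 - 1)), qtl_variance,
                          n_families, children)
        chrom, _ = scan.top_position()
        hits += chrom == 2
    return hits / n_seeds


def linkage_null_calibration(
    n_seeds: int = 50,
    n_families: int = 600,
    children: int = 3,
    lod_threshold: float = 3.0,
    seed: int = 0,
) -> float:
    """Fraction of null genomes whose genome-wide max LOD stays below the
    reporting threshold."""
    rng = np.random.default_rng(seed)
    below = 0
    for _ in range(n_seeds):
        scan = _scan_once(int(rng.integers(2**31 - 1)), 0.0, n_families, children)
        below += scan.max_lod < lod_threshold
    return below / n_seeds


def qc_deviant_recall(
    n_lines: int = 30,
    deviant_rate: float = 0.02,
    multiplier: float = 5.0,
    noise_sd: float = 150.0,
    seed: int = 0,
) -> float:
    """Fraction of injected deviant wells flagged at any QC stage."""
    rng = np.random.default_rng(seed)
    lines = [f"L{i:03d}" for i in range(n_lines)]
    latent = pd.Series(rng.normal(0.0, 0.3, n_lines), index=lines)
    design = AssayDesign.default()
    dp = {"drugA": DrugParams(4.0, 1.5, 0.2), "drugB": DrugParams(1.0, 2.0, 0.2)}
    plates, truth = simulate_plates(
        lines, latent, design, dp,
        ArtifactSpec(deviant_rate=deviant_rate, noise_sd=noise_sd,
                     deviant_multiplier=multiplier),
        seed=int(rng.integers(2**31 - 1)),
    )
    _, report = run_qc(plates)
    injected = set(
        zip(truth.deviant_wells.plate_id, truth.deviant_wells.row,
            truth.deviant_wells.col)
    )
    removed = set(report.plates.loc[~report.plates.retained, "plate_id"])
    injected = {k for k in injected if k[0] not in removed}
    if not injected:
        return float("nan")
    flagged = report.flagged_well_keys()
    return len(injected & flagged) / len(injected)
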