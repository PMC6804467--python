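"""Synthetic data generation with known ground truth.

Everything downstream of the wet lab is emulated here: a genetic map and
gene-dropped genotypes over nuclear-family pedigrees, a heritable latent
synergy trait with an optional planted QTL, and raw fluorescence (RFU)
plates for monotherapy and combination dose grids, including the artifacts
the QC pipeline is built to catch (deviant wells, dead plates, noise).

The dose-response model is the median-effect law: for a cell line with
median-effect dose ``Dm`` and sigmoidicity ``m``, the fraction of cells
unaffected at dose ``D`` is ``1 / (1 + (D / Dm) ** m)``.  Combination wells
are generated so that the line's true Chou–Talalay combination index (CI)
at every designed dose pair equals a monotone function of its latent trait,
giving an exact end-to-end oracle for the estimation pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .pedigree import Pedigree

__all__ = [
    "GeneticMap",
    "GenotypeMatrix",
    "QTL",
    "TraitModel",
    "DrugParams",
    "ArtifactSpec",
    "AssayDesign",
    "SimTruth",
    "haldane_theta",
    "simulate_genotypes",
    "simulate_trait",
    "simulate_plates",
    "latent_to_ci",
    "median_effect_viability",
    "solve_combination_fa",
]

MISSING_ALLELE = 0


def haldane_theta(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a map distance in cM (Haldane, no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------


class GeneticMap:
    """Marker positions in centimorgans along numbered chromosomes.

    Wraps a DataFrame with columns ``chromosome`` (int), ``marker_id`` (str)
    and ``position_cM`` (float); positions must be nondecreasing within a
    chromosome and marker ids unique.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"chromosome", "marker_id", "position_cM"}
        if not required.issubset(df.columns):
            raise ValueError(f"map frame needs columns {sorted(required)}")
        df = df.reset_index(drop=True).copy()
        df["chromosome"] = df["chromosome"].astype(int)
        df["position_cM"] = df["position_cM"].astype(float)
        if df["marker_id"].duplicated().any():
            raise ValueError("duplicate marker ids in map")
        if (df["position_cM"] < 0).any():
            raise ValueError("map positions must be nonnegative")
        for _, sub in df.groupby("chromosome", sort=False):
            if (np.diff(sub["position_cM"].to_numpy()) < 0).any():
                raise ValueError("positions must be nondecreasing per chromosome")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def marker_ids(self) -> list[str]:
        return self.df["marker_id"].tolist()

    @property
    def chromosomes(self) -> list[int]:
        return sorted(self.df["chromosome"].unique().tolist())

    def chromosome_indices(self, chrom: int) -> np.ndarray:
        return np.flatnonzero((self.df["chromosome"] == chrom).to_numpy())

    def positions(self, chrom: int) -> np.ndarray:
        return self.df.loc[self.df["chromosome"] == chrom, "position_cM"].to_numpy()

    def nearest_marker(self, chrom: int, position_cM: float) -> int:
        """Global index of the marker nearest a chromosome position."""
        idx = self.chromosome_indices(chrom)
        if idx.size == 0:
            raise ValueError(f"no markers on chromosome {chrom}")
        pos = self.df["position_cM"].to_numpy()[idx]
        return int(idx[np.argmin(np.abs(pos - position_cM))])

    @classmethod
    def uniform(
        cls,
        n_chromosomes: int = 4,
        n_markers_per_chromosome: int = 60,
        spacing_cM: float = 2.0,
    ) -> "GeneticMap":
        """Evenly spaced markers, the desk-scale default genome."""
        rows = []
        for c in range(1, n_chromosomes + 1):
            for i in range(n_markers_per_chromosome):
                rows.append((c, f"C{c}M{i + 1:03d}", i * spacing_cM))
        return cls(pd.DataFrame(rows, columns=["chromosome", "marker_id", "position_cM"]))


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Ordered allele pairs per individual x marker.

    ``alleles`` has shape (n_individuals, n_markers, 2) with integer allele
    codes >= 1 and 0 meaning missing. For simulated (gene-dropped) data the
    first slot of each pair is the paternally transmitted allele.
    """

    ids: list[str]
    marker_ids: list[str]
    alleles: np.ndarray

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles)
        if self.alleles.shape != (len(self.ids), len(self.marker_ids), 2):
            raise ValueError("allele array shape mismatch")
        self._row = {iid: i for i, iid in enumerate(self.ids)}

    def row(self, iid: str) -> int:
        return self._row[iid]

    def genotype(self, iid: str, marker_index: int) -> tuple[int, int]:
        a = self.alleles[self._row[iid], marker_index]
        return int(a[0]), int(a[1])


def _normalize_freqs(
    founder_allele_freqs, n_markers: int
) -> list[np.ndarray]:
    """Expand the frequency spec to one vector per marker and validate sums."""
    if founder_allele_freqs is None:
        founder_allele_freqs = [0.5, 0.5]
    arr = np.asarray(founder_allele_freqs, dtype=float)
    if arr.ndim == 1:
        freqs = [arr] * n_markers
    elif arr.ndim == 2:
        if arr.shape[0] != n_markers:
            raise ValueError("per-marker frequency matrix has wrong length")
        freqs = [arr[i] for i in range(n_markers)]
    else:
        raise ValueError("frequencies must be a vector or per-marker matrix")
    for i, f in enumerate(freqs):
        if (f < 0).any():
            raise ValueError(f"negative allele frequency at marker {i}")
        if abs(f.sum() - 1.0) > 1e-8:
            raise ValueError(
                f"allele frequencies at marker {i} sum to {f.sum():.10f}, not 1"
            )
    return freqs


def _gametes_batch(
    parent_alleles: np.ndarray,
    chrom_indices: list[np.ndarray],
    switch_probs: list[np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """Drop one gamete through each of a batch of parents.

    ``parent_alleles`` is (n, n_markers, 2); per chromosome each gamete
    starts on a random haplotype and switches between adjacent markers with
    the Haldane probability. Returns (n, n_markers).
    """
    n, n_markers, _ = parent_alleles.shape
    gam = np.empty((n, n_markers), dtype=parent_alleles.dtype)
    for idx, theta in zip(chrom_indices, switch_probs):
        switches = rng.random((n, theta.size)) < theta
        start = rng.integers(0, 2, size=(n, 1))
        hap = (
            start + np.concatenate([np.zeros((n, 1), dtype=int),
                                    np.cumsum(switches, axis=1)], axis=1)
        ) % 2
        sub = parent_alleles[:, idx, :]  # (n, n_chr_markers, 2)
        gam[:, idx] = np.take_along_axis(sub, hap[:, :, None], axis=2)[:, :, 0]
    return gam


def simulate_genotypes(
    ped: Pedigree,
    gmap: GeneticMap,
    founder_allele_freqs=None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Gene-drop genotypes through a pedigree.

    Founders are drawn marker-independently from Hardy–Weinberg proportions
    at the supplied allele frequencies (default biallelic 0.5/0.5);
    non-founders receive one recombinant gamete per parent with Haldane
    crossover probabilities between adjacent markers. The output contains
    no Mendelian errors by construction.
    """
    if len(gmap) == 0:
        raise ValueError("genetic map is empty")
    freqs = _normalize_freqs(founder_allele_freqs, len(gmap))
    rng = np.random.default_rng(seed)
    n_markers = len(gmap)
    ids = ped.ids
    alleles = np.zeros((len(ids), n_markers, 2), dtype=np.int16)
    row = {iid: i for i, iid in enumerate(ids)}

    switch_prob = {
        chrom: np.asarray(haldane_theta(np.diff(gmap.positions(chrom))))
        for chrom in gmap.chromosomes
    }

    # founders: inverse-CDF draw, vectorized over markers
    max_k = max(f.size for f in freqs)
    cum = np.zeros((n_markers, max_k))
    for j, f in enumerate(freqs):
        cum[j, : f.size] = np.cumsum(f)
        cum[j, f.size :] = 1.0

    # group individuals by pedigree depth so each generation drops in bulk
    depth: dict[str, int] = {}
    for ind in ped.topological():
        depth[ind.id] = (
            0
            if ind.is_founder
            else 1 + max(depth[ind.father_id], depth[ind.mother_id])
        )
    by_depth: dict[int, list] = {}
    for ind in ped.individuals:
        by_depth.setdefault(depth[ind.id], []).append(ind)

    chrom_indices = [gmap.chromosome_indices(c) for c in gmap.chromosomes]
    switch_probs = [switch_prob[c] for c in gmap.chromosomes]

    founders = by_depth.get(0, [])
    f_rows = [row[i.id] for i in founders]
    u = rng.random((len(f_rows), n_markers, 2))
    alleles[f_rows] = (u[:, :, :, None] > cum[None, :, None, :]).sum(axis=3) + 1

    for d in sorted(by_depth):
        if d == 0:
            continue
        group = by_depth[d]
        rows = [row[i.id] for i in group]
        pat = _gametes_batch(
            alleles[[row[i.father_id] for i in group]],
            chrom_indices, switch_probs, rng,
        )
        mat = _gametes_batch(
            alleles[[row[i.mother_id] for i in group]],
            chrom_indices, switch_probs, rng,
        )
        alleles[rows, :, 0] = pat
        alleles[rows, :, 1] = mat
    return GenotypeMatrix(ids=ids, marker_ids=gmap.marker_ids, alleles=alleles)


# ---------------------------------------------------------------------------
# Trait model
# ---------------------------------------------------------------------------


@dataclass
class QTL:
    """A quantitative trait locus planted at a map position.

    ``allele_effects`` maps allele code -> additive effect; an individual's
    QTL genotype value is the sum of its two allele effects at the marker
    nearest (chromosome, position_cM).
    """

    chromosome: int
    position_cM: float
    allele_effects: dict[int, float]

    def variance(self, allele_freqs: np.ndarray) -> float:
        """Genotype-value variance under Hardy–Weinberg at given frequencies."""
        f = np.asarray(allele_freqs, dtype=float)
        effects = np.array(
            [self.allele_effects.get(a + 1, 0.0) for a in range(f.size)]
        )
        mean = float(f @ effects)
        var1 = float(f @ (effects - mean) ** 2)
        return 2.0 * var1  # two independent alleles


@dataclass
class TraitModel:
    """Additive decomposition of the latent trait: QTL + polygenic + noise.

    ``target_h2``, when given, is validated against the variance components
    under the generating allele frequencies (see :meth:`check_h2`).
    """

    polygenic_variance: float = 0.0
    environmental_variance: float = 1.0
    qtl: QTL | None = None
    target_h2: float | None = None

    def __post_init__(self):
        if self.polygenic_variance < 0 or self.environmental_variance < 0:
            raise ValueError("variance components must be nonnegative")
        if self.target_h2 is not None and not 0.0 <= self.target_h2 <= 1.0:
            raise ValueError(f"target_h2 must lie in [0, 1], got {self.target_h2}")

    def genetic_variance(self, qtl_allele_freqs=None) -> float:
        v = self.polygenic_variance
        if self.qtl is not None:
            if qtl_allele_freqs is None:
                qtl_allele_freqs = [0.5, 0.5]
            v += self.qtl.variance(np.asarray(qtl_allele_freqs))
        return v

    def h2(self, qtl_allele_freqs=None) -> float:
        vg = self.genetic_variance(qtl_allele_freqs)
        vp = vg + self.environmental_variance
        return vg / vp if vp > 0 else 0.0

    def check_h2(self, qtl_allele_freqs=None, tol: float = 1e-9) -> None:
        if self.target_h2 is None:
            return
        got = self.h2(qtl_allele_freqs)
        if abs(got - self.target_h2) > tol:
            raise ValueError(
                f"target_h2={self.target_h2} inconsistent with components (h2={got})"
            )

    @classmethod
    def from_h2(
        cls,
        h2: float,
        total_variance: float = 1.0,
        qtl_fraction: float = 0.0,
        qtl_chromosome: int = 2,
        qtl_position_cM: float = 60.0,
        qtl_allele_freq: float = 0.5,
    ) -> "TraitModel":
        """Build a model with a requested heritability.

        ``qtl_fraction`` is the share of the genetic variance carried by a
        single biallelic QTL (additive allele effect solved from
        ``2 p (1-p) a^2 = qtl_variance``); the rest is polygenic.
        """
        if not 0.0 <= h2 <= 1.0:
            raise ValueError(f"h2 must lie in [0, 1], got {h2}")
        if not 0.0 <= qtl_fraction <= 1.0:
            raise ValueError("qtl_fraction must lie in [0, 1]")
        vg = h2 * total_variance
        ve = (1.0 - h2) * total_variance
        v_qtl = qtl_fraction * vg
        qtl = None
        if v_qtl > 0:
            p = qtl_allele_freq
            a = math.sqrt(v_qtl / (2.0 * p * (1.0 - p)))
            qtl = QTL(qtl_chromosome, qtl_position_cM, {1: 0.0, 2: a})
        return cls(
            polygenic_variance=vg - v_qtl,
            environmental_variance=ve,
            qtl=qtl,
            target_h2=h2,
        )


def simulate_trait(
    ped: Pedigree,
    geno: GenotypeMatrix | None,
    model: TraitModel,
    seed: int = 0,
    gmap: GeneticMap | None = None,
) -> pd.Series:
    """Simulate the latent trait P = G + E over a pedigree.

    The genetic value G is the QTL genotype effect (read off the gene-dropped
    genotypes at the marker nearest the QTL) plus a polygenic value: founders
    are sampled N(0, Vg_poly) and non-founders are midparent plus a Mendelian
    segregation deviate N(0, Vg_poly / 2). E is independent N(0, Ve).

    Returns a Series indexed by individual id.
    """
    model.check_h2()
    if model.qtl is not None:
        if geno is None or gmap is None:
            raise ValueError("a QTL model needs genotypes and a map")
        marker = gmap.nearest_marker(model.qtl.chromosome, model.qtl.position_cM)
        pos = gmap.positions(model.qtl.chromosome)
        if not pos.min() <= model.qtl.position_cM <= pos.max():
            raise ValueError(
                f"QTL position {model.qtl.position_cM} cM outside map range "
                f"[{pos.min()}, {pos.max()}] on chromosome {model.qtl.chromosome}"
            )
    rng = np.random.default_rng(seed)
    vg = model.polygenic_variance
    ve = model.environmental_variance

    poly: dict[str, float] = {}
    for ind in ped.topological():
        if ind.is_founder:
            poly[ind.id] = rng.normal(0.0, math.sqrt(vg)) if vg > 0 else 0.0
        else:
            mid = 0.5 * (poly[ind.father_id] + poly[ind.mother_id])
            seg = rng.normal(0.0, math.sqrt(vg / 2.0)) if vg > 0 else 0.0
            poly[ind.id] = mid + seg

    values = {}
    for ind in ped.individuals:
        g = poly[ind.id]
        if model.qtl is not None:
            a1, a2 = geno.genotype(ind.id, marker)
            g += model.qtl.allele_effects.get(a1, 0.0)
            g += model.qtl.allele_effects.get(a2, 0.0)
        e = rng.normal(0.0, math.sqrt(ve)) if ve > 0 else 0.0
        values[ind.id] = g + e
    return pd.Series(values, name="trait")


# ---------------------------------------------------------------------------
# Assay design and plates
# ---------------------------------------------------------------------------


@dataclass
class DrugParams:
    """Population dose-response parameters for one drug.

    ``dm`` is the population median-effect dose (µM), ``m`` the sigmoidicity;
    ``cv`` is the between-line lognormal coefficient of variation applied to
    ``dm`` (cell lines differ in potency, not curve shape, by default).
    """

    dm: float
    m: float
    cv: float = 0.0

    def __post_init__(self):
        if self.dm <= 0 or self.m <= 0 or self.cv < 0:
            raise ValueError("dm and m must be positive, cv nonnegative")


@dataclass
class ArtifactSpec:
    """Plate artifacts injected by the generator for the QC pipeline to find."""

    deviant_rate: float = 0.0
    dead_plate_rate: float = 0.0
    noise_sd: float = 0.0
    deviant_multiplier: float = 5.0
    dead_rfu_max: float = 1500.0

    def __post_init__(self):
        for r in (self.deviant_rate, self.dead_plate_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class AssayDesign:
    """Dose grids and plate layout for one drug-pair panel.

    ``doses`` maps drug id -> strictly positive dose grid (µM); combination
    pairs default to the fixed-ratio pairing of the two grids (dose i of
    drug 1 with dose i of drug 2). One cell line per plate; each plate holds
    both monotherapy grids, the combination grid, and control wells, each
    condition in quadruplicate, and every line is run on ``n_runs`` plates.
    """

    doses: dict[str, np.ndarray]
    pair: tuple[str, str]
    combination_pairs: list[tuple[float, float]] = field(default_factory=list)
    n_quadruplicate: int = 4
    n_runs: int = 2
    plate_shape: tuple[int, int] = (16, 24)
    n_vehicle: int = 16
    n_negative: int = 16

    def __post_init__(self):
        self.doses = {d: np.asarray(v, dtype=float) for d, v in self.doses.items()}
        for d, v in self.doses.items():
            if (v <= 0).any():
                raise ValueError(f"doses for {d} must be strictly positive")
        d1, d2 = self.pair
        if d1 not in self.doses or d2 not in self.doses:
            raise ValueError("pair drugs must have dose grids")
        if not self.combination_pairs:
            g1, g2 = self.doses[d1], self.doses[d2]
            if len(g1) != len(g2):
                raise ValueError("fixed-ratio pairing needs equal grid lengths")
            self.combination_pairs = list(zip(g1.tolist(), g2.tolist()))
        for a, b in self.combination_pairs:
            if a <= 0 or b <= 0:
                raise ValueError("combination doses must be strictly positive")
        n_assay = (
            sum(len(v) for v in self.doses.values()) + len(self.combination_pairs)
        ) * self.n_quadruplicate
        if n_assay + self.n_vehicle + self.n_negative > np.prod(self.plate_shape):
            raise ValueError("design does not fit on the plate")

    @property
    def n_doses(self) -> int:
        return len(next(iter(self.doses.values())))

    @classmethod
    def default(
        cls,
        drug1: str = "drugA",
        drug2: str = "drugB",
        dm1: float = 4.0,
        dm2: float = 1.0,
        n_doses: int = 6,
    ) -> "AssayDesign":
        """Six-dose two-fold grids bracketing each drug's population Dm.

        The grid spans Dm/8 to 4 Dm (for six doses): cytotoxicity screens
        place more doses below the median-effect dose so the combination
        wells, which respond more strongly than either monotherapy, stay
        inside the assay's dynamic range.
        """
        mult = 2.0 ** (np.arange(n_doses) - (n_doses - n_doses // 2))
        return cls(
            doses={drug1: dm1 * mult, drug2: dm2 * mult},
            pair=(drug1, drug2),
        )


def median_effect_viability(dose, dm: float, m: float):
    """Fraction of cells unaffected at a dose under the median-effect law."""
    return 1.0 / (1.0 + (np.asarray(dose, dtype=float) / dm) ** m)


def latent_to_ci(
    latent, ci_range: tuple[float, float] = (0.3, 2.0)
) -> np.ndarray:
    """Map the latent trait to a true combination index.

    ``exp(latent)`` clipped into ``ci_range``: CI stays positive, is
    log-scale heritable, and latent 0 maps to additivity (CI = 1).
    """
    lo, hi = ci_range
    if not 0 < lo <= hi:
        raise ValueError("ci_range must satisfy 0 < lo <= hi")
    return np.clip(np.exp(np.asarray(latent, dtype=float)), lo, hi)


def solve_combination_fa(
    d1: float, d2: float, dm1: float, m1: float, dm2: float, m2: float, ci: float
) -> float:
    """Fraction affected at which a dose pair attains a target CI.

    Solves ``d1/E1(Fa) + d2/E2(Fa) = ci`` with ``E_i = Dm_i (Fa/Fu)^(1/m_i)``;
    the left side is strictly decreasing in Fa, so the root is unique.
    """
    if ci <= 0:
        raise ValueError("target CI must be positive")

    def g(logit_fa: float) -> float:
        r = math.exp(logit_fa)  # Fa / Fu
        return d1 / (dm1 * r ** (1.0 / m1)) + d2 / (dm2 * r ** (1.0 / m2)) - ci

    lo, hi = -60.0, 60.0
    return 1.0 / (1.0 + math.exp(-brentq(g, lo, hi, xtol=1e-13)))


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated plates."""

    line_params: pd.DataFrame  # cell_line, drug, dm, m
    true_ci: pd.DataFrame  # cell_line, drug1, drug2, dose1, dose2, ci_true
    latent: pd.Series  # latent trait per line
    deviant_wells: pd.DataFrame  # plate_id, row, col
    dead_plates: list[str]


PLATE_COLUMNS = [
    "plate_id",
    "cell_line",
    "run",
    "row",
    "col",
    "role",
    "drug1",
    "dose1",
    "drug2",
    "dose2",
    "rfu",
]


def simulate_plates(
    cell_lines: list[str] | Pedigree,
    latent: pd.Series,
    design: AssayDesign,
    drug_params: dict[str, DrugParams],
    artifact_spec: ArtifactSpec | None = None,
    seed: int = 0,
    vehicle_level: float = 10000.0,
    negative_level: float = 500.0,
    ci_range: tuple[float, float] = (0.3, 2.0),
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate raw RFU plates for every cell line in a panel.

    Per line and drug, the true curve is the median-effect law with a
    line-specific ``Dm`` (lognormal around the population value with the
    drug's between-line CV). Combination wells are placed on the response
    surface where the line's true CI — ``latent_to_ci`` of its latent trait
    — is attained at each designed dose pair. RFU is an affine map of
    viability between the negative- and vehicle-control levels plus
    Gaussian noise; deviant wells are multiplied by a large factor and dead
    plates redrawn uniformly below the death threshold.

    Returns the long-format well table and a :class:`SimTruth` bundle.
    """
    if isinstance(cell_lines, Pedigree):
        cell_lines = cell_lines.ids
    art = artifact_spec or ArtifactSpec()
    for d in design.doses:
        if d not in drug_params:
            raise ValueError(f"missing drug parameters for {d}")
    if vehicle_level <= negative_level:
        raise ValueError("vehicle_level must exceed negative_level")
    rng = np.random.default_rng(seed)
    drug1, drug2 = design.pair

    # per-line true curve parameters
    params_rows = []
    line_dm: dict[tuple[str, str], float] = {}
    line_m: dict[tuple[str, str], float] = {}
    for line in cell_lines:
        for d in (drug1, drug2):
            p = drug_params[d]
            if p.cv > 0:
                sigma = math.sqrt(math.log(1.0 + p.cv**2))
                dm = p.dm * rng.lognormal(-0.5 * sigma**2, sigma)
            else:
                dm = p.dm
            line_dm[(line, d)] = dm
            line_m[(line, d)] = p.m
            params_rows.append((line, d, dm, p.m))

    ci_by_line = pd.Series(
        latent_to_ci(latent.reindex(cell_lines).to_numpy(), ci_range),
        index=cell_lines,
    )

    truth_ci_rows = []
    fa_true: dict[tuple[str, float, float], float] = {}
    for line in cell_lines:
        ci = float(ci_by_line[line])
        for d1, d2 in design.combination_pairs:
            fa = solve_combination_fa(
                d1,
                d2,
                line_dm[(line, drug1)],
                line_m[(line, drug1)],
                line_dm[(line, drug2)],
                line_m[(line, drug2)],
                ci,
            )
            fa_true[(line, d1, d2)] = fa
            truth_ci_rows.append((line, drug1, drug2, d1, d2, ci))

    span = vehicle_level - negative_level
    rows: list[tuple] = []
    deviant_rows: list[tuple] = []
    dead_plates: list[str] = []
    n_rows_plate, n_cols_plate = design.plate_shape

    for line in cell_lines:
        for run in range(1, design.n_runs + 1):
            plate_id = f"{line}_r{run}"
            # enumerate wells row-major: mono grids, combos, controls
            wells: list[tuple[str, str | None, float | None, str | None, float | None, float]] = []
            for d in (drug1, drug2):
                dm, mm = line_dm[(line, d)], line_m[(line, d)]
                for dose in design.doses[d]:
                    v = float(median_effect_viability(dose, dm, mm))
                    for _ in range(design.n_quadruplicate):
                        wells.append(("single_drug", d, float(dose), None, None, v))
            for d1, d2 in design.combination_pairs:
                v = 1.0 - fa_true[(line, d1, d2)]
                for _ in range(design.n_quadruplicate):
                    wells.append(("combination", drug1, d1, drug2, d2, v))
            for _ in range(design.n_vehicle):
                wells.append(("vehicle_control", None, None, None, None, 1.0))
            for _ in range(design.n_negative):
                wells.append(("negative_control", None, None, None, None, 0.0))

            dead = rng.random() < art.dead_plate_rate
            if dead:
                dead_plates.append(plate_id)
            for w, (role, dr1, do1, dr2, do2, viab) in enumerate(wells):
                r, c = divmod(w, n_cols_plate)
                if r >= n_rows_plate:
                    raise ValueError("plate overflow")  # guarded in AssayDesign
                rfu = negative_level + viab * span
                if art.noise_sd > 0:
                    rfu += rng.normal(0.0, art.noise_sd)
                rfu = max(rfu, 0.0)
                if dead:
                    rfu = rng.uniform(0.0, art.dead_rfu_max)
                elif art.deviant_rate > 0 and rng.random() < art.deviant_rate:
                    rfu *= art.deviant_multiplier
                    deviant_rows.append((plate_id, r, c))
                rows.append(
                    (plate_id, line, run, r, c, role, dr1, do1, dr2, do2, rfu)
                )

    plates = pd.DataFrame(rows, columns=PLATE_COLUMNS)
    truth = SimTruth(
        line_params=pd.DataFrame(
            params_rows, columns=["cell_line", "drug", "dm", "m"]
        ),
        true_ci=pd.DataFrame(
            truth_ci_rows,
            columns=["cell_line", "drug1", "drug2", "dose1", "dose2", "ci_true"],
        ),
        latent=latent.reindex(cell_lines),
        deviant_wells=pd.DataFrame(deviant_rows, columns=["plate_id", "row", "col"]),
        dead_plates=dead_plates,
    )
    return plates, truth
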