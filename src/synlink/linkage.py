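"""Quantitative-trait linkage scan from sib-pair IBD sharing.

Loci physically close on a chromosome stay linked through meiosis, so a
locus influencing a trait makes sibs who share more alleles identical by
descent (IBD) at that locus more phenotypically similar. The scan has two
parts:

* **Multipoint IBD.** For every full-sib pair, a hidden chain over the four
  meiosis indicators (which parental haplotype each sib received from each
  parent: 2^4 = 16 inheritance states) is evaluated by forward–backward
  over the markers of each chromosome, with Haldane transition
  probabilities between adjacent positions. Collapsing states gives the
  posterior over IBD counts {0, 1, 2} and the expected sharing
  π̂ = (P1 + 2 P2) / 2 on a cM grid. Uninformative data leave the prior
  (¼, ½, ¼), π̂ = 0.5.

* **Haseman–Elston regression.** At each grid position the squared sib-pair
  trait difference is regressed on π̂; linkage pushes the slope negative,
  and the one-sided evidence is reported as LOD = t² / (2 ln 10) when the
  slope is negative, else 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree
from .simulate import GeneticMap, GenotypeMatrix, haldane_theta

__all__ = [
    "IBDProfile",
    "HEResult",
    "LinkageScan",
    "sibpair_ibd",
    "he_regression",
    "genome_scan",
]

logger = logging.getLogger(__name__)

# state index = f1*8 + f2*4 + m1*2 + m2; bit = which parental haplotype the
# sib received (f* paternal meioses, m* maternal meioses)
_STATE_BITS = np.array(
    [[(s >> 3) & 1, (s >> 2) & 1, (s >> 1) & 1, s & 1] for s in range(16)]
)
_STATE_IBD = (_STATE_BITS[:, 0] == _STATE_BITS[:, 1]).astype(int) + (
    _STATE_BITS[:, 2] == _STATE_BITS[:, 3]
).astype(int)
_IBD_MASKS = [(_STATE_IBD == k) for k in range(3)]


@dataclass
class IBDProfile:
    """Posterior IBD sharing for every sib pair along the genome.

    ``posterior`` has shape (n_pairs, n_positions, 3) over IBD states
    {0, 1, 2}; ``pihat`` is the expected proportion of alleles shared IBD.
    ``positions`` marks which rows are scan-grid points vs markers.
    """

    pairs: list[tuple[str, str, str]]
    positions: pd.DataFrame  # chromosome, position_cM, is_grid
    posterior: np.ndarray
    pihat: np.ndarray
    n_markers_dropped: int = 0

    @property
    def grid_mask(self) -> np.ndarray:
        return self.positions["is_grid"].to_numpy()

    def grid_pihat(self) -> np.ndarray:
        return self.pihat[:, self.grid_mask]


def _pair_marker_emission_missing_parent(
    f_pair: np.ndarray,
    m_pair: np.ndarray,
    s1: np.ndarray,
    s2: np.ndarray,
    freq: np.ndarray,
) -> np.ndarray:
    """Emission over 16 states summing over any missing parental genotypes.

    Parental alleles are ordered pairs with 0 = missing; missing parents are
    integrated over Hardy–Weinberg ordered genotypes at the marker's allele
    frequencies. Sib genotypes are unordered; a missing sib contributes 1.
    """
    alleles = np.arange(1, freq.size + 1)

    def parent_options(pair):
        if pair[0] != 0 and pair[1] != 0:
            return [((int(pair[0]), int(pair[1])), 1.0)]
        opts = []
        for a in alleles:
            for b in alleles:
                opts.append(((int(a), int(b)), float(freq[a - 1] * freq[b - 1])))
        return opts

    def sib_match(obs, pat_allele, mat_allele):
        if obs[0] == 0 or obs[1] == 0:
            return 1.0
        o = (int(obs[0]), int(obs[1]))
        return 1.0 if o in ((pat_allele, mat_allele), (mat_allele, pat_allele)) else 0.0

    e = np.zeros(16)
    for gf, pf in parent_options(f_pair):
        for gm, pm in parent_options(m_pair):
            w = pf * pm
            for s in range(16):
                f1, f2, m1, m2 = _STATE_BITS[s]
                e[s] += (
                    w
                    * sib_match(s1, gf[f1], gm[m1])
                    * sib_match(s2, gf[f2], gm[m2])
                )
    return e


def _emissions(
    ped: Pedigree,
    geno: GenotypeMatrix,
    pairs: list[tuple[str, str, str]],
    freqs: list[np.ndarray],
) -> tuple[np.ndarray, int]:
    """Emission probabilities (n_pairs, n_markers, 16).

    Vectorized for the complete-parent case; entries with a missing parental
    genotype fall back to an exact sum over Hardy–Weinberg genotypes.
    Markers that are Mendelian-inconsistent for a pair are dropped (emission
    set uninformative) and counted.
    """
    n_pairs = len(pairs)
    n_markers = len(geno.marker_ids)
    f_rows, m_rows, s1_rows, s2_rows = [], [], [], []
    for id1, id2, _fam in pairs:
        ind = ped[id1]
        f_rows.append(geno.row(ind.father_id))
        m_rows.append(geno.row(ind.mother_id))
        s1_rows.append(geno.row(id1))
        s2_rows.append(geno.row(id2))
    F = geno.alleles[f_rows]  # (n_pairs, n_markers, 2)
    M = geno.alleles[m_rows]
    S1 = geno.alleles[s1_rows]
    S2 = geno.alleles[s2_rows]

    s1_missing = (S1 == 0).any(axis=2)
    s2_missing = (S2 == 0).any(axis=2)
    parent_missing = (F == 0).any(axis=2) | (M == 0).any(axis=2)

    E = np.empty((n_pairs, n_markers, 16))
    for s in range(16):
        f1, f2, m1, m2 = _STATE_BITS[s]
        t1p, t1m = F[:, :, f1], M[:, :, m1]
        t2p, t2m = F[:, :, f2], M[:, :, m2]
        match1 = ((t1p == S1[:, :, 0]) & (t1m == S1[:, :, 1])) | (
            (t1p == S1[:, :, 1]) & (t1m == S1[:, :, 0])
        )
        match2 = ((t2p == S2[:, :, 0]) & (t2m == S2[:, :, 1])) | (
            (t2p == S2[:, :, 1]) & (t2m == S2[:, :, 0])
        )
        E[:, :, s] = np.where(s1_missing, 1.0, match1) * np.where(
            s2_missing, 1.0, match2
        )

    if parent_missing.any():
        for p, j in zip(*np.nonzero(parent_missing)):
            E[p, j] = _pair_marker_emission_missing_parent(
                F[p, j], M[p, j], S1[p, j], S2[p, j], freqs[j]
            )

    inconsistent = E.sum(axis=2) == 0
    n_dropped = int(inconsistent.sum())
    if n_dropped:
        logger.warning(
            "dropping %d Mendelian-inconsistent pair-marker observations",
            n_dropped,
        )
        E[inconsistent] = 1.0
    return E, n_dropped


def _transition_apply(f: np.ndarray, theta: float) -> np.ndarray:
    """One Haldane step of the 16-state chain: each of the four meiosis bits
    flips independently with probability theta."""
    if theta <= 0:
        return f
    g = f.reshape(f.shape[0], 2, 2, 2, 2)
    for ax in range(1, 5):
        g = (1.0 - theta) * g + theta * np.flip(g, axis=ax)
    return g.reshape(f.shape[0], 16)


def _chromosome_positions(
    gmap: GeneticMap, chrom: int, grid_step_cM: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merged marker + grid positions for one chromosome.

    Returns (positions, marker_index_or_-1, is_grid); the scan grid is the
    half-open range [first marker, last marker) in steps of ``grid_step_cM``.
    """
    marker_idx = gmap.chromosome_indices(chrom)
    mpos = gmap.df["position_cM"].to_numpy()[marker_idx]
    lo, hi = mpos.min(), mpos.max()
    if grid_step_cM <= 0:
        raise ValueError("grid_step_cM must be positive")
    grid = np.arange(lo, hi, grid_step_cM) if hi > lo else np.array([lo])
    events = [(p, int(mi), False) for p, mi in zip(mpos, marker_idx)]
    events += [(p, -1, True) for p in grid]
    events.sort(key=lambda e: (e[0], e[2]))  # markers first at equal positions
    pos = np.array([e[0] for e in events])
    midx = np.array([e[1] for e in events], dtype=int)
    isgrid = np.array([e[2] for e in events], dtype=bool)
    return pos, midx, isgrid


def sibpair_ibd(
    ped: Pedigree,
    geno: GenotypeMatrix,
    gmap: GeneticMap,
    grid_step_cM: float = 1.0,
    allele_freqs=None,
    pairs: list[tuple[str, str, str]] | None = None,
) -> IBDProfile:
    """Multipoint sib-pair IBD posteriors along every chromosome.

    Forward–backward over the 16 inheritance-vector states with Haldane
    transitions; emissions use parental genotypes when present and
    integrate over Hardy–Weinberg genotypes (at ``allele_freqs``, default
    uniform biallelic) when a parent is untyped.
    """
    if pairs is None:
        pairs = ped.sib_pairs()
    if not pairs:
        raise ValueError("pedigree contains no full-sib pairs")
    from .simulate import _normalize_freqs

    freqs = _normalize_freqs(allele_freqs, len(gmap))
    E, n_dropped = _emissions(ped, geno, pairs, freqs)
    n_pairs = len(pairs)

    pos_frames = []
    post_chunks = []
    for chrom in gmap.chromosomes:
        pos, midx, isgrid = _chromosome_positions(gmap, chrom, grid_step_cM)
        n_pos = pos.size
        thetas = np.asarray(haldane_theta(np.diff(pos)), dtype=float)

        def emit(t: int) -> np.ndarray:
            if midx[t] >= 0:
                return E[:, midx[t], :]
            return np.ones((n_pairs, 16))

        collapse = np.zeros((16, 3))
        collapse[np.arange(16), _STATE_IBD] = 1.0
        # forward
        alpha = np.empty((n_pos, n_pairs, 16))
        a = np.full((n_pairs, 16), 1.0 / 16.0) * emit(0)
        a /= a.sum(axis=1, keepdims=True)
        alpha[0] = a
        for t in range(1, n_pos):
            a = _transition_apply(a, thetas[t - 1]) * emit(t)
            a /= a.sum(axis=1, keepdims=True)
            alpha[t] = a
        # backward, collapsing to IBD counts on the fly
        b = np.ones((n_pairs, 16))
        post3 = np.empty((n_pos, n_pairs, 3))
        p = alpha[n_pos - 1] * b
        post3[n_pos - 1] = (p / p.sum(axis=1, keepdims=True)) @ collapse
        for t in range(n_pos - 2, -1, -1):
            b = _transition_apply(b * emit(t + 1), thetas[t])
            b /= b.sum(axis=1, keepdims=True)
            p = alpha[t] * b
            post3[t] = (p / p.sum(axis=1, keepdims=True)) @ collapse

        post_chunks.append(post3.transpose(1, 0, 2))
        pos_frames.append(
            pd.DataFrame(
                {"chromosome": chrom, "position_cM": pos, "is_grid": isgrid}
            )
        )

    posterior = np.concatenate(post_chunks, axis=1)
    pihat = 0.5 * posterior[:, :, 1] + posterior[:, :, 2]
    return IBDProfile(
        pairs=pairs,
        positions=pd.concat(pos_frames, ignore_index=True),
        posterior=posterior,
        pihat=pihat,
        n_markers_dropped=n_dropped,
    )


@dataclass
class HEResult:
    """Haseman–Elston regression at one genome position."""

    slope: float
    t_stat: float
    lod: float
    n_pairs: int


def _he_stats(
    y: np.ndarray, pihat: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized HE regression of y on each column of pihat.

    Returns (slope, t, lod); columns with no IBD variation get NaN.
    """
    n = y.size
    x = pihat - pihat.mean(axis=0)
    yc = y - y.mean()
    sxx = (x**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = (x * yc[:, None]).sum(axis=0) / sxx
        sse = (yc**2).sum() - slope**2 * sxx
        se = np.sqrt(np.maximum(sse, 0.0) / (n - 2) / sxx)
        t = slope / se
    bad = sxx <= 1e-10  # pihat lives in [0, 1]; this is numerically zero
    slope[bad] = np.nan
    t[bad] = np.nan
    lod = np.where((slope < 0) & np.isfinite(t), t**2 / (2.0 * math.log(10.0)), 0.0)
    lod[~np.isfinite(t)] = np.nan
    return slope, t, lod


def he_regression(
    trait: pd.Series,
    ibd: IBDProfile,
    position_index: int,
    min_pairs: int = 20,
) -> HEResult | None:
    """HE regression of squared sib-pair trait differences on π̂ at one position.

    Returns None (logged) when fewer than ``min_pairs`` informative pairs
    exist or π̂ carries no variation at the position.
    """
    y, keep = _pair_sq_diffs(trait, ibd.pairs)
    if y.size < min_pairs:
        logger.warning("only %d informative sib pairs; position skipped", y.size)
        return None
    slope, t, lod = _he_stats(y, ibd.pihat[keep][:, [position_index]])
    if not np.isfinite(t[0]):
        logger.warning("no IBD variation at position %d; skipped", position_index)
        return None
    return HEResult(
        slope=float(slope[0]), t_stat=float(t[0]), lod=float(lod[0]), n_pairs=y.size
    )


def _pair_sq_diffs(
    trait: pd.Series, pairs: list[tuple[str, str, str]]
) -> tuple[np.ndarray, np.ndarray]:
    y = []
    keep = np.zeros(len(pairs), dtype=bool)
    for k, (i, j, _fam) in enumerate(pairs):
        ti = trait.get(i)
        tj = trait.get(j)
        if ti is None or tj is None or not (np.isfinite(ti) and np.isfinite(tj)):
            continue
        keep[k] = True
        y.append((float(ti) - float(tj)) ** 2)
    return np.asarray(y), keep


@dataclass
class LinkageScan:
    """Genome-wide HE scan: per-position LOD table and reported peaks."""

    table: pd.DataFrame  # chromosome, position_cM, n_pairs, slope, t, lod
    peaks: pd.DataFrame  # chromosome, peak_cM, max_lod, support_lo_cM, support_hi_cM
    lod_threshold: float

    @property
    def max_lod(self) -> float:
        return float(np.nanmax(self.table["lod"].to_numpy()))

    def top_position(self) -> tuple[int, float]:
        i = int(self.table["lod"].idxmax())
        return int(self.table.loc[i, "chromosome"]), float(
            self.table.loc[i, "position_cM"]
        )


def genome_scan(
    trait: pd.Series,
    ped: Pedigree,
    geno: GenotypeMatrix,
    gmap: GeneticMap,
    grid_step_cM: float = 1.0,
    lod_threshold: float = 3.0,
    min_pairs: int = 20,
    allele_freqs=None,
    ibd: IBDProfile | None = None,
) -> LinkageScan:
    """Full-genome Haseman–Elston scan on the cM grid.

    Reports the LOD track, per-chromosome peaks above ``lod_threshold`` and
    the 1-LOD support interval around each peak. A precomputed
    :class:`IBDProfile` can be passed to amortize the HMM across traits.
    """
    if ibd is None:
        ibd = sibpair_ibd(
            ped, geno, gmap, grid_step_cM=grid_step_cM, allele_freqs=allele_freqs
        )
    grid = ibd.grid_mask
    if not grid.any():
        raise ValueError("empty scan grid")
    y, keep = _pair_sq_diffs(trait, ibd.pairs)
    if y.size < min_pairs:
        raise ValueError(
            f"only {y.size} informative sib pairs (need >= {min_pairs})"
        )
    slope, t, lod = _he_stats(y, ibd.pihat[keep][:, grid])
    table = ibd.positions.loc[grid, ["chromosome", "position_cM"]].reset_index(
        drop=True
    )
    table["n_pairs"] = y.size
    table["slope"] = slope
    table["t"] = t
    table["lod"] = lod

    peak_rows = []
    for chrom, sub in table.groupby("chromosome"):
        lods = sub["lod"].to_numpy()
        pos = sub["position_cM"].to_numpy()
        if not np.isfinite(lods).any():
            continue
        imax = int(np.nanargmax(lods))
        if lods[imax] < lod_threshold:
            continue
        support = lods >= lods[imax] - 1.0
        # contiguous run containing the peak
        lo_i = imax
        while lo_i > 0 and support[lo_i - 1]:
            lo_i -= 1
        hi_i = imax
        while hi_i < lods.size - 1 and support[hi_i + 1]:
            hi_i += 1
        peak_rows.append(
            (int(chrom), float(pos[imax]), float(lods[imax]), float(pos[lo_i]),
             float(pos[hi_i]))
        )
    peaks = pd.DataFrame(
        peak_rows,
        columns=["chromosome", "peak_cM", "max_lod", "support_lo_cM", "support_hi_cM"],
    )
    return LinkageScan(table=table, peaks=peaks, lod_threshold=lod_threshold)
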