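"""End-to-end orchestration: simulate → QC → synergy → heritability → linkage.

Library-level driver behind the command-line interface; every stage reads
and writes the plain-text formats in :mod:`synlink.io`, so stages can also
be run individually on externally produced files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, linkage, quantgen, synergy
from .config import RunConfig
from .pedigree import simulate_pedigrees
from .qc import QCConfig, run_qc
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

logger = logging.getLogger(__name__)


def build_design(cfg: RunConfig) -> AssayDesign:
    design = AssayDesign.default(
        drug1=cfg.drug1, drug2=cfg.drug2, dm1=cfg.dm1, dm2=cfg.dm2,
        n_doses=cfg.n_doses,
    )
    design.n_quadruplicate = cfg.n_quadruplicate
    design.n_runs = cfg.n_runs
    return design


def simulate_all(cfg: RunConfig, out_dir: Path) -> dict[str, Path]:
    """Generate pedigree, genotypes, latent trait and plates; write all files
    plus ground truth. Deterministic per config seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    seeds = rng.integers(0, 2**31 - 1, size=4)

    ped = simulate_pedigrees(
        cfg.n_families, (cfg.children_low, cfg.children_high), seed=int(seeds[0])
    )
    gmap = GeneticMap.uniform(
        cfg.n_chromosomes, cfg.markers_per_chromosome, cfg.marker_spacing_cM
    )
    geno = simulate_genotypes(ped, gmap, seed=int(seeds[1]))
    model = TraitModel.from_h2(
        cfg.target_h2,
        qtl_fraction=cfg.qtl_fraction,
        qtl_chromosome=cfg.qtl_chromosome,
        qtl_position_cM=cfg.qtl_position_cM,
    )
    latent = simulate_trait(ped, geno, model, seed=int(seeds[2]), gmap=gmap)

    design = build_design(cfg)
    drug_params = {
        cfg.drug1: DrugParams(dm=cfg.dm1, m=cfg.m1, cv=cfg.dm_cv),
        cfg.drug2: DrugParams(dm=cfg.dm2, m=cfg.m2, cv=cfg.dm_cv),
    }
    artifacts = ArtifactSpec(
        deviant_rate=cfg.deviant_rate,
        dead_plate_rate=cfg.dead_plate_rate,
        noise_sd=cfg.noise_sd,
    )
    plates, truth = simulate_plates(
        ped,
        latent,
        design,
        drug_params,
        artifacts,
        seed=int(seeds[3]),
        vehicle_level=cfg.vehicle_level,
        negative_level=cfg.negative_level,
        ci_range=(cfg.ci_range_low, cfg.ci_range_high),
    )

    paths = {
        "ped": out_dir / "panel.ped",
        "map": out_dir / "panel.map",
        "plates": out_dir / "plates.csv",
        "latent": out_dir / "truth_latent.tsv",
        "true_ci": out_dir / "truth_ci.tsv",
        "deviants": out_dir / "truth_deviant_wells.tsv",
        "dead": out_dir / "truth_dead_plates.tsv",
        "config": out_dir / "resolved_config.yaml",
    }
    io.write_ped(paths["ped"], ped, geno=geno)
    io.write_map(paths["map"], gmap)
    io.write_plates(paths["plates"], plates)
    io.write_tsv(
        paths["latent"],
        truth.latent.rename("latent").rename_axis("cell_line").reset_index(),
    )
    io.write_tsv(paths["true_ci"], truth.true_ci)
    io.write_tsv(paths["deviants"], truth.deviant_wells)
    io.write_tsv(
        paths["dead"], pd.DataFrame({"plate_id": truth.dead_plates})
    )
    cfg.to_yaml(paths["config"])
    return paths


def run_all(cfg: RunConfig, data_dir: Path, out_dir: Path) -> dict:
    """Run QC, synergy, per-dose heritability and the linkage scan on the
    files in ``data_dir``; write result TSVs and return a summary dict."""
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in ("panel.ped", "panel.map", "plates.csv"):
        if not (data_dir / name).exists():
            raise FileNotFoundError(f"missing input file: {data_dir / name}")

    ped, geno, _ = io.read_ped(data_dir / "panel.ped")
    gmap = io.read_map(data_dir / "panel.map")
    if geno is not None:
        geno = io.attach_marker_ids(geno, gmap)
    plates = io.read_plates(data_dir / "plates.csv")

    # --- QC ---------------------------------------------------------------
    qc_cfg = QCConfig(
        cv_threshold=cfg.cv_threshold,
        plate_rfu_threshold=cfg.plate_rfu_threshold,
        resid_threshold=cfg.resid_threshold,
        max_iter=cfg.max_iter,
        eps=cfg.eps,
    )
    series, report = run_qc(plates, qc_cfg)
    io.write_tsv(out_dir / "qc_plates.tsv", report.plates)
    io.write_tsv(out_dir / "qc_wells.tsv", report.wells)

    # --- synergy ----------------------------------------------------------
    pair = (cfg.drug1, cfg.drug2)
    lines = sorted({k[0] for k in series})
    ci_rows = []
    for line in lines:
        for res in synergy.ci_profile(series, line, pair):
            ci_rows.append(
                (
                    res.cell_line, res.drug1, res.drug2, res.d1, res.d2,
                    res.e1, res.e2, res.ci_raw, res.ci, res.label, res.reason,
                )
            )
    ci_table = pd.DataFrame(
        ci_rows,
        columns=[
            "cell_line", "drug1", "drug2", "dose1", "dose2",
            "e1", "e2", "ci_raw", "ci", "label", "reason",
        ],
    )
    io.write_tsv(out_dir / "combination_index.tsv", ci_table)

    # --- heritability per dose pair ---------------------------------------
    kin = quantgen.kinship_matrix(ped)
    traits = {}
    for (d1, d2), sub in ci_table.dropna(subset=["ci"]).groupby(
        ["dose1", "dose2"], sort=True
    ):
        traits[(float(d1), float(d2))] = sub.set_index("cell_line")["ci"].astype(float)
    herit_table, best_dose = quantgen.heritability_by_dose(
        traits, kin, seed=cfg.seed
    )
    herit_out = herit_table.copy()
    herit_out["dose"] = herit_out["dose"].astype(str)
    io.write_tsv(out_dir / "heritability.tsv", herit_out)

    # --- linkage on the max-heritability dose ------------------------------
    scan = linkage.genome_scan(
        traits[best_dose],
        ped,
        geno,
        gmap,
        grid_step_cM=cfg.grid_step_cM,
        lod_threshold=cfg.lod_threshold,
        min_pairs=cfg.min_sib_pairs,
    )
    io.write_tsv(out_dir / "linkage_scan.tsv", scan.table)
    io.write_tsv(out_dir / "linkage_peaks.tsv", scan.peaks)
    cfg.to_yaml(out_dir / "resolved_config.yaml")

    summary = {
        "n_plates": int(plates["plate_id"].nunique()),
        "n_plates_removed": report.n_plates_removed,
        "n_wells_replaced": int(len(report.wells)),
        "n_lines_analyzed": len(lines),
        "n_ci_values": int(ci_table["ci"].notna().sum()),
        "best_dose": str(best_dose),
        "max_lod": scan.max_lod,
        "n_peaks": int(len(scan.peaks)),
    }
    pd.DataFrame([summary]).to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    logger.info("run complete: %s", summary)
    return summary
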