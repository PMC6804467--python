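"""Readers and writers for the package's plain-text formats.

* PED: whitespace-delimited pedigree rows (family, id, father, mother, sex,
  phenotype placeholder), optionally followed by allele-pair genotype
  columns in map order; 0 codes a missing parent or allele.
* MAP: 4 columns (chromosome, marker id, position in cM, bp placeholder).
* Plates: long-format CSV, one well per row.
* Result tables: tab-separated with headers, floats at 6 significant digits.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import Individual, Pedigree
from .simulate import PLATE_COLUMNS, GeneticMap, GenotypeMatrix

__all__ = [
    "write_ped",
    "read_ped",
    "write_map",
    "read_map",
    "write_plates",
    "read_plates",
    "write_tsv",
]

FLOAT_FORMAT = "%.6g"


def write_ped(
    path,
    ped: Pedigree,
    geno: GenotypeMatrix | None = None,
    phenotype: pd.Series | None = None,
) -> None:
    """Write a PED file, optionally with genotype allele-pair columns."""
    lines = []
    for ind in ped.individuals:
        pheno = "-9"
        if phenotype is not None and ind.id in phenotype.index:
            v = phenotype[ind.id]
            if pd.notna(v):
                pheno = FLOAT_FORMAT % v
        fields = [
            ind.family_id,
            ind.id,
            ind.father_id or "0",
            ind.mother_id or "0",
            str(ind.sex),
            pheno,
        ]
        if geno is not None:
            row = geno.alleles[geno.row(ind.id)]
            fields.extend(str(int(a)) for a in row.reshape(-1))
        lines.append(" ".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ped(
    path, n_markers: int | None = None
) -> tuple[Pedigree, GenotypeMatrix | None, pd.Series]:
    """Read a PED file; returns (pedigree, genotypes or None, phenotype)."""
    inds = []
    geno_rows = []
    pheno = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        fam, iid, fid, mid, sex, ph = parts[:6]
        inds.append(
            Individual(
                id=iid,
                family_id=fam,
                father_id=None if fid == "0" else fid,
                mother_id=None if mid == "0" else mid,
                sex=int(sex),
            )
        )
        pheno[iid] = float(ph) if ph != "-9" else np.nan
        if len(parts) > 6:
            geno_rows.append([int(a) for a in parts[6:]])
    ped = Pedigree(inds)
    geno = None
    if geno_rows:
        arr = np.asarray(geno_rows, dtype=np.int16)
        if arr.shape[1] % 2:
            raise ValueError("odd number of allele columns in PED")
        nm = arr.shape[1] // 2
        if n_markers is not None and nm != n_markers:
            raise ValueError(f"PED has {nm} markers, expected {n_markers}")
        geno = GenotypeMatrix(
            ids=ped.ids,
            marker_ids=[f"M{i + 1}" for i in range(nm)],
            alleles=arr.reshape(len(inds), nm, 2),
        )
    return ped, geno, pd.Series(pheno, name="phenotype")


def write_map(path, gmap: GeneticMap) -> None:
    df = gmap.df.copy()
    df["bp"] = 0
    df.to_csv(path, sep=" ", header=False, index=False)


def read_map(path) -> GeneticMap:
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chromosome", "marker_id", "position_cM", "bp"],
    )
    return GeneticMap(df[["chromosome", "marker_id", "position_cM"]])


def write_plates(path, plates: pd.DataFrame) -> None:
    plates[PLATE_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def read_plates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns {sorted(missing)}")
    return df


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def attach_marker_ids(geno: GenotypeMatrix, gmap: GeneticMap) -> GenotypeMatrix:
    """Re-label a PED-loaded genotype matrix with the map's marker ids."""
    if len(gmap) != len(geno.marker_ids):
        raise ValueError("map and genotype marker counts differ")
    return GenotypeMatrix(
        ids=geno.ids, marker_ids=gmap.marker_ids, alleles=geno.alleles
    )
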