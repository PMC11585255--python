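"""Readers and writers for the pipeline's file formats.

Formats: plate CSV (per-well anisotropy or raw intensities), Ki table TSV,
tidy DE table TSV, GMT gene sets, FASTA sequence windows (via Biopython),
JASPAR-style motif matrices, BED-like motif hit TSV, and an importer for
Ki-table spreadsheets.  Writers emit exactly the dialects the readers
consume; plate tables round-trip bit-exactly through
``write_plate_csv``/``read_plate_csv``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .equilibria import anisotropy_from_intensities
from .fitting import TitrationCurve
from .motifs import ALPHABET, MotifMatrix
from .pathway_bias import DE_COLUMNS, PathwayDB

__all__ = [
    "read_plate_csv",
    "write_plate_csv",
    "plate_frame_to_curves",
    "read_ki_table",
    "write_ki_table",
    "read_de_table",
    "write_de_table",
    "read_gmt",
    "write_gmt",
    "read_fasta",
    "write_fasta",
    "read_jaspar_matrix",
    "write_motif_hits",
    "import_ki_workbook",
]

PLATE_COLUMNS = ["well", "competitor_nM", "technical_rep", "dilution_rep",
                 "ligand", "coregulator", "assembly"]


def read_plate_csv(path) -> pd.DataFrame:
    """Plate table with either an ``anisotropy`` column or raw intensities.

    Raw ``i_parallel``/``i_perpendicular`` columns are converted to
    anisotropy on read; the returned frame always carries ``anisotropy``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV {path} missing columns: {sorted(missing)}")
    if "anisotropy" not in df.columns:
        if not {"i_parallel", "i_perpendicular"} <= set(df.columns):
            raise ValueError(
                "plate CSV needs an 'anisotropy' column or both 'i_parallel' and 'i_perpendicular'"
            )
        df["anisotropy"] = anisotropy_from_intensities(
            df["i_parallel"].to_numpy(), df["i_perpendicular"].to_numpy()
        )
    return df


def write_plate_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def curve_to_plate_frame(curve: TitrationCurve) -> pd.DataFrame:
    md = curve.metadata
    return pd.DataFrame({
        "well": np.arange(curve.n_obs),
        "competitor_nM": curve.concentrations,
        "anisotropy": curve.responses,
        "technical_rep": curve.technical_rep if curve.technical_rep is not None else 1,
        "dilution_rep": curve.dilution_rep if curve.dilution_rep is not None else 1,
        "ligand": md.get("ligand", ""),
        "coregulator": md.get("coregulator", ""),
        "assembly": md.get("assembly", ""),
    })


def plate_frame_to_curves(df: pd.DataFrame) -> list[TitrationCurve]:
    """Split a plate table into one TitrationCurve per (ligand, coregulator, assembly)."""
    curves = []
    for (lig, coreg, asm), sub in df.groupby(["ligand", "coregulator", "assembly"], sort=True):
        curves.append(TitrationCurve(
            sub["competitor_nM"].to_numpy(),
            sub["anisotropy"].to_numpy(),
            sub["technical_rep"].to_numpy(),
            sub["dilution_rep"].to_numpy(),
            metadata={"ligand": lig, "coregulator": coreg, "assembly": asm},
        ))
    return curves


def read_ki_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"ligand", "coregulator", "assembly", "replicate", "ki_nM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ki table {path} missing columns: {sorted(missing)}")
    return df.rename(columns={"ki_nM": "ki"})


def write_ki_table(df: pd.DataFrame, path) -> None:
    out = df.rename(columns={"ki": "ki_nM"})
    out.to_csv(path, sep="\t", index=False)


def read_de_table(path) -> pd.DataFrame:
    """Tidy DE table TSV: gene_id, ligand, timepoint, log2fc, padj."""
    df = pd.read_csv(path, sep="\t")
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"DE table {path} missing columns: {sorted(missing)}")
    return df


def write_de_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> PathwayDB:
    """GMT: one pathway per line — id, description, then member gene ids."""
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line (need id, description, genes): {line[:80]!r}")
            pid, desc, genes = fields[0], fields[1], fields[2:]
            sets[pid] = set(g for g in genes if g)
            names[pid] = desc
    return PathwayDB(sets, names)


def write_gmt(db: PathwayDB, path) -> None:
    with open(path, "w") as fh:
        for pid, genes in sorted(db.items()):
            fh.write("\t".join([pid, db.display_name(pid), *sorted(genes)]) + "\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_jaspar_matrix(path, background=(0.25, 0.25, 0.25, 0.25),
                       pseudo: float = 0.5) -> MotifMatrix:
    """JASPAR-style matrix: optional ``>`` header, one ``A [ 1 2 ... ]`` row per base.

    Values may be counts or probabilities; counts (any row sum > 1 + 1e-6)
    get the pseudo-count, probabilities are used as supplied.
    """
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(">"):
                continue
            base = line[0].upper()
            if base not in ALPHABET:
                raise ValueError(f"unexpected matrix row: {line[:40]!r}")
            body = line[1:].replace("[", " ").replace("]", " ")
            rows[base] = [float(v) for v in body.split()]
    if set(rows) != set(ALPHABET):
        raise ValueError(f"matrix file must contain one row per base; got {sorted(rows)}")
    widths = {len(v) for v in rows.values()}
    if len(widths) != 1:
        raise ValueError("matrix rows have unequal lengths")
    mat = np.array([rows[b] for b in ALPHABET]).T  # (width, 4)
    if np.any(mat.sum(axis=1) > 1.0 + 1e-6):
        return MotifMatrix.from_counts(mat, background, pseudo=pseudo)
    return MotifMatrix.from_probabilities(mat, background)


def write_motif_hits(hits: pd.DataFrame, path) -> None:
    """BED-like TSV: sequence_id, start, end, strand, score (0-based half-open)."""
    hits.to_csv(path, sep="\t", index=False)


def import_ki_workbook(path, sheet_name=0) -> pd.DataFrame:
    """Import a Ki-table spreadsheet (ligand bias supplementary-data layout).

    Expects columns recognisable as ligand, coregulator, assembly, replicate
    and Ki; Ki columns labelled in µM are converted to nM.
    """
    df = pd.read_excel(path, sheet_name=sheet_name)
    df.columns = [str(c).strip() for c in df.columns]
    colmap = {}
    for col in df.columns:
        low = col.lower()
        if "ligand" in low:
            colmap[col] = "ligand"
        elif "coreg" in low or "coactivator" in low:
            colmap[col] = "coregulator"
        elif "assembly" in low or "complex" in low:
            colmap[col] = "assembly"
        elif "replicate" in low or low == "rep":
            colmap[col] = "replicate"
        elif low.startswith("ki") or low.startswith("k_i"):
            colmap[col] = "ki"
            scale = 1e3 if ("um" in low or "µm" in low or "(um)" in low) else 1.0
    df = df.rename(columns=colmap)
    required = {"ligand", "coregulator", "assembly", "replicate", "ki"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"workbook {path} missing recognisable columns: {sorted(missing)}")
    df = df[["ligand", "coregulator", "assembly", "replicate", "ki"]].dropna()
    df["ki"] = df["ki"].astype(float) * scale
    df["replicate"] = df["replicate"].astype(int)
    return df
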