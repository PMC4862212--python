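"""Readers and writers for the pipeline's text interchange formats.

FASTA for the protein database (via Biopython), tab-separated tables for
PSMs, DIGE spot volumes and design, and ionomics concentrations, JSON
for the synthetic ground truth, YAML for pipeline configuration.  All
tables are UTF-8 and tab-separated; multi-accession PSMs join
accessions with ``;``.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .digestion import STANDARD_RESIDUES
from .ionomics import ELEMENTS
from .spectral import PSM_COLUMNS
from .synthetic import Proteome, SimulationConfig, SyntheticTruth

VALID_CONDITIONS = ("control", "salt")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> Proteome:
    """Parse a protein FASTA; accession = first whitespace token of the header.

    Duplicate accessions and non-standard residues are rejected.
    """
    sequences: dict[str, str] = {}
    descriptions: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        acc = record.id
        if acc in sequences:
            raise ValueError(f"duplicate accession {acc!r} in {path}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for {acc!r} in {path}")
        bad = set(seq) - STANDARD_RESIDUES
        if bad:
            raise ValueError(f"non-standard residue(s) {sorted(bad)} in {acc!r}")
        sequences[acc] = seq
        descriptions[acc] = record.description.partition(" ")[2]
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return Proteome(sequences, descriptions)


def write_fasta(proteome: Proteome, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=acc, description=proteome.descriptions.get(acc, ""))
        for acc, seq in sorted(proteome.sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# delimited tables
# ---------------------------------------------------------------------------

def read_psm_table(path) -> pd.DataFrame:
    """One PSM per row; the accessions column is ``;``-joined."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing PSM column(s) {missing}")
    bad_cond = set(df["condition"]) - set(VALID_CONDITIONS)
    if bad_cond:
        raise ValueError(f"{path}: unknown condition label(s) {sorted(bad_cond)}")
    df["replicate"] = df["replicate"].astype(int)
    df["accessions"] = df["accessions"].map(
        lambda s: tuple(sorted(filter(None, str(s).split(";"))))
    )
    if df["accessions"].map(len).eq(0).any():
        raise ValueError(f"{path}: PSM row with empty accession list")
    return df[list(PSM_COLUMNS)]


def write_psm_table(psm: pd.DataFrame, path) -> None:
    out = psm.copy()
    out["accessions"] = out["accessions"].map(";".join)
    out.to_csv(path, sep="\t", index=False)


def read_spot_table(path) -> tuple[pd.DataFrame, pd.Series]:
    """Spot volumes (+ optional ``overlap`` flag column)."""
    df = pd.read_csv(path, sep="\t")
    needed = ["gel", "channel", "spot_id", "volume"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing spot column(s) {missing}")
    if (df["volume"].astype(float) < 0).any():
        raise ValueError(f"{path}: negative spot volume")
    overlap = pd.Series(dtype=bool)
    if "overlap" in df.columns:
        overlap = df.groupby("spot_id")["overlap"].any()
    return df[needed].astype({"volume": float}), overlap


def write_spot_table(spots: pd.DataFrame, path, overlap_flags: pd.Series | None = None) -> None:
    out = spots.copy()
    if overlap_flags is not None:
        out["overlap"] = out["spot_id"].map(overlap_flags).fillna(False)
    out.to_csv(path, sep="\t", index=False)


def read_design_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = ["gel", "channel", "sample_id", "condition"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing design column(s) {missing}")
    return df[needed]


def write_design_table(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_ionomics_table(path) -> pd.DataFrame:
    """Sample x element concentrations (mg/L) with condition labels.

    Unrecognised extra columns produce a warning and are ignored.
    """
    df = pd.read_csv(path, sep="\t")
    needed = ["sample_id", "condition"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    missing_el = [e for e in ELEMENTS if e not in df.columns]
    if missing_el:
        raise ValueError(f"{path}: missing element column(s) {missing_el}")
    extra = [c for c in df.columns if c not in needed + list(ELEMENTS)]
    if extra:
        warnings.warn(f"{path}: ignoring unrecognised column(s) {extra}")
    bad_cond = set(df["condition"]) - set(VALID_CONDITIONS)
    if bad_cond:
        raise ValueError(f"{path}: unknown condition label(s) {sorted(bad_cond)}")
    for element in ELEMENTS:
        values = pd.to_numeric(df[element], errors="coerce")
        if values.isna().sum() > df[element].isna().sum():
            raise ValueError(f"{path}: non-numeric concentration in column {element}")
        if (values.dropna() < 0).any():
            raise ValueError(f"{path}: negative concentration in column {element}")
        df[element] = values
    return df[needed + list(ELEMENTS)]


def write_ionomics_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# truth and configuration
# ---------------------------------------------------------------------------

def write_truth(truth: SyntheticTruth, path) -> None:
    payload = {
        "differential_proteins": truth.differential_proteins,
        "exclusive_salt": sorted(truth.exclusive_salt),
        "exclusive_control": sorted(truth.exclusive_control),
        "differential_elements": truth.differential_elements,
        "dige_differential_spots": truth.dige_differential_spots,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_truth(path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(
        differential_proteins=dict(payload.get("differential_proteins", {})),
        exclusive_salt=set(payload.get("exclusive_salt", [])),
        exclusive_control=set(payload.get("exclusive_control", [])),
        differential_elements=dict(payload.get("differential_elements", {})),
        dige_differential_spots=dict(payload.get("dige_differential_spots", {})),
        seed=int(payload.get("seed", 0)),
    )


def load_simulation_config(path) -> SimulationConfig:
    """YAML keys override SimulationConfig defaults; unknown keys rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    valid = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"{path}: unknown simulation key(s) {sorted(unknown)}")
    for key in ("effect_sizes", "dige_ratios", "charges", "outlier_elements"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    for key in ("protein_length_range", "scan_range", "dige_dye_effects"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    if "element_profile" in raw:
        raw["element_profile"] = {
            el: tuple(v) for el, v in raw["element_profile"].items()
        }
    config = SimulationConfig(**raw)
    config.validate()
    return config
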