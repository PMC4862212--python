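"""Spectral-count protein quantification with consensus differential calling.

Implements the four label-free abundance indices used in GeLC-MS/MS
comparative studies and the associated decision rules:

* **TSC** — total (unweighted) spectral counts: a spectrum matched to a
  shared peptide increments every protein it could belong to.
* **WSC** — weighted spectral counts: each spectrum is assigned to exactly
  one candidate protein, the one with the most independent evidence
  (spectra from peptides unique to it, counted experiment-wide; ties go to
  the lexicographically smaller accession).
* **emPAI** — ``10^(N_observed/N_observable) - 1`` with peptide counts
  restricted to peptides observable in the instrument scan window.
* **NSAF** — length-normalised spectral count divided by the sample-wide
  sum of length-normalised counts.

Proteins are retained for testing only when detected (unweighted counts)
in every replicate of at least one condition and supported by at least
two peptides unique to them; retained proteins are tested per index with
an equal-variance Student's t-test, gated on signed fold change, and
summarised by a consensus tier (0-4) counting the indices on which the
protein passes both gates.  Condition-exclusive proteins bypass the
t-test and are reported through the INF/ZERO pathway.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import digestion
from ._stats import (
    INF,
    UNDEFINED,
    ZERO,
    FLAG_NS,
    fold_change,
    significance_flag,
    ttest_equal_var,
)

INDEX_NAMES = ("TSC", "WSC", "emPAI", "NSAF")

PSM_COLUMNS = ("spectrum_id", "peptide", "accessions", "sample_id", "condition", "replicate")

CONTROL = "control"
SALT = "salt"


# ---------------------------------------------------------------------------
# protein index
# ---------------------------------------------------------------------------

@dataclass
class ProteinIndex:
    """Digestion-derived metadata for every protein in the search database."""

    sequences: dict[str, str]
    descriptions: dict[str, str]
    peptides: dict[str, frozenset]           # accession -> tryptic peptides
    observable: dict[str, frozenset]         # accession -> observable subset
    peptide_parents: dict[str, frozenset]    # peptide -> accessions containing it

    @property
    def accessions(self) -> list[str]:
        return sorted(self.sequences)

    def length(self, accession: str) -> int:
        return len(self.sequences[accession])

    def n_observable(self, accession: str) -> int:
        return len(self.observable[accession])

    def is_unique_peptide(self, peptide: str) -> bool:
        """Unique = tryptic fragment of exactly one database protein."""
        return len(self.peptide_parents.get(peptide, ())) == 1


def build_protein_index(
    sequences: Mapping[str, str],
    descriptions: Mapping[str, str] | None = None,
    missed_cleavages: int = 0,
    scan_range: tuple[float, float] = digestion.DEFAULT_SCAN_RANGE,
    charges: Sequence[int] = digestion.DEFAULT_CHARGES,
) -> ProteinIndex:
    """Digest every database protein and index peptide->protein membership."""
    peptides: dict[str, frozenset] = {}
    observable: dict[str, frozenset] = {}
    parents: dict[str, set] = {}
    for acc, seq in sequences.items():
        peps = frozenset(digestion.digest_protein(seq, missed_cleavages))
        peptides[acc] = peps
        observable[acc] = frozenset(
            p for p in peps if digestion.is_observable(p, scan_range, charges)
        )
        for p in peps:
            parents.setdefault(p, set()).add(acc)
    return ProteinIndex(
        sequences=dict(sequences),
        descriptions=dict(descriptions or {}),
        peptides=peptides,
        observable=observable,
        peptide_parents={p: frozenset(a) for p, a in parents.items()},
    )


# ---------------------------------------------------------------------------
# PSM table handling
# ---------------------------------------------------------------------------

def validate_psm_table(psm: pd.DataFrame) -> None:
    missing = [c for c in PSM_COLUMNS if c not in psm.columns]
    if missing:
        raise ValueError(f"PSM table missing column(s): {missing}")
    if len(psm) == 0:
        return
    if psm["peptide"].map(lambda p: not p or set(p) - digestion.STANDARD_RESIDUES).any():
        raise ValueError("PSM table contains empty or non-standard peptide sequences")
    if psm["accessions"].map(len).min() == 0:
        raise ValueError("every PSM must list at least one accession")
    dup = psm.duplicated(subset=["sample_id", "spectrum_id"])
    if dup.any():
        raise ValueError("spectrum_id values must be unique within a sample")


def sample_metadata(psm: pd.DataFrame) -> pd.DataFrame:
    """One row per sample: sample_id, condition, replicate (sorted)."""
    meta = (
        psm[["sample_id", "condition", "replicate"]]
        .drop_duplicates()
        .sort_values(["condition", "replicate"])
        .reset_index(drop=True)
    )
    if meta["sample_id"].duplicated().any():
        raise ValueError("a sample_id maps to more than one condition/replicate")
    return meta


# ---------------------------------------------------------------------------
# abundance indices
# ---------------------------------------------------------------------------

def compute_tsc(psm: pd.DataFrame) -> pd.Series:
    """Total spectral counts for one sample's PSM table.

    Shared spectra increment every listed protein, so the column total can
    exceed the number of spectra.
    """
    counts: dict[str, int] = {}
    for accs in psm["accessions"]:
        for acc in accs:
            counts[acc] = counts.get(acc, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def unique_evidence(psm_all: pd.DataFrame, index: ProteinIndex) -> pd.Series:
    """Experiment-wide spectra from peptides unique to each protein."""
    uniq = psm_all[psm_all["peptide"].map(index.is_unique_peptide)]
    counts: dict[str, int] = {}
    for accs in uniq["accessions"]:
        for acc in accs:
            counts[acc] = counts.get(acc, 0) + 1
    return pd.Series(counts, dtype=int)


def compute_wsc(psm: pd.DataFrame, evidence: pd.Series) -> pd.Series:
    """Weighted spectral counts: each spectrum goes to one protein only.

    ``evidence`` is the experiment-wide unique-peptide spectrum count from
    :func:`unique_evidence`; the winner among a spectrum's candidates is
    the protein with the greatest evidence, ties broken by lexicographic
    accession order.  The counts therefore sum to the number of spectra.
    """
    counts: dict[str, int] = {}
    for accs in psm["accessions"]:
        winner = min(accs, key=lambda a: (-evidence.get(a, 0), a))
        counts[winner] = counts.get(winner, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def compute_empai(n_observed: int, n_observable: int) -> float:
    """emPAI = 10^(N_observed/N_observable) - 1."""
    if n_observable < 1:
        raise ValueError("emPAI undefined for proteins with no observable peptides")
    if not 0 <= n_observed <= n_observable:
        raise ValueError("need 0 <= N_observed <= N_observable")
    return float(10.0 ** (n_observed / n_observable) - 1.0)


def compute_nsaf(tsc: pd.Series, lengths: pd.Series) -> pd.Series:
    """NSAF_i = (SpC_i / L_i) / sum_j (SpC_j / L_j); NaN if no spectra."""
    lengths = lengths.reindex(tsc.index)
    if (lengths <= 0).any():
        raise ValueError("all protein lengths must be positive")
    saf = tsc / lengths
    total = saf.sum()
    if total == 0:
        return pd.Series(np.nan, index=tsc.index)
    return saf / total


def quant_matrices(
    psm_all: pd.DataFrame, index: ProteinIndex, pool_empai: bool = False
) -> dict[str, pd.DataFrame]:
    """Protein x sample matrices for all four indices.

    Rows cover every protein observed in the experiment (all zero
    elsewhere); columns are the sample ids in condition/replicate order.
    With ``pool_empai`` the emPAI numerator counts distinct observable
    peptides over all replicates of a sample's condition instead of per
    replicate.
    """
    validate_psm_table(psm_all)
    meta = sample_metadata(psm_all)
    samples = list(meta["sample_id"])
    observed = sorted({a for accs in psm_all["accessions"] for a in accs})
    evidence = unique_evidence(psm_all, index)

    tsc = pd.DataFrame(0, index=observed, columns=samples, dtype=int)
    wsc = pd.DataFrame(0, index=observed, columns=samples, dtype=int)
    empai = pd.DataFrame(np.nan, index=observed, columns=samples, dtype=float)
    nsaf = pd.DataFrame(np.nan, index=observed, columns=samples, dtype=float)
    lengths = pd.Series({a: index.length(a) for a in observed})

    by_sample = dict(tuple(psm_all.groupby("sample_id", sort=False)))
    condition_of = dict(zip(meta["sample_id"], meta["condition"]))
    for sample in samples:
        sub = by_sample.get(sample, psm_all.iloc[0:0])
        tsc[sample] = compute_tsc(sub).reindex(observed, fill_value=0)
        wsc[sample] = compute_wsc(sub, evidence).reindex(observed, fill_value=0)
        nsaf[sample] = compute_nsaf(tsc[sample], lengths)
        if pool_empai:
            sub = psm_all[psm_all["condition"] == condition_of[sample]]
        seen: dict[str, set] = {a: set() for a in observed}
        for pep, accs in zip(sub["peptide"], sub["accessions"]):
            for acc in accs:
                if pep in index.observable[acc]:
                    seen[acc].add(pep)
        for acc in observed:
            n_obs = index.n_observable(acc)
            empai.loc[acc, sample] = (
                compute_empai(len(seen[acc]), n_obs) if n_obs else np.nan
            )
    return {"TSC": tsc, "WSC": wsc, "emPAI": empai, "NSAF": nsaf}


# ---------------------------------------------------------------------------
# filtering and differential calling
# ---------------------------------------------------------------------------

def observed_unique_peptide_counts(psm_all: pd.DataFrame, index: ProteinIndex) -> pd.Series:
    """Distinct observed peptides unique to each protein, experiment-wide."""
    counts: dict[str, set] = {}
    for pep in psm_all["peptide"].unique():
        parents = index.peptide_parents.get(pep, frozenset())
        if len(parents) == 1:
            (acc,) = parents
            counts.setdefault(acc, set()).add(pep)
    return pd.Series({a: len(s) for a, s in counts.items()}, dtype=int)


def filter_proteins(
    tsc: pd.DataFrame,
    meta: pd.DataFrame,
    unique_counts: pd.Series,
    min_unique_peptides: int = 2,
) -> pd.Index:
    """Presence/uniqueness filter on unweighted counts.

    Retained iff detected in *every* replicate of at least one condition
    and supported by >= ``min_unique_peptides`` unique peptides across the
    experiment.
    """
    keep = pd.Series(False, index=tsc.index)
    for _, cols in meta.groupby("condition")["sample_id"]:
        keep |= (tsc[list(cols)] > 0).all(axis=1)
    keep &= unique_counts.reindex(tsc.index, fill_value=0) >= min_unique_peptides
    return tsc.index[keep]


def classify_exclusivity(tsc_row: pd.Series, meta: pd.DataFrame) -> str:
    """none | salt_only | control_only based on unweighted counts."""
    by_cond = {
        cond: tsc_row[list(cols)].to_numpy()
        for cond, cols in meta.groupby("condition")["sample_id"]
    }
    control_zero = not by_cond.get(CONTROL, np.array([0])).any()
    salt_zero = not by_cond.get(SALT, np.array([0])).any()
    if control_zero and not salt_zero:
        return "salt_only"
    if salt_zero and not control_zero:
        return "control_only"
    return "none"


def differential_test(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    alpha_weak: float = 0.05,
    alpha_strong: float = 0.01,
) -> pd.DataFrame:
    """Per-protein equal-variance t-test (control vs salt) on one index.

    Returns a frame with ``p_value`` and ``flag`` columns; proteins whose
    values are not finite in every replicate (e.g. undefined emPAI) get a
    missing p-value and an NS flag.
    """
    ctrl_cols = list(meta.loc[meta["condition"] == CONTROL, "sample_id"])
    salt_cols = list(meta.loc[meta["condition"] == SALT, "sample_id"])
    a = matrix[ctrl_cols].to_numpy(float)
    b = matrix[salt_cols].to_numpy(float)
    finite = np.isfinite(a).all(axis=1) & np.isfinite(b).all(axis=1)
    p = np.full(len(matrix), np.nan)
    if finite.any():
        p[finite] = ttest_equal_var(a[finite], b[finite], axis=1)
    flags = [significance_flag(v, alpha_weak, alpha_strong) for v in p]
    return pd.DataFrame({"p_value": p, "flag": flags}, index=matrix.index)


@dataclass
class DifferentialConfig:
    alpha_weak: float = 0.05
    alpha_strong: float = 0.01
    fc_gate: float = 2.0
    min_unique_peptides: int = 2
    #: t-test log10(x+1)-transformed index values instead of raw ones
    log_transform: bool = False
    #: count emPAI's observed peptides over a whole condition, not per replicate
    pool_empai: bool = False


def differential_analysis(
    matrices: Mapping[str, pd.DataFrame],
    psm_all: pd.DataFrame,
    index: ProteinIndex,
    config: DifferentialConfig | None = None,
) -> pd.DataFrame:
    """Full consensus differential table across the four indices.

    One row per retained protein: per-index fold change (signed, or
    INF/ZERO tokens), p-value and flag, the consensus tier, and the
    exclusivity status.  Exclusive proteins skip the t-test and meet the
    per-index criteria on every index with nonzero signal.
    """
    cfg = config or DifferentialConfig()
    meta = sample_metadata(psm_all)
    tsc = matrices["TSC"]
    unique_counts = observed_unique_peptide_counts(psm_all, index)
    retained = filter_proteins(tsc, meta, unique_counts, cfg.min_unique_peptides)

    ctrl_cols = list(meta.loc[meta["condition"] == CONTROL, "sample_id"])
    salt_cols = list(meta.loc[meta["condition"] == SALT, "sample_id"])

    rows = []

    def _test_matrix(name: str) -> pd.DataFrame:
        m = matrices[name].loc[retained]
        if cfg.log_transform:
            m = np.log10(m.astype(float) + 1.0)
        return m

    tests = {
        name: differential_test(_test_matrix(name), meta, cfg.alpha_weak, cfg.alpha_strong)
        for name in INDEX_NAMES
    }
    for acc in retained:
        exclusivity = classify_exclusivity(tsc.loc[acc], meta)
        row: dict = {
            "accession": acc,
            "description": index.descriptions.get(acc, ""),
            "exclusivity": exclusivity,
            "unique_peptides": int(unique_counts.get(acc, 0)),
        }
        tier = 0
        for name in INDEX_NAMES:
            values = matrices[name].loc[acc]
            ctrl = values[ctrl_cols].to_numpy(float)
            salt = values[salt_cols].to_numpy(float)
            if exclusivity == "none":
                fc = fold_change(ctrl, salt) if np.isfinite(ctrl).all() and np.isfinite(salt).all() else UNDEFINED
                p = tests[name].loc[acc, "p_value"]
                flag = tests[name].loc[acc, "flag"]
                meets = (
                    flag != FLAG_NS
                    and isinstance(fc, float)
                    and abs(fc) > cfg.fc_gate
                )
            else:
                # exclusive proteins: variance structure undefined, report tokens
                fc = INF if exclusivity == "salt_only" else ZERO
                present = salt if exclusivity == "salt_only" else ctrl
                p, flag = np.nan, ""
                meets = bool(np.nansum(present) > 0)
            row[f"{name}_fc"] = fc
            row[f"{name}_p"] = p
            row[f"{name}_flag"] = flag
            row[f"{name}_meets"] = bool(meets)
            tier += bool(meets)
        row["consensus_tier"] = tier
        rows.append(row)
    result = pd.DataFrame(rows)
    if len(result):
        result = result.sort_values(
            ["consensus_tier", "accession"], ascending=[False, True]
        ).reset_index(drop=True)
    return result


TIER_LABELS = {4: "all four", 3: "three of four", 2: "two of four", 1: "single method", 0: "none"}


def salt_responsive(differential: pd.DataFrame) -> pd.DataFrame:
    """Proteins with consensus tier >= 1 (the reported salt-responsive set)."""
    if len(differential) == 0:
        return differential
    out = differential[differential["consensus_tier"] >= 1].copy()
    out["tier_label"] = out["consensus_tier"].map(TIER_LABELS)
    return out.reset_index(drop=True)


def spectral_workflow(
    sequences: Mapping[str, str],
    psm_all: pd.DataFrame,
    descriptions: Mapping[str, str] | None = None,
    config: DifferentialConfig | None = None,
    missed_cleavages: int = 0,
    scan_range: tuple[float, float] = digestion.DEFAULT_SCAN_RANGE,
    charges: Sequence[int] = digestion.DEFAULT_CHARGES,
) -> dict:
    """FASTA + PSM tables -> index matrices + consensus differential report."""
    cfg = config or DifferentialConfig()
    index = build_protein_index(sequences, descriptions, missed_cleavages, scan_range, charges)
    matrices = quant_matrices(psm_all, index, pool_empai=cfg.pool_empai)
    differential = differential_analysis(matrices, psm_all, index, config)
    return {
        "index": index,
        "matrices": matrices,
        "differential": differential,
        "salt_responsive": salt_responsive(differential),
    }
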