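"""Evaluation against planted truth, and calibration/power simulations.

These utilities answer two questions about the pipelines: do the
significance calls keep their nominal error rates on null data (type-I
calibration), and do they recover planted effects under the study's
design (power / parameter recovery)?  They drive both the evaluation CLI
subcommand and the reproducibility script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import dige, ionomics, spectral
from ._stats import FLAG_NS, unsign_ratio
from .synthetic import (
    SimulationConfig,
    SyntheticTruth,
    generate_dige_experiment,
    generate_ionomics_table,
    generate_proteome,
    generate_psm_tables,
)


# ---------------------------------------------------------------------------
# truth comparison
# ---------------------------------------------------------------------------

def confusion_by_tier(differential: pd.DataFrame, truth: SyntheticTruth) -> pd.DataFrame:
    """Sensitivity/specificity of tier >= k calls against planted truth.

    A protein counts as truly salt-responsive when it carries a planted
    fold change or is condition-exclusive.
    """
    tested = set(differential["accession"])
    positives = (set(truth.differential_proteins) | truth.exclusive_proteins) & tested
    negatives = tested - positives
    tiers = differential.set_index("accession")["consensus_tier"]
    rows = []
    for k in (1, 2, 3, 4):
        called = set(tiers.index[tiers >= k])
        tp = len(called & positives)
        fp = len(called & negatives)
        rows.append(
            {
                "tier": k,
                "called": len(called),
                "true_positives": tp,
                "false_positives": fp,
                "sensitivity": tp / len(positives) if positives else np.nan,
                "specificity": 1 - fp / len(negatives) if negatives else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("tier")


def fold_change_recovery(
    differential: pd.DataFrame, truth: SyntheticTruth, index_name: str = "TSC"
) -> pd.DataFrame:
    """Estimated vs planted fold change for the planted, tested proteins."""
    est = differential.set_index("accession")[f"{index_name}_fc"]
    rows = []
    for acc, true_fc in truth.differential_proteins.items():
        if acc not in est.index:
            continue
        value = est[acc]
        if isinstance(value, str):
            # reports round-trip through TSV, where the column mixes
            # numbers with the INF/ZERO exclusivity tokens
            try:
                value = float(value)
            except ValueError:
                value = None
        if not isinstance(value, (int, float, np.floating)) or not np.isfinite(value):
            rows.append({"accession": acc, "true_fc": true_fc, "estimated_ratio": np.nan})
            continue
        rows.append(
            {
                "accession": acc,
                "true_fc": true_fc,
                "estimated_ratio": unsign_ratio(float(value)),
            }
        )
    df = pd.DataFrame(rows, columns=["accession", "true_fc", "estimated_ratio"])
    if len(df):
        df["relative_error"] = (df["estimated_ratio"] - df["true_fc"]) / df["true_fc"]
    return df


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------

def null_spectral_config(**overrides) -> SimulationConfig:
    """A small null experiment (no planted effects) for calibration runs."""
    base = dict(
        n_proteins=40,
        protein_length_range=(80, 250),
        effect_sizes=(),
        n_exclusive_salt=0,
        n_exclusive_control=0,
        mean_depth=2000.0,
        noise_dispersion=0.05,
        shared_peptide_fraction=0.1,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def spectral_null_flagging_rate(
    n_experiments: int, seed: int, alpha: float = 0.05, config: SimulationConfig | None = None
) -> float:
    """Fraction of retained proteins flagged at ``alpha`` on null data (TSC).

    Each experiment regenerates a proteome and PSM tables with no planted
    effects, applies the presence/uniqueness filter, and t-tests the
    unweighted counts.  Returns flagged / tested pooled over experiments.
    """
    cfg = config or null_spectral_config()
    flagged = tested = 0
    for i in range(n_experiments):
        exp_seed = (seed * 100_003 + i) % 2_147_483_647
        proteome, truth = generate_proteome(cfg, exp_seed)
        psm = generate_psm_tables(proteome, truth, cfg, exp_seed)
        if len(psm) == 0:
            continue
        index = spectral.build_protein_index(
            proteome.sequences, missed_cleavages=cfg.missed_cleavages
        )
        meta = spectral.sample_metadata(psm)
        samples = list(meta["sample_id"])
        observed = sorted({a for accs in psm["accessions"] for a in accs})
        tsc = pd.DataFrame(0, index=observed, columns=samples, dtype=int)
        for sample, sub in psm.groupby("sample_id"):
            tsc[sample] = spectral.compute_tsc(sub).reindex(observed, fill_value=0)
        unique_counts = spectral.observed_unique_peptide_counts(psm, index)
        retained = spectral.filter_proteins(tsc, meta, unique_counts)
        if len(retained) == 0:
            continue
        p = spectral.differential_test(tsc.loc[retained], meta)["p_value"].to_numpy()
        ok = np.isfinite(p)
        tested += int(ok.sum())
        flagged += int((p[ok] <= alpha).sum())
    if tested == 0:
        raise RuntimeError("no proteins survived the filter in any null experiment")
    return flagged / tested


def dige_null_rate(
    n_experiments: int, seed: int, alpha: float = 0.03, config: SimulationConfig | None = None
) -> float:
    """Fraction of retained null spots with p <= alpha, pooled over seeds."""
    # the null experiment removes planted ratios and the systematic dye bias
    # (a bias term the swap cancels, not sampling noise), so the retained
    # spots match the t-test's own sampling assumptions exactly
    cfg = config or SimulationConfig(
        dige_n_spots=60, dige_ratios=(), dige_noise_sigma=0.1,
        dige_dye_effects=(1.0, 1.0, 1.0),
        dige_missing_fraction=0.05, dige_overlap_fraction=0.0,
    )
    significant = tested = 0
    for i in range(n_experiments):
        spots, design, overlap, _ = generate_dige_experiment(cfg, (seed * 100_003 + i) % 2_147_483_647)
        result = dige.dige_workflow(spots, design, overlap, dige.DigeConfig(alpha))
        report = result["report"]
        tested += len(report)
        significant += int(report["significant"].sum())
    if tested == 0:
        raise RuntimeError("no spots retained in any null experiment")
    return significant / tested


def ionomics_null_rate(
    n_experiments: int, seed: int, alpha: float = 0.05, config: SimulationConfig | None = None
) -> float:
    """Per-element false-positive rate on a null ionomics profile."""
    if config is None:
        profile = {el: (b, 1.0) for el, (b, _) in SimulationConfig().element_profile.items()}
        config = SimulationConfig(element_profile=profile, outlier_elements=())
    flagged = tested = 0
    for i in range(n_experiments):
        table, _ = generate_ionomics_table(config, (seed * 100_003 + i) % 2_147_483_647)
        stats = ionomics.anova_per_element(table.set_index("sample_id"))
        p = stats["p_value"].to_numpy()
        ok = np.isfinite(p)
        tested += int(ok.sum())
        flagged += int((p[ok] <= alpha).sum())
    return flagged / tested


# ---------------------------------------------------------------------------
# recovery under planted effects
# ---------------------------------------------------------------------------

def recovery_config(**overrides) -> SimulationConfig:
    """High-depth, low-dispersion design with planted fold changes {4, 8}.

    The depth is set so even the least abundant planted proteins (the
    abundance prior spans ~2 orders of magnitude) accumulate enough
    control spectra that ratio accuracy reflects the estimator rather
    than Poisson shot noise.
    """
    base = dict(
        n_proteins=150,
        effect_sizes=(4.0,) * 8 + (8.0,) * 7,
        n_exclusive_salt=2,
        n_exclusive_control=4,
        mean_depth=40_000.0,
        noise_dispersion=0.001,
        shared_peptide_fraction=0.1,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def spectral_recovery(
    n_experiments: int, seed: int, config: SimulationConfig | None = None
) -> dict:
    """Tier >= 2 recovery rate and fold-change accuracy for planted proteins."""
    cfg = config or recovery_config()
    recovered = planted_tested = within = fc_count = 0
    for i in range(n_experiments):
        exp_seed = (seed * 100_003 + i) % 2_147_483_647
        proteome, truth = generate_proteome(cfg, exp_seed)
        psm = generate_psm_tables(proteome, truth, cfg, exp_seed)
        result = spectral.spectral_workflow(
            proteome.sequences, psm, proteome.descriptions,
            missed_cleavages=cfg.missed_cleavages,
        )
        differential = result["differential"]
        tiers = differential.set_index("accession")["consensus_tier"]
        for acc in truth.differential_proteins:
            if acc in tiers.index:
                planted_tested += 1
                recovered += int(tiers[acc] >= 2)
        rec = fold_change_recovery(differential, truth)
        ok = rec["relative_error"].abs() <= 0.25
        fc_count += int(rec["relative_error"].notna().sum())
        within += int(ok.sum())
    return {
        "tier2_recovery": recovered / planted_tested if planted_tested else np.nan,
        "fc_within_25pct": within / fc_count if fc_count else np.nan,
        "n_planted_tested": planted_tested,
    }


def ionomics_direction_recovery(
    n_experiments: int, seed: int, config: SimulationConfig | None = None
) -> float:
    """Fraction of seeds where every planted element is flagged correctly.

    Correct = significant at 0.05 with the planted direction (fold change
    sign matching the planted multiplier).
    """
    cfg = config or SimulationConfig(outlier_elements=())
    hits = 0
    for i in range(n_experiments):
        table, truth = generate_ionomics_table(cfg, (seed * 100_003 + i) % 2_147_483_647)
        stats = ionomics.anova_per_element(table.set_index("sample_id"))
        ok = True
        for element, mult in truth.differential_elements.items():
            row = stats.loc[element]
            fc = row["fold_change"]
            if row["flag"] == FLAG_NS or not isinstance(fc, (int, float, np.floating)):
                ok = False
                break
            if (mult > 1) != (fc > 0):
                ok = False
                break
        hits += ok
    return hits / n_experiments
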