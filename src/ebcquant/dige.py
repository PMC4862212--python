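"""Two-dimensional DIGE spot statistics with internal-standard normalisation.

Each gel carries a pooled internal standard alongside two experimental
samples labelled with spectrally distinct dyes (swapped between gels to
cancel dye bias).  Dividing a spot's volume by the same-gel standard
volume cancels gel-to-gel multiplicative effects; the log10 of that
ratio (the standardised log abundance) is the quantity tested.  Spots
must be matched in every spot map (e.g. 12/12 for 4 gels x 3 channels)
and must not overlap neighbouring spots; retained spots are tested with
a two-sample Student's t-test on the log standardised abundance and
reported with the signed average ratio of the unlogged standardised
abundances (salt relative to control).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import fold_change, ttest_equal_var

STANDARD_CHANNEL = "Cy2"
DYE_CHANNELS = ("Cy3", "Cy5")

DESIGN_COLUMNS = ("gel", "channel", "sample_id", "condition")
SPOT_COLUMNS = ("gel", "channel", "spot_id", "volume")

CONTROL = "control"
SALT = "salt"
STANDARD = "standard"


def validate_design(design: pd.DataFrame) -> None:
    """Every gel must carry exactly one standard channel and two samples."""
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design table missing column(s): {missing}")
    for gel, sub in design.groupby("gel"):
        n_std = (sub["channel"] == STANDARD_CHANNEL).sum()
        if n_std != 1:
            raise ValueError(f"gel {gel!r} must have exactly one {STANDARD_CHANNEL} channel")
        if len(sub) != 3:
            raise ValueError(f"gel {gel!r} must have three channels, found {len(sub)}")
        conds = set(sub.loc[sub["channel"] != STANDARD_CHANNEL, "condition"])
        if conds != {CONTROL, SALT}:
            raise ValueError(f"gel {gel!r} must pair one control and one salt sample")


def standardize(spots: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-spot standardised abundance: volume / same-gel standard volume.

    Returns one row per (spot_id, gel, experimental channel) with
    ``standardized`` and ``log_standardized`` (log10) columns.  Spots with
    a missing or zero standard volume on a gel are absent from that gel's
    maps (both experimental channels drop out).
    """
    validate_design(design)
    missing = [c for c in SPOT_COLUMNS if c not in spots.columns]
    if missing:
        raise ValueError(f"spot table missing column(s): {missing}")
    std = (
        spots[spots["channel"] == STANDARD_CHANNEL]
        .set_index(["gel", "spot_id"])["volume"]
        .rename("standard_volume")
    )
    exp = spots[spots["channel"] != STANDARD_CHANNEL].copy()
    exp = exp.join(std, on=["gel", "spot_id"])
    exp = exp[exp["standard_volume"].notna() & (exp["standard_volume"] > 0)]
    exp = exp[exp["volume"].notna() & (exp["volume"] > 0)]
    exp["standardized"] = exp["volume"] / exp["standard_volume"]
    exp["log_standardized"] = np.log10(exp["standardized"])
    meta = design.set_index(["gel", "channel"])[["sample_id", "condition"]]
    exp = exp.join(meta, on=["gel", "channel"])
    return exp.reset_index(drop=True)


def spot_map_counts(spots: pd.DataFrame) -> pd.Series:
    """Number of spot maps (gel x channel images) each spot appears in."""
    present = spots[spots["volume"].notna() & (spots["volume"] > 0)]
    return present.groupby("spot_id").apply(
        lambda s: len(s[["gel", "channel"]].drop_duplicates()), include_groups=False
    )


def matching_filter(
    spots: pd.DataFrame,
    total_maps: int,
    overlap_flags: pd.Series | None = None,
) -> pd.Index:
    """Spots present in all ``total_maps`` maps and not overlap-flagged."""
    counts = spot_map_counts(spots)
    keep = counts.index[counts == total_maps]
    if overlap_flags is not None:
        flagged = set(overlap_flags.index[overlap_flags.astype(bool)])
        keep = keep[~keep.isin(flagged)]
    return pd.Index(sorted(keep), name="spot_id")


def dige_test(standardized: pd.DataFrame, alpha: float = 0.03) -> pd.DataFrame:
    """Spot-level t-test and signed average ratio.

    ``standardized`` is the output of :func:`standardize` restricted to
    the spots under test.  The t-test runs on per-sample log standardised
    abundance; the average ratio applies the signed convention to
    mean(salt)/mean(control) of the unlogged standardised abundance.
    """
    rows = []
    for spot_id, sub in standardized.groupby("spot_id"):
        ctrl = sub[sub["condition"] == CONTROL]
        salt = sub[sub["condition"] == SALT]
        if len(ctrl) < 2 or len(salt) < 2:
            raise ValueError(f"spot {spot_id!r}: need >=2 gels per condition")
        p = float(
            ttest_equal_var(
                ctrl["log_standardized"].to_numpy(), salt["log_standardized"].to_numpy()
            )
        )
        ratio = fold_change(ctrl["standardized"].to_numpy(), salt["standardized"].to_numpy())
        rows.append(
            {
                "spot_id": spot_id,
                "p_value": p,
                "average_ratio": ratio,
                "n_control": len(ctrl),
                "n_salt": len(salt),
                "significant": bool(p <= alpha),
            }
        )
    return pd.DataFrame(rows).set_index("spot_id")


@dataclass
class DigeConfig:
    alpha: float = 0.03


def dige_workflow(
    spots: pd.DataFrame,
    design: pd.DataFrame,
    overlap_flags: pd.Series | None = None,
    config: DigeConfig | None = None,
) -> dict:
    """Spot volumes + gel design -> filtered, tested spot report.

    The report has one row per retained spot (matched in every map, no
    overlap flag): p-value on log standardised abundance, signed average
    ratio, map count, and the significance call at ``config.alpha``.
    """
    cfg = config or DigeConfig()
    validate_design(design)
    n_gels = design["gel"].nunique()
    total_maps = 3 * n_gels
    std = standardize(spots, design)
    counts = spot_map_counts(spots)
    retained = matching_filter(spots, total_maps, overlap_flags)
    tested = std[std["spot_id"].isin(retained)]
    if len(tested):
        report = dige_test(tested, cfg.alpha)
    else:
        report = pd.DataFrame(
            columns=["p_value", "average_ratio", "n_control", "n_salt", "significant"]
        )
    report["n_maps_present"] = counts.reindex(report.index).astype("Int64")
    return {
        "standardized": std,
        "n_maps_present": counts,
        "retained_spots": retained,
        "report": report.sort_index(),
        "significant": report[report["significant"]].sort_index() if len(report) else report,
    }


def up_down_split(ratios) -> tuple[int, int]:
    """Count increased (positive signed ratio > 1) vs decreased spots."""
    arr = np.asarray(list(ratios), dtype=float)
    return int((arr > 0).sum()), int((arr < 0).sum())
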