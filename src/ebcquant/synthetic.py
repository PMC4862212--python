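"""Synthetic inputs with known ground truth for the three assay pipelines.

The generators emulate the shape of a two-condition (control vs
salt-treated) single-cell-type experiment: a few hundred proteins
observed through tryptic-peptide spectral counts in 3 biological
replicates per condition, a 4-gel DIGE design with a pooled internal
standard and dye swapping, and a 27-element ionomics table with 6
replicates per condition whose default treatment effects follow the
headline salt responses (Na strongly up, Cl up, K and S strongly down,
Mn/P/V/Zn up, Mg/Co down).

Proteins are assembled by concatenating tryptic peptide building blocks
(each ending in K/R, with no internal cleavage sites and no leading
proline), so in-silico digestion of a generated protein returns exactly
its building blocks and every emitted PSM peptide is a true tryptic
fragment of each protein it is attributed to.  Spectral counts are
negative binomial (Poisson in the zero-dispersion limit); spot volumes
and element concentrations carry multiplicative log-normal noise, the
natural model for positive, right-skewed intensity data.

All generators derive independent deterministic streams from a single
master seed, so a fixed seed reproduces every table bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import spectral
from .digestion import DEFAULT_CHARGES, DEFAULT_SCAN_RANGE

CONTROL = "control"
SALT = "salt"

_PEPTIDE_ALPHABET = tuple("ACDEFGHILMNQSTVWY")  # no K/R (cleavage) or P (suppression)

#: per-element (baseline mg/L in control, salt/control multiplier).
#: Baselines put K, Cl, Na, S at the study's printed control means and place
#: trace elements below 0.05 mg/L so concentrations span ~7 orders of
#: magnitude; multipliers plant the headline salt responses.
DEFAULT_ELEMENT_PROFILE: dict[str, tuple[float, float]] = {
    "Na": (557.0, 21.0),
    "Cl": (3144.0, 5.7),
    "K": (7429.0, 1 / 4.5),
    "S": (442.0, 1 / 4.0),
    "Mn": (2.0, 2.5),
    "P": (180.0, 2.0),
    "V": (0.02, 3.0),
    "Zn": (1.0, 2.0),
    "Mg": (310.0, 1 / 2.0),
    "Co": (0.03, 1 / 2.0),
    "Al": (1.2, 1.0),
    "As": (0.02, 1.0),
    "Ba": (0.5, 1.0),
    "B": (5.0, 1.0),
    "Br": (12.0, 1.0),
    "Cd": (0.003, 1.0),
    "Ca": (420.0, 1.0),
    "Cr": (0.01, 1.0),
    "Cu": (0.4, 1.0),
    "Fe": (4.0, 1.0),
    "Pb": (0.005, 1.0),
    "Hg": (0.002, 1.0),
    "Mo": (0.05, 1.0),
    "Ni": (0.1, 1.0),
    "Se": (0.04, 1.0),
    "Si": (25.0, 1.0),
    "Ag": (0.004, 1.0),
}


@dataclass
class SimulationConfig:
    """Knobs for all four generators; defaults reflect the study design."""

    # proteome / PSM
    n_proteins: int = 300
    protein_length_range: tuple[int, int] = (80, 450)
    n_replicates_psm: int = 3
    shared_peptide_fraction: float = 0.10
    mean_depth: float = 5000.0
    effect_sizes: tuple[float, ...] = (4.0,) * 15 + (8.0,) * 15
    n_exclusive_salt: int = 2
    n_exclusive_control: int = 4
    noise_dispersion: float = 0.05
    abundance_sigma: float = 1.0
    missed_cleavages: int = 0
    scan_range: tuple[float, float] = DEFAULT_SCAN_RANGE
    charges: tuple[int, ...] = DEFAULT_CHARGES
    # DIGE
    dige_n_gels: int = 4
    dige_n_spots: int = 120
    dige_ratios: tuple[float, ...] = (6.2, 2.9, 2.5, 2.2, 2.0, 1 / 2.5, 1 / 1.8)
    dige_noise_sigma: float = 0.05
    dige_gel_effect_sigma: float = 0.3
    dige_dye_effects: tuple[float, float, float] = (1.0, 1.1, 0.9)  # Cy2, Cy3, Cy5
    dige_missing_fraction: float = 0.05
    dige_overlap_fraction: float = 0.03
    # ionomics
    n_replicates_ionomics: int = 6
    element_profile: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ELEMENT_PROFILE)
    )
    ionomics_noise_sigma: float = 0.20  # sigma of ln(concentration)
    outlier_elements: tuple[str, ...] = ()
    outlier_factor: float = 20.0

    def validate(self) -> None:
        lo, hi = self.protein_length_range
        if lo > hi or lo <= 0:
            raise ValueError(f"degenerate protein length range {self.protein_length_range}")
        if self.n_proteins < 2:
            raise ValueError("need at least 2 proteins")
        if not 0 <= self.shared_peptide_fraction <= 1:
            raise ValueError("shared_peptide_fraction must lie in [0, 1]")
        if any(fc <= 0 or not np.isfinite(fc) for fc in self.effect_sizes):
            raise ValueError("effect sizes must be finite and positive")
        if self.dige_n_gels < 2 or self.dige_n_gels % 2:
            raise ValueError("dige_n_gels must be even and >= 2 for a balanced dye swap")
        if self.noise_dispersion < 0 or self.mean_depth <= 0:
            raise ValueError("depth must be positive, dispersion non-negative")
        from .ionomics import ELEMENTS

        unknown = set(self.element_profile) - set(ELEMENTS)
        if unknown:
            raise ValueError(f"unknown element name(s) in profile: {sorted(unknown)}")
        missing = set(ELEMENTS) - set(self.element_profile)
        if missing:
            raise ValueError(f"element profile missing: {sorted(missing)}")
        if any(b <= 0 or m <= 0 for b, m in self.element_profile.values()):
            raise ValueError("element baselines and multipliers must be positive")
        unknown_out = set(self.outlier_elements) - set(ELEMENTS)
        if unknown_out:
            raise ValueError(f"unknown outlier element(s): {sorted(unknown_out)}")


@dataclass
class SyntheticTruth:
    """Planted ground truth; exclusivity is encoded separately from ratios."""

    differential_proteins: dict[str, float] = field(default_factory=dict)
    exclusive_salt: set[str] = field(default_factory=set)
    exclusive_control: set[str] = field(default_factory=set)
    differential_elements: dict[str, float] = field(default_factory=dict)
    dige_differential_spots: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    @property
    def exclusive_proteins(self) -> set[str]:
        return self.exclusive_salt | self.exclusive_control


@dataclass
class Proteome:
    sequences: dict[str, str]
    descriptions: dict[str, str]


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Independent deterministic stream per generator."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------

def _random_peptide(rng: np.random.Generator) -> str:
    """A tryptic building block: 6-24 residues, ends K/R, no internal sites."""
    n = int(rng.integers(6, 25))
    body = "".join(rng.choice(_PEPTIDE_ALPHABET, size=n - 1))
    terminal = "K" if rng.random() < 0.5 else "R"
    return body + terminal


def generate_proteome(config: SimulationConfig, seed: int) -> tuple[Proteome, SyntheticTruth]:
    """Random protein database plus the planted-effect truth map.

    Sequences are concatenations of tryptic building blocks; a configured
    fraction of building blocks is copied into a second protein so those
    peptides are genuinely shared.  Planted accessions (differential and
    condition-exclusive) are drawn without overlap.
    """
    config.validate()
    rng = _rng(seed, 1)
    lo, hi = config.protein_length_range
    accessions = [f"P{i + 1:04d}" for i in range(config.n_proteins)]
    peptide_lists: dict[str, list[str]] = {}
    for acc in accessions:
        target = int(rng.integers(lo, hi + 1))
        peps: list[str] = []
        while sum(map(len, peps)) < target:
            peps.append(_random_peptide(rng))
        peptide_lists[acc] = peps

    n_planted = len(config.effect_sizes)
    n_special = n_planted + config.n_exclusive_salt + config.n_exclusive_control
    if n_special > config.n_proteins:
        raise ValueError("more planted/exclusive proteins than proteins")
    special = list(rng.choice(accessions, size=n_special, replace=False))

    # peptides are shared only among background proteins: a planted fold
    # change must stay identifiable from counts (shared spectra from a flat
    # partner would pull the observable ratio toward 1, so the noise-free
    # limit could no longer reproduce the planted truth)
    background = [a for a in accessions if a not in set(special)]
    n_pep_total = sum(len(v) for v in peptide_lists.values())
    n_shared = int(round(config.shared_peptide_fraction * n_pep_total))
    if n_shared and len(background) < 2:
        raise ValueError("shared peptides need >=2 background proteins")
    for _ in range(n_shared):
        donor, recipient = rng.choice(background, size=2, replace=False)
        pep = peptide_lists[donor][int(rng.integers(len(peptide_lists[donor])))]
        pos = int(rng.integers(len(peptide_lists[recipient]) + 1))
        peptide_lists[recipient].insert(pos, pep)

    sequences = {acc: "".join(peps) for acc, peps in peptide_lists.items()}
    descriptions = {acc: f"synthetic protein {acc}" for acc in accessions}
    differential = dict(zip(special[:n_planted], map(float, config.effect_sizes)))
    exclusive_salt = set(special[n_planted : n_planted + config.n_exclusive_salt])
    exclusive_control = set(special[n_planted + config.n_exclusive_salt :])
    truth = SyntheticTruth(
        differential_proteins=differential,
        exclusive_salt=exclusive_salt,
        exclusive_control=exclusive_control,
        seed=int(seed),
    )
    return Proteome(sequences, descriptions), truth


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

def _negative_binomial(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB(mean, var = mean + dispersion*mean^2); Poisson when dispersion=0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def generate_psm_tables(
    proteome: Proteome,
    truth: SyntheticTruth,
    config: SimulationConfig,
    seed: int,
) -> pd.DataFrame:
    """PSM rows for 2 conditions x ``n_replicates_psm`` samples.

    Expected spectra per protein are proportional to abundance times the
    number of observable tryptic peptides; the proportionality constant
    is set so a control sample averages ``mean_depth`` spectra.  Planted
    proteins scale their salt-condition mean by the true fold change;
    exclusive proteins have zero expected count in the absent condition.
    Counts are distributed uniformly over each protein's observable
    peptides, and a spectrum's accession list is every protein containing
    its peptide.
    """
    config.validate()
    rng = _rng(seed, 2)
    index = spectral.build_protein_index(
        proteome.sequences,
        proteome.descriptions,
        config.missed_cleavages,
        config.scan_range,
        config.charges,
    )
    accessions = index.accessions
    n = len(accessions)
    base_abundance = rng.lognormal(0.0, config.abundance_sigma, size=n)
    n_obs = np.array([index.n_observable(a) for a in accessions], dtype=float)
    ctrl_abund = base_abundance.copy()
    salt_abund = base_abundance.copy()
    for i, acc in enumerate(accessions):
        if acc in truth.differential_proteins:
            salt_abund[i] *= truth.differential_proteins[acc]
        elif acc in truth.exclusive_salt:
            ctrl_abund[i] = 0.0
        elif acc in truth.exclusive_control:
            salt_abund[i] = 0.0
    weights_ctrl = ctrl_abund * n_obs
    norm = weights_ctrl.sum()
    if norm == 0:
        raise ValueError("all proteins have zero control abundance")
    # exclusive-to-salt proteins contribute nothing to the control total, so
    # give them a typical weight when sizing their salt-condition mean
    weights_salt = salt_abund * n_obs
    mu_ctrl = config.mean_depth * weights_ctrl / norm
    mu_salt = config.mean_depth * weights_salt / norm
    for i, acc in enumerate(accessions):
        if acc in truth.exclusive_salt:
            mu_salt[i] = config.mean_depth * base_abundance[i] * n_obs[i] / norm

    rows: list[dict] = []
    observable_lists = {a: sorted(index.observable[a]) for a in accessions}
    for condition, mu in ((CONTROL, mu_ctrl), (SALT, mu_salt)):
        for rep in range(1, config.n_replicates_psm + 1):
            sample_id = f"{condition}_{rep}"
            counts = _negative_binomial(rng, mu, config.noise_dispersion)
            spectrum = 0
            for i, acc in enumerate(accessions):
                c = int(counts[i])
                if c == 0:
                    continue
                peps = observable_lists[acc]
                if not peps:
                    continue
                per_pep = rng.multinomial(c, np.full(len(peps), 1.0 / len(peps)))
                for pep, k in zip(peps, per_pep):
                    parents = tuple(sorted(index.peptide_parents[pep]))
                    for _ in range(int(k)):
                        spectrum += 1
                        rows.append(
                            {
                                "spectrum_id": f"{sample_id}.{spectrum:06d}",
                                "peptide": pep,
                                "accessions": parents,
                                "sample_id": sample_id,
                                "condition": condition,
                                "replicate": rep,
                            }
                        )
    return pd.DataFrame(rows, columns=list(spectral.PSM_COLUMNS))


# ---------------------------------------------------------------------------
# DIGE
# ---------------------------------------------------------------------------

def generate_dige_experiment(
    config: SimulationConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, SyntheticTruth]:
    """Spot volumes, gel design, overlap flags, and spot-level truth.

    Each gel carries the pooled internal standard (Cy2) plus one control
    and one salt sample, with the Cy3/Cy5 assignment alternating across
    gels.  The standard's true value is the equal-weight mean of every
    experimental sample's true abundance, so standardised abundances of
    unplanted spots equal 1 in the noise-free limit.  Planted spots are
    never among the randomly-missing or overlap-flagged ones, so the
    filter chain can be tested against a clean truth.
    """
    config.validate()
    rng = _rng(seed, 3)
    n_gels = config.dige_n_gels
    n_spots = config.dige_n_spots
    spot_ids = [f"spot{i + 1:04d}" for i in range(n_spots)]

    base = rng.lognormal(np.log(1e5), 1.0, size=n_spots)
    ratios = np.ones(n_spots)
    planted_idx = rng.choice(n_spots, size=len(config.dige_ratios), replace=False)
    for idx, r in zip(planted_idx, config.dige_ratios):
        ratios[idx] = r
    truth = SyntheticTruth(
        dige_differential_spots={spot_ids[i]: float(ratios[i]) for i in planted_idx},
        seed=int(seed),
    )

    design_rows = []
    true_value: dict[tuple[str, str], np.ndarray] = {}
    for g in range(1, n_gels + 1):
        gel = f"gel{g}"
        control_dye, salt_dye = ("Cy3", "Cy5") if g % 2 else ("Cy5", "Cy3")
        design_rows.append(
            {"gel": gel, "channel": "Cy2", "sample_id": "pooled_standard", "condition": "standard"}
        )
        design_rows.append(
            {"gel": gel, "channel": control_dye, "sample_id": f"control_{g}", "condition": CONTROL}
        )
        design_rows.append(
            {"gel": gel, "channel": salt_dye, "sample_id": f"salt_{g}", "condition": SALT}
        )
        true_value[(gel, control_dye)] = base
        true_value[(gel, salt_dye)] = base * ratios
    design = pd.DataFrame(design_rows)
    standard_true = base * (1 + ratios) / 2  # equal-weight pool over all samples

    dye_effect = dict(zip(("Cy2", "Cy3", "Cy5"), config.dige_dye_effects))
    gel_effect = {
        f"gel{g}": float(rng.lognormal(0.0, config.dige_gel_effect_sigma))
        for g in range(1, n_gels + 1)
    }

    spot_rows = []
    for g in range(1, n_gels + 1):
        gel = f"gel{g}"
        for channel in ("Cy2", "Cy3", "Cy5"):
            # the standard channel is the deterministic reference: noise on a
            # channel shared by both same-gel samples would correlate the two
            # conditions and break the unpaired spot t-test's assumptions
            if channel == "Cy2":
                volumes = standard_true * gel_effect[gel] * dye_effect[channel]
            else:
                noise = np.exp(rng.normal(0.0, config.dige_noise_sigma, size=n_spots))
                volumes = true_value[(gel, channel)] * gel_effect[gel] * dye_effect[channel] * noise
            for sid, vol in zip(spot_ids, volumes):
                spot_rows.append({"gel": gel, "channel": channel, "spot_id": sid, "volume": vol})
    spots = pd.DataFrame(spot_rows)

    unplanted = [s for i, s in enumerate(spot_ids) if i not in set(planted_idx)]
    n_missing = int(round(config.dige_missing_fraction * n_spots))
    missing_spots = list(rng.choice(unplanted, size=min(n_missing, len(unplanted)), replace=False))
    maps = [(f"gel{g}", ch) for g in range(1, n_gels + 1) for ch in ("Cy2", "Cy3", "Cy5")]
    drop_mask = pd.Series(False, index=spots.index)
    for sid in missing_spots:
        k = int(rng.integers(1, 4))
        for m in rng.choice(len(maps), size=k, replace=False):
            gel, ch = maps[int(m)]
            drop_mask |= (
                (spots["spot_id"] == sid) & (spots["gel"] == gel) & (spots["channel"] == ch)
            )
    spots = spots[~drop_mask].reset_index(drop=True)

    n_overlap = int(round(config.dige_overlap_fraction * n_spots))
    remaining = [s for s in unplanted if s not in set(missing_spots)]
    overlap_spots = set(rng.choice(remaining, size=min(n_overlap, len(remaining)), replace=False))
    overlap_flags = pd.Series(
        {sid: sid in overlap_spots for sid in spot_ids}, name="overlap"
    )
    return spots, design, overlap_flags, truth


# ---------------------------------------------------------------------------
# ionomics
# ---------------------------------------------------------------------------

def generate_ionomics_table(
    config: SimulationConfig, seed: int
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Element concentration table (mg/L) with planted treatment effects.

    concentration = baseline x (multiplier if salt) x log-normal noise;
    optionally one gross outlier (``outlier_factor`` x the drawn value,
    comfortably beyond the 3-SD screen) is injected per named element
    into one random sample.
    """
    config.validate()
    from .ionomics import ELEMENTS

    rng = _rng(seed, 4)
    n_rep = config.n_replicates_ionomics
    rows = []
    sample_ids = []
    for condition in (CONTROL, SALT):
        for rep in range(1, n_rep + 1):
            sample_ids.append(f"{condition}_{rep}")
            rows.append({"sample_id": f"{condition}_{rep}", "condition": condition})
    table = pd.DataFrame(rows).set_index("sample_id")
    for element in ELEMENTS:
        baseline, mult = config.element_profile[element]
        means = np.array(
            [baseline if c == CONTROL else baseline * mult for c in table["condition"]]
        )
        noise = np.exp(rng.normal(0.0, config.ionomics_noise_sigma, size=len(table)))
        table[element] = means * noise
    for element in config.outlier_elements:
        victim = table.index[int(rng.integers(len(table)))]
        table.loc[victim, element] *= config.outlier_factor
    truth = SyntheticTruth(
        differential_elements={
            el: float(mult)
            for el, (_, mult) in config.element_profile.items()
            if mult != 1.0
        },
        seed=int(seed),
    )
    return table.reset_index(), truth


__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "Proteome",
    "DEFAULT_ELEMENT_PROFILE",
    "generate_proteome",
    "generate_psm_tables",
    "generate_dige_experiment",
    "generate_ionomics_table",
]
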