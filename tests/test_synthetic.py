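"""Ground-truth generators: determinism, construction rules, noise-free limits."""

import numpy as np
import pandas as pd
import pytest

from ebcquant import digestion, io, spectral
from ebcquant.synthetic import (
    SimulationConfig,
    generate_dige_experiment,
    generate_ionomics_table,
    generate_proteome,
    generate_psm_tables,
)


def small_config(**kw):
    base = dict(n_proteins=30, effect_sizes=(4.0, 8.0), n_exclusive_salt=1,
                n_exclusive_control=1, mean_depth=800.0, noise_dispersion=0.05)
    base.update(kw)
    return SimulationConfig(**base)


class TestProteome:
    def test_null_experiment_has_no_planted_effects(self):
        cfg = SimulationConfig(n_proteins=2, effect_sizes=(), n_exclusive_salt=0,
                               n_exclusive_control=0)
        proteome, truth = generate_proteome(cfg, 1)
        assert len(proteome.sequences) == 2
        assert truth.differential_proteins == {}
        assert truth.exclusive_proteins == set()

    def test_fixed_seed_is_byte_identical(self, tmp_path):
        cfg = small_config()
        paths = []
        for run in (1, 2):
            proteome, _ = generate_proteome(cfg, 42)
            path = tmp_path / f"run{run}.fasta"
            io.write_fasta(proteome, path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_truth_maps_every_planted_effect(self):
        cfg = SimulationConfig(n_proteins=300, effect_sizes=(4.0,) * 30)
        proteome, truth = generate_proteome(cfg, 3)
        assert len(truth.differential_proteins) == 30
        assert set(truth.differential_proteins.values()) == {4.0}
        assert set(truth.differential_proteins) <= set(proteome.sequences)

    def test_degenerate_length_range_rejected(self):
        with pytest.raises(ValueError, match="length range"):
            generate_proteome(SimulationConfig(protein_length_range=(400, 80)), 1)

    def test_every_protein_has_observable_tryptic_peptide(self):
        proteome, _ = generate_proteome(small_config(), 7)
        for seq in proteome.sequences.values():
            peps = digestion.digest_protein(seq, 0)
            assert digestion.count_observable_peptides(peps) >= 1


class TestPsmTables:
    def test_peptides_are_true_tryptic_fragments(self):
        cfg = small_config(shared_peptide_fraction=0.2)
        proteome, truth = generate_proteome(cfg, 5)
        psm = generate_psm_tables(proteome, truth, cfg, 5)
        digests = {acc: set(digestion.digest_protein(seq, 0))
                   for acc, seq in proteome.sequences.items()}
        for pep, accs in zip(psm["peptide"], psm["accessions"]):
            for acc in accs:
                assert pep in digests[acc]

    def test_exclusive_protein_absent_from_other_condition(self):
        cfg = small_config()
        proteome, truth = generate_proteome(cfg, 5)
        psm = generate_psm_tables(proteome, truth, cfg, 5)
        for acc in truth.exclusive_salt:
            control = psm[psm["condition"] == "control"]
            assert not control["accessions"].map(lambda a: acc in a).any()
        for acc in truth.exclusive_control:
            salt = psm[psm["condition"] == "salt"]
            assert not salt["accessions"].map(lambda a: acc in a).any()

    def test_no_sharing_means_single_accession_rows(self):
        cfg = small_config(shared_peptide_fraction=0.0)
        proteome, truth = generate_proteome(cfg, 5)
        psm = generate_psm_tables(proteome, truth, cfg, 5)
        assert psm["accessions"].map(len).eq(1).all()

    def test_planted_ratio_recovered_at_high_depth(self):
        """Law of large numbers: TSC ratio within 10% of truth at depth 1e4."""
        cfg = small_config(n_proteins=40, effect_sizes=(4.0,), mean_depth=10_000.0,
                           noise_dispersion=0.0)
        proteome, truth = generate_proteome(cfg, 9)
        psm = generate_psm_tables(proteome, truth, cfg, 9)
        (acc,) = truth.differential_proteins
        tsc_by_cond = {}
        for cond in ("control", "salt"):
            sub = psm[psm["condition"] == cond]
            tsc_by_cond[cond] = sum(accs.count(acc) for accs in sub["accessions"]) / 3
        ratio = tsc_by_cond["salt"] / tsc_by_cond["control"]
        assert ratio == pytest.approx(4.0, rel=0.10)

    def test_determinism(self):
        cfg = small_config()
        proteome, truth = generate_proteome(cfg, 21)
        a = generate_psm_tables(proteome, truth, cfg, 21)
        b = generate_psm_tables(proteome, truth, cfg, 21)
        pd.testing.assert_frame_equal(a, b)


class TestDigeGenerator:
    def test_noise_free_unplanted_spots_standardize_to_one(self):
        cfg = SimulationConfig(dige_n_spots=20, dige_ratios=(), dige_noise_sigma=0.0,
                               dige_dye_effects=(1.0, 1.0, 1.0),
                               dige_missing_fraction=0.0, dige_overlap_fraction=0.0)
        spots, design, _, _ = generate_dige_experiment(cfg, 2)
        from ebcquant import dige

        std = dige.standardize(spots, design)
        assert np.allclose(std["standardized"], 1.0)

    def test_balanced_swap_construction(self):
        cfg = SimulationConfig(dige_n_gels=4)
        _, design, _, _ = generate_dige_experiment(cfg, 2)
        control = design[design["condition"] == "control"]
        assert (control["channel"] == "Cy3").sum() == 2
        assert (control["channel"] == "Cy5").sum() == 2
        with pytest.raises(ValueError, match="even"):
            generate_dige_experiment(SimulationConfig(dige_n_gels=3), 2)

    def test_missing_spots_fail_matching_filter(self):
        cfg = SimulationConfig(dige_n_spots=40, dige_ratios=(),
                               dige_missing_fraction=0.2, dige_overlap_fraction=0.0)
        spots, design, overlap, _ = generate_dige_experiment(cfg, 6)
        from ebcquant import dige

        counts = dige.spot_map_counts(spots)
        retained = dige.matching_filter(spots, 12, overlap)
        assert (counts < 12).any()
        assert set(retained) == set(counts.index[counts == 12])


class TestIonomicsGenerator:
    def test_noise_free_sodium_ratio_is_21(self):
        cfg = SimulationConfig(ionomics_noise_sigma=0.0, outlier_elements=())
        table, truth = generate_ionomics_table(cfg, 3)
        means = table.groupby("condition")["Na"].mean()
        assert means["salt"] / means["control"] == pytest.approx(21.0, rel=1e-12)
        assert truth.differential_elements["Na"] == 21.0

    def test_concentrations_span_seven_orders(self):
        table, _ = generate_ionomics_table(SimulationConfig(), 3)
        values = table.drop(columns=["sample_id", "condition"]).to_numpy(float)
        assert values.max() / values.min() > 1e6

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            SimulationConfig(outlier_elements=("Unobtainium",)).validate()
        profile = dict(SimulationConfig().element_profile)
        profile["Xx"] = (1.0, 1.0)
        with pytest.raises(ValueError, match="unknown"):
            SimulationConfig(element_profile=profile).validate()

    def test_replicate_structure(self):
        table, _ = generate_ionomics_table(SimulationConfig(), 8)
        assert table["condition"].value_counts().to_dict() == {"control": 6, "salt": 6}
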