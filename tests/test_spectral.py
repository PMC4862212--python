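"""Abundance indices, presence/uniqueness filter, and consensus calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ebcquant import spectral
from ebcquant._stats import INF, ZERO, fold_change
from conftest import make_psm


def _sample(rows, sample, cond, rep):
    return [(f"{sample}.{i}", pep, accs, sample, cond, rep) for i, (pep, accs) in enumerate(rows)]


class TestIndices:
    def test_tsc_shared_spectrum_counts_for_every_protein(self, psm_factory):
        psm = psm_factory([("s1", "GGGGGGGGGGK", ("A", "B"), "c1", "control", 1)])
        tsc = spectral.compute_tsc(psm)
        assert tsc["A"] == 1 and tsc["B"] == 1 and tsc.sum() == 2

    def test_tsc_empty_and_unique(self, psm_factory):
        assert spectral.compute_tsc(psm_factory([])).empty
        psm = psm_factory([(f"s{i}", "AAAAAAAAAAK", ("A",), "c1", "control", 1) for i in range(5)])
        assert spectral.compute_tsc(psm)["A"] == 5

    def test_wsc_assigns_shared_spectra_to_most_evidenced(self, psm_factory):
        rows = [(f"u{i}", "AAAAAAAAAAK", ("A",), "c1", "control", 1) for i in range(3)]
        rows += [("u4", "DDDDDDDDDDK", ("B",), "c1", "control", 1)]
        rows += [("sh", "GGGGGGGGGGK", ("A", "B"), "c1", "control", 1)]
        psm = psm_factory(rows)
        evidence = pd.Series({"A": 3, "B": 1})
        wsc = spectral.compute_wsc(psm, evidence)
        assert wsc["A"] == 4 and wsc["B"] == 1

    def test_wsc_tie_breaks_lexicographically(self, psm_factory):
        psm = psm_factory([("sh", "GGGGGGGGGGK", ("B", "A"), "c1", "control", 1)])
        wsc = spectral.compute_wsc(psm, pd.Series({"A": 2, "B": 2}))
        assert wsc.to_dict() == {"A": 1}

    def test_wsc_conservation_and_tsc_bound(self, two_protein_db, psm_factory):
        rows = [("s1", "AAAAAAAAAAK", ("A",), "c1", "control", 1),
                ("s2", "GGGGGGGGGGK", ("A", "B"), "c1", "control", 1),
                ("s3", "EEEEEEEEEEK", ("B",), "c1", "control", 1)]
        psm = psm_factory(rows)
        index = spectral.build_protein_index(two_protein_db)
        evidence = spectral.unique_evidence(psm, index)
        wsc = spectral.compute_wsc(psm, evidence)
        tsc = spectral.compute_tsc(psm)
        assert wsc.sum() == len(psm)           # conservation
        assert tsc.sum() >= wsc.sum()          # equality iff no shared spectra

    @pytest.mark.parametrize(
        "n_obs, n_total, expected",
        [(10, 10, 9.0), (0, 10, 0.0), (4, 10, 10 ** 0.4 - 1)],
    )
    def test_empai_formula(self, n_obs, n_total, expected):
        assert spectral.compute_empai(n_obs, n_total) == pytest.approx(expected, rel=1e-12)

    def test_empai_requires_observable_peptides(self):
        with pytest.raises(ValueError):
            spectral.compute_empai(0, 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(1, 40))
    def test_empai_monotone_in_observed(self, n_total):
        values = [spectral.compute_empai(n, n_total) for n in range(n_total + 1)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_nsaf_hand_values(self):
        nsaf = spectral.compute_nsaf(pd.Series({"A": 10, "B": 5}), pd.Series({"A": 200, "B": 50}))
        assert nsaf["A"] == pytest.approx(1 / 3)
        assert nsaf["B"] == pytest.approx(2 / 3)
        single = spectral.compute_nsaf(pd.Series({"A": 7}), pd.Series({"A": 100}))
        assert single["A"] == 1.0

    def test_nsaf_zero_spectra_is_missing(self):
        nsaf = spectral.compute_nsaf(pd.Series({"A": 0, "B": 0}), pd.Series({"A": 10, "B": 10}))
        assert nsaf.isna().all()

    def test_quant_matrices_invariants(self, two_protein_db, psm_factory):
        rows = []
        for cond, reps in (("control", 3), ("salt", 3)):
            for r in range(1, reps + 1):
                sample = f"{cond}_{r}"
                rows += _sample(
                    [("AAAAAAAAAAK", ("A",)), ("GGGGGGGGGGK", ("A", "B")), ("DDDDDDDDDDK", ("B",))],
                    sample, cond, r,
                )
        psm = make_psm(rows)
        index = spectral.build_protein_index(two_protein_db)
        mats = spectral.quant_matrices(psm, index)
        assert np.allclose(mats["NSAF"].sum(axis=0), 1.0, atol=1e-9)
        n_spectra = psm.groupby("sample_id").size()
        assert (mats["WSC"].sum(axis=0)[n_spectra.index] == n_spectra).all()
        assert (mats["TSC"].sum(axis=0) >= mats["WSC"].sum(axis=0)).all()
        assert ((mats["emPAI"] >= 0) | mats["emPAI"].isna()).all().all()


class TestFoldChange:
    def test_signed_convention(self):
        assert fold_change([2, 2, 2], [4, 4, 4]) == pytest.approx(2.0)
        assert fold_change([4, 4, 4], [2, 2, 2]) == pytest.approx(-2.0)

    def test_exclusivity_tokens(self):
        assert fold_change([0, 0, 0], [3, 5, 2]) == INF
        assert fold_change([3, 5, 2], [0, 0, 0]) == ZERO
        assert fold_change([0, 0], [0, 0]) == "UNDEFINED"

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0.01, 100.0))
    def test_magnitude_at_least_one(self, ratio):
        fc = fold_change([1.0, 1.0], [ratio, ratio])
        assert abs(fc) >= 1.0
        # antisymmetry: swapping conditions flips to the reciprocal slot
        rev = fold_change([ratio, ratio], [1.0, 1.0])
        assert abs(abs(fc) - abs(rev)) < 1e-9


class TestFilterAndTest:
    def _matrix(self, control, salt):
        data = {f"control_{i+1}": [v] for i, v in enumerate(control)}
        data.update({f"salt_{i+1}": [v] for i, v in enumerate(salt)})
        meta = pd.DataFrame(
            [{"sample_id": f"{c}_{i+1}", "condition": c, "replicate": i + 1}
             for c in ("control", "salt") for i in range(3)]
        )
        return pd.DataFrame(data, index=["A"]), meta

    @pytest.mark.parametrize(
        "control, salt, n_unique, kept",
        [
            ((1, 2, 3), (0, 0, 5), 2, True),    # complete in control only
            ((4, 0, 4), (3, 0, 9), 2, False),   # no complete condition
            ((1, 1, 1), (2, 2, 2), 1, False),   # too few unique peptides
        ],
    )
    def test_presence_uniqueness_filter(self, control, salt, n_unique, kept):
        tsc, meta = self._matrix(control, salt)
        retained = spectral.filter_proteins(tsc, meta, pd.Series({"A": n_unique}))
        assert ("A" in retained) is kept

    def test_degenerate_variance_conventions(self):
        equal, meta = self._matrix((1, 2, 3), (1, 2, 3))
        # identical groups: p = 1 and NS
        res = spectral.differential_test(pd.DataFrame(
            {c: equal[c] for c in equal.columns}), meta)
        assert res.loc["A", "p_value"] == pytest.approx(1.0)
        assert res.loc["A", "flag"] == "NS"
        const_diff, _ = self._matrix((2, 2, 2), (5, 5, 5))
        res = spectral.differential_test(const_diff, meta)
        assert res.loc["A", "p_value"] == 0.0
        assert res.loc["A", "flag"] == "**"

    def test_flag_thresholds(self):
        from ebcquant._stats import significance_flag

        assert significance_flag(0.03) == "*"
        assert significance_flag(0.01) == "**"
        assert significance_flag(0.05) == "*"
        assert significance_flag(0.051) == "NS"


class TestConsensus:
    def _experiment(self, psm_factory):
        """A: strong planted effect; B: flat; X: exclusive to salt."""
        db = {
            "A": "AAAAAAAAAAKCCCCCCCCCCK",
            "B": "DDDDDDDDDDKEEEEEEEEEEK",
            "X": "FFFFFFFFFFKHHHHHHHHHHK",
        }
        rows = []
        for r in (1, 2, 3):
            sample = f"control_{r}"
            rows += _sample(
                [("AAAAAAAAAAK", ("A",)), ("CCCCCCCCCCK", ("A",))] * 2
                + [("DDDDDDDDDDK", ("B",)), ("EEEEEEEEEEK", ("B",))] * 50,
                sample, "control", r)
        for r in (1, 2, 3):
            sample = f"salt_{r}"
            rows += _sample(
                [("AAAAAAAAAAK", ("A",)), ("CCCCCCCCCCK", ("A",))] * 10
                + [("DDDDDDDDDDK", ("B",)), ("EEEEEEEEEEK", ("B",))] * 50
                + [("FFFFFFFFFFK", ("X",)), ("HHHHHHHHHHK", ("X",))] * 5,
                sample, "salt", r)
        return db, make_psm(rows)

    def test_consensus_tiers_and_exclusivity(self, psm_factory):
        db, psm = self._experiment(psm_factory)
        result = spectral.spectral_workflow(db, psm)
        d = result["differential"].set_index("accession")
        assert d.loc["A", "consensus_tier"] >= 2
        assert d.loc["A", "TSC_fc"] == pytest.approx(5.0)
        assert d.loc["B", "consensus_tier"] == 0
        assert d.loc["X", "exclusivity"] == "salt_only"
        assert d.loc["X", "TSC_fc"] == INF
        assert d.loc["X", "consensus_tier"] == 4
        # reported set only contains tier >= 1
        assert set(result["salt_responsive"]["accession"]) == {"A", "X"}
        # tier monotonicity
        tiers = result["differential"]["consensus_tier"]
        assert (tiers >= 2).sum() <= (tiers >= 1).sum()

    def test_tier_counts_indices_meeting_criteria(self, psm_factory):
        db, psm = self._experiment(psm_factory)
        result = spectral.spectral_workflow(db, psm)
        d = result["differential"].set_index("accession")
        meets = [d.loc["A", f"{n}_meets"] for n in spectral.INDEX_NAMES]
        assert d.loc["A", "consensus_tier"] == sum(meets)


def test_rankings_agree_without_sharing_and_equal_lengths(psm_factory):
    """With unique peptides and equal lengths, TSC/WSC/NSAF rank identically."""
    db = {"A": "AAAAAAAAAAK" * 3, "B": "DDDDDDDDDDK" * 3, "C": "FFFFFFFFFFK" * 3}
    rows = []
    for cond in ("control", "salt"):
        for r in (1, 2, 3):
            sample = f"{cond}_{r}"
            rows += _sample(
                [("AAAAAAAAAAK", ("A",))] * 6 + [("DDDDDDDDDDK", ("B",))] * 3
                + [("FFFFFFFFFFK", ("C",))] * 1,
                sample, cond, r)
    psm = make_psm(rows)
    index = spectral.build_protein_index(db)
    mats = spectral.quant_matrices(psm, index)
    for sample in mats["TSC"].columns:
        r_tsc = mats["TSC"][sample].rank()
        assert (mats["WSC"][sample].rank() == r_tsc).all()
        assert (mats["NSAF"][sample].rank() == r_tsc).all()


def test_pooled_empai_counts_condition_wide(two_protein_db):
    """Pooling makes emPAI equal across replicates of a condition."""
    rows = []
    for r in (1, 2, 3):
        peps = [("AAAAAAAAAAK", ("A",))]
        if r == 1:  # second peptide of A seen in one replicate only
            peps.append(("CCCCCCCCCCK", ("A",)))
        rows += _sample(peps + [("DDDDDDDDDDK", ("B",))], f"control_{r}", "control", r)
        rows += _sample([("AAAAAAAAAAK", ("A",)), ("DDDDDDDDDDK", ("B",))], f"salt_{r}", "salt", r)
    db = {"A": "AAAAAAAAAAKCCCCCCCCCCK", "B": "DDDDDDDDDDK"}
    psm = make_psm(rows)
    index = spectral.build_protein_index(db)
    per_rep = spectral.quant_matrices(psm, index)["emPAI"]
    pooled = spectral.quant_matrices(psm, index, pool_empai=True)["emPAI"]
    assert per_rep.loc["A", "control_1"] > per_rep.loc["A", "control_2"]
    ctrl_cols = ["control_1", "control_2", "control_3"]
    assert pooled.loc["A", ctrl_cols].nunique() == 1
    assert pooled.loc["A", "control_2"] == per_rep.loc["A", "control_1"]


def test_log_transform_flag_keeps_clean_calls(two_protein_db):
    rows = []
    for cond, mult in (("control", 1), ("salt", 6)):
        for r in (1, 2, 3):
            rows += _sample([("AAAAAAAAAAK", ("A",)), ("CCCCCCCCCCK", ("A",))] * (2 * mult + r)
                            + [("EEEEEEEEEEK", ("B",)), ("DDDDDDDDDDK", ("B",))] * 20,
                            f"{cond}_{r}", cond, r)
    psm = make_psm(rows)
    raw = spectral.spectral_workflow(two_protein_db, psm)
    logged = spectral.spectral_workflow(
        two_protein_db, psm, config=spectral.DifferentialConfig(log_transform=True))
    for res in (raw, logged):
        d = res["differential"].set_index("accession")
        assert d.loc["A", "consensus_tier"] >= 1
    p_raw = raw["differential"].set_index("accession").loc["A", "TSC_p"]
    p_log = logged["differential"].set_index("accession").loc["A", "TSC_p"]
    assert p_raw != p_log
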