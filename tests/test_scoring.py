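import numpy as np
import pandas as pd
import pytest

from polyscore import (
    GenotypePanel,
    VariantRecord,
    WeightEntry,
    WeightSet,
    WeightFileRecord,
    build_weights,
    harmonize_external_weights,
    score_individuals,
)
from polyscore.scoring import ScoringError

from conftest import random_panel
from oracles import score_bruteforce


def _assoc_frame(rows):
    return pd.DataFrame(rows, columns=["variant_id", "effect_allele", "non_effect_allele", "beta"])


class TestBuildWeights:
    def test_positive_beta_scores_effect_allele(self):
        ws = build_weights(_assoc_frame([("rs2715157", "A", "G", 0.67)]))
        assert ws.entries == [WeightEntry("rs2715157", "A", 0.67)]

    def test_negative_beta_recoded_to_other_allele(self):
        ws = build_weights(_assoc_frame([("rs187238", "G", "C", -0.73)]))
        assert ws.entries == [WeightEntry("rs187238", "C", 0.73)]

    def test_unweighted_mode_unit_weights_same_orientation(self):
        ws = build_weights(
            _assoc_frame([("rs2715157", "A", "G", 0.67), ("rs187238", "G", "C", -0.73)]),
            mode="unweighted",
        )
        assert ws.entries == [WeightEntry("rs2715157", "A", 1.0), WeightEntry("rs187238", "C", 1.0)]

    def test_zero_beta_warns_and_zero_weight(self):
        with pytest.warns(UserWarning, match="exactly 0"):
            ws = build_weights(_assoc_frame([("rs1", "A", "G", 0.0)]))
        assert ws.entries == [WeightEntry("rs1", "A", 0.0)]

    def test_undefined_beta_is_error(self):
        with pytest.raises(ScoringError, match="rs1"):
            build_weights(_assoc_frame([("rs1", "A", "G", np.nan)]))


class TestHarmonization:
    def _panel(self):
        variants = [
            VariantRecord("rs16944", "IL1B", "2", 112837290, "A", "G"),
            VariantRecord("rs9", "X", "1", 9, "T", "C"),
        ]
        d = np.array([[0.0, 1.0], [1.0, 2.0], [2.0, 0.0]])
        return GenotypePanel(variants, d, ["I1", "I2", "I3"])

    def test_swapped_alleles_negate_then_recode(self):
        """Published +0.26 on the panel's non-effect allele becomes a 0.26
        weight back on that same allele after sign recoding."""
        raw = [WeightFileRecord("rs16944", "G", "A", 0.26)]
        ws, log = harmonize_external_weights(raw, self._panel())
        assert ws.entries == [WeightEntry("rs16944", "G", 0.26)]
        assert log.loc[0, "action"] == "swap"
        assert log.loc[0, "beta_out"] == pytest.approx(-0.26)

    def test_identity_orientation_unchanged(self):
        raw = [WeightFileRecord("rs16944", "A", "G", 0.4)]
        ws, log = harmonize_external_weights(raw, self._panel())
        assert ws.entries == [WeightEntry("rs16944", "A", 0.4)]
        assert log.loc[0, "action"] == "match"

    def test_strand_flip_resolved(self):
        # panel rs9 is T/C; published on the other strand as A/G
        raw = [WeightFileRecord("rs9", "A", "G", -0.5)]
        ws, log = harmonize_external_weights(raw, self._panel())
        assert log.loc[0, "action"] == "flip"
        assert ws.entries == [WeightEntry("rs9", "C", 0.5)]

    def test_strand_ambiguous_dropped_by_default(self):
        raw = [
            WeightFileRecord("rs16944", "C", "G", 0.3),
            WeightFileRecord("rs9", "T", "C", 0.2),
        ]
        ws, log = harmonize_external_weights(raw, self._panel())
        actions = dict(zip(log["variant_id"], log["action"]))
        assert actions["rs16944"] == "dropped_ambiguous"
        assert ws.variant_ids == ["rs9"]

    def test_absent_and_mismatched_dropped(self):
        raw = [
            WeightFileRecord("rs_missing", "A", "G", 0.3),
            WeightFileRecord("rs16944", "A", "C", 0.3),
            WeightFileRecord("rs9", "T", "C", 0.2),
        ]
        ws, log = harmonize_external_weights(raw, self._panel())
        actions = dict(zip(log["variant_id"], log["action"]))
        assert actions["rs_missing"] == "dropped_absent"
        assert actions["rs16944"] == "dropped_mismatch"

    def test_no_scorable_variants_is_error(self):
        raw = [WeightFileRecord("rs_missing", "A", "G", 0.3)]
        with pytest.raises(ScoringError, match="no scorable"):
            harmonize_external_weights(raw, self._panel())

    def test_panel_oriented_set_is_fixed_point(self):
        """Harmonizing weights already in panel orientation equals building
        them directly from the association frame."""
        assoc = _assoc_frame([("rs16944", "A", "G", -0.26), ("rs9", "T", "C", 0.5)])
        direct = build_weights(assoc)
        raw = [WeightFileRecord(*row) for row in assoc.itertuples(index=False)]
        harmonized, log = harmonize_external_weights(raw, self._panel())
        assert harmonized.entries == direct.entries
        assert set(log["action"]) == {"match"}


class TestScoring:
    def test_all_zero_weights_score_zero(self):
        rng = np.random.default_rng(0)
        panel = random_panel(rng, 10, 4)
        ws = WeightSet([WeightEntry(v, panel.variant(v).effect_allele, 0.0)
                        for v in panel.variant_ids], "weighted", "in_sample")
        scores = score_individuals(panel, ws)
        assert (scores["pgs"] == 0).all()

    def test_reoriented_contribution_hand_computed(self):
        """Weight 0.73 on the C allele of a G/C variant: an individual with
        G-dosage 2 contributes 0, with G-dosage 0 contributes 1.46."""
        variants = [VariantRecord("rs187238", "IL18", "11", 112164265, "G", "C")]
        panel = GenotypePanel(variants, np.array([[2.0], [0.0]]), ["I1", "I2"])
        ws = WeightSet([WeightEntry("rs187238", "C", 0.73)], "weighted", "in_sample")
        scores = score_individuals(panel, ws)
        assert scores["pgs"].tolist() == pytest.approx([0.0, 1.46])

    @pytest.mark.parametrize("policy", ["mean_dosage", "skip"])
    def test_matches_bruteforce_loop(self, policy):
        rng = np.random.default_rng(99)
        for _ in range(10):
            panel = random_panel(rng, n=int(rng.integers(3, 30)), m=int(rng.integers(1, 10)),
                                 missing_rate=0.15)
            entries = []
            for vid in panel.variant_ids:
                v = panel.variant(vid)
                allele = v.effect_allele if rng.random() < 0.5 else v.non_effect_allele
                entries.append(WeightEntry(vid, allele, float(rng.exponential(0.5))))
            ws = WeightSet(entries, "weighted", "in_sample")
            got = score_individuals(panel, ws, missing_policy=policy)["pgs"].to_numpy()
            expected = score_bruteforce(panel, ws, policy)
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_zero_weight_variant_never_changes_scores(self):
        rng = np.random.default_rng(1)
        panel = random_panel(rng, 20, 5, missing_rate=0.1)
        entries = [WeightEntry(v, panel.variant(v).effect_allele, 0.3) for v in panel.variant_ids[:4]]
        base = score_individuals(panel, WeightSet(entries, "weighted", "in_sample"))
        extra = entries + [WeightEntry(panel.variant_ids[4],
                                       panel.variant(panel.variant_ids[4]).effect_allele, 0.0)]
        augmented = score_individuals(panel, WeightSet(extra, "weighted", "in_sample"))
        np.testing.assert_array_equal(base["pgs"], augmented["pgs"])

    def test_unweighted_score_integer_with_complete_genotypes(self):
        rng = np.random.default_rng(2)
        panel = random_panel(rng, 30, 6, missing_rate=0.0)
        entries = [WeightEntry(v, panel.variant(v).non_effect_allele, 1.0)
                   for v in panel.variant_ids]
        scores = score_individuals(panel, WeightSet(entries, "unweighted", "in_sample"),
                                   missing_policy="skip")
        assert (scores["pgs"] == scores["pgs"].round()).all()
        assert (scores["n_variants_used"] == 6).all()

    def test_recoding_shifts_by_fixed_constant(self):
        """Recoded non-negative scoring differs from the naive signed sum by
        2 * sum(|beta|) over the negative-effect variants, per individual."""
        rng = np.random.default_rng(3)
        panel = random_panel(rng, 25, 8, missing_rate=0.0)
        betas = rng.normal(scale=0.5, size=8)
        assoc = _assoc_frame(
            [(v, panel.variant(v).effect_allele, panel.variant(v).non_effect_allele, b)
             for v, b in zip(panel.variant_ids, betas)]
        )
        recoded = score_individuals(panel, build_weights(assoc))["pgs"].to_numpy()
        signed = panel.dosages @ betas
        shift = 2 * np.abs(betas[betas < 0]).sum()
        np.testing.assert_allclose(recoded - signed, shift, atol=1e-10)

    def test_absent_weight_variant_warns_all_absent_errors(self):
        rng = np.random.default_rng(4)
        panel = random_panel(rng, 5, 2, missing_rate=0.0)
        present = WeightEntry(panel.variant_ids[0], panel.variant(panel.variant_ids[0]).effect_allele, 1.0)
        absent = WeightEntry("rs_gone", "A", 1.0)
        with pytest.warns(UserWarning, match="rs_gone"):
            score_individuals(panel, WeightSet([present, absent], "weighted", "in_sample"))
        with pytest.raises(ScoringError, match="no weight variants"), \
                pytest.warns(UserWarning, match="rs_gone"):
            score_individuals(panel, WeightSet([absent], "weighted", "in_sample"))
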