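import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from periyield.errors import (
    InvalidArgumentError,
    InvalidSequenceError,
    PropertyUnavailableError,
)
from periyield.sequence_features import (
    ALPHABET,
    FeatureRegistry,
    PropertyPredictorSuite,
    ResidueGroup,
    SequenceRecord,
    aa_composition,
    base_feature_vector,
    dipeptide_occurrences,
    full_feature_vector,
    interactive_features,
    isoelectric_point,
    max_consecutive_run,
    named_subset,
    net_charge,
    physchem_scalars,
    predicted_properties,
)
from periyield.sequence_features.scales import CHOU_FASMAN_HELIX

sequences = st.text(alphabet=ALPHABET, min_size=2, max_size=80)


def rec(seq, rid="t"):
    return SequenceRecord(rid, seq)


class TestSequenceRecord:
    def test_uppercased(self):
        assert rec("acde").sequence == "ACDE"

    def test_rejects_short(self):
        with pytest.raises(InvalidSequenceError):
            rec("A")

    @pytest.mark.parametrize("letter", list("BJOUXZ"))
    def test_rejects_nonstandard_letters(self, letter):
        with pytest.raises(InvalidSequenceError, match="illegal residue"):
            rec("AC" + letter + "DE")

    def test_error_names_position(self):
        with pytest.raises(InvalidSequenceError, match="position 3"):
            rec("ACXDE", rid="bad")


class TestResidueGroup:
    def test_rejects_empty(self):
        with pytest.raises(InvalidArgumentError):
            ResidueGroup("empty", frozenset())

    def test_rejects_outside_alphabet(self):
        with pytest.raises(InvalidArgumentError):
            ResidueGroup("bad", frozenset("AX"))


class TestAaComposition:
    def test_single_residue(self):
        freqs = aa_composition(rec("AAAA"))
        assert freqs["A"] == 1.0
        assert all(freqs[a] == 0.0 for a in ALPHABET if a != "A")

    def test_uniform(self):
        freqs = aa_composition(rec("ACDE"))
        for a in "ACDE":
            assert freqs[a] == 0.25
        assert sum(freqs.values()) == pytest.approx(1.0)

    def test_hand_count(self):
        freqs = aa_composition(rec("HKRA"))
        assert all(freqs[a] == 0.25 for a in "HKRA")

    @given(sequences)
    @settings(max_examples=50, deadline=None)
    def test_frequencies_sum_to_one(self, seq):
        freqs = aa_composition(rec(seq))
        assert abs(sum(freqs.values()) - 1.0) < 1e-12
        assert all(0.0 <= v <= 1.0 for v in freqs.values())


class TestMaxConsecutiveRun:
    BPC = ResidueGroup("bpc", frozenset("HKR"))

    def test_group_run(self):
        assert max_consecutive_run(rec("HKRAHKR"), self.BPC) == 3

    def test_single_letter_group(self):
        assert max_consecutive_run(rec("AAKAA"), ResidueGroup("a", frozenset("A"))) == 2

    def test_absent_group(self):
        assert max_consecutive_run(rec("DDDD"), self.BPC) == 0


class TestDipeptides:
    def test_hand_count(self):
        counts = dipeptide_occurrences(rec("AQDQDA"))
        qd = ALPHABET.index("Q") * 20 + ALPHABET.index("D")
        assert counts[qd] == 2

    def test_overlapping(self):
        counts = dipeptide_occurrences(rec("AAA"))
        assert counts[0] == 2
        assert counts.sum() == 2

    @given(sequences)
    @settings(max_examples=50, deadline=None)
    def test_counts_sum_to_length_minus_one(self, seq):
        # exhaustive-sum oracle: every adjacent position contributes one count
        assert dipeptide_occurrences(rec(seq)).sum() == len(seq) - 1


class TestPhyschem:
    def test_symmetric_charges(self):
        assert physchem_scalars(rec("KKDD"))["abs_charge_per_residue"] == 0.0

    def test_bpc_frequency(self, registry):
        scalars = physchem_scalars(rec("HKRA"), registry)
        assert scalars["group_frequencies"]["basic_positive"] == 0.75

    def test_pi_matches_root_oracle(self):
        # independent root-finder (brentq) on the same net-charge function
        from scipy.optimize import brentq

        record = rec("GGGGG")
        root = brentq(lambda ph: net_charge(record, ph), 0.0, 14.0, xtol=1e-9)
        assert isoelectric_point(record) == pytest.approx(root, abs=1e-3)
        # frozen value: symmetric termini-only peptide -> (8.6 + 3.6) / 2
        assert isoelectric_point(record) == pytest.approx(6.1, abs=1e-3)

    def test_histidine_counts_positive(self):
        assert physchem_scalars(rec("HA"))["abs_charge_per_residue"] == 0.5


class TestPredictedProperties:
    def test_constant_stub(self, stub_suite):
        values = predicted_properties(rec("MKTAYIAK"), stub_suite)
        assert all(v == 1.0 for v in values.values())
        assert len(values) == 11

    def test_base_change_identity(self):
        suite = PropertyPredictorSuite(
            {
                "logPFR": lambda s: 2.0,
                **{
                    name: (lambda s: 0.0)
                    for name in (
                        "solubility", "unfoldability", "disorder_count",
                        "transmembrane", "exposed_fraction", "contact_number",
                        "helix_propensity", "sheet_propensity", "coil_propensity",
                    )
                },
            }
        )
        values = predicted_properties(rec("MKTAYIAK"), suite)
        assert values["nlogPFR"] == pytest.approx(2.0 * math.log(10), abs=1e-5)
        assert values["nlogPFR"] == pytest.approx(4.60517, abs=1e-5)

    def test_default_identity_holds(self, suite):
        values = predicted_properties(rec("MKTAYIAKQRQISFVKSHFSRQ"), suite)
        assert values["nlogPFR"] == pytest.approx(values["logPFR"] * math.log(10))

    def test_poly_alanine_helix_propensity(self, suite):
        # table-lookup oracle: mean of a constant scale is the scale value
        values = predicted_properties(rec("A" * 20), suite)
        assert values["helix_propensity"] == pytest.approx(CHOU_FASMAN_HELIX["A"])

    def test_failure_names_property(self):
        def boom(seq):
            raise RuntimeError("nope")

        suite = PropertyPredictorSuite({"logPFR": boom})
        with pytest.raises(PropertyUnavailableError) as err:
            predicted_properties(rec("MKTA"), suite)
        assert err.value.property_name == "logPFR"


class TestBaseVector:
    def test_length_122(self, registry, suite):
        assert base_feature_vector(rec("MKTAYIAKQR"), registry, suite).shape == (122,)

    def test_deterministic(self, registry, suite):
        a = base_feature_vector(rec("MKTAYIAKQR"), registry, suite)
        b = base_feature_vector(rec("MKTAYIAKQR", rid="other"), registry, suite)
        assert np.array_equal(a, b)

    def test_reversed_sequence_vs_recomputation(self, registry, suite):
        forward = "MKKTAYIAAKQRQISFVKSHFSRQ"
        reverse = forward[::-1]
        fwd = base_feature_vector(rec(forward), registry, suite)
        rev = base_feature_vector(rec(reverse), registry, suite)
        # composition block identical, run-dependent entries may differ;
        # oracle = direct recomputation on the reversed string
        names = registry.base_names
        freq_idx = [i for i, n in enumerate(names) if n.startswith(("freq_", "gfreq_"))]
        assert np.array_equal(fwd[freq_idx], rev[freq_idx])
        assert np.array_equal(rev, base_feature_vector(rec(reverse, rid="x"), registry, suite))
        assert not np.array_equal(fwd, rev)  # runs differ for this sequence


class TestInteractive:
    def test_zeros(self):
        assert not interactive_features(np.zeros(122)).any()

    def test_product_definition(self):
        base = np.zeros(122)
        base[0], base[1] = 2.0, 3.0
        values = interactive_features(base)
        assert values[0] == 6.0  # pair (0, 1) is first in registry order

    def test_pair_count(self, registry):
        assert interactive_features(np.ones(122)).shape == (7381,)
        assert registry.n_interactive == 122 * 121 // 2

    def test_pair_audit(self, registry):
        pairs = registry.interactive_pairs
        assert len(set(pairs)) == 7381
        assert all(i < j for i, j in pairs)

    def test_wrong_length_rejected(self):
        from periyield.errors import ContractViolationError

        with pytest.raises(ContractViolationError):
            interactive_features(np.ones(50))


class TestFullVector:
    def test_length(self, registry, suite):
        assert full_feature_vector(rec("MKTAYIAKQR"), registry, suite).shape == (7903,)

    def test_arithmetic(self):
        assert 122 + 7381 + 400 == 7903

    def test_blockwise_agreement(self, registry, suite):
        # oracle: independent per-family recomputation
        record = rec("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEV")
        full = full_feature_vector(record, registry, suite)
        base = base_feature_vector(record, registry, suite)
        assert np.array_equal(full[:122], base)
        assert np.array_equal(full[122:7503], interactive_features(base))
        assert np.array_equal(full[7503:], dipeptide_occurrences(record))
        assert np.isfinite(full).all()


class TestNamedSubset:
    def test_classification_has_seven(self, suite):
        assert len(named_subset(rec("MKTAYIAKQR"), "classification", suite)) == 7

    def test_qd_count(self, suite):
        assert named_subset(rec("AQDQDA"), "classification", suite)["QD"] == 2

    def test_high_product(self, suite):
        values = named_subset(rec("TTTFFF"), "reg_high", suite)
        assert values["TxMCPhe"] == pytest.approx(0.5 * 3)

    def test_unknown_task(self, suite):
        with pytest.raises(InvalidArgumentError):
            named_subset(rec("MKTA"), "reg_ultra", suite)

    @pytest.mark.parametrize("task", ["classification", "reg_high", "reg_medium", "reg_low"])
    def test_cross_indexes_into_full_vector(self, task, registry, suite):
        from periyield.sequence_features import SUBSET_SHORT_NAMES, subset_feature_names

        record = rec("MKTAYIAKQDQRQISFVTKSHFSRQLEERCLGLIEVVTQAPILSRVGDY")
        named = named_subset(record, task, suite, registry)
        full = full_feature_vector(record, registry, suite)
        names = subset_feature_names(task, registry)
        assert tuple(named) == SUBSET_SHORT_NAMES[task]
        for short, full_name in zip(named, names):
            assert named[short] == pytest.approx(
                full[registry.index_of(full_name)], rel=1e-12, abs=1e-12
            ), (short, full_name)

    def test_tyrosine_count_variant(self, suite):
        # 25 consecutive I residues guarantee a transmembrane segment
        record = rec("Y" * 5 + "I" * 25)
        freq_variant = named_subset(record, "reg_low", suite)
        count_variant = named_subset(record, "reg_low", suite, tyrosine_count_variant=True)
        assert freq_variant["Yxtransmembrane"] > 0
        # count = frequency * length
        assert count_variant["Yxtransmembrane"] == pytest.approx(
            freq_variant["Yxtransmembrane"] * len(record)
        )


class TestRegistry:
    def test_cardinalities(self, registry):
        assert registry.n_base == 122
        assert registry.n_interactive == 7381
        assert registry.n_dipeptide == 400
        assert registry.n_total == 7903

    def test_unique_names(self, registry):
        names = registry.all_names
        assert len(names) == len(set(names)) == 7903

    def test_miscounted_registry_rejected(self):
        groups = [ResidueGroup("only", frozenset("HKR"))]
        with pytest.raises(InvalidArgumentError, match="122"):
            FeatureRegistry(groups)

    def test_yaml_roundtrip(self, registry, tmp_path):
        path = tmp_path / "registry.yaml"
        registry.to_yaml(path)
        loaded = FeatureRegistry.from_yaml(path)
        assert loaded.all_names == registry.all_names

    def test_unknown_feature_name(self, registry):
        with pytest.raises(InvalidArgumentError):
            registry.index_of("dp_ZZ")


@given(seq=sequences)
@settings(max_examples=25, deadline=None)
def test_extraction_is_pure(registry, suite, seq):
    a = full_feature_vector(rec(seq), registry, suite)
    b = full_feature_vector(rec(seq, rid="again"), registry, suite)
    assert np.array_equal(a, b)
    assert np.isfinite(a).all()
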