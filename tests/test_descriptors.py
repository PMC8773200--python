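"""Descriptor families: hand cases, oracle equivalence and invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import il10pep.descriptors as d
from il10pep import (ALPHABET, DescriptorConfig, LabeledDataset, Peptide,
                     aac, autocorrelation, column_names, ctd, dpc, encode,
                     qso, soc)
from il10pep.errors import ConfigError, DescriptorError
from oracles import (AA, aac_naive, autocorrelation_naive, ctd_naive,
                     dpc_naive, qso_naive, random_peptide, soc_naive)

TOY = d.DistanceMatrix("toy", np.ones((20, 20)) - np.eye(20))  # d(x,y)=1, d(x,x)=0

peptides_st = st.text(alphabet=ALPHABET, min_size=5, max_size=40)


class TestAAC:
    def test_homopolymer(self):
        v = aac("AAAA")
        assert v[0] == 1.0 and v[1:].sum() == 0.0

    def test_uniform(self):
        v = aac("ACDE")
        np.testing.assert_allclose(v[:4], 0.25)
        assert v[4:].sum() == 0

    @given(peptides_st)
    def test_sums_to_one(self, seq):
        assert abs(aac(seq).sum() - 1.0) < 1e-12


class TestDPC:
    def test_homopolymer(self):
        v = dpc("AAA")
        assert v[0] == 1.0 and v.sum() == 1.0

    def test_alternating(self):
        v = dpc("ACAC")
        names = column_names(DescriptorConfig(families=("DPC",)))
        assert v[names.index("DPC.AC")] == pytest.approx(2 / 3)
        assert v[names.index("DPC.CA")] == pytest.approx(1 / 3)

    def test_dimension_is_400(self):
        assert dpc("ACDEFGHIKLMNPQRSTVWY").size == 400

    def test_length_one_rejected(self):
        with pytest.raises(DescriptorError):
            dpc("A")

    @given(peptides_st)
    def test_sums_to_one(self, seq):
        assert abs(dpc(seq).sum() - 1.0) < 1e-12


class TestCTD:
    def test_homogeneous_group(self):
        """KKKK sits entirely in the positive-charge group: C=1, all T=0."""
        schemes = [s for s in d.default_group_schemes()
                   if s.property_name == "charge"]
        v = ctd("KKKK", schemes)
        assert v[0] == 1.0          # group1 = KR composition
        assert v[3:6].tolist() == [0.0, 0.0, 0.0]

    def test_alternating_charge_transitions(self):
        """KDKD: every adjacent pair is a positive<->negative transition."""
        schemes = [s for s in d.default_group_schemes()
                   if s.property_name == "charge"]
        v = ctd("KDKD", schemes)
        # groups: KR, neutral, DE -> K in g1, D in g3; T pairs (12),(13),(23)
        assert v[4] == pytest.approx(1.0)  # T.13 = 3/3

    def test_last_occurrence_is_100_when_group_covers_final_residue(self):
        schemes = [s for s in d.default_group_schemes()
                   if s.property_name == "charge"]
        v = ctd("AAAK", schemes)  # K (g1) is the final residue
        names = [n.split("charge.")[1] for n in
                 column_names(DescriptorConfig(families=("CTD",)))
                 if "charge" in n]
        assert v[names.index("D.g1.p100")] == 100.0

    @given(peptides_st)
    def test_composition_sums_and_distribution_range(self, seq):
        v = ctd(seq)
        per = 21
        for s in range(7):
            block = v[s * per:(s + 1) * per]
            assert abs(block[:3].sum() - 1.0) < 1e-12
            dist = block[6:]
            assert ((dist == 0) | ((dist > 0) & (dist <= 100))).all()

    def test_invalid_partition_rejected(self):
        with pytest.raises(ConfigError):
            d.GroupScheme("bad", ("AC", "DE", "FG"))


class TestSOC:
    def test_homopolymer_zero(self):
        np.testing.assert_allclose(soc("AAAAAA", TOY, 3), 0.0)

    def test_toy_enumeration(self):
        np.testing.assert_allclose(soc("ACAC", TOY, 3), [3.0, 0.0, 1.0])

    def test_lag_too_large(self):
        with pytest.raises(DescriptorError, match="length"):
            soc("ACDE", TOY, 4)


class TestQSO:
    def test_homopolymer(self):
        v = qso("AAAAA", d.load_distance_matrix("grantham"), 3)
        assert v[0] == pytest.approx(1.0)
        assert np.abs(v[1:]).sum() == pytest.approx(0.0)

    def test_hand_case(self):
        # tau1 = 5, tau2 = 0 -> X_21 = 0.1*5 / (1 + 0.1*5) = 1/3
        v = qso("ACACAC", TOY, 2, w=0.1)
        assert v[20] == pytest.approx(1 / 3)
        assert v[21] == 0.0

    @given(peptides_st)
    def test_sums_to_one(self, seq):
        v = qso(seq, d.load_distance_matrix("grantham"), 4)
        assert abs(v.sum() - 1.0) < 1e-12


class TestAutocorrelation:
    def test_constant_property_moreau_broto(self):
        table = d.PropertyTable("const", {a: 1.0 for a in ALPHABET})
        v = autocorrelation("ACDEFG", table, 3, "moreau_broto",
                            standardize=False)
        np.testing.assert_allclose(v, 1.0)

    @pytest.mark.parametrize("kind", ["moran", "geary"])
    def test_homopolymer_zero_variance_convention(self, kind):
        table = d.load_property_table("hydrophobicity")
        v = autocorrelation("AAAAAA", table, 3, kind)
        np.testing.assert_allclose(v, 0.0)

    def test_lag_too_large(self):
        table = d.load_property_table("hydrophobicity")
        with pytest.raises(DescriptorError):
            autocorrelation("ACDE", table, 4)

    def test_unknown_kind(self):
        with pytest.raises(ConfigError):
            autocorrelation("ACDE", d.load_property_table("asa"), 2, "spatial")


@pytest.fixture(scope="module")
def peptides():
    rng = np.random.default_rng(42)
    return [random_peptide(rng, int(rng.integers(5, 41)))
            for _ in range(40)]


class TestOracleEquivalence:
    """Vectorised implementations vs independent naive-loop oracles."""

    def test_aac_dpc(self, peptides):
        for seq in peptides:
            np.testing.assert_allclose(aac(seq), aac_naive(seq), atol=1e-12)
            np.testing.assert_allclose(dpc(seq), dpc_naive(seq), atol=1e-12)

    def test_ctd(self, peptides):
        schemes = d.default_group_schemes()
        for seq in peptides:
            np.testing.assert_allclose(ctd(seq, schemes),
                                       ctd_naive(seq, schemes), atol=1e-12)

    def test_soc_qso(self, peptides):
        dm = d.load_distance_matrix("grantham")
        for seq in peptides:
            np.testing.assert_allclose(soc(seq, dm, 4),
                                       soc_naive(seq, dm, 4), atol=1e-10)
            np.testing.assert_allclose(qso(seq, dm, 4, 0.1),
                                       qso_naive(seq, dm, 4, 0.1), atol=1e-12)

    @pytest.mark.parametrize("kind", ["moreau_broto", "moran", "geary"])
    def test_autocorrelation(self, peptides, kind):
        table = d.load_property_table("hydrophobicity")
        values = dict(zip(ALPHABET, table.standardized()))
        for seq in peptides:
            np.testing.assert_allclose(
                autocorrelation(seq, table, 4, kind),
                autocorrelation_naive(seq, values, 4, kind), atol=1e-12)


class TestVendoredConstants:
    def test_property_tables_standardize_to_unit_moments(self):
        for name in d.DEFAULT_AUTOC_PROPERTIES:
            z = d.load_property_table(name).standardized()
            assert abs(z.mean()) < 1e-9 and abs(z.std() - 1.0) < 1e-9

    def test_distance_matrices_are_metric_like(self):
        for name in d.DEFAULT_DISTANCE_MATRICES:
            m = d.load_distance_matrix(name).d
            assert (m >= 0).all()
            np.testing.assert_allclose(np.diag(m), 0.0, atol=1e-12)
            np.testing.assert_allclose(m, m.T, atol=1e-3)

    def test_seven_group_schemes_partition_alphabet(self):
        schemes = d.default_group_schemes()
        assert len(schemes) == 7
        for s in schemes:
            assert sorted("".join(s.groups)) == sorted(ALPHABET)


class TestEncode:
    def test_family_column_counts(self):
        ds = LabeledDataset([Peptide("a", "ACDEFGHIKLMNPQRS")], np.array([1]))
        assert encode(ds, DescriptorConfig(families=("AAC",))).shape[1] == 20
        assert encode(ds, DescriptorConfig(families=("DPC",))).shape[1] == 400
        assert encode(ds, DescriptorConfig(families=("CTD",))).shape[1] == 147

    def test_full_default_closed_form_count(self):
        cfg = DescriptorConfig()
        L_q, L_s, L_a = cfg.qso_maxlag, cfg.soc_nlag, cfg.autoc_maxlag
        expected = 20 + 400 + 147 + 2 * (20 + L_q) + 2 * L_s + 24 * L_a
        names = column_names(cfg)
        assert len(names) == expected == len(set(names))

    def test_column_names_stable_and_order_canonical(self):
        cfg = DescriptorConfig(families=("DPC", "AAC"))
        names = column_names(cfg)
        assert names[:20] == [f"AAC.{a}" for a in ALPHABET]  # AAC before DPC
        assert names == column_names(cfg)

    def test_encode_is_pure(self, small_dataset):
        cfg = DescriptorConfig()
        a, b = encode(small_dataset, cfg), encode(small_dataset, cfg)
        assert a.equals(b)

    def test_aggregated_error_lists_offenders(self):
        ds = LabeledDataset(
            [Peptide("ok", "ACDEFGHIKLMNPQRS"), Peptide("short1", "ACDE"),
             Peptide("short2", "ACD")],
            np.array([1, 0, 0]))
        with pytest.raises(DescriptorError, match="short1.*short2"):
            encode(ds, DescriptorConfig())

    def test_permutation_sensitivity(self, rng):
        """AAC is order-invariant; the sequence-order families are not."""
        seq = random_peptide(rng, 16)
        perm = "".join(rng.permutation(list(seq)))
        assert perm != seq
        np.testing.assert_allclose(aac(seq), aac(perm))
        dm = d.load_distance_matrix("grantham")
        table = d.load_property_table("hydrophobicity")
        assert not np.allclose(dpc(seq), dpc(perm))
        assert not np.allclose(soc(seq, dm, 4), soc(perm, dm, 4))
        assert not np.allclose(qso(seq, dm, 4), qso(perm, dm, 4))
        assert not np.allclose(autocorrelation(seq, table, 4),
                               autocorrelation(perm, table, 4))

    def test_wide_preset_raises_lags(self):
        cfg = DescriptorConfig.wide()
        assert cfg.qso_maxlag == cfg.soc_nlag == cfg.autoc_maxlag == 30
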