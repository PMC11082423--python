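"""Reading, validation, harmonization and instrument selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_assoc
from mrmediate.errors import (
    ConfigurationError,
    EmptyInputError,
    EmptyOverlapError,
    LDCoverageError,
)
from mrmediate.sumstats import (
    LDMatrix,
    harmonize,
    load_column_map,
    read_gwas_table,
    select_instruments,
)

TABLE = """variant_id\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn
rs1\tA\tG\t0.3\t0.10\t0.01\t1e-20\t1000
rs2\tC\tT\t0.2\t-0.05\t0.02\t0.01\t1000
rs3\tG\tA\t0.4\t0.02\t0.01\t0.04\t1000
"""


def test_read_well_formed_table(tmp_path):
    path = tmp_path / "x.tsv"
    path.write_text(TABLE)
    assoc = read_gwas_table(path, trait_id="bmi")
    assert assoc.trait_id == "bmi"
    assert assoc.n_variants == 3
    assert assoc.load_report.n_rejected == 0
    np.testing.assert_allclose(assoc.table["beta"], [0.10, -0.05, 0.02])


def test_invalid_rows_skipped_and_counted(tmp_path):
    bad = TABLE + "rs4\tA\tG\t0.3\t0.10\t0\t0.01\t1000\n"  # se = 0
    path = tmp_path / "x.tsv"
    path.write_text(bad)
    assoc = read_gwas_table(path, trait_id="bmi")
    assert assoc.n_variants == 3
    assert assoc.load_report.n_rejected == 1
    assert assoc.load_report.reasons.get("nonpositive_se") == 1


def test_column_map_equivalence(tmp_path, rng):
    alt = TABLE.replace("variant_id", "SNP").replace("effect_allele", "EA").replace(
        "other_allele", "OA"
    )
    p1, p2 = tmp_path / "canon.tsv", tmp_path / "alt.tsv"
    p1.write_text(TABLE)
    p2.write_text(alt)
    cmap = {"variant_id": "SNP", "effect_allele": "EA", "other_allele": "OA"}
    a = read_gwas_table(p1, trait_id="t")
    b = read_gwas_table(p2, column_map=cmap, trait_id="t")
    pd.testing.assert_frame_equal(a.table, b.table)


def test_column_map_yaml_roundtrip(tmp_path):
    import yaml

    path = tmp_path / "map.yaml"
    path.write_text(yaml.safe_dump({"variant_id": "SNP"}))
    assert load_column_map(path) == {"variant_id": "SNP"}


def test_missing_mandatory_column_raises(tmp_path):
    path = tmp_path / "x.tsv"
    path.write_text("variant_id\tbeta\nrs1\t0.1\n")
    with pytest.raises(ConfigurationError, match="effect_allele"):
        read_gwas_table(path, trait_id="t")


def test_all_rows_invalid_raises(tmp_path):
    path = tmp_path / "x.tsv"
    path.write_text(
        "variant_id\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn\n"
        "rs1\tA\tA\t0.3\t0.1\t0.01\t0.5\t10\n"
    )
    with pytest.raises(EmptyInputError):
        read_gwas_table(path, trait_id="t")


def test_or_column_log_transform(tmp_path):
    path = tmp_path / "x.tsv"
    path.write_text(TABLE)
    raw = read_gwas_table(path, trait_id="t")
    path2 = tmp_path / "or.tsv"
    df = raw.table.copy()
    df["beta"] = np.exp(df["beta"])
    df.to_csv(path2, sep="\t", index=False)
    logged = read_gwas_table(path2, trait_id="t", beta_is_or=True)
    np.testing.assert_allclose(logged.table["beta"], raw.table["beta"], atol=1e-12)


class TestSelectInstruments:
    def test_significance_threshold(self):
        assoc = make_assoc("t", [0.1, 0.1], 0.01, pval=[1e-9, 1e-7])
        kept = select_instruments(assoc, 5e-8)
        assert kept.variant_ids == ["rs0"]

    def test_greedy_keeps_smaller_p_of_correlated_pair(self):
        assoc = make_assoc("t", [0.1, 0.1], 0.01, pval=[1e-9, 1e-10])
        ld = LDMatrix(["rs0", "rs1"], [[1.0, 0.5], [0.5, 1.0]])
        kept = select_instruments(assoc, 5e-8, ld, 0.001)
        assert kept.variant_ids == ["rs1"]

    def test_matches_brute_force_greedy(self, rng):
        k = 10
        pvals = rng.uniform(1e-12, 1e-9, k)
        assoc = make_assoc("t", np.full(k, 0.1), 0.01, pval=pvals)
        a = rng.uniform(size=(k, k))
        r2 = (a + a.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = LDMatrix(assoc.variant_ids, r2)
        kept = select_instruments(assoc, 5e-8, ld, 0.4)
        # brute force: same greedy definition written independently
        order = sorted(range(k), key=lambda i: (pvals[i], assoc.variant_ids[i]))
        expected = []
        for i in order:
            if all(r2[i, j] < 0.4 for j in expected):
                expected.append(i)
        assert set(kept.variant_ids) == {assoc.variant_ids[i] for i in expected}

    def test_row_order_invariance(self, rng):
        k = 8
        pvals = rng.uniform(1e-12, 1e-9, k)
        assoc = make_assoc("t", np.full(k, 0.1), 0.01, pval=pvals)
        a = rng.uniform(size=(k, k))
        r2 = (a + a.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = LDMatrix(assoc.variant_ids, r2)
        kept1 = select_instruments(assoc, 5e-8, ld, 0.3)
        shuffled = make_assoc(
            "t",
            np.full(k, 0.1),
            0.01,
            variant_ids=list(reversed(assoc.variant_ids)),
            pval=list(reversed(pvals)),
        )
        kept2 = select_instruments(shuffled, 5e-8, ld, 0.3)
        assert kept1.variant_ids == kept2.variant_ids

    def test_missing_ld_coverage_raises(self):
        assoc = make_assoc("t", [0.1, 0.1], 0.01, pval=[1e-9, 1e-10])
        ld = LDMatrix(["rs0"], [[1.0]])
        with pytest.raises(LDCoverageError):
            select_instruments(assoc, 5e-8, ld, 0.001)

    def test_no_ld_warns_and_skips_pruning(self):
        assoc = make_assoc("t", [0.1, 0.1], 0.01, pval=[1e-9, 1e-10])
        with pytest.warns(UserWarning, match="pruning"):
            kept = select_instruments(assoc, 5e-8, None)
        assert len(kept.variant_ids) == 2


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_beta(self):
        expo = make_assoc("x", [0.1], 0.01, effect_allele=["A"], other_allele=["G"])
        outc = make_assoc("y", [0.2], 0.01, effect_allele=["G"], other_allele=["A"])
        data = harmonize([expo], outc)
        assert data.by[0] == pytest.approx(-0.2)

    def test_strand_complement_aligned(self):
        expo = make_assoc("x", [0.1], 0.01, effect_allele=["A"], other_allele=["G"])
        outc = make_assoc("y", [0.2], 0.01, effect_allele=["T"], other_allele=["C"])
        data = harmonize([expo], outc)
        assert data.by[0] == pytest.approx(0.2)

    def test_disjoint_variants_raise(self):
        expo = make_assoc("x", [0.1], 0.01, variant_ids=["rs0"])
        outc = make_assoc("y", [0.2], 0.01, variant_ids=["rs9"])
        with pytest.raises(EmptyOverlapError):
            harmonize([expo], outc)

    def test_palindromic_mid_frequency_dropped(self):
        expo2 = make_assoc(
            "x",
            [0.1, 0.3],
            0.01,
            effect_allele=["A", "C"],
            other_allele=["T", "G"],
            eaf=[0.50, 0.2],
        )
        outc2 = make_assoc(
            "y",
            [0.2, 0.1],
            0.01,
            effect_allele=["A", "C"],
            other_allele=["T", "G"],
            eaf=[0.50, 0.2],
        )
        data = harmonize([expo2], outc2)
        assert data.variant_ids == ["rs1"]
        assert ("rs0", "palindromic_ambiguous") in data.dropped

    def test_palindromic_resolved_by_frequency(self):
        # frequencies on opposite sides of 0.5: other study reports the flip
        expo = make_assoc(
            "x", [0.1], 0.01, effect_allele=["A"], other_allele=["T"], eaf=[0.2]
        )
        outc = make_assoc(
            "y", [0.2], 0.01, effect_allele=["A"], other_allele=["T"], eaf=[0.8]
        )
        data = harmonize([expo], outc)
        assert data.by[0] == pytest.approx(-0.2)

    def test_irreconcilable_alleles_dropped(self):
        expo = make_assoc(
            "x", [0.1, 0.1], 0.01, effect_allele=["A", "A"], other_allele=["G", "G"]
        )
        outc = make_assoc(
            "y", [0.2, 0.2], 0.01, effect_allele=["A", "A"], other_allele=["C", "G"]
        )
        data = harmonize([expo], outc)
        assert data.variant_ids == ["rs1"]
        assert ("rs0", "allele_mismatch") in data.dropped

    def test_missing_in_outcome_recorded(self):
        expo = make_assoc("x", [0.1, 0.2], 0.01)
        outc = make_assoc("y", [0.2], 0.01, variant_ids=["rs0"])
        data = harmonize([expo], outc)
        assert ("rs1", "missing_in_outcome") in data.dropped

    def test_aligned_input_identity(self, rng):
        expo = make_assoc("x", rng.normal(0, 0.1, 5), 0.01)
        outc = make_assoc("y", rng.normal(0, 0.1, 5), 0.02)
        data = harmonize([expo], outc)
        np.testing.assert_allclose(data.bx[:, 0], expo.table["beta"])
        np.testing.assert_allclose(data.by, outc.table["beta"])

    def test_idempotent(self, rng):
        eaf = rng.uniform(0.05, 0.45, 6)
        expo = make_assoc(
            "x",
            rng.normal(0, 0.1, 6),
            0.01,
            effect_allele=["A", "C", "G", "T", "A", "C"],
            other_allele=["G", "T", "A", "C", "C", "A"],
            eaf=eaf,
        )
        outc = make_assoc(
            "y",
            rng.normal(0, 0.1, 6),
            0.02,
            effect_allele=["G", "T", "A", "C", "A", "C"],
            other_allele=["A", "C", "G", "T", "C", "A"],
            eaf=np.where([1, 1, 1, 1, 0, 0], 1 - eaf, eaf),
        )
        once = harmonize([expo], outc)
        again = harmonize(
            [once.exposure_as_association_set(0)], once.outcome_as_association_set()
        )
        assert once.variant_ids == again.variant_ids
        np.testing.assert_allclose(once.bx, again.bx, atol=1e-12)
        np.testing.assert_allclose(once.by, again.by, atol=1e-12)

    @given(flip=st.lists(st.booleans(), min_size=4, max_size=4))
    def test_allele_flip_invariance(self, flip):
        """Swapping allele labels and negating betas in the outcome leaves the
        harmonized data unchanged."""
        rng = np.random.default_rng(7)
        beta_x = rng.normal(0, 0.1, 4)
        beta_y = rng.normal(0, 0.1, 4)
        ea, oa = ["A", "C", "G", "T"], ["G", "T", "A", "C"]
        expo = make_assoc("x", beta_x, 0.01, effect_allele=ea, other_allele=oa)
        outc1 = make_assoc("y", beta_y, 0.02, effect_allele=ea, other_allele=oa)
        ea2 = [o if f else e for e, o, f in zip(ea, oa, flip)]
        oa2 = [e if f else o for e, o, f in zip(ea, oa, flip)]
        beta2 = [-b if f else b for b, f in zip(beta_y, flip)]
        outc2 = make_assoc("y", beta2, 0.02, effect_allele=ea2, other_allele=oa2)
        d1 = harmonize([expo], outc1)
        d2 = harmonize([expo], outc2)
        np.testing.assert_allclose(d1.by, d2.by, atol=1e-12)


class TestLDMatrix:
    def test_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            LDMatrix(["a", "b"], [[1.0, 0.5], [0.4, 1.0]])
        with pytest.raises(ValueError, match="diagonal"):
            LDMatrix(["a", "b"], [[0.9, 0.5], [0.5, 1.0]])

    def test_read_write_roundtrip(self, tmp_path):
        ld = LDMatrix.block(["a", "b", "c", "d"], 2, 0.9)
        path = tmp_path / "ld.tsv"
        ld.write(path)
        back = LDMatrix.read(path)
        assert back.variant_ids == ld.variant_ids
        np.testing.assert_allclose(back.r2, ld.r2)
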