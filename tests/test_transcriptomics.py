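"""DE-table reading, gene/gene-set classification, and purpose consensus."""

import math

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from shunt_ledger.errors import ConfigurationError, SchemaError, ValidationError
from shunt_ledger.transcriptomics import (DETable, Dialect, GeneSet,
                                          ModelProfile, PurposeRule, Verdict,
                                          classify_gene, classify_gene_set,
                                          consensus, read_de_table,
                                          write_de_table)

M1 = ModelProfile("model1", 1e-6, 1.0)
M2 = ModelProfile("model2", 0.05, 0.0)


def make_table(rows, model_id="model1"):
    df = pd.DataFrame(rows, columns=["gene", "fc", "padj", "expr"]).set_index("gene")
    return DETable(model_id=model_id, data=df)


class TestReadDETable:
    def test_ratio_dialect_round_trip(self, tmp_path):
        t = make_table([("PHGDH", 3.0, 1e-9, 50.0), ("PSAT1", 0.4, 1e-8, 20.0)])
        dest = tmp_path / "m1.tsv"
        write_de_table(t, dest, header_comment="seed=0")
        t2 = read_de_table(dest, model_id="model1")
        pd.testing.assert_frame_equal(t.data, t2.data)

    def test_log2_dialect_converts_to_ratio(self, tmp_path):
        dest = tmp_path / "log2.tsv"
        dest.write_text("gene\tlog2fc\tq\n" "A\t1\t0.001\n" "B\t-1\t0.5\n")
        t = read_de_table(dest, Dialect(fc="log2fc", padj="q", log2_fc=True))
        assert t.data.loc["A", "fc"] == 2.0
        assert t.data.loc["B", "fc"] == 0.5
        assert math.isinf(t.data.loc["A", "expr"])  # no expression column

    def test_duplicate_gene_is_an_error(self, tmp_path):
        dest = tmp_path / "dup.tsv"
        dest.write_text("gene\tfc\tpadj\nPHGDH\t2\t0.1\nPHGDH\t3\t0.2\n")
        with pytest.raises(ValidationError, match="PHGDH"):
            read_de_table(dest)

    def test_missing_column_is_an_error(self, tmp_path):
        dest = tmp_path / "short.tsv"
        dest.write_text("gene\tfc\nA\t2\n")
        with pytest.raises(SchemaError, match="padj"):
            read_de_table(dest)

    def test_invalid_values_are_errors(self):
        with pytest.raises(ValidationError, match="fold changes"):
            make_table([("A", -2.0, 0.5, 10.0)])
        with pytest.raises(ValidationError, match="padj"):
            make_table([("A", 2.0, 1.5, 10.0)])


class TestClassifyGene:
    @pytest.mark.parametrize("fc,padj,expr,profile,expected", [
        (3.0, 1e-9, 50.0, M1, "induced"),
        (3.0, 1e-3, 50.0, M1, "unchanged"),   # significant only per model 2
        (3.0, 1e-3, 50.0, M2, "induced"),     # thresholds are model-local
        (0.4, 1e-8, 50.0, M1, "suppressed"),
        (1.0, 1e-9, 50.0, M1, "unchanged"),   # no direction at fc == 1
        (3.0, 1e-9, 0.5, M1, "low_expression"),
        (3.0, 1e-9, 0.5, M2, "induced"),      # model 2 has no expression floor
    ])
    def test_gene_status(self, fc, padj, expr, profile, expected):
        assert classify_gene(fc, padj, expr, profile) == expected

    @given(st.floats(1e-12, 1.0), st.floats(0.1, 10.0))
    def test_relaxing_threshold_never_unmakes_an_induced_call(self, padj, fc):
        """Threshold monotonicity: induced at 1e-6 implies induced at 0.05."""
        strict = classify_gene(fc, padj, 50.0, M1)
        lax = classify_gene(fc, padj, 50.0, ModelProfile("x", 0.05, 1.0))
        if strict == "induced":
            assert lax == "induced"
        if lax == "unchanged":
            assert strict in ("unchanged",)


SERINO = GeneSet("shunt_serinogenesis", ("PHGDH", "PSAT1", "PSPH", "SFXN1"))


class TestClassifyGeneSet:
    def test_all_induced(self):
        t = make_table([(g, 4.0, 1e-9, 50.0) for g in SERINO.genes])
        v = classify_gene_set(t, SERINO, M1)
        assert v.status == "induced"
        assert set(v.gene_statuses) == set(SERINO.genes)

    def test_majority_induced_none_suppressed(self):
        t = make_table([("PHGDH", 4.0, 1e-9, 50.0), ("PSAT1", 4.0, 1e-9, 50.0),
                        ("PSPH", 1.1, 0.5, 50.0), ("SFXN1", 0.9, 0.5, 50.0)])
        assert classify_gene_set(t, SERINO, M1).status == "induced"

    def test_minority_induced_is_unchanged(self):
        t = make_table([("PHGDH", 4.0, 1e-9, 50.0), ("PSAT1", 1.0, 0.5, 50.0),
                        ("PSPH", 1.1, 0.5, 50.0), ("SFXN1", 0.9, 0.5, 50.0)])
        assert classify_gene_set(t, SERINO, M1).status == "unchanged"

    def test_opposing_members_are_mixed(self):
        t = make_table([("PHGDH", 4.0, 1e-9, 50.0), ("PSAT1", 0.3, 1e-9, 50.0)])
        assert classify_gene_set(t, SERINO, M1).status == "mixed"

    def test_all_low_members_give_low_expression(self):
        t = make_table([(g, 2.0, 1e-9, 0.1) for g in SERINO.genes])
        assert classify_gene_set(t, SERINO, M1).status == "low_expression"

    def test_low_members_are_excluded_from_the_denominator(self):
        t = make_table([("PHGDH", 4.0, 1e-9, 0.1), ("PSAT1", 4.0, 1e-9, 0.1),
                        ("PSPH", 4.0, 1e-9, 50.0), ("SFXN1", 1.0, 0.9, 50.0)])
        assert classify_gene_set(t, SERINO, M1).status == "induced"

    def test_missing_genes_are_skipped_not_imputed(self):
        t = make_table([("PHGDH", 4.0, 1e-9, 50.0), ("PSAT1", 4.0, 1e-9, 50.0)])
        v = classify_gene_set(t, SERINO, M1)
        assert v.status == "induced"
        assert v.missing_genes == ("PSPH", "SFXN1")

    def test_entirely_absent_set_is_an_error(self):
        t = make_table([("GAPDH", 1.0, 0.9, 50.0)])
        with pytest.raises(ValidationError, match="no member present"):
            classify_gene_set(t, SERINO, M1)


def _verdict(geneset, model, status):
    return Verdict(geneset, model, status, {})


class TestConsensus:
    RULES = (
        PurposeRule("needs_a", all_induced=("set_a",)),
        PurposeRule("needs_any", any_induced=("set_a", "set_b")),
    )

    def test_universal_partial_rejected(self):
        verdicts = [
            _verdict("set_a", "m1", "induced"), _verdict("set_b", "m1", "unchanged"),
            _verdict("set_a", "m2", "induced"), _verdict("set_b", "m2", "unchanged"),
        ]
        rep = consensus(verdicts, self.RULES, known_genesets=["set_a", "set_b"])
        assert rep.classification == {"needs_a": "universal", "needs_any": "universal"}

        verdicts[2] = _verdict("set_a", "m2", "unchanged")
        rep = consensus(verdicts, self.RULES, known_genesets=["set_a", "set_b"])
        assert rep.classification["needs_a"] == "partial"

    def test_all_unchanged_rejects_every_purpose(self):
        verdicts = [_verdict("set_a", m, "unchanged") for m in ("m1", "m2")]
        verdicts += [_verdict("set_b", m, "unchanged") for m in ("m1", "m2")]
        rep = consensus(verdicts, self.RULES, known_genesets=["set_a", "set_b"])
        assert set(rep.classification.values()) == {"rejected"}

    def test_suppression_contradicts(self):
        verdicts = [_verdict("set_a", "m1", "suppressed"),
                    _verdict("set_b", "m1", "induced")]
        rep = consensus(verdicts, self.RULES, known_genesets=["set_a", "set_b"])
        assert rep.model_status["needs_a"]["m1"] == "contradicted"
        assert rep.classification["needs_a"] == "rejected"
        # any_induced still satisfied by set_b... but set_a suppression
        # contradicts the purpose that references it
        assert rep.model_status["needs_any"]["m1"] == "contradicted"

    def test_single_model_is_flagged(self):
        rep = consensus([_verdict("set_a", "m1", "induced")], self.RULES,
                        known_genesets=["set_a", "set_b"])
        assert any("single-model" in f for f in rep.flags)

    def test_unknown_gene_set_in_rule_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError, match="set_z"):
            consensus([_verdict("set_a", "m1", "induced")],
                      (PurposeRule("bad", all_induced=("set_z",)),),
                      known_genesets=["set_a"])
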