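"""Strand assignment rules and count-tensor assembly, including the
end-to-end pipeline on the planted-truth toy fixture."""

import numpy as np
import pandas as pd
import pytest

from tensorsig.catalogue import (
    DEFAULT_AXIS_LABELS,
    AnnotatedVariant,
    CountTensor,
    assign_replication_state,
    assign_transcription_state,
    build_count_tensor,
)
from tensorsig.channels import VariantRecord, classify_snv


def _annotated(sample="S0", channel=0, **states):
    v = VariantRecord("chr1", 100, "C", "T", sample)
    return AnnotatedVariant(v, channel, **states)


class TestStrandAssignment:
    def test_g_to_a_in_minus_gene_is_coding(self):
        # the mutated G sits on the template strand, so the pyrimidine C
        # of the pair lies on the coding (-) strand of a trx(-) gene
        _, pyr_plus = classify_snv(VariantRecord("c", 5, "G", "A", "S"), "A", "A")
        assert assign_transcription_state(pyr_plus, {"-"}) == "coding"

    def test_c_to_t_in_minus_gene_is_template(self):
        _, pyr_plus = classify_snv(VariantRecord("c", 5, "C", "T", "S"), "A", "A")
        assert assign_transcription_state(pyr_plus, {"-"}) == "template"

    def test_bidirectional_locus_is_unknown(self):
        assert assign_transcription_state(True, {"+", "-"}) == "unknown"

    def test_intergenic_is_unknown(self):
        assert assign_transcription_state(True, set()) == "unknown"

    def test_c_variant_in_rep_plus_is_leading(self):
        assert assign_replication_state(True, "rep+") == "leading"

    def test_g_variant_in_rep_plus_is_lagging(self):
        assert assign_replication_state(False, "rep+") == "lagging"

    def test_star_region_is_unknown(self):
        assert assign_replication_state(True, "*") == "unknown"
        assert assign_replication_state(True, None) == "unknown"


class TestBuildCountTensor:
    def test_empty_input_gives_zero_tensor(self):
        tensor, other = build_count_tensor([], ["S0", "S1"])
        assert tensor.counts.shape == (3, 3, 16, 4, 2, 96, 2)
        assert tensor.counts.sum() == 0
        assert tensor.n_state_combinations == 1152

    def test_single_snv_single_entry(self):
        tensor, _ = build_count_tensor(
            [_annotated(tx_state="coding", rep_state="lagging",
                        epi_state="Tx", nuc_state="linker",
                        clu_state="clustered", channel=17)],
            ["S0"],
        )
        assert tensor.counts.sum() == 1
        idx = np.argwhere(tensor.counts == 1)
        assert len(idx) == 1
        labels = DEFAULT_AXIS_LABELS
        i, j, e, u, c, ch, n = idx[0]
        assert labels["transcription"][i] == "coding"
        assert labels["replication"][j] == "lagging"
        assert labels["epigenome"][e] == "Tx"
        assert labels["nucleosome"][u] == "linker"
        assert labels["cluster"][c] == "clustered"
        assert ch == 17

    def test_unknown_sample_rejected(self):
        with pytest.raises(KeyError):
            build_count_tensor([_annotated(sample="nope")], ["S0"])

    def test_non_snvs_go_to_other_matrix(self):
        mnv = AnnotatedVariant(
            VariantRecord("chr1", 5, "CC", "TT", "S0"), None,
            other_category="mnv.CC>TT",
        )
        tensor, other = build_count_tensor([mnv, _annotated()], ["S0"])
        assert tensor.counts.sum() == 1
        assert other.counts.sum() == 1
        assert other.category_labels == ["mnv.CC>TT"]

    def test_state_axis_product(self):
        tensor, _ = build_count_tensor([], ["S0"])
        sizes = tensor.counts.shape[:5]
        assert np.prod(sizes) == 1152
        assert np.prod(sizes[:4]) == 576  # without the cluster axis


@pytest.fixture(scope="module")
def prepared(variant_fixture):
    from tensorsig.io import prepare

    tensor, other, annotations = prepare(
        variant_fixture.vcf,
        variant_fixture.fasta,
        genes=variant_fixture.genes_bed,
        repliseq=variant_fixture.repliseq_bedgraphs,
        chromhmm=variant_fixture.chromhmm_beds,
        dyads=variant_fixture.dyads_bed,
    )
    return tensor, other, annotations


class TestPipelineOnFixture:
    """The catalogue applied to the toy genome must reproduce the planted
    per-variant truth exactly."""

    def test_all_variants_catalogued(self, variant_fixture, prepared):
        tensor, other, _ = prepared
        assert tensor.counts.sum() + other.counts.sum() == len(variant_fixture.truth)

    def test_channels_match_planted_truth(self, variant_fixture, prepared):
        _, _, ann = prepared
        merged = variant_fixture.truth.merge(
            ann, on=["sample_id", "chrom", "pos"], suffixes=("_true", "")
        )
        assert len(merged) == len(variant_fixture.truth)
        assert (merged["channel_true"] == merged["channel"]).all()

    @pytest.mark.parametrize("state", ["tx", "rep", "epi", "nuc"])
    def test_states_match_planted_truth(self, variant_fixture, prepared, state):
        _, _, ann = prepared
        merged = variant_fixture.truth.merge(
            ann, on=["sample_id", "chrom", "pos"], suffixes=("_true", "")
        )
        mismatches = merged[merged[f"{state}_true"] != merged[state]]
        assert mismatches.empty, mismatches.head()

    def test_marginals_equal_truth_tallies(self, variant_fixture, prepared):
        tensor, _, _ = prepared
        truth = variant_fixture.truth
        label_cols = {"transcription": "tx", "replication": "rep",
                      "epigenome": "epi", "nucleosome": "nuc"}
        for axis, col in label_cols.items():
            marg = tensor.marginal(axis).sum(axis=-1)
            expected = truth[col].value_counts()
            for label, count in expected.items():
                li = tensor.axis_labels[axis].index(label)
                assert marg[li] == count, (axis, label)

    def test_conservation_per_sample(self, variant_fixture, prepared):
        tensor, other, _ = prepared
        per_sample = tensor.per_sample_totals() + other.counts.sum(axis=0)
        truth_counts = variant_fixture.truth["sample_id"].value_counts()
        for sid, total in zip(tensor.sample_ids, per_sample):
            assert total == truth_counts[sid]
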