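"""Coding-potential heuristic and positional lncRNA classification."""

import numpy as np
import pytest

from isoannot.lncrna import (
    HexamerModel,
    classify_position,
    coding_potential,
    lncrna_summary,
    longest_orf,
)
from isoannot.model import Annotation, GeneLocus

from conftest import make_tx


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _codingish(rng, n_codons, weights, codons):
    idx = rng.choice(len(codons), size=n_codons, p=weights)
    return "ATG" + "".join(codons[i] for i in idx)


@pytest.fixture(scope="module")
def coding_model():
    rng = np.random.default_rng(42)
    stops = {"TAA", "TAG", "TGA"}
    codons = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in stops
    ]
    w = np.exp(rng.normal(0, 1, size=len(codons)))
    w /= w.sum()
    training = [_codingish(rng, 300, w, codons) for _ in range(50)]
    return rng, codons, w, training, HexamerModel(training)


def test_longest_orf_basics():
    assert longest_orf("CCCCCCCCC") == 0  # no ATG
    assert longest_orf("ATGAAATTTTAA") == 3  # ATG AAA TTT stop
    assert longest_orf("ATGAAA") == 2  # open 3' end
    # ORF found in a shifted frame
    assert longest_orf("CATGAAATTTTAA") == 3


def test_no_start_codon_is_noncoding(coding_model):
    *_, model = coding_model
    seq = "C" * 300
    call = coding_potential("t", seq, model)
    assert call.orf_codons == 0 and call.call == "noncoding"


def test_planted_long_orf_is_coding(coding_model):
    rng, codons, w, training, model = coding_model
    seq = _codingish(rng, 300, w, codons)
    call = coding_potential("t", seq, model)
    assert call.orf_codons >= 100 and call.call == "coding"


def test_short_sequences_never_called_noncoding(coding_model):
    *_, model = coding_model
    call = coding_potential("t", "C" * 150, model, min_lnc_length=200)
    assert call.call == "coding"  # excluded from the lncRNA set


def test_empty_training_set_rejected():
    with pytest.raises(ValueError):
        HexamerModel([])


def test_hexamer_classifier_separates_coding_from_random(coding_model):
    """Sequences simulated from the training codon model vs uniform-random
    sequences of equal length: classification accuracy > 0.9 (n=200 each)."""
    rng, codons, w, training, model = coding_model
    n = 200
    correct = 0
    for _ in range(n):
        seq = _codingish(rng, 100, w, codons)[: 303]
        if model.score(seq) >= 0:
            correct += 1
    for _ in range(n):
        seq = _random_seq(rng, 303)
        if model.score(seq) < 0:
            correct += 1
    assert correct / (2 * n) > 0.9


def _ref():
    host = make_tx("r1", [(1000, 1200), (2000, 2200), (3000, 3200)], "+")
    return Annotation([GeneLocus("host", "chr1", "+", [host])])


def test_position_intronic():
    t = make_tx("t", [(1300, 1700)], "+")
    pc = classify_position(t, _ref())
    assert pc.position_class == "intronic" and pc.anchor_gene_id == "host"
    # either strand counts as intronic
    assert classify_position(make_tx("t", [(1300, 1700)], "-"), _ref()).position_class == "intronic"


def test_position_sense_and_antisense():
    sense = make_tx("t", [(1100, 1500)], "+")
    anti = make_tx("t", [(1100, 1500)], "-")
    assert classify_position(sense, _ref()).position_class == "sense"
    assert classify_position(anti, _ref()).position_class == "antisense"


def test_position_intergenic():
    t = make_tx("t", [(10_000, 10_400)], "+")
    assert classify_position(t, _ref()).position_class == "intergenic"


def test_intronic_outranks_exonic_overlap():
    """A transcript inside one gene's intron that also matches the intronic
    definition never becomes sense/antisense."""
    t = make_tx("t", [(1300, 1700)], "+")
    for ann in (_ref(),):
        assert classify_position(t, ann).position_class == "intronic"


def test_reference_order_never_changes_calls(rng):
    host1 = make_tx("r1", [(1000, 1200), (2000, 2200)], "+")
    host2 = make_tx("r2", [(1050, 1250), (1900, 2100)], "-")
    genes = [
        GeneLocus("a", "chr1", "+", [host1]),
        GeneLocus("b", "chr1", "-", [host2]),
    ]
    t = make_tx("t", [(1100, 1500)], "+")
    calls = set()
    for order in ([0, 1], [1, 0]):
        ann = Annotation([genes[i] for i in order])
        pc = classify_position(t, ann)
        calls.add((pc.position_class, pc.anchor_gene_id))
    assert len(calls) == 1


def test_classes_partition_total():
    classes = [
        classify_position(make_tx(f"t{i}", [(10_000 + 500 * i, 10_300 + 500 * i)]), _ref())
        for i in range(5)
    ]
    out = lncrna_summary(classes)
    assert sum(d["count"] for d in out["classes"].values()) == out["total"]
    assert out["classes"]["intergenic"]["count"] == 5
    assert out["classes"]["intergenic"]["pct"] == 100.0


def test_pipeline_noncoding_and_classes_match_truth(clean_sim):
    """On the noise-free simulation the noncoding set and every positional
    class are recovered exactly."""
    from isoannot.lncrna import call_noncoding
    from isoannot.model import spliced_sequence

    from conftest import collapsed_to_truth

    cfg, ann, genome, truth, reads, result = clean_sim
    mapping = collapsed_to_truth(result, reads, truth)
    training = [
        spliced_sequence(t, genome)
        for g in ann
        for t in g.members
        if t.id in truth.coding_transcripts
    ]
    calls = call_noncoding(result.isoforms, genome, training)
    found_nc = {
        mapping[c.transcript_id] for c in calls if c.call == "noncoding"
    }
    assert found_nc == set(truth.lncrna_class)
    coding_ref = Annotation(
        [g for g in ann if g.members[0].id in truth.coding_transcripts]
    )
    by_id = {t.id: t for t in result.isoforms}
    for c in calls:
        if c.call != "noncoding":
            continue
        pc = classify_position(by_id[c.transcript_id], coding_ref)
        assert pc.position_class == truth.lncrna_class[mapping[c.transcript_id]]


def test_external_calls_override(clean_sim):
    from isoannot.lncrna import call_noncoding

    cfg, ann, genome, truth, reads, result = clean_sim
    forced = {result.isoforms[0].id: "noncoding"}
    calls = call_noncoding(
        result.isoforms[:1], genome, ["ATGAAA" * 50], external_calls=forced
    )
    assert calls[0].call == "noncoding"
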