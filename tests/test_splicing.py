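"""Alternative-splicing event extraction, typing and counting."""

import numpy as np
import pytest

from isoannot.model import GeneLocus
from isoannot.splicing import (
    count_by_sample,
    event_counts,
    gene_events,
    pairwise_events,
)

from conftest import make_tx


def ev_set(t1, t2):
    return {(e.type, e.region, e.anchors) for e in pairwise_events(t1, t2)}


@pytest.mark.parametrize(
    "ex1, ex2, expected",
    [
        # intron retention: one chain's intron fully exonic in the other
        ([(0, 100), (200, 300)], [(0, 300)], [("IR", (100, 200))]),
        # exon skipping
        (
            [(0, 100), (200, 300), (400, 500)],
            [(0, 100), (400, 500)],
            [("ES", (200, 300))],
        ),
        # alternative donor on "+": donor 100 vs 120
        ([(0, 100), (200, 300)], [(0, 120), (200, 300)], [("AD", (100, 120))]),
        # alternative acceptor on "+": acceptor 200 vs 220
        ([(0, 100), (200, 300)], [(0, 100), (220, 300)], [("AA", (200, 220))]),
        # mutually exclusive exons
        (
            [(0, 100), (200, 250), (400, 500)],
            [(0, 100), (300, 350), (400, 500)],
            [("MEE", (200, 350))],
        ),
        # identical chains: nothing
        ([(0, 100), (200, 300)], [(0, 100), (200, 300)], []),
        # two independent events in one pair
        (
            [(0, 100), (200, 300), (400, 500), (600, 700)],
            [(0, 100), (400, 500), (600, 700)],
            [("ES", (200, 300))],
        ),
    ],
)
def test_pairwise_event_typing(ex1, ex2, expected):
    t1, t2 = make_tx("a", ex1), make_tx("b", ex2)
    got = sorted((e.type, e.region) for e in pairwise_events(t1, t2))
    assert got == sorted(expected)


def test_double_skip_is_complex_not_mistyped():
    t1 = make_tx("a", [(0, 100), (200, 250), (300, 350), (400, 500)])
    t2 = make_tx("b", [(0, 100), (400, 500)])
    evs = pairwise_events(t1, t2)
    assert [e.type for e in evs] == ["complex"]
    assert event_counts(evs)["ES"] == 0


def test_symmetry(rng):
    t1 = make_tx("a", [(0, 100), (200, 300), (400, 500)])
    t2 = make_tx("b", [(0, 120), (400, 500)])
    assert ev_set(t1, t2) == ev_set(t2, t1)


def test_donor_acceptor_flip_with_strand():
    """The same genomic structure read on the other strand swaps AD and AA."""
    plus = (make_tx("a", [(0, 100), (200, 300)]), make_tx("b", [(0, 120), (200, 300)]))
    minus = (
        make_tx("a", [(0, 100), (200, 300)], "-"),
        make_tx("b", [(0, 120), (200, 300)], "-"),
    )
    assert [e.type for e in pairwise_events(*plus)] == ["AD"]
    assert [e.type for e in pairwise_events(*minus)] == ["AA"]


def test_terminal_end_differences_are_not_events():
    # differing 5'/3' extremities (TSS / polyA variation)
    t1 = make_tx("a", [(0, 100), (200, 300)])
    t2 = make_tx("b", [(150, 300)])  # starts inside t1's intron
    assert pairwise_events(t1, t2) == []
    t3 = make_tx("c", [(10, 100), (200, 350)])  # same chain, different ends
    assert pairwise_events(t1, t3) == []


def test_different_strand_or_chrom_rejected():
    t1 = make_tx("a", [(0, 100)])
    with pytest.raises(ValueError):
        pairwise_events(t1, make_tx("b", [(0, 100)], "-"))
    with pytest.raises(ValueError):
        pairwise_events(t1, make_tx("b", [(0, 100)], chrom="chr2"))


def test_gene_events_deduplicated_by_key():
    base = make_tx("t1", [(0, 100), (200, 300), (400, 500)])
    skip_a = make_tx("t2", [(0, 100), (400, 500)])
    skip_b = make_tx("t3", [(0, 100), (400, 520)])  # same skip, longer end
    locus = GeneLocus("G", "chr1", "+", [base, skip_a, skip_b])
    evs = gene_events(locus)
    assert [(e.type, e.region) for e in evs] == [("ES", (200, 300))]
    # single isoform: no events
    assert gene_events(GeneLocus("G", "chr1", "+", [base])) == []


def test_gene_events_equal_pairwise_union(clean_sim):
    """Deduplicated per-gene sets equal the brute-force union over all
    isoform pairs on every simulated locus with <= 6 isoforms."""
    from itertools import combinations

    cfg, ann, genome, truth, reads, result = clean_sim
    checked = 0
    for locus in result.isoform_loci:
        if not 2 <= len(locus.members) <= 6:
            continue
        brute = {}
        for a, b in combinations(sorted(locus.members, key=lambda t: t.id), 2):
            for e in pairwise_events(a, b, locus.id):
                brute.setdefault(e.key, e)
        assert {e.key for e in gene_events(locus)} == set(brute)
        checked += 1
    assert checked >= 20


def test_planted_events_recovered_exactly(clean_sim):
    cfg, ann, genome, truth, reads, result = clean_sim
    found = set()
    for locus in result.isoform_loci:
        for e in gene_events(locus):
            found.add((e.type, e.region, e.anchors))
    expected = {
        (e["type"], tuple(e["region"]), tuple(e["anchors"]))
        for e in truth.as_events
    }
    assert found == expected


def test_planted_mix_recovered_within_multinomial_bounds():
    """Event-type proportions of a large simulation match the configured mix
    within 99% multinomial bounds."""
    from isoannot.simulate import SimConfig, simulate_genome

    mix = {"IR": 0.30, "ES": 0.25, "AA": 0.20, "AD": 0.20, "MEE": 0.05}
    cfg = SimConfig(
        seed=31,
        n_genes=160,
        isoform_count_distribution={2: 0.4, 3: 0.3, 4: 0.3},
        as_event_mix=mix,
    )
    ann, genome, truth = simulate_genome(cfg)
    n = len(truth.as_events)
    assert n >= 200
    obs = {t: 0 for t in mix}
    for e in truth.as_events:
        obs[e["type"]] += 1
    for t, p in mix.items():
        sd = np.sqrt(n * p * (1 - p))
        assert abs(obs[t] - n * p) < 2.58 * sd + 1


def test_count_by_sample_restriction_semantics():
    base = make_tx("t1", [(0, 100), (200, 300), (400, 500)], samples={"W"})
    skip = make_tx("t2", [(0, 100), (400, 500)], samples={"W"})
    locus = GeneLocus("G", "chr1", "+", [base, skip])
    out = count_by_sample([locus], ["Q", "W", "D"])
    assert len(out["W"]) == 1 and len(out["combined"]) == 1
    assert out["Q"] == [] and out["D"] == []
    # witnesses split across samples: combined only
    base2 = base.copy(samples={"Q"})
    skip2 = skip.copy(samples={"W"})
    out = count_by_sample(
        [GeneLocus("G", "chr1", "+", [base2, skip2])], ["Q", "W", "D"]
    )
    assert out["Q"] == [] and out["W"] == [] and len(out["combined"]) == 1


def test_combined_at_least_max_per_sample(clean_sim):
    cfg, ann, genome, truth, reads, result = clean_sim
    out = count_by_sample(result.isoform_loci, list(cfg.samples))
    n_combined = len(out["combined"])
    for s in cfg.samples:
        assert len(out[s]) <= n_combined
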