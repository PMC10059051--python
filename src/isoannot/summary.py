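"""Dataset-level summary statistics and the end-to-end pipeline driver.

Every percentage reported by the package goes through :func:`percentage`
(round half up to 2 decimals) and is recomputable from the printed numerator
and denominator; :func:`audit_percentages` re-derives each one as a
self-consistency check.
"""

from __future__ import annotations

import json
from collections import Counter
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def round2(x: float) -> float:
    """Round half up to 2 decimals (3.125 -> 3.13)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_UP))


def percentage(numerator: int | float, denominator: int | float) -> float:
    """numerator/denominator as a percent, 2 decimals, round half up."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round2(100.0 * numerator / denominator)


def isoform_distribution(isoforms_per_gene) -> dict:
    """Histogram of isoforms per gene over bins {1..10, >10} with shares."""
    counts = list(isoforms_per_gene)
    total = len(counts)
    hist = Counter(min(c, 11) for c in counts)
    bins = {}
    for k in range(1, 11):
        n = hist.get(k, 0)
        bins[str(k)] = {"count": n, "pct": percentage(n, total) if total else 0.0}
    n = hist.get(11, 0)
    bins[">10"] = {"count": n, "pct": percentage(n, total) if total else 0.0}
    return {"total_genes": total, "bins": bins}


def novelty_fractions(calls) -> dict:
    """Novel shares at gene and transcript level from novelty calls."""
    out = {}
    for level in ("gene", "transcript"):
        sub = [c for c in calls if c.level == level]
        novel = sum(1 for c in sub if c.call == "novel")
        out[level] = {
            "total": len(sub),
            "novel": novel,
            "known": len(sub) - novel,
            "novel_pct": percentage(novel, len(sub)) if sub else 0.0,
        }
    return out


def unique_sets(isoforms, samples) -> dict:
    """Sample-unique and shared isoform counts with mean spliced lengths.

    An isoform is unique to a sample when its supporting reads all come from
    that one sample; the remaining categories are the 2-way/3-way/etc.
    sharing patterns.  unique + shared counts partition the isoform total.
    """
    patterns = Counter()
    per_sample_unique: dict[str, list[int]] = {s: [] for s in samples}
    for t in isoforms:
        present = tuple(sorted(t.samples)) if t.samples else ("unlabelled",)
        patterns[present] += 1
        if len(present) == 1 and present[0] in per_sample_unique:
            per_sample_unique[present[0]].append(t.spliced_length)
    uniq = {}
    for s in samples:
        lens = per_sample_unique[s]
        uniq[s] = {
            "count": len(lens),
            "mean_length": round2(float(np.mean(lens))) if lens else 0.0,
        }
    shared = {
        "+".join(p): n for p, n in sorted(patterns.items()) if len(p) > 1
    }
    return {
        "total": len(isoforms),
        "unique": uniq,
        "shared": shared,
        "partition_ok": sum(patterns.values()) == len(isoforms),
    }


def enrich(hits, universe, term_map: dict[str, set]) -> list[dict]:
    """One-sided hypergeometric over-representation with BH correction.

    ``hits`` must be a subset of ``universe``; ``term_map`` maps term id to
    the set of genes annotated with it.  p is the upper tail of the
    hypergeometric distribution of the observed term-hit count.
    """
    hits = set(hits)
    universe = set(universe)
    outside = hits - universe
    if outside:
        raise ValueError(f"hits outside universe: {sorted(outside)[:5]}")
    if not term_map:
        raise ValueError("empty term map")
    M, n_hits = len(universe), len(hits)
    rows = []
    for term in sorted(term_map):
        members = term_map[term] & universe
        k = len(members & hits)
        K = len(members)
        # P(X >= k), X ~ Hypergeom(M, K, n_hits)
        p = float(sps.hypergeom.sf(k - 1, M, K, n_hits))
        rows.append(
            {"term": term, "k": k, "K": K, "n": n_hits, "M": M, "p": min(p, 1.0)}
        )
    _, q, *_ = multipletests([r["p"] for r in rows], method="fdr_bh")
    for r, qi in zip(rows, q):
        r["q"] = float(qi)
        r["significant"] = bool(qi < 0.05)
    return rows


def audit_summary(summary: dict) -> list[str]:
    """Recompute every percentage in a pipeline summary from its printed
    numerator and denominator; returns the list of inconsistencies (empty
    when the summary is self-consistent)."""
    problems: list[str] = []

    def check(label, pct, num, den):
        if den and pct != percentage(num, den):
            problems.append(f"{label}: {pct} != {num}/{den}")

    dist = summary.get("isoform_distribution", {})
    total = dist.get("total_genes", 0)
    for k, b in dist.get("bins", {}).items():
        check(f"isoform bin {k}", b["pct"], b["count"], total)
    if total and sum(b["count"] for b in dist["bins"].values()) != total:
        problems.append("isoform bins do not sum to total")
    for level, d in summary.get("novelty", {}).items():
        check(f"novelty {level}", d["novel_pct"], d["novel"], d["total"])
    lnc = summary.get("lncrna", {})
    for cls, d in lnc.get("classes", {}).items():
        check(f"lncrna {cls}", d["pct"], d["count"], lnc.get("total", 0))
    apa = summary.get("apa", {})
    if apa.get("n_genes"):
        check("apa 1-9", apa["bin_1_9_pct"], apa["bin_1_9"], apa["n_genes"])
        check(
            "apa 10+", apa["bin_10_plus_pct"], apa["bin_10_plus"], apa["n_genes"]
        )
        if apa["bin_1_9"] + apa["bin_10_plus"] != apa["n_genes"]:
            problems.append("apa bins do not partition genes")
    us = summary.get("unique_sets", {})
    if us and not us.get("partition_ok", True):
        problems.append("unique/shared categories do not partition isoforms")
    return problems


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def run_all(
    cfg=None,
    out_dir=None,
    with_de: bool = True,
):
    """Simulate a dataset and run every stage; returns the pipeline summary.

    The driver wires the stages in order: simulate -> collapse -> novelty
    (against a reference that withholds part of the truth) -> splicing ->
    polyadenylation -> lncRNA -> differential expression -> summaries.
    Deterministic given ``cfg.seed``.  When ``out_dir`` is given, per-stage
    tables plus a run manifest are written there.
    """
    import pandas as pd

    from . import __version__
    from .collapse import collapse
    from .diffexpr import de_test, gene_level, overlap_report
    from .lncrna import call_noncoding, classify_position, lncrna_summary
    from .model import spliced_sequence, write_annotation
    from .novelty import classify_all, novelty_table
    from .polya import apa_summary, flank_profile, gene_polya_sites
    from .simulate import (
        SimConfig,
        simulate_counts,
        simulate_flnc,
        simulate_genome,
        withhold,
    )
    from .splicing import count_by_sample, event_counts, genes_with_events

    cfg = cfg or SimConfig()
    ann, genome, truth = simulate_genome(cfg)
    reads = simulate_flnc(ann, truth, cfg)
    if not reads:
        raise ValueError("empty input: simulation produced no reads")

    result = collapse(reads)
    iso_loci = result.isoform_loci

    ref, dropped_genes, dropped_tx = withhold(ann, truth, seed=cfg.seed)
    calls = classify_all(result.loci, result.isoforms, ref)

    events_by_sample = count_by_sample(iso_loci, list(cfg.samples))
    combined = events_by_sample["combined"]

    # polyadenylation on the raw reads of each collapsed locus
    all_sites = []
    sites_per_gene = {}
    for locus in result.loci:
        sites = gene_polya_sites(locus.id, locus.members)
        all_sites.extend(sites)
        if sites:
            sites_per_gene[locus.id] = len(sites)
    apa = apa_summary(sites_per_gene)
    profile = flank_profile(all_sites, genome)

    # noncoding calling on collapsed isoforms, trained on the reference
    # coding transcripts (simulated coding genes)
    training = [
        spliced_sequence(t, genome)
        for g in ann
        for t in g.members
        if t.id in truth.coding_transcripts
    ]
    coding_calls = call_noncoding(result.isoforms, genome, training)
    noncoding_ids = {c.transcript_id for c in coding_calls if c.call == "noncoding"}
    coding_ref = [g for g in ann if g.members[0].id in truth.coding_transcripts]
    from .model import Annotation

    position_ref = Annotation(coding_ref)
    lnc_transcripts = [t for t in result.isoforms if t.id in noncoding_ids]
    classes = [classify_position(t, position_ref) for t in lnc_transcripts]
    mrna_transcripts = [t for t in result.isoforms if t.id not in noncoding_ids]
    lnc = lncrna_summary(classes, lnc_transcripts, mrna_transcripts, [])

    summary = {
        "totals": {
            "reads": len(reads),
            "isoforms": len(result.isoforms),
            "loci": len(result.loci),
        },
        "novelty": novelty_fractions(calls),
        "isoform_distribution": isoform_distribution(
            [len(l.members) for l in iso_loci]
        ),
        "as_counts": {
            s: event_counts(evs) for s, evs in events_by_sample.items()
        },
        "as_totals": {
            s: sum(event_counts(evs).values())
            for s, evs in events_by_sample.items()
        },
        "as_genes_per_type": genes_with_events(combined),
        "as_gene_share_pct": percentage(
            len({e.gene_id for e in combined}), len(result.loci)
        )
        if result.loci
        else 0.0,
        "apa": apa,
        "polya_element_hit_fraction": round2(profile.element_hit_fraction),
        "lncrna": lnc,
        "unique_sets": unique_sets(result.isoforms, list(cfg.samples)),
    }

    de_out = {}
    if with_de:
        counts = simulate_counts(truth, cfg.de_config, seed=cfg.seed)
        groups = ["C1"] * cfg.de_config.n_replicates + [
            "C2"
        ] * cfg.de_config.n_replicates
        det = de_test(counts, groups, level="transcript")
        tx2gene = {
            t: g for g, ts in truth.gene_to_isoforms.items() for t in ts
        }
        gcounts = gene_level(counts, tx2gene)
        deg = de_test(gcounts, groups, level="gene")
        rep = overlap_report(det, deg, tx2gene)
        de_out = {
            "n_det": rep.n_det,
            "n_detg": rep.n_detg,
            "n_deg": rep.n_deg,
            "n_overlap": rep.n_overlap,
            "pct_of_detg": rep.pct_of_detg,
            "pct_of_deg": rep.pct_of_deg,
        }
        summary["de"] = de_out

    problems = audit_summary(summary)
    if problems:
        raise AssertionError(f"summary self-audit failed: {problems}")

    if out_dir is not None:
        import hashlib
        import os

        os.makedirs(out_dir, exist_ok=True)
        write_annotation(ann, os.path.join(out_dir, "truth.gff3"))
        from .model import write_bed12, write_fasta

        write_bed12(reads, os.path.join(out_dir, "reads.bed12"))
        write_fasta(genome, os.path.join(out_dir, "genome.fa"))
        truth.to_json(os.path.join(out_dir, "sim_truth.json"))
        novelty_table(calls).to_csv(
            os.path.join(out_dir, "novelty.tsv"), sep="\t", index=False
        )
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=1, default=str)
        digest = hashlib.sha256(
            json.dumps(summary, sort_keys=True, default=str).encode()
        ).hexdigest()
        manifest = {
            "package": "isoannot",
            "version": __version__,
            "seed": cfg.seed,
            "n_genes": cfg.n_genes,
            "samples": list(cfg.samples),
            "summary_digest": digest,
        }
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)

    return summary
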