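"""Receptor seeding, homology expansion, locus assembly, spo0E flagging."""

import random

import numpy as np
import pytest

from alomine import architecture, synthetic
from alomine.architecture import (
    assemble_loci,
    expand_by_homology,
    find_receptor_candidates,
    flag_spo0e,
    mine_genome,
)
from alomine.orffinder import MinerConfig
from alomine.seqio import GeneFeature, GenomeRecord, revcomp
from alomine.synthetic import SimConfig
from alomine.tprscan import scan_protein


def _assess(features, profile, calibration):
    return {
        f.feature_id: scan_protein(profile, f.protein, calibration, f.feature_id)
        for f in features
    }


@pytest.fixture(scope="module")
def planted(profile, calibration):
    cfg = SimConfig(seed=11)
    genomes, truth, features = synthetic.simulate_genome(cfg)
    return genomes, truth, features


def test_seed_selection_on_planted_genome(planted, profile, calibration):
    genomes, truth, features = planted
    receptors = [f for f in features if len(f.protein) >= 250]
    assessments = _assess(receptors, profile, calibration)
    seeds = find_receptor_candidates(receptors, assessments)
    seed_ids = {s.feature.feature_id for s in seeds}
    # every planted receptor (loci + TPR decoys) seeds; random genes never do
    for t in truth.loci:
        assert f"{t.locus_id}_receptor" in seed_ids
    for d in truth.decoy_receptors:
        assert d.feature_id in seed_ids
    for d in truth.decoy_random_genes:
        assert d.feature_id not in seed_ids


def test_short_receptor_excluded(profile, calibration):
    """A 240-aa protein is excluded however strong its repeat score."""
    consensus = "AEAWYNLGNAYYKQGDYDEAIEYYQKALELDPRS"
    prot = ("M" + consensus * 8)[:240]
    feat = GeneFeature("c", 0, 3 * (len(prot) + 1), "+", protein=prot, feature_id="p1")
    assessments = _assess([feat], profile, calibration)
    assert assessments["p1"].probability >= 0.75
    assert find_receptor_candidates([feat], assessments) == []


def test_empty_proteome():
    assert find_receptor_candidates([], {}) == []


def _mutate(seq, frac, rng):
    aas = "ACDEFGHIKLMNPQRSTVWY"
    out = list(seq)
    for i in rng.sample(range(len(seq)), int(frac * len(seq))):
        out[i] = rng.choice(aas)
    return "".join(out)


def test_expand_by_homology_recovers_divergent_family(profile, calibration):
    """Divergent homologs below the repeat threshold are pulled in by
    similarity to the seeds (the 2 -> 16 style expansion)."""
    rng = random.Random(21)
    nrng = np.random.default_rng(21)
    base = synthetic._receptor_protein(nrng, profile, 7)
    feats = []
    for i in range(2):  # strong seeds
        feats.append(
            GeneFeature("c", 1000 * i, 1000 * i + 3 * (len(base) + 1), "+",
                        protein=_mutate(base, 0.05, rng), feature_id=f"seed{i}")
        )
    for i in range(3):
        # divergent homologs: conserved N-terminal half, repeat region replaced
        # by unrelated sequence, so the repeat scan alone cannot find them
        prot = _mutate(base[:65], 0.10, rng) + synthetic._random_protein(
            nrng, len(base) - 65
        )
        feats.append(
            GeneFeature("c", 5000 + 1000 * i, 5000 + 1000 * i + 3 * (len(prot) + 1), "+",
                        protein=prot, feature_id=f"div{i}")
        )
    for i in range(5):  # unrelated decoys
        prot = synthetic._random_protein(nrng, len(base))
        feats.append(
            GeneFeature("c", 10000 + 1000 * i, 10000 + 1000 * i + 3 * (len(prot) + 1), "+",
                        protein=prot, feature_id=f"dec{i}")
        )
    assessments = _assess(feats, profile, calibration)
    seeds = find_receptor_candidates(feats, assessments)
    assert {s.feature.feature_id for s in seeds} >= {"seed0", "seed1"}
    expanded = expand_by_homology(seeds, feats, assessments)
    ids = {r.feature.feature_id for r in expanded}
    assert {"seed0", "seed1", "div0", "div1", "div2"} <= ids
    assert not any(i.startswith("dec") for i in ids)
    # members that fell below the repeat threshold are recovered by expansion
    sources = {r.feature.feature_id: r.source for r in expanded}
    below = [f"div{i}" for i in range(3)
             if assessments[f"div{i}"].probability < 0.75]
    assert below, "fixture should contain at least one sub-threshold homolog"
    assert all(sources[d] == "homology_expansion" for d in below)


def test_expand_with_no_homologs(profile, calibration, planted):
    genomes, truth, features = planted
    receptors = [f for f in features if len(f.protein) >= 250]
    assessments = _assess(receptors, profile, calibration)
    seeds = find_receptor_candidates(receptors[:1], {
        receptors[0].feature_id: assessments[receptors[0].feature_id]
    })
    out = expand_by_homology(seeds, receptors[:1], assessments)
    assert [r.feature.feature_id for r in out] == [s.feature.feature_id for s in seeds]


def test_assemble_loci_planted_operons(planted, profile, calibration):
    genomes, truth, features = planted
    gmap = {g.id: g for g in genomes}
    receptors = [f for f in features if len(f.protein) >= 250]
    assessments = _assess(receptors, profile, calibration)
    seeds = find_receptor_candidates(receptors, assessments)
    loci = assemble_loci(seeds, gmap)
    by_rec = {}
    for l in loci:
        f = l.receptor.feature
        key = f.end if f.strand == "+" else f.start
        by_rec[(f.contig_id, f.strand, key)] = l
    for t in truth.loci:
        key = (t.contig_id, t.strand, t.receptor_end if t.strand == "+" else t.receptor_start)
        l = by_rec[key]
        assert not l.orphan
        pep_ends = {
            p.feature.end if p.feature.strand == "+" else p.feature.start
            for p, _ in l.peptides
        }
        assert (t.peptide_end if t.strand == "+" else t.peptide_start) in pep_ends
    for d in truth.decoy_receptors:
        key = (d.contig_id, d.strand, d.end if d.strand == "+" else d.start)
        assert by_rec[key].orphan


def test_orphan_when_signal_negative(profile, calibration):
    """A receptor whose downstream ORF lacks a signal keeps the peptide but
    is flagged orphan."""
    nrng = np.random.default_rng(31)
    rec_prot = synthetic._receptor_protein(nrng, profile, 7)
    rec_nt = synthetic._backtranslate(rec_prot, nrng)
    pep_prot = synthetic._decoy_short_orf_protein(nrng, SimConfig())
    pep_nt = synthetic._backtranslate(pep_prot, nrng)
    seq = "TAA" + rec_nt + "TAA" + pep_nt + synthetic._random_nt(nrng, 3000, 0.42)
    g = GenomeRecord("c", seq)
    rec_feat = GeneFeature("c", 3, 3 + len(rec_nt), "+", protein=rec_prot, feature_id="r1")
    a = scan_protein(profile, rec_prot, calibration, "r1")
    from alomine.architecture import ReceptorCandidate

    locus = assemble_loci([ReceptorCandidate(rec_feat, a, "tpr_seed")], {"c": g})[0]
    assert locus.peptides  # ORF found and retained
    assert locus.orphan  # but no signal


def test_flag_spo0e_keyword_and_gap(planted, profile, calibration):
    genomes, truth, features = planted
    gmap = {g.id: g for g in genomes}
    receptors = [f for f in features if len(f.protein) >= 250
                 and not f.feature_id.endswith("spo0e")]
    assessments = _assess(receptors, profile, calibration)
    seeds = find_receptor_candidates(receptors, assessments)
    loci = flag_spo0e(assemble_loci(seeds, gmap), features)
    by_rec = {}
    for l in loci:
        f = l.receptor.feature
        key = f.end if f.strand == "+" else f.start
        by_rec[(f.contig_id, f.strand, key)] = l
    for t in truth.loci:
        key = (t.contig_id, t.strand, t.receptor_end if t.strand == "+" else t.receptor_start)
        assert by_rec[key].spo0e_downstream == t.spo0e


def test_flag_spo0e_distant_gene_not_flagged():
    rec = GeneFeature("c", 100, 1000, "+", protein="M" * 300, feature_id="r")
    from alomine.architecture import AloLocus, ReceptorCandidate
    from alomine.tprscan import TprAssessment

    locus = AloLocus("alo1", ReceptorCandidate(rec, TprAssessment("r", [], 0, 1.0, True), "tpr_seed"),
                     [], True, False, "F001")
    far = GeneFeature("c", 6000, 6500, "+", product="Spo0E-like sporulation regulatory protein")
    near_wrong_strand = GeneFeature("c", 1050, 1500, "-", product="spo0E family protein")
    out = flag_spo0e([locus], [far, near_wrong_strand])
    assert not out[0].spo0e_downstream
    near = GeneFeature("c", 1050, 1500, "+", product="Spo0E-like sporulation regulatory protein")
    out = flag_spo0e([locus], [far, near])
    assert out[0].spo0e_downstream


def test_flag_spo0e_reference_mode_requires_reference():
    with pytest.raises(ValueError):
        flag_spo0e([], [], mode="reference_homology")


def test_mine_genome_empty_without_seeds(profile, calibration):
    rng = np.random.default_rng(5)
    g = GenomeRecord("c", synthetic._random_nt(rng, 6000, 0.42))
    assert mine_genome([g], profile, calibration) == []


def test_mining_invariant_under_revcomp(profile, calibration):
    genomes, truth, features = synthetic.simulate_genome(SimConfig(seed=12))
    fwd = mine_genome(genomes, profile, calibration)
    rc = [GenomeRecord(g.id, revcomp(g.seq), g.description) for g in genomes]
    rev = mine_genome(rc, profile, calibration)
    lens = {g.id: len(g.seq) for g in genomes}

    def keys(loci, mirror):
        out = set()
        for l in loci:
            f = l.receptor.feature
            if mirror:
                L = lens[f.contig_id]
                out.add((f.contig_id, L - f.end, L - f.start,
                         {"+": "-", "-": "+"}[f.strand], l.orphan, len(l.peptides)))
            else:
                out.add((f.contig_id, f.start, f.end, f.strand, l.orphan, len(l.peptides)))
        return out

    assert keys(fwd, False) == keys(rev, True)
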