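"""Locus assembly: receptor seeding, homology expansion, cognate peptides,
orphan classification and spo0E-adjacency flagging.

A candidate locus is a two-gene operon: a >=250 aa receptor with an
N-terminal HTH-like block and a C-terminal TPR-like repeat array, followed
by a short (30-50 aa) pro-peptide ORF whose start codon lies within the
window spanning the receptor's last 100 nt and the 200 nt downstream.
Receptors whose cognate ORF is missing, or whose peptide lacks a secretion
signal (and is not rescued by family homology), are kept as orphans rather
than discarded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from . import homology, signalpred, tprscan
from .orffinder import MinerConfig, OrfCandidate, find_cognate_peptides, find_orfs
from .seqio import GeneFeature, GenomeRecord
from .signalpred import SignalCall, SignalParams
from .tprscan import NullCalibration, RepeatProfile, TprAssessment


@dataclass
class ReceptorCandidate:
    feature: GeneFeature
    tpr: TprAssessment
    source: str  # tpr_seed | homology_expansion
    hth_score: float | None = None

    @property
    def protein_id(self) -> str:
        return self.feature.feature_id

    @property
    def protein(self) -> str:
        return self.feature.protein


@dataclass
class AloLocus:
    locus_id: str
    receptor: ReceptorCandidate
    peptides: list[tuple[OrfCandidate, SignalCall]]
    orphan: bool
    spo0e_downstream: bool
    family_id: str


def _feature_pid(feat: GeneFeature) -> str:
    return feat.feature_id or f"{feat.contig_id}:{feat.start}-{feat.end}({feat.strand})"


def find_receptor_candidates(
    features: list[GeneFeature],
    assessments: dict[str, TprAssessment],
    config: MinerConfig | None = None,
) -> list[ReceptorCandidate]:
    """Seed receptors: TPR probability >= threshold and length >= 250 aa."""
    cfg = config or MinerConfig()
    out = []
    for feat in features:
        pid = _feature_pid(feat)
        if pid not in assessments:
            raise ValueError(f"no TPR assessment for protein {pid!r}")
        a = assessments[pid]
        if a.probability >= cfg.tpr_prob_min and len(feat.protein) >= cfg.min_receptor_aa:
            out.append(ReceptorCandidate(feature=feat, tpr=a, source="tpr_seed"))
    out.sort(key=lambda r: (r.feature.contig_id, r.feature.start, r.feature.strand))
    return out


def expand_by_homology(
    seeds: list[ReceptorCandidate],
    all_features: list[GeneFeature],
    assessments: dict[str, TprAssessment],
    config: MinerConfig | None = None,
    rounds: int = 2,
) -> list[ReceptorCandidate]:
    """Add >=250 aa proteins hitting any seed (two transitive rounds).

    The two-round expansion stands in for iterative profile search at desk
    scale: hits of hits are re-searched once. New members are tagged
    ``homology_expansion``; the result is the deduplicated union with seeds.
    """
    if not seeds:
        raise ValueError("expand_by_homology requires at least one seed")
    cfg = config or MinerConfig()
    by_pid = {_feature_pid(f): f for f in all_features}
    member_ids = {r.protein_id or _feature_pid(r.feature) for r in seeds}
    candidates = {
        pid: f
        for pid, f in by_pid.items()
        if pid not in member_ids and len(f.protein) >= cfg.min_receptor_aa
    }
    added: dict[str, GeneFeature] = {}
    for _ in range(rounds):
        current = {pid: by_pid[pid].protein for pid in member_ids if pid in by_pid}
        for r in seeds:  # seeds may not be in all_features' id map
            current[_feature_pid(r.feature)] = r.protein
        new_ids = []
        for pid, feat in sorted(candidates.items()):
            best_e = min(
                homology.align_local(q, feat.protein).evalue
                for q in current.values()
            )
            if best_e <= cfg.evalue_within:
                new_ids.append(pid)
        if not new_ids:
            break
        for pid in new_ids:
            added[pid] = candidates.pop(pid)
            member_ids.add(pid)
    out = list(seeds)
    for pid, feat in sorted(added.items()):
        a = assessments.get(pid, TprAssessment(pid, [], 0.0, 0.0, False))
        out.append(ReceptorCandidate(feature=feat, tpr=a, source="homology_expansion"))
    out.sort(key=lambda r: (r.feature.contig_id, r.feature.start, r.feature.strand))
    return out


def assemble_loci(
    receptors: list[ReceptorCandidate],
    genomes: dict[str, GenomeRecord],
    config: MinerConfig | None = None,
    signal_params: SignalParams | None = None,
) -> list[AloLocus]:
    """Pair each receptor with cognate-window peptide ORFs and classify orphans.

    Peptide signal calls are rescued within single-linkage peptide families
    before the orphan flag is set; receptor families provide the locus
    family id. Multiple peptides per locus are allowed.
    """
    cfg = config or MinerConfig()
    sp = signal_params or SignalParams()
    per_locus: list[tuple[ReceptorCandidate, list[OrfCandidate]]] = []
    peptide_seqs: dict[str, str] = {}
    calls: dict[str, SignalCall] = {}
    for idx, rec in enumerate(
        sorted(receptors, key=lambda r: (r.feature.contig_id, r.feature.start, r.feature.strand))
    ):
        genome = genomes[rec.feature.contig_id]
        peps = find_cognate_peptides(rec.feature, genome, cfg)
        for j, pep in enumerate(peps):
            pid = f"locus{idx:03d}_pep{j}"
            pep.feature.feature_id = pid
            peptide_seqs[pid] = pep.protein
            calls[pid] = signalpred.predict_signal(pep.protein, sp, protein_id=pid)
        per_locus.append((rec, peps))

    # homology rescue across peptide families
    if len(peptide_seqs) >= 2:
        pep_hits = homology.all_vs_all(peptide_seqs, evalue_max=cfg.evalue_within)
        pep_fams = homology.cluster(pep_hits, peptide_seqs)
        rescued = signalpred.rescue_by_homology(list(calls.values()), pep_fams, sp)
        calls = {c.protein_id: c for c in rescued}

    # receptor families
    rec_seqs = {
        (r.protein_id or _feature_pid(r.feature)): r.protein for r, _ in per_locus
    }
    fam_of: dict[str, str] = {}
    if len(rec_seqs) >= 2:
        rec_hits = homology.all_vs_all(rec_seqs, evalue_max=cfg.evalue_within)
        for fam in homology.cluster(rec_hits, rec_seqs):
            for m in fam.member_ids:
                fam_of[m] = fam.family_id
    elif rec_seqs:
        fam_of = {next(iter(rec_seqs)): "F001"}

    loci = []
    for idx, (rec, peps) in enumerate(per_locus):
        pairs = [(pep, calls[pep.feature.feature_id]) for pep in peps]
        orphan = not any(c.has_signal for _, c in pairs)
        rid = rec.protein_id or _feature_pid(rec.feature)
        loci.append(
            AloLocus(
                locus_id=f"alo{idx + 1}",
                receptor=rec,
                peptides=pairs,
                orphan=orphan,
                spo0e_downstream=False,
                family_id=fam_of.get(rid, ""),
            )
        )
    return loci


def _locus_span(locus: AloLocus) -> tuple[str, int, int, str]:
    feats = [locus.receptor.feature] + [p.feature for p, _ in locus.peptides]
    contig = feats[0].contig_id
    return (
        contig,
        min(f.start for f in feats),
        max(f.end for f in feats),
        locus.receptor.feature.strand,
    )


def flag_spo0e(
    loci: list[AloLocus],
    features: list[GeneFeature],
    mode: str = "keyword",
    reference: str | None = None,
    config: MinerConfig | None = None,
) -> list[AloLocus]:
    """Flag loci whose next downstream same-strand gene is spo0E-like.

    Downstream is 3' of the whole locus on the receptor's strand, within
    ``max_operon_gap_nt``. In keyword mode the annotated product must match
    /spo0E/i; in reference_homology mode it must hit ``reference`` at
    E <= evalue_within.
    """
    cfg = config or MinerConfig()
    if mode not in ("keyword", "reference_homology"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "reference_homology" and reference is None:
        raise ValueError("reference_homology mode requires a reference protein")
    pat = re.compile(r"spo0E", re.IGNORECASE)
    for locus in loci:
        contig, lstart, lend, strand = _locus_span(locus)
        locus_feats = {
            (f.start, f.end)
            for f in [locus.receptor.feature] + [p.feature for p, _ in locus.peptides]
        }
        best = None
        for f in features:
            if f.contig_id != contig or f.strand != strand:
                continue
            if (f.start, f.end) in locus_feats:
                continue
            if strand == "+":
                gap = f.start - lend
            else:
                gap = lstart - f.end
            if 0 <= gap <= cfg.max_operon_gap_nt:
                if best is None or gap < best[0]:
                    best = (gap, f)
        flag = False
        if best is not None:
            f = best[1]
            if mode == "keyword":
                flag = bool(pat.search(f.product))
            else:
                if f.protein:
                    hit = homology.align_local(reference, f.protein)
                    flag = hit.evalue <= cfg.evalue_within
        locus.spo0e_downstream = flag
    return loci


# ---------------------------------------------------------------------------
# end-to-end mining
# ---------------------------------------------------------------------------

def mine_genome(
    genomes: list[GenomeRecord],
    profile: RepeatProfile,
    calibration: NullCalibration,
    config: MinerConfig | None = None,
    signal_params: SignalParams | None = None,
    annotations: list[GeneFeature] | None = None,
    spo0e_mode: str = "keyword",
    spo0e_reference: str | None = None,
    log=None,
) -> list[AloLocus]:
    """Run the full mining pipeline on a set of contigs.

    Candidate receptor genes come from the annotations when provided
    (annotated CDS >= 250 aa), otherwise from six-frame ORF calling.
    Scaffolds shorter than ``min_scaffold_nt`` are skipped. Returns loci
    sorted by genomic position; spo0E flags are set only when annotations
    are available or a reference protein is given.
    """
    cfg = config or MinerConfig()
    genome_map = {g.id: g for g in genomes}

    def info(msg: str) -> None:
        if log is not None:
            log.info(msg)

    n_short = sum(1 for g in genomes if len(g.seq) < cfg.min_scaffold_nt)
    usable = [g for g in genomes if len(g.seq) >= cfg.min_scaffold_nt]
    info(f"scaffold filter (< {cfg.min_scaffold_nt} nt): dropped {n_short} contigs")

    features: list[GeneFeature] = []
    if annotations is not None:
        for f in annotations:
            if f.contig_id not in genome_map:
                continue
            if len(genome_map[f.contig_id].seq) < cfg.min_scaffold_nt:
                continue
            if not f.protein and f.kind == "CDS":
                g = genome_map[f.contig_id]
                sub = g.seq[f.start : f.end]
                if f.strand == "-":
                    from .seqio import revcomp

                    sub = revcomp(sub)
                if len(sub) % 3 == 0:
                    try:
                        from .seqio import translate

                        f.protein = translate(sub, start_as_met=True)
                    except ValueError:
                        continue
            if len(f.protein) >= cfg.min_receptor_aa:
                features.append(f)
    else:
        for g in usable:
            for orf in find_orfs(g, cfg.min_receptor_aa, 100000):
                feat = orf.feature
                feat.feature_id = _feature_pid(feat)
                features.append(feat)
    for f in features:
        if not f.feature_id:
            f.feature_id = _feature_pid(f)
    info(f"candidate proteins >= {cfg.min_receptor_aa} aa: {len(features)}")

    assessments = {
        f.feature_id: tprscan.scan_protein(profile, f.protein, calibration, f.feature_id)
        for f in features
    }
    seeds = find_receptor_candidates(features, assessments, cfg)
    info(f"TPR seeds at probability >= {cfg.tpr_prob_min}: {len(seeds)}")
    if not seeds:
        info("no TPR seeds found; returning empty locus set")
        return []
    receptors = expand_by_homology(seeds, features, assessments, cfg)
    info(f"receptors after homology expansion: {len(receptors)}")
    loci = assemble_loci(receptors, genome_map, cfg, signal_params)
    n_orphan = sum(1 for l in loci if l.orphan)
    info(f"assembled {len(loci)} loci ({n_orphan} orphans)")
    if annotations is not None or spo0e_reference is not None:
        ann = annotations if annotations is not None else []
        loci = flag_spo0e(loci, ann, mode=spo0e_mode, reference=spo0e_reference, config=cfg)
    return loci


def loci_to_rows(loci: list[AloLocus]) -> list[dict]:
    rows = []
    for l in loci:
        f = l.receptor.feature
        rows.append(
            {
                "locus_id": l.locus_id,
                "contig": f.contig_id,
                "receptor_start": f.start,
                "receptor_end": f.end,
                "strand": f.strand,
                "tpr_prob": f"{l.receptor.tpr.probability:.4f}",
                "source": l.receptor.source,
                "n_peptides": len(l.peptides),
                "orphan": int(l.orphan),
                "spo0e_downstream": int(l.spo0e_downstream),
                "family_id": l.family_id,
            }
        )
    return rows
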