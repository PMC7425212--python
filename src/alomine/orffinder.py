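"""Six-frame ORF discovery and the windowed cognate-peptide search.

The cognate-peptide window reproduces the published search rule: the last
100 nt of a receptor gene together with the 200 nt immediately downstream
of it are scanned for short ORFs (default 30-50 aa) on the receptor's
strand, so the peptide gene may partially overlap the receptor's 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqio import (
    GeneFeature,
    GenomeRecord,
    INITIATORS,
    STOP_CODONS,
    revcomp,
    translate,
)


@dataclass
class MinerConfig:
    """Every numeric threshold of the mining pipeline in one place.

    Defaults are the published values: TPR probability > 0.75, receptors
    >= 250 aa, scaffolds >= 2500 nt, within-genome homology at E <= 1e-5 and
    cross-genome at E <= 1e-10, peptide ORFs of 30-50 aa searched in a
    window of 100 nt back / 200 nt forward of the receptor 3' end, mature
    peptides of 5-10 aa, MS-detectable fragments of 5-35 aa.
    """

    tpr_prob_min: float = 0.75
    min_receptor_aa: int = 250
    min_scaffold_nt: int = 2500
    evalue_within: float = 1e-5
    evalue_cross: float = 1e-10
    peptide_len_aa: tuple[int, int] = (30, 50)
    window_back_nt: int = 100
    window_fwd_nt: int = 200
    mature_len_aa: tuple[int, int] = (5, 10)
    fragment_len_aa: tuple[int, int] = (5, 35)
    max_operon_gap_nt: int = 200
    same_strand_peptide: bool = True

    def __post_init__(self) -> None:
        for name in ("peptide_len_aa", "mature_len_aa", "fragment_len_aa"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name}: need 0 < min <= max, got ({lo}, {hi})")
        for name in (
            "tpr_prob_min",
            "min_receptor_aa",
            "min_scaffold_nt",
            "evalue_within",
            "evalue_cross",
            "window_back_nt",
            "window_fwd_nt",
            "max_operon_gap_nt",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class OrfCandidate:
    """An ORF call: feature interval includes the stop codon."""

    feature: GeneFeature
    start_codon: str
    length_aa: int

    @property
    def protein(self) -> str:
        return self.feature.protein

    def start_codon_pos(self) -> int:
        """Genomic position of the 5'-most base of the start codon."""
        return self.feature.start if self.feature.strand == "+" else self.feature.end - 1


def _scan_frames(seq: str, min_aa: int, max_aa: int, all_starts: bool):
    """Yield (start, end, start_codon, protein) in scan-space coordinates.

    ORFs run from an initiator (the first after the previous in-frame stop
    unless ``all_starts``) to the first in-frame stop; the interval includes
    the stop codon.
    """
    n = len(seq)
    for frame in range(3):
        open_starts: list[int] = []
        i = frame
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                for p in open_starts:
                    length_aa = (i - p) // 3
                    if min_aa <= length_aa <= max_aa:
                        yield p, i + 3, seq[p : p + 3], frame
                open_starts = []
            elif codon in INITIATORS:
                if all_starts or not open_starts:
                    open_starts.append(i)
            i += 3


def find_orfs(
    genome: GenomeRecord,
    min_aa: int,
    max_aa: int,
    region: tuple[int, int] | None = None,
    strand: str | None = None,
    all_starts: bool = False,
) -> list[OrfCandidate]:
    """Find ORFs of ``min_aa``..``max_aa`` residues (stop excluded) in six frames.

    ``region`` restricts results to ORFs whose interval intersects it;
    ``strand`` restricts to one strand. Results are sorted by
    (start, end, strand).
    """
    if min_aa > max_aa:
        raise ValueError("min_aa must be <= max_aa")
    L = len(genome.seq)
    if region is not None:
        rs, re_ = region
        if not (0 <= rs < re_ <= L):
            raise ValueError(f"region [{rs}, {re_}) outside contig of length {L}")
    strands = ("+", "-") if strand is None else (strand,)
    out: list[OrfCandidate] = []
    for st in strands:
        scan_seq = genome.seq if st == "+" else revcomp(genome.seq)
        for p, q, start_codon, _frame in _scan_frames(scan_seq, min_aa, max_aa, all_starts):
            if st == "+":
                gstart, gend = p, q
            else:
                gstart, gend = L - q, L - p
            if region is not None and not (gstart < region[1] and gend > region[0]):
                continue
            protein = translate(scan_seq[p:q], start_as_met=True)
            feat = GeneFeature(
                contig_id=genome.id,
                start=gstart,
                end=gend,
                strand=st,
                kind="peptide_ORF" if max_aa <= 100 else "CDS",
                protein=protein,
            )
            out.append(OrfCandidate(feature=feat, start_codon=start_codon, length_aa=len(protein)))
    out.sort(key=lambda o: (o.feature.start, o.feature.end, o.feature.strand))
    return out


def cognate_window(
    receptor: GeneFeature,
    contig_len: int,
    config: MinerConfig | None = None,
) -> tuple[int, int, str]:
    """Window around a receptor's 3' end searched for the cognate peptide ORF.

    For a + strand receptor [s, e): [e - window_back, e + window_fwd), and the
    strand-mirrored equivalent for - strand, both clipped to the contig.
    """
    cfg = config or MinerConfig()
    if receptor.end > contig_len:
        raise ValueError("receptor extends beyond contig")
    if receptor.strand == "+":
        ws = receptor.end - cfg.window_back_nt
        we = receptor.end + cfg.window_fwd_nt
    else:
        ws = receptor.start - cfg.window_fwd_nt
        we = receptor.start + cfg.window_back_nt
    return max(0, ws), min(contig_len, we), receptor.strand


def find_cognate_peptides(
    receptor: GeneFeature,
    genome: GenomeRecord,
    config: MinerConfig | None = None,
    all_starts: bool = False,
) -> list[OrfCandidate]:
    """Short ORFs whose start codon lies in the receptor's cognate window.

    Same-strand by default (``config.same_strand_peptide``); the ORF may
    extend beyond the window. An empty result marks an orphan receptor.
    """
    cfg = config or MinerConfig()
    ws, we, wstrand = cognate_window(receptor, len(genome.seq), cfg)
    if ws >= we:
        return []
    lo, hi = cfg.peptide_len_aa
    strand = wstrand if cfg.same_strand_peptide else None
    orfs = find_orfs(genome, lo, hi, strand=strand, all_starts=all_starts)
    hits = [o for o in orfs if ws <= o.start_codon_pos() < we]
    # the receptor's own tail can never qualify (length band), but drop any
    # ORF identical to the receptor interval defensively
    hits = [
        o
        for o in hits
        if not (o.feature.start == receptor.start and o.feature.end == receptor.end)
    ]
    hits.sort(key=lambda o: (o.feature.start, o.feature.end))
    return hits
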