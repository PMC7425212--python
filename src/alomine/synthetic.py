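"""Synthetic genomes with planted receptor-peptide operons and simulated MS
fragment sets, with full ground truth, so every pipeline stage is testable
without downloads.

The generator emits the locus anatomy the miner is built for: a receptor
gene (start codon, HTH-like N-terminal block, linker, 6-8 repeat units
sampled from the shipped TPR profile, stop) followed on the same strand by
a short pro-peptide ORF (K/R-positive n-region, hydrophobic h-region,
polar linker, 5-10 aa small/polar mature segment) whose start codon falls
inside the receptor's cognate window. Decoys cover the three confusable
gene classes: TPR receptors without a peptide (their downstream window is
guaranteed initiator-free, so the planted truth really lacks a cognate
ORF), short ORFs without a signal region (hydrophobic residues capped so
no h-region can form), and plain random genes. An in-frame TAA is planted
immediately upstream of every gene so ORF calls coincide with the plant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msmap import MsFragment
from .orffinder import MinerConfig
from .seqio import CODON_TO_AA, GeneFeature, GenomeRecord, revcomp
from .tprscan import RepeatProfile, load_builtin_profile, sample_unit

_BG_AA = "ACDEFGHIKLMNPQRSTVWY"

# codon choices per residue, translation table 11
_CODONS_OF: dict[str, list[str]] = {}
for codon, aa in sorted(CODON_TO_AA.items()):
    _CODONS_OF.setdefault(aa, []).append(codon)

HYDROPHOBIC_POOL = "LLIVFA"  # h-region residues, L-weighted
MATURE_POOL = "SGHRNQTDAE"  # small/polar, SHGRGG-like
STRONG_HYDRO = set("ACFILMV")  # capped in decoy short ORFs


@dataclass
class SimConfig:
    """The stated world of the generator; defaults mirror the mined anatomy."""

    n_contigs: int = 3
    contig_len_nt: int = 15000
    gc_frac: float = 0.42
    n_loci: int = 5
    n_tpr_units: tuple[int, int] = (6, 8)
    peptide_len_aa: tuple[int, int] = (30, 50)
    mature_len_aa: tuple[int, int] = (5, 10)
    signal_kr: tuple[int, int] = (1, 2)
    h_region_len: tuple[int, int] = (8, 12)
    decoy_tpr: int = 2
    decoy_short_orf: int = 3
    decoy_random_genes: int = 2
    spo0e_frac: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tpr_units", "peptide_len_aa", "mature_len_aa", "signal_kr", "h_region_len"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if not 0 < self.gc_frac < 1:
            raise ValueError("gc_frac must be in (0, 1)")


@dataclass
class PlantedLocus:
    locus_id: str
    contig_id: str
    strand: str
    receptor_start: int
    receptor_end: int
    peptide_start: int
    peptide_end: int
    receptor_protein: str
    propeptide: str
    mature: str
    signal_end: int  # residues [0, signal_end) form the signal sequence
    spo0e: bool


@dataclass
class FragmentOrigin:
    sequence: str
    propeptide_id: str
    start: int
    end: int
    is_noise: bool


@dataclass
class SyntheticTruth:
    loci: list[PlantedLocus]
    decoy_receptors: list[GeneFeature]
    decoy_short_orfs: list[GeneFeature]
    decoy_random_genes: list[GeneFeature]
    features: list[GeneFeature]
    config: SimConfig
    fragment_origins: list[FragmentOrigin] = field(default_factory=list)
    mature_detectable: dict[str, bool] = field(default_factory=dict)


def _random_nt(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _backtranslate(protein: str, rng: np.random.Generator) -> str:
    codons = []
    for i, aa in enumerate(protein):
        if i == 0 and aa == "M":
            codons.append("ATG")
        else:
            opts = _CODONS_OF[aa]
            codons.append(opts[rng.integers(len(opts))])
    codons.append("TAA")
    return "".join(codons)


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(_BG_AA))[rng.integers(0, 20, size=n)])


def _receptor_protein(rng: np.random.Generator, profile: RepeatProfile, n_units: int) -> str:
    hth = _random_protein(rng, int(rng.integers(50, 61)))
    linker = _random_protein(rng, int(rng.integers(10, 21)))
    units = "".join(sample_unit(profile, rng) for _ in range(n_units))
    return "M" + hth + linker + units + _random_protein(rng, 3)


def _peptide_protein(rng: np.random.Generator, cfg: SimConfig) -> tuple[str, int, int]:
    """Build a pro-peptide; returns (protein, signal_end, mature_len)."""
    lo, hi = cfg.peptide_len_aa
    mlo, mhi = cfg.mature_len_aa
    klo, khi = cfg.signal_kr
    hlo, hhi = cfg.h_region_len
    for _ in range(100):
        L = int(rng.integers(lo, hi + 1))
        m = int(rng.integers(mlo, mhi + 1))
        n_kr = int(rng.integers(klo, khi + 1))
        h = int(rng.integers(hlo, hhi + 1))
        linker = L - 1 - n_kr - h - m
        if linker >= 2:
            break
    else:
        raise ValueError("peptide length ranges leave no room for a linker")
    n_region = "".join("KR"[rng.integers(2)] for _ in range(n_kr))
    h_region = "".join(
        HYDROPHOBIC_POOL[rng.integers(len(HYDROPHOBIC_POOL))] for _ in range(h)
    )
    link = "".join(MATURE_POOL[rng.integers(len(MATURE_POOL))] for _ in range(linker))
    mature = "".join(MATURE_POOL[rng.integers(len(MATURE_POOL))] for _ in range(m))
    protein = "M" + n_region + h_region + link + mature
    signal_end = 1 + n_kr + h
    return protein, signal_end, m


def _decoy_short_orf_protein(rng: np.random.Generator, cfg: SimConfig) -> str:
    """Short ORF with no signal region: <= 4 strongly hydrophobic residues in
    any 8-residue window, so no h-region can assemble by chance."""
    lo, hi = cfg.peptide_len_aa
    L = int(rng.integers(lo, hi + 1))
    out: list[str] = ["M"]
    polar = [a for a in _BG_AA if a not in STRONG_HYDRO]
    while len(out) < L:
        recent = sum(1 for a in out[-7:] if a in STRONG_HYDRO)
        if recent >= 4:
            out.append(polar[rng.integers(len(polar))])
        else:
            out.append(_BG_AA[rng.integers(20)])
    return "".join(out)


def _scrub_initiators(seq: str) -> str:
    """Remove every ATG/GTG/TTG triplet (any offset) from a forward-strand
    sequence by G->C substitution at the third position."""
    s = list(seq)
    changed = True
    while changed:
        changed = False
        for i in range(len(s) - 2):
            if s[i] in "AGT" and s[i + 1] == "T" and s[i + 2] == "G":
                s[i + 2] = "C"
                changed = True
    return "".join(s)


def _item_cassettes(cfg: SimConfig, rng: np.random.Generator, profile: RepeatProfile, miner: MinerConfig):
    """Build every planted item as a (kind, sense-strand nt, metadata) cassette."""
    items = []
    for i in range(cfg.n_loci):
        n_units = int(rng.integers(cfg.n_tpr_units[0], cfg.n_tpr_units[1] + 1))
        rec_prot = _receptor_protein(rng, profile, n_units)
        rec_nt = _backtranslate(rec_prot, rng)
        pep_prot, sig_end, m = _peptide_protein(rng, cfg)
        pep_nt = _backtranslate(pep_prot, rng)
        gap1 = _random_nt(rng, int(rng.integers(6, 60)), cfg.gc_frac)
        spo0e = bool(rng.random() < cfg.spo0e_frac)
        parts = ["TAA", rec_nt, gap1, "TAA", pep_nt]
        offs = {}
        pos = 0
        for name, part in zip(("pad", "rec", "gap1", "pad2", "pep"), parts):
            offs[name] = (pos, pos + len(part))
            pos += len(part)
        meta = {
            "rec": offs["rec"],
            "pep": offs["pep"],
            "rec_prot": rec_prot,
            "pep_prot": pep_prot,
            "mature": pep_prot[len(pep_prot) - m :],
            "signal_end": sig_end,
            "spo0e": spo0e,
        }
        if spo0e:
            gap2 = _random_nt(rng, int(rng.integers(20, 80)), cfg.gc_frac)
            sp_prot = "M" + _random_protein(rng, int(rng.integers(120, 160)))
            sp_nt = _backtranslate(sp_prot, rng)
            parts += [gap2, "TAA", sp_nt]
            pos2 = pos + len(gap2) + 3
            meta["spo0e_span"] = (pos2, pos2 + len(sp_nt))
            meta["spo0e_prot"] = sp_prot
        items.append(("locus", "".join(parts), meta))
    for i in range(cfg.decoy_tpr):
        n_units = int(rng.integers(cfg.n_tpr_units[0], cfg.n_tpr_units[1] + 1))
        rec_prot = _receptor_protein(rng, profile, n_units)
        rec_nt = _backtranslate(rec_prot, rng)
        window = _scrub_initiators(_random_nt(rng, miner.window_fwd_nt + 10, cfg.gc_frac))
        cassette = "TAA" + rec_nt + window
        items.append(("decoy_tpr", cassette, {"rec": (3, 3 + len(rec_nt)), "rec_prot": rec_prot}))
    for i in range(cfg.decoy_short_orf):
        prot = _decoy_short_orf_protein(rng, cfg)
        nt = _backtranslate(prot, rng)
        items.append(("decoy_orf", "TAA" + nt, {"orf": (3, 3 + len(nt)), "prot": prot}))
    for i in range(cfg.decoy_random_genes):
        prot = "M" + _random_protein(rng, int(rng.integers(250, 350)))
        nt = _backtranslate(prot, rng)
        items.append(("decoy_gene", "TAA" + nt, {"gene": (3, 3 + len(nt)), "prot": prot}))
    return items


def _map_span(local: tuple[int, int], off: int, clen: int, strand: str) -> tuple[int, int]:
    a, b = local
    if strand == "+":
        return off + a, off + b
    return off + clen - b, off + clen - a


def simulate_genome(config: SimConfig | None = None, miner_config: MinerConfig | None = None):
    """Generate (genomes, truth, features) with planted loci and decoys.

    Deterministic given ``config.seed``. Raises when the configured contig
    length cannot hold the planted cassettes plus minimal intergenic gaps.
    """
    cfg = config or SimConfig()
    miner = miner_config or MinerConfig()
    rng = np.random.default_rng(cfg.seed)
    profile = load_builtin_profile()
    items = _item_cassettes(cfg, rng, profile, miner)

    per_contig: list[list] = [[] for _ in range(cfg.n_contigs)]
    for i, item in enumerate(items):
        per_contig[i % cfg.n_contigs].append(item)

    genomes: list[GenomeRecord] = []
    loci: list[PlantedLocus] = []
    decoy_receptors: list[GeneFeature] = []
    decoy_short_orfs: list[GeneFeature] = []
    decoy_random: list[GeneFeature] = []
    features: list[GeneFeature] = []
    locus_counter = 0
    for ci, contig_items in enumerate(per_contig):
        contig_id = f"contig{ci + 1}"
        total_cassette = sum(len(c) for _, c, _ in contig_items)
        n_gaps = len(contig_items) + 1
        min_gap = 60
        leftover = cfg.contig_len_nt - total_cassette - min_gap * n_gaps
        if leftover < 0:
            raise ValueError(
                f"contig_len_nt={cfg.contig_len_nt} too small for planted genes "
                f"({total_cassette} nt); increase contig_len_nt"
            )
        extra = rng.multinomial(leftover, np.ones(n_gaps) / n_gaps)
        gaps = [min_gap + int(e) for e in extra]
        seq_parts = []
        pos = 0
        for gi, (kind, cassette, meta) in enumerate(contig_items):
            gap = _random_nt(rng, gaps[gi], cfg.gc_frac)
            seq_parts.append(gap)
            pos += len(gap)
            strand = "+" if rng.random() < 0.5 else "-"
            clen = len(cassette)
            seq_parts.append(cassette if strand == "+" else revcomp(cassette))
            off = pos
            if kind == "locus":
                locus_counter += 1
                lid = f"truth{locus_counter:03d}"
                rs, re_ = _map_span(meta["rec"], off, clen, strand)
                ps, pe = _map_span(meta["pep"], off, clen, strand)
                loci.append(
                    PlantedLocus(
                        locus_id=lid,
                        contig_id=contig_id,
                        strand=strand,
                        receptor_start=rs,
                        receptor_end=re_,
                        peptide_start=ps,
                        peptide_end=pe,
                        receptor_protein=meta["rec_prot"],
                        propeptide=meta["pep_prot"],
                        mature=meta["mature"],
                        signal_end=meta["signal_end"],
                        spo0e=meta["spo0e"],
                    )
                )
                features.append(
                    GeneFeature(contig_id, rs, re_, strand, "CDS",
                                product="quorum-sensing peptide receptor",
                                protein=meta["rec_prot"], feature_id=f"{lid}_receptor")
                )
                features.append(
                    GeneFeature(contig_id, ps, pe, strand, "peptide_ORF",
                                product="quorum-sensing pro-peptide",
                                protein=meta["pep_prot"], feature_id=f"{lid}_peptide")
                )
                if meta["spo0e"]:
                    ss, se = _map_span(meta["spo0e_span"], off, clen, strand)
                    features.append(
                        GeneFeature(contig_id, ss, se, strand, "CDS",
                                    product="Spo0E-like sporulation regulatory protein",
                                    protein=meta["spo0e_prot"],
                                    feature_id=f"{lid}_spo0e")
                    )
            elif kind == "decoy_tpr":
                rs, re_ = _map_span(meta["rec"], off, clen, strand)
                feat = GeneFeature(contig_id, rs, re_, strand, "CDS",
                                   product="TPR-repeat protein (no cognate peptide)",
                                   protein=meta["rec_prot"],
                                   feature_id=f"decoy_tpr_{len(decoy_receptors) + 1}")
                decoy_receptors.append(feat)
                features.append(feat)
            elif kind == "decoy_orf":
                os_, oe = _map_span(meta["orf"], off, clen, strand)
                feat = GeneFeature(contig_id, os_, oe, strand, "peptide_ORF",
                                   product="hypothetical short ORF",
                                   protein=meta["prot"],
                                   feature_id=f"decoy_orf_{len(decoy_short_orfs) + 1}")
                decoy_short_orfs.append(feat)
                features.append(feat)
            else:
                gs, ge = _map_span(meta["gene"], off, clen, strand)
                feat = GeneFeature(contig_id, gs, ge, strand, "CDS",
                                   product="hypothetical protein",
                                   protein=meta["prot"],
                                   feature_id=f"decoy_gene_{len(decoy_random) + 1}")
                decoy_random.append(feat)
                features.append(feat)
            pos += clen
        seq_parts.append(_random_nt(rng, gaps[-1], cfg.gc_frac))
        genomes.append(GenomeRecord(id=contig_id, seq="".join(seq_parts),
                                    description="synthetic contig"))

    truth = SyntheticTruth(
        loci=loci,
        decoy_receptors=decoy_receptors,
        decoy_short_orfs=decoy_short_orfs,
        decoy_random_genes=decoy_random,
        features=features,
        config=cfg,
    )
    return genomes, truth, features


@dataclass
class FragSimParams:
    """Fragment-simulation model: 1-3 cleavage sites near the signal end,
    each fragment running to the mature cut with probability
    ``mature_release_prob`` (else to the C terminus), geometric spectral
    counts, and noise fragments drawn from non-peptide proteins. Fragments
    are emitted only within the MS-detectable 5-35 aa band; an infeasible
    cut marks the peptide undetectable in the truth."""

    n_cleavage_sites: tuple[int, int] = (1, 3)
    mature_release_prob: float = 0.5
    spectra_mean: float = 8.0
    noise_fragment_rate: float = 0.1
    fragment_len_aa: tuple[int, int] = (5, 35)


def simulate_fragments(
    truth: SyntheticTruth,
    params: FragSimParams | None = None,
    seed: int = 0,
) -> list[MsFragment]:
    """Simulated MS fragment set for the planted pro-peptides.

    Records per-fragment origins and per-peptide mature-detectability in
    ``truth``; deterministic given ``seed``.
    """
    p = params or FragSimParams()
    rng = np.random.default_rng(seed)
    flo, fhi = p.fragment_len_aa
    fragments: list[MsFragment] = []
    truth.fragment_origins = []
    truth.mature_detectable = {}
    if not truth.loci:
        raise ValueError("truth contains no planted peptides")

    def emit(seq: str, pid: str, start: int, end: int, noise: bool = False) -> None:
        count = 1 + int(rng.geometric(1.0 / p.spectra_mean))
        fragments.append(MsFragment(sequence=seq, spectra_count=count, sample="sim"))
        truth.fragment_origins.append(FragmentOrigin(seq, pid, start, end, noise))

    for locus in truth.loci:
        pro = locus.propeptide
        L = len(pro)
        e = L - len(locus.mature)
        sig_end = locus.signal_end
        n_cuts = int(rng.integers(p.n_cleavage_sites[0], p.n_cleavage_sites[1] + 1))
        truth.mature_detectable[locus.locus_id] = False
        band_lo = max(1, sig_end - 4)
        cuts = sorted(
            rng.choice(
                np.arange(band_lo, sig_end + 1),
                size=min(n_cuts, sig_end + 1 - band_lo),
                replace=False,
            ).tolist()
        )
        for s in cuts:
            end = e if rng.random() < p.mature_release_prob else L
            lo = max(s, end - fhi)
            if lo > min(sig_end, end - flo):
                continue  # no detectable fragment from this cut
            s_eff = max(s, lo)
            if end - s_eff < flo or end - s_eff > fhi:
                continue
            emit(pro[s_eff:end], locus.locus_id, s_eff, end)
            if end == e:
                truth.mature_detectable[locus.locus_id] = True

    non_pep = [
        f.protein
        for f in truth.decoy_random_genes + truth.decoy_receptors
        if len(f.protein) > fhi
    ]
    n_noise = int(round(p.noise_fragment_rate * len(truth.loci)))
    for _ in range(n_noise):
        if not non_pep:
            break
        src = non_pep[rng.integers(len(non_pep))]
        flen = int(rng.integers(flo, fhi + 1))
        start = int(rng.integers(0, len(src) - flen + 1))
        emit(src[start : start + flen], "noise", start, start + flen, noise=True)
    return fragments


def fragments_to_rows(fragments: list[MsFragment]) -> list[dict]:
    return [
        {"sequence": f.sequence, "spectra_count": f.spectra_count, "sample": f.sample}
        for f in fragments
    ]


def truth_to_rows(truth: SyntheticTruth) -> list[dict]:
    return [
        {
            "locus_id": l.locus_id,
            "contig": l.contig_id,
            "strand": l.strand,
            "receptor_start": l.receptor_start,
            "receptor_end": l.receptor_end,
            "peptide_start": l.peptide_start,
            "peptide_end": l.peptide_end,
            "propeptide": l.propeptide,
            "mature": l.mature,
            "signal_end": l.signal_end,
            "spo0e": int(l.spo0e),
        }
        for l in truth.loci
    ]
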