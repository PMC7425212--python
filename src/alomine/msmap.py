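"""Mapping MS-identified peptide fragments onto pro-peptides and inferring
secretion cleavage and mature-peptide release.

Secreted pro-peptides lose their N-terminal signal sequence during or after
secretion, so detected fragments start at heterogeneous positions inside
the signal region but contain the C terminus — unless extracellular
processing has released the short mature peptide, in which case fragments
stop short of the C terminus and the missing suffix IS the mature peptide.
The inference below mechanizes exactly that signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .orffinder import MinerConfig
from .seqio import AA_ALPHABET


@dataclass
class MsFragment:
    """One identified peptide sequence with its cumulative spectral count."""

    sequence: str
    spectra_count: int
    sample: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.spectra_count < 0:
            raise ValueError("spectra_count must be >= 0")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(f"invalid residue(s) in fragment: {sorted(bad)}")


@dataclass
class Placement:
    fragment: MsFragment
    start: int
    end: int


@dataclass
class FragmentMap:
    propeptide_id: str
    placements: list[Placement]
    coverage: list[int]
    unique_only: bool


@dataclass
class ProcessingInference:
    propeptide_id: str
    detected: bool
    n_cleavage_positions: int
    cleavage_positions: tuple[int, ...]
    max_internal_end: int | None
    mature_candidate: str
    mature_support: int
    label: str  # mature_called | longer_mature | no_internal_cut | undetected


def _il_collapse(s: str) -> str:
    return s.replace("I", "L")


def map_fragments(
    fragments: list[MsFragment],
    propeptides: dict[str, str],
    unique_only: bool = True,
    config: MinerConfig | None = None,
    collapse_il: bool = False,
    log=None,
) -> dict[str, FragmentMap]:
    """Place each fragment on every pro-peptide by exact substring search.

    Fragments outside the MS-detectable length band (default 5-35 aa) are
    discarded with a logged reason; with ``unique_only`` a fragment matching
    more than one pro-peptide is discarded entirely (the MaxQuant
    unique-peptides convention). ``collapse_il`` treats I and L as
    indistinguishable, as they are by mass.
    """
    cfg = config or MinerConfig()
    lo, hi = cfg.fragment_len_aa
    props = {
        pid: (_il_collapse(seq.upper()) if collapse_il else seq.upper())
        for pid, seq in propeptides.items()
    }
    maps = {
        pid: FragmentMap(pid, [], [0] * len(seq), unique_only)
        for pid, seq in propeptides.items()
    }
    for frag in fragments:
        seq = _il_collapse(frag.sequence) if collapse_il else frag.sequence
        if not (lo <= len(seq) <= hi):
            if log is not None:
                log.info(
                    f"fragment {frag.sequence!r} discarded: length {len(seq)} "
                    f"outside [{lo}, {hi}]"
                )
            continue
        placed: list[tuple[str, int]] = []
        for pid in sorted(props):
            target = props[pid]
            i = target.find(seq)
            while i != -1:
                placed.append((pid, i))
                i = target.find(seq, i + 1)
        matched_props = {pid for pid, _ in placed}
        if unique_only and len(matched_props) > 1:
            if log is not None:
                log.info(
                    f"fragment {frag.sequence!r} discarded: maps to "
                    f"{len(matched_props)} pro-peptides"
                )
            continue
        for pid, i in placed:
            fm = maps[pid]
            fm.placements.append(Placement(frag, i, i + len(seq)))
            for k in range(i, i + len(seq)):
                fm.coverage[k] += frag.spectra_count
    for fm in maps.values():
        fm.placements.sort(key=lambda p: (p.start, p.end, p.fragment.sequence))
    return maps


def infer_processing(
    fmap: FragmentMap,
    propeptide_seq: str,
    config: MinerConfig | None = None,
) -> ProcessingInference:
    """Infer secretion cleavage and the mature peptide from placed fragments.

    Cleavage positions are the distinct placement starts > 0. The candidate
    cut is the internal placement end (end < L) maximizing summed spectral
    support among ends whose suffix length falls in the mature band
    (default 5-10 aa); ties break toward the shortest suffix. When every
    internal end leaves a longer suffix, the max-support internal end is
    reported as a longer-mature candidate; when all placements reach the C
    terminus no internal cut exists.
    """
    cfg = config or MinerConfig()
    L = len(propeptide_seq)
    mlo, mhi = cfg.mature_len_aa
    if not fmap.placements:
        return ProcessingInference(
            fmap.propeptide_id, False, 0, (), None, "", 0, "undetected"
        )
    starts = tuple(sorted({p.start for p in fmap.placements if p.start > 0}))
    internal_ends = sorted({p.end for p in fmap.placements if p.end < L})
    if not internal_ends:
        return ProcessingInference(
            fmap.propeptide_id, True, len(starts), starts, None, "", 0, "no_internal_cut"
        )
    support = {
        e: sum(p.fragment.spectra_count for p in fmap.placements if p.end == e)
        for e in internal_ends
    }
    max_internal_end = max(internal_ends)
    in_band = [e for e in internal_ends if mlo <= (L - e) <= mhi]
    if in_band:
        # max support; ties -> shortest suffix (largest e)
        e_star = max(in_band, key=lambda e: (support[e], e))
        return ProcessingInference(
            fmap.propeptide_id,
            True,
            len(starts),
            starts,
            max_internal_end,
            propeptide_seq[e_star:],
            support[e_star],
            "mature_called",
        )
    e_star = max(internal_ends, key=lambda e: (support[e], e))
    return ProcessingInference(
        fmap.propeptide_id,
        True,
        len(starts),
        starts,
        max_internal_end,
        propeptide_seq[e_star:],
        support[e_star],
        "longer_mature",
    )


def summarize_detection(inferences: list[ProcessingInference]) -> dict[str, int]:
    """Tallies over one inference per pro-peptide."""
    return {
        "n_propeptides": len(inferences),
        "n_detected": sum(1 for i in inferences if i.detected),
        "n_mature_called": sum(1 for i in inferences if i.label == "mature_called"),
    }


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_fragments_tsv(path) -> list[MsFragment]:
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "sample": str})
    required = {"sequence", "spectra_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fragments TSV missing column(s): {sorted(missing)}")
    return [
        MsFragment(
            sequence=row.sequence,
            spectra_count=int(row.spectra_count),
            sample=str(getattr(row, "sample", "") or ""),
        )
        for row in df.itertuples(index=False)
    ]


def inferences_to_rows(inferences: list[ProcessingInference]) -> list[dict]:
    return [
        {
            "propeptide_id": i.propeptide_id,
            "detected": int(i.detected),
            "label": i.label,
            "n_cleavage_positions": i.n_cleavage_positions,
            "mature_candidate": i.mature_candidate,
            "mature_support": i.mature_support,
        }
        for i in inferences
    ]
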