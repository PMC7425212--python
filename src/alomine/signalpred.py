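"""N-terminal secretion-signal prediction for candidate pro-peptides.

A Sec-type signal sequence is a short positively charged n-region followed
by a hydrophobic helix (h-region). The predictor slides a Kyte-Doolittle
hydropathy window over the N-terminal prefix and calls a signal when a
window reaches the hydropathy threshold and at least one K/R precedes it.
A homology-rescue step mechanizes the published manual rule: near-threshold
misses are flipped to positive when the majority of their peptide family is
positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# Kyte & Doolittle hydropathy scale
KD_SCALE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


@dataclass
class SignalParams:
    """Tunables of the hydrophobic-helix heuristic.

    ``h_window`` residues averaged with the Kyte-Doolittle scale must reach
    ``h_threshold`` within the first ``search_prefix`` residues; with
    ``require_positive_n`` at least one K/R must precede the window.
    ``near_threshold_margin`` bounds how far below threshold a call may sit
    and still be eligible for homology rescue.
    """

    hydropathy_scale: dict = field(default_factory=lambda: dict(KD_SCALE))
    h_window: int = 8
    h_threshold: float = 1.6
    n_region_len: int = 5
    require_positive_n: bool = True
    search_prefix: int = 30
    near_threshold_margin: float = 0.15

    def __post_init__(self) -> None:
        if self.h_window < 5:
            raise ValueError("h_window must be >= 5")
        if self.search_prefix < self.h_window + self.n_region_len:
            raise ValueError("search_prefix must be >= h_window + n_region_len")


@dataclass
class SignalCall:
    protein_id: str
    has_signal: bool
    n_region: tuple[int, int]
    h_region: tuple[int, int]
    best_mean_hydropathy: float
    margin: float
    rescued: bool = False


def hydropathy_profile(protein: str, window: int, scale: dict | None = None) -> np.ndarray:
    """Sliding mean hydropathy; value i covers residues [i, i+window).

    Returns an empty array when the window exceeds the protein length.
    """
    sc = scale or KD_SCALE
    vals = np.array([sc.get(aa, 0.0) for aa in protein.upper()])
    L = len(vals)
    if window > L:
        return np.zeros(0)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    return (csum[window:] - csum[:-window]) / window


def predict_signal(protein: str, params: SignalParams | None = None, protein_id: str = "") -> SignalCall:
    """Call an N-terminal Sec-type signal on a pro-peptide.

    Positive iff some h_window within the first search_prefix residues has
    mean hydropathy >= h_threshold and (when required) a K/R occurs before
    that window. Among qualifying windows the highest-mean one is reported;
    a negative call reports the overall best window and a (negative) margin.
    """
    p = params or SignalParams()
    protein = protein.upper()
    if not protein:
        raise ValueError("empty protein")
    prefix = protein[: p.search_prefix]
    means = hydropathy_profile(prefix, p.h_window, p.hydropathy_scale)
    if means.size == 0:
        return SignalCall(protein_id, False, (0, 0), (0, 0), float("-inf"), float("-inf"))

    def n_region_ok(i: int) -> bool:
        if not p.require_positive_n:
            return True
        return any(aa in "KR" for aa in protein[:i])

    order = sorted(range(means.size), key=lambda i: (-means[i], i))
    chosen = None
    for i in order:
        if means[i] < p.h_threshold:
            break
        if n_region_ok(i):
            chosen = i
            break
    best_overall = order[0]
    if chosen is not None:
        i = chosen
        mean = float(means[i])
        return SignalCall(
            protein_id,
            True,
            (0, i),
            (i, i + p.h_window),
            mean,
            (mean - p.h_threshold) / p.h_threshold,
        )
    i = best_overall
    mean = float(means[i])
    return SignalCall(
        protein_id,
        False,
        (0, i),
        (i, i + p.h_window),
        mean,
        (mean - p.h_threshold) / p.h_threshold,
    )


def rescue_by_homology(
    calls: list[SignalCall],
    families,
    params: SignalParams | None = None,
) -> list[SignalCall]:
    """Flip near-threshold negatives whose peptide family is majority-positive.

    ``families`` is an iterable of objects with ``member_ids`` (e.g.
    homology.FamilyCluster); each call's protein may belong to at most one.
    The majority is evaluated on the pre-rescue calls, so the result does not
    depend on processing order. Rescued calls carry ``rescued=True``.
    """
    p = params or SignalParams()
    by_id = {c.protein_id: c for c in calls}
    if len(by_id) != len(calls):
        raise ValueError("duplicate protein ids in calls")
    family_of: dict[str, frozenset] = {}
    for fam in families:
        members = frozenset(fam.member_ids)
        for m in members:
            if m in family_of:
                raise ValueError(f"protein {m!r} assigned to more than one family")
            family_of[m] = members
    out = []
    for c in calls:
        if c.has_signal or c.protein_id not in family_of:
            out.append(c)
            continue
        members = family_of[c.protein_id]
        peers = [by_id[m] for m in members if m in by_id]
        if not peers:
            out.append(c)
            continue
        pos_frac = sum(1 for q in peers if q.has_signal) / len(peers)
        if c.margin >= -p.near_threshold_margin and pos_frac > 0.5:
            out.append(replace(c, has_signal=True, rescued=True))
        else:
            out.append(c)
    return out


def calls_to_rows(calls: list[SignalCall]) -> list[dict]:
    return [
        {
            "protein_id": c.protein_id,
            "has_signal": int(c.has_signal),
            "h_region": f"{c.h_region[0]}-{c.h_region[1]}",
            "margin": f"{c.margin:.4f}",
            "rescued": int(c.rescued),
        }
        for c in calls
    ]
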