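"""Fragment placement and cleavage/mature-peptide inference."""

import random

import pytest

from alomine.msmap import (
    MsFragment,
    infer_processing,
    map_fragments,
    summarize_detection,
)

ALOP13_PRO = "SYFHNITIGNGSQITVSSHGRGG"


def test_alop13_worked_example():
    """The two most abundant fragments of the worked pro-peptide end at the
    internal cut; the missing 6-residue suffix is the mature peptide."""
    frags = [
        MsFragment("SYFHNITIGNGSQITVS", 12),
        MsFragment("FHNITIGNGSQITVS", 4),
    ]
    maps = map_fragments(frags, {"aloP13": ALOP13_PRO})
    inf = infer_processing(maps["aloP13"], ALOP13_PRO)
    assert inf.label == "mature_called"
    assert inf.mature_candidate == "SHGRGG"
    assert len(inf.mature_candidate) == 6
    assert inf.mature_support == 16
    assert inf.cleavage_positions == (2,)  # FHNITI... starts at 2


def test_full_length_fragment_single_placement():
    pro = "MKKLLSSAGGHQSRTPNSHGAGG"
    maps = map_fragments([MsFragment(pro, 3)], {"p": pro})
    (pl,) = maps["p"].placements
    assert (pl.start, pl.end) == (0, len(pro))


def test_unique_only_discards_shared_fragment():
    shared = "SSHGRGGAQ"
    props = {"a": "MKKLL" + shared + "TT", "b": "MRRVV" + shared + "GG"}
    maps = map_fragments([MsFragment(shared, 5)], props, unique_only=True)
    assert not maps["a"].placements and not maps["b"].placements
    maps2 = map_fragments([MsFragment(shared, 5)], props, unique_only=False)
    assert maps2["a"].placements and maps2["b"].placements


def test_length_band_filter():
    props = {"p": "A" * 40}
    frags = [MsFragment("AAAA", 1), MsFragment("A" * 36, 1)]  # 4 aa and 36 aa
    maps = map_fragments(frags, props)
    assert maps["p"].placements == []


def test_placements_match_brute_force_oracle():
    rng = random.Random(6)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    props = {
        f"p{i}": "".join(rng.choice(aas) for _ in range(40)) for i in range(5)
    }
    frags = []
    for _ in range(30):
        pid = f"p{rng.randrange(5)}"
        s = rng.randrange(0, 30)
        e = s + rng.randint(5, 10)
        frags.append(MsFragment(props[pid][s:e], 1))
    maps = map_fragments(frags, props, unique_only=False)
    got = {
        (pid, pl.fragment.sequence, pl.start, pl.end)
        for pid, fm in maps.items()
        for pl in fm.placements
    }
    expected = set()
    for f in frags:
        for pid, seq in props.items():
            for i in range(len(seq) - len(f.sequence) + 1):
                if seq[i : i + len(f.sequence)] == f.sequence:
                    expected.add((pid, f.sequence, i, i + len(f.sequence)))
    assert got == expected


def test_il_collapse_option():
    props = {"p": "MKKILLSAGGHQSRTPNSHGAGG"}
    frag = MsFragment("KKLLLSAGG", 2)  # I read as L
    assert map_fragments([frag], props)["p"].placements == []
    assert map_fragments([frag], props, collapse_il=True)["p"].placements


def test_no_internal_cut():
    pro = "MKKLLSSAGGHQSRTPNSHGAGG"
    frags = [MsFragment(pro[5:], 3), MsFragment(pro[8:], 2)]
    maps = map_fragments(frags, {"p": pro})
    inf = infer_processing(maps["p"], pro)
    assert inf.label == "no_internal_cut" and inf.mature_candidate == ""
    assert inf.detected and inf.n_cleavage_positions == 2


def test_longer_mature():
    pro = "MKKLLSSAGGHQSRTPNSHGAGGAVTQR"  # 28 aa
    frag = pro[3:13]  # ends 15 residues before the C terminus
    maps = map_fragments([MsFragment(frag, 4)], {"p": pro})
    inf = infer_processing(maps["p"], pro)
    assert inf.label == "longer_mature"
    assert inf.mature_candidate == pro[13:]
    assert len(inf.mature_candidate) > 10


def test_undetected():
    maps = map_fragments([], {"p": ALOP13_PRO})
    inf = infer_processing(maps["p"], ALOP13_PRO)
    assert inf.label == "undetected" and not inf.detected


def test_mature_reconstruction_invariant():
    """Prefix up to the cut plus the mature candidate rebuilds the pro-peptide."""
    frags = [MsFragment("SYFHNITIGNGSQITVS", 12)]
    maps = map_fragments(frags, {"p": ALOP13_PRO})
    inf = infer_processing(maps["p"], ALOP13_PRO)
    e = len(ALOP13_PRO) - len(inf.mature_candidate)
    assert ALOP13_PRO[:e] + inf.mature_candidate == ALOP13_PRO


def test_support_monotonicity():
    """Adding more support at the true cut never changes a correct call."""
    frags = [
        MsFragment("SYFHNITIGNGSQITVS", 12),
        MsFragment("NITIGNGSQITVSSHGRG", 9),  # ends 1 short of full: suffix len 1 -> not in band
    ]
    maps = map_fragments(frags, {"p": ALOP13_PRO})
    base = infer_processing(maps["p"], ALOP13_PRO)
    assert base.mature_candidate == "SHGRGG"
    frags.append(MsFragment("FHNITIGNGSQITVS", 100))
    maps2 = map_fragments(frags, {"p": ALOP13_PRO})
    boosted = infer_processing(maps2["p"], ALOP13_PRO)
    assert boosted.mature_candidate == "SHGRGG"
    assert boosted.mature_support > base.mature_support


def test_tie_breaks_to_shortest_suffix():
    pro = "MKKLLSSAGGHQSRTPNSHGAGG"  # 23 aa
    # ends at 16 (suffix 7) and 17 (suffix 6), equal support -> choose 17
    frags = [MsFragment(pro[5:16], 3), MsFragment(pro[5:17], 3)]
    maps = map_fragments(frags, {"p": pro})
    inf = infer_processing(maps["p"], pro)
    assert inf.mature_candidate == pro[17:]


def test_summarize_detection_tallies():
    frags = [MsFragment("SYFHNITIGNGSQITVS", 12)]
    props = {"a": ALOP13_PRO, "b": "MRRVVTTAGGHQSRTPNSHAAGG"}
    maps = map_fragments(frags, props)
    infs = [infer_processing(maps[p], props[p]) for p in sorted(props)]
    counts = summarize_detection(infs)
    assert counts == {"n_propeptides": 2, "n_detected": 1, "n_mature_called": 1}
    assert summarize_detection([]) == {
        "n_propeptides": 0,
        "n_detected": 0,
        "n_mature_called": 0,
    }


def test_fragment_validation():
    with pytest.raises(ValueError):
        MsFragment("ABZ!", 1)
    with pytest.raises(ValueError):
        MsFragment("PEPTIDE", -1)
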