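"""Summary tables and the replicate fold-change summarizer.

Replicate fold-changes are averaged geometrically (the mean of log
fold-changes), the convention under which the worked replicate set
(3.7, 6, 4) prints as 4.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

from .architecture import AloLocus, loci_to_rows
from .msmap import ProcessingInference, inferences_to_rows
from .seqio import write_gff3, write_tsv


@dataclass
class FoldChangeSummary:
    values: tuple[float, ...]
    geometric_mean: float
    rounded: float


def fold_change_summary(values) -> FoldChangeSummary:
    """Geometric mean of per-replicate fold-changes, half-up rounded to 1 dp."""
    vals = tuple(float(v) for v in values)
    if not vals:
        raise ValueError("need at least one fold-change value")
    if any(v <= 0 for v in vals):
        raise ValueError("fold-changes must be positive")
    gm = math.exp(sum(math.log(v) for v in vals) / len(vals))
    rounded = float(Decimal(repr(gm)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return FoldChangeSummary(values=vals, geometric_mean=gm, rounded=rounded)


LOCUS_REPORT_COLUMNS = [
    "locus_id", "contig", "receptor_start", "receptor_end", "strand",
    "tpr_prob", "source", "n_peptides", "orphan", "spo0e_downstream",
    "family_id", "propeptide_id", "detected", "label", "mature_candidate",
    "mature_support",
]


def locus_report(
    loci: list[AloLocus],
    inferences: list[ProcessingInference] | None = None,
    outdir=None,
    contig_lengths: dict[str, int] | None = None,
) -> list[dict]:
    """One row per locus joining mining and MS-inference results.

    ``inferences`` are matched on propeptide_id == the locus's peptide ids;
    inference ids that match no locus raise, listing the offenders. When
    ``outdir`` is given, writes loci.tsv and loci.gff3.
    """
    inferences = inferences or []
    pep_ids = {
        p.feature.feature_id for l in loci for p, _ in l.peptides
    }
    orphans_inf = [i.propeptide_id for i in inferences if i.propeptide_id not in pep_ids]
    if orphans_inf:
        raise ValueError(
            f"inference id(s) not found among locus peptides: {sorted(orphans_inf)}"
        )
    inf_by_id = {i.propeptide_id: i for i in inferences}
    rows = []
    for lrow, l in zip(loci_to_rows(loci), loci):
        inf = None
        for p, _ in l.peptides:
            if p.feature.feature_id in inf_by_id:
                inf = inf_by_id[p.feature.feature_id]
                break
        row = dict(lrow)
        if inf is not None:
            irow = inferences_to_rows([inf])[0]
            row.update(
                propeptide_id=irow["propeptide_id"],
                detected=irow["detected"],
                label=irow["label"],
                mature_candidate=irow["mature_candidate"],
                mature_support=irow["mature_support"],
            )
        else:
            row.update(
                propeptide_id="", detected="", label="", mature_candidate="",
                mature_support="",
            )
        rows.append(row)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_tsv(rows, outdir / "loci.tsv", columns=LOCUS_REPORT_COLUMNS)
        feats = []
        for l in loci:
            rf = l.receptor.feature
            rf.feature_id = rf.feature_id or l.locus_id + "_receptor"
            feats.append(rf)
            feats.extend(p.feature for p, _ in l.peptides)
        write_gff3(feats, outdir / "loci.gff3", contig_lengths)
    return rows
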