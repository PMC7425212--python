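# alomine

Genome mining for RRNPP-like peptide–receptor quorum-sensing loci
("Alo"-type systems) in Gram-positive bacteria, plus peptidomics fragment
mapping that infers how the secreted pro-peptides are processed into mature
communication peptides.

## The problem

Many Firmicutes communicate with short peptides. A two-gene operon encodes
(1) an intracellular receptor — an N-terminal helix-turn-helix (HTH)
DNA-binding domain followed by a C-terminal array of degenerate 34-residue
tetratricopeptide repeats (TPRs) that forms the peptide-binding pocket —
and (2) a short pro-peptide (30–50 aa) with an N-terminal Sec secretion
signal (positively charged n-region + hydrophobic h-region). The pro-peptide
is secreted, its signal is cleaved, and extracellular proteases release a
short mature peptide (typically 5–10 aa, usually the pro-peptide's
C terminus) that re-enters the cell and binds the receptor.

`alomine` reimplements the discovery and evidence chain for such loci as a
reusable, fully tested pipeline:

1. **tprscan** — position-specific log-odds scan for C-terminal TPR-like
   repeat arrays. Non-overlapping 34-residue windows are accepted greedily;
   the summed score `S` is converted to a calibrated probability
   `P = logistic(a + b·z)` with `z = (S − μ₀)/σ₀` from a null of
   composition-matched shuffled repeats, anchored so `P = 0.5` at the null
   99th percentile. Receptor seeds require `P > 0.75` and length ≥ 250 aa.
2. **homology** — exact Smith–Waterman (BLOSUM62, affine gaps 11/1) with
   Karlin–Altschul significance `E = K·m·n·e^(−λS)` (K = 0.041, λ = 0.267);
   seeds are expanded transitively (two rounds, E ≤ 1e−5) to recover
   homologs whose repeat region diverged below the scan threshold; families
   are single-linkage components of the hit graph.
3. **orffinder** — six-frame ORF calls; the cognate peptide is a same-strand
   30–50 aa ORF whose start codon lies in the window covering the
   receptor's last 100 nt plus 200 nt downstream.
4. **signalpred** — Kyte–Doolittle sliding-window (8 residues, threshold
   1.6) signal-helix call with a K/R n-region requirement, plus a
   mechanized homology-rescue rule for near-threshold misses in
   majority-positive peptide families.
5. **architecture** — assembles loci, keeps signal-negative cases as
   orphans, and flags loci whose next downstream same-strand gene is
   spo0E-like (a sporulation-phosphatase regulator frequently encoded
   immediately after these operons).
6. **msmap** — places MS-identified peptide fragments on pro-peptides by
   exact substring match (unique peptides only, 5–35 aa). Fragments that
   contain the C terminus but not the N terminus evidence secretion
   cleavage; the *absence* of a short C-terminal suffix from otherwise
   C-terminal-reaching fragments is the signature of mature-peptide
   release, and that missing suffix is the mature peptide.
7. **synthetic_data / report / cli** — a ground-truth genome and fragment
   simulator, summary tables, and a `click` CLI.

## Worked example

```bash
alomine simulate --outdir demo --seed 1
alomine mine demo/genome.fasta --annotations demo/truth.gff3 --outdir demo/mine --seed 0
alomine msmap demo/fragments.tsv demo/propeptides.faa --outdir demo/ms --seed 0
```

The miner logs its per-filter attrition and recovers the planted systems:

```
INFO candidate proteins >= 250 aa: 9
INFO TPR seeds at probability >= 0.75: 7
INFO receptors after homology expansion: 7
INFO assembled 7 loci (2 orphans)
INFO 5/5 pro-peptides detected, 4 mature peptides called
```

The five non-orphan loci are the five planted receptor–peptide operons; the
two orphans are the planted TPR-receptor decoys that genuinely lack a
cognate peptide. `demo/mine/loci.tsv` starts:

```
locus_id  contig   receptor_start  receptor_end  strand  tpr_prob  source    n_peptides  orphan  spo0e_downstream  family_id
alo1      contig1  2213            3140          +       1.0000    tpr_seed  3           0       0                 F001
alo2      contig1  5792            6635          -       1.0000    tpr_seed  2           0       0                 F001
alo3      contig1  8978            9908          +       1.0000    tpr_seed  0           1       0                 F001
```

Fragment mapping on the simulated secretome (`demo/ms/summary.json`) reports
`{"n_propeptides": 5, "n_detected": 5, "n_mature_called": 4}`: four
pro-peptides had fragments ending at an internal cut whose missing 5–10 aa
suffix was called as the mature peptide; the fifth was detected only
through fragments reaching the C terminus (no internal cut).

Replicate fold-changes are averaged geometrically:

```
$ alomine report 3.7 6 4
n=3 geometric_mean=4.4614 rounded=4.5
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes the mature-peptide inference on the worked 23-residue
pro-peptide from its two internal MS fragments by running `map_fragments`
and `infer_processing`, and writes the resulting candidate length (aa) as
JSON.
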