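# pocketcons

Conservation-aware druggability analysis of protein binding pockets.

Antibacterial target selection needs two answers at once: can a binding site
bind potent drug-like small molecules (*druggability*), and is it
evolutionarily conserved enough across pathogens that resistance is unlikely
and a broad-spectrum inhibitor is feasible? `pocketcons` implements both
halves as an open, tested pipeline for structural bioinformaticians: per-residue
conservation grading from a multiple sequence alignment and a
neighbor-joining tree, grid-based pocket detection with physicochemical
descriptors and the SiteScore/DScore druggability equations, simplified
fragment-probe hotspot mapping, and the combined filter that keeps only
conserved *and* druggable sites.

## The model

**Conservation.** Sequences are curated (length outliers below 60% of the
family mean removed, one representative per organism), pairwise distances are
computed from BLOSUM62 similarities rescaled per pair to [0, 1], and a
neighbor-joining tree is built (Saitou–Nei, deterministic tie-breaks).
Per-column conservation is a tree-weighted sum-of-pairs statistic
(Gerstein–Sonnhammer–Chothia sequence weights), standardised across columns
and binned into nine equal-width grades, grade 9 = most conserved. Grades are
projected onto a structure by global pairwise alignment; "conserved" means
grade 8 or 9.

**Druggability.** A fine grid (default 0.35 Å) is laid over the structure;
*site points* are sterically accessible grid points within 4 Å of the protein
whose ray-cast burial is at least 0.5 (110 quasi-uniform rays, 8 Å reach).
Connected components with ≥ 15 points become sites (at most 10 reported),
each with a descriptor block — volume *n*·spacing³, enclosure *e* (mean
burial), exposure, contact, hydrophobic/hydrophilic character, their balance,
donor/acceptor character, charged lining fraction — and two scores:

    SiteScore = 0.0733·√min(n,100) + 0.6688·e − 0.20·min(p,1)
    DScore    = 0.094 ·√min(n,100) + 0.60  ·e − 0.324·p

with *p* the hydrophilic score (capped at 1 only in SiteScore). 0.8 is the
ligandable/druggable threshold on both scores.

**The combined filter.** A site is retained when SiteScore ≥ 0.8, DScore ≥
0.8 and at least 50% of its graded lining residues are conserved; a charged
lining fraction above 26.3% raises an additional warning flag. Sites are
typed orthosteric / cofactor / other by 4 Å proximity to reference ligand or
cofactor atoms, and group differences (e.g. orthosteric vs other scores) are
tested with an exact, tie-aware Mann–Whitney U test.

A synthetic-data module generates every input the pipeline needs — shell
proteins with engineered cavities of controlled size, mouth opening and
lining chemistry; alignments evolved along known trees with slow/fast site
classes; structure ensembles with planted conformational families; candidate
descriptor tables — so the whole analysis is testable without downloads.

## Worked example

```sh
pcp run --config config.yaml --out out/
```

with

```yaml
seed: 1
structure:
  synthetic:
    shell_radius: 12.0
    cavity_radius: 4.0
    mouth_fraction: 0.1
    residue_count: 90
    plant_ligand: true
alignment:
  synthetic:
    n_leaves: 8
```

builds a 90-residue shell protein with a 4 Å cavity whose lining evolves
slowly, evolves an 8-sequence alignment from its sequence, grades
conservation, detects pockets, maps probes and applies the combined filter.
It prints (abridged):

```json
{
  "n_sites": 2,
  "n_probe_clusters": 41,
  "n_predicted_sites": 3,
  "percent_conserved_residues": 50.617,
  "retained_ranks": [1, 2],
  "stage_counts": {"input": 2, "after_scores": 2, "after_conservation": 2}
}
```

The rank-1 site is the planted cavity: orthosteric (its lining touches the
planted ligand), SiteScore 1.045 and DScore 1.054 (both above the 0.8
threshold, upper-right quadrant), 82% of its lining conserved — so it is
retained. `out/assessment.csv` holds the per-site record, `out/sites.csv`
the full descriptor block, and `out/manifest.json` the seeds and thresholds
that make the run reproducible byte for byte.

The same stages are available piecemeal: `pcp simulate`, `pcp conserve`,
`pcp structures` (ensemble RMSD + k-means representatives), `pcp pockets`,
`pcp hotspots` — or as library functions in `pocketcons.seqcons`,
`.structio`, `.sitefind`, `.probemap`, `.assess`, `.synthdata`.

## Acceptance script

`scripts/acceptance.py` re-runs the complete synthetic end-to-end analysis
from scratch — structure generation, alignment evolution, conservation
grading, pocket detection, probe mapping and the combined filter — and
writes the machine-readable results object:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The full pipeline report lands next to it under `results/pipeline/`.

## Documentation

`docs/methods.md` describes the scoring model, the surrogate choices behind
the descriptors and probe mapping, every tunable parameter with its default,
and what the synthetic generators do and do not emulate.
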