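# wyldomkit

A profile-HMM survey toolkit for WYL-domain transcription factors in
bacteria.

WYL domains are Sm-fold domains found in a widespread family of bacterial
transcriptional regulators (the PafBC family of the mycobacterial DNA damage
response is the best-studied example). In most of these proteins the WYL
domain sits between an N-terminal winged helix-turn-helix (HTH) DNA-binding
domain and a C-terminal extension (WCX) with a ferredoxin-like fold; a
smaller group pairs the WYL domain with a helicase domain instead. Surveying
this family across reference proteomes requires carving clean profile HMMs
for WYL, WCX and the two HTH wing sub-types out of a composite profile that
spans both WYL and WCX, annotating every proteome with those models,
grouping proteins into clan-level domain-architecture classes, and
aggregating the classes over the taxonomy.

`wyldomkit` implements that pipeline end to end, self-contained:

- **`msa_core`** — sequences, pairwise identity (shorter-sequence
  denominator), greedy identity clustering, a deterministic progressive
  aligner (UPGMA guide tree, BLOSUM62 profile-profile merges), alignment
  trimming, subunit-pair concatenation and per-column conservation scores.
- **`phmm_engine`** — a local multi-hit profile-HMM engine: model estimation
  from alignments, Viterbi/Forward scoring in bits against an i.i.d.
  background null, per-domain envelope extraction, Gumbel E-value
  calibration on random sequences, and threshold-driven `search`/`scan`
  with the survey's E-value bounds (search `-E 1 -domE 1 -incE 0.01
  -incdomE 0.03`; scan `-E 0.1 -domE 0.1 -incE 0.01 -incdomE 0.03`).
- **`hmm_maturation`** — the iterative model-definition protocol:
  length-stratified sampling around the 127-residue composite split,
  automated seed curation, boundary definition from short-hit C-termini,
  and rebuild-and-research iterations gated by a bit-score gathering
  threshold (27.0 for WYL with 3 iterations; 30.0 with 1 iteration for the
  HTH wing models at 90% clustering identity; no iteration for WCX).
- **`architecture_classifier`** — clan-level signatures (independent domain
  E-value < 0.01), same-clan overlap resolution, class grouping with
  length/boundary statistics, the <100-member display filter, and the
  127-residue composite length split.
- **`taxonomy_stats`** — per-taxon unique-species counts and
  sequences-per-species averages, non-bacterial exclusion, the 1.5%
  small-group display filter, and per-organism averages over a species
  universe that includes zero-hit species.
- **`synthetic_data`** — a deterministic generator of reference-proteome-like
  collections with planted architectures (HTH-WYL-WCX, HTH-WYL, fused
  tandem modules, helicase-associated WYL), BLOSUM-biased substitution
  noise, indels, taxonomy labels and full ground truth, so every stage is
  verifiable without downloads.

## The model

A profile HMM with match states M_1..M_M, inserts and deletes is scored
against a sequence in a Plan7-style local multi-hit topology (flanking N/C
states, a J loop between domains, uniform local entry B→M_k and free local
exit M_k→E). Scores are log-odds in bits,

    S(x) = log2 P(x | profile) − log2 P(x | null),

with an i.i.d. background null and geometric length model. Statistical
significance comes from a Gumbel law fitted by maximum likelihood to
multi-hit Viterbi scores of random background sequences:

    E(S) = N · (1 − exp(−exp(−λ (S − μ)))),

monotone decreasing in S and linear in the database size N. Per-domain
scores rescore each envelope with the full-sequence flank costs so they sit
on the calibration scale.

## Worked example

```python
from wyldomkit import (default_library, emit_collection, progressive_align,
                       build_profile, calibrate, scan, GeneratorConfig)
from wyldomkit.synthetic_data import PhylumSpec, seed_instances
from wyldomkit.architecture_classifier import resolve_overlaps, signature_of

library = default_library()
cfg = GeneratorConfig(seed=7, phyla=[PhylumSpec("Actinobacteria", 5, 3.0)],
                      background_proteins_per_species=1)
collection = emit_collection(cfg, library)

models = []
for i, arch in enumerate(library.values()):
    seed_aln = progressive_align(seed_instances(arch, 30, 0.15, 0.02, seed=i))
    model = build_profile(seed_aln, name=arch.name, clan=arch.clan)
    calibrate(model, n_random=150, length=300, seed=11)
    models.append(model)

protein = collection.records[0]
hits = resolve_overlaps([h for h in scan(models, protein) if h.included])
print(protein.id, "->", " - ".join(signature_of(hits)))
for h in hits:
    print(f"  {h.model_name:6s} {h.env_start:4d}-{h.env_end:<4d} "
          f"{h.bit_score:7.1f} bits  iE={h.i_evalue:.2g}")
```

prints

```
acti_sp001.p001 -> Helicase - WYL
  HelC     28-146    281.7 bits  iE=5.6e-84
  WYL     181-270    261.0 bits  iE=1.5e-82
```

a helicase-associated WYL protein: the helicase model matches residues
28–146 and the WYL model 181–270, both far above the inclusion thresholds,
and the clan signature Helicase–WYL matches the planted truth
(`HelC:28-146;WYL:181-270`) exactly.

The same stages are available from the shell:

```
wyldomkit simulate --seed 42 --out-prefix out/collection
wyldomkit build-seed --msa seed.afa --name WYL --out WYL.hmm
wyldomkit mature --db out/collection.fasta --seed-msa seed.afa --out WYL.hmm
wyldomkit scan --models models/ --fasta out/collection.fasta --out hits.tsv
wyldomkit classify --models models/ --fasta out/collection.fasta --out-prefix out/arch
wyldomkit taxstats --arch out/arch.architectures.tsv --tax out/collection.taxonomy.tsv --out out/phyla.tsv
```

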