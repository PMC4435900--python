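# motiftrace

Phylogenomic tracing of short conserved motifs ("microdomains") in the
intrinsically disordered regions of a bacterial protein family.

Many bacterial hub proteins — the archetype being RNase E, the scaffold of
the RNA degradosome in the γ-Proteobacteria — carry a conserved catalytic
core followed by a large intrinsically disordered (ID) region. The ID
region evolves fast and shows strong composition bias (RNQ-rich and
AEPV-rich blocks) and tandem repeats, yet it harbours short conserved
motifs of 10–25 residues that mediate binding to proteins, membranes and
RNA (e.g. the membrane-targeting amphipathic helix, the helicase / enolase
/ PNPase binding sites). `motiftrace` reconstructs when such motifs were
gained and lost during the evolution of the family: from per-genome
proteomes and a rooted species tree it infers orthologs, extracts the
family, annotates the disordered region, discovers the motifs, and places
each motif's acquisition on the tree.

## The pipeline

1. **Orthology** — all protein pairs between genomes are scored by exact
   Smith–Waterman local alignment (BLOSUM62, affine gaps). If *a* is the
   best hit of *b* and *b* the best hit of *a* they are orthologs; they are
   *one-to-one* orthologs when no within-genome paralog outscores the pair.
2. **Families** — the one-to-one pairs form an unweighted graph; the
   Markov Cluster Algorithm (alternating expansion M→M^e and inflation
   M→M^{∘r} of a column-stochastic flow matrix) extracts the families.
   The inflation exponent r controls granularity.
3. **Region annotation** — composition-biased segments are called by an
   exact binomial tail test P(X ≥ k) against background residue
   frequencies at a stringent threshold (default 1e−15); tandem repeats,
   the hydrophobic moment μ_H = |Σ_n H(r_n) e^{i n δ}|/L (δ = 100° for an
   α-helix), fixed patterns such as the Zn-link `CPxCxGxG`, and a
   charge–hydropathy disorder heuristic complete the annotation.
4. **Motif discovery** — a ZOOPS (zero-or-one occurrence per sequence)
   finite mixture: with probability γ a sequence carries one motif
   instance emitted column-wise from a PWM θ, all other residues being
   i.i.d. background. Up to 30 motifs of width 10–25 are discovered
   sequentially by expectation–maximisation with erasure; sequences are
   annotated with log-odds scanning, giving a binary motif × species
   presence matrix.
5. **Ancestral reconstruction** — each motif's presence evolves as a
   two-state continuous-time Markov chain with gain rate a (0→1) and loss
   rate b (1→0); P01(t) = a/(a+b)·(1−e^{−(a+b)t}). Rates are fitted by
   maximum likelihood (Felsenstein pruning), marginal posterior state
   probabilities are computed at every node, and a motif is called
   *acquired once* when thresholding the marginals (default P ≥ 0.92)
   yields exactly one gain event.

A synthetic-evolution module generates the whole study design with known
ground truth — Yule species trees, characters evolved under the two-state
chain, and proteomes with conserved cores, biased fast-evolving ID
regions, repeat tracks and planted motif instances — so every inference
step can be scored exactly.

## Worked example

Simulate 16 species in which motif `alpha` was gained on the stem of one
clade and motif `beta` on the stem of another, then run the full pipeline:

```python
import shutil
from motiftrace.simulate import clade_gain_scenario, write_dataset
from motiftrace.pipeline import PipelineConfig, run_pipeline

tree, proteomes, truth, stems = clade_gain_scenario(seed=1)
print("clade stems:", stems)
write_dataset("example/data", tree, proteomes, truth)

cfg = PipelineConfig(
    outdir="example/run", seed=1,
    proteomes_dir="example/data/proteomes",
    tree_path="example/data/species.nwk",
    manifest_path="example/data/manifest.tsv",
    core_boundaries_path="example/data/core_boundaries.tsv",
    n_motifs=8)
report = run_pipeline(cfg)
print(report[["rank", "motif", "width", "consensus", "gain_nodes",
              "scaled_likelihood_of_gain", "call"]].to_string(index=False))
```

Output:

```
clade stems: {'alpha': 'n009', 'beta': 'n004'}
 rank  motif  width              consensus gain_nodes  scaled_likelihood_of_gain     call
    1 motif1     12           AEVPAEVPAEVP       n001                     1.0000     once
    2 motif2     10             REEREEREEH       n001                     1.0000     once
    3 motif3     10             HKCMFDYWIH       n009                     0.9749     once
    4 motif4     10             QYNRIIARNI  n003;n014                     0.9938 multiple
    5 motif5     22 KLERAKKKPQAGRNQTDNGREE       n014                     0.9905     once
    6 motif6     19    YRKSNIKKRCSNNKQPDEQ       n014                     0.9905     once
    7 motif7     10             LDGYFWPTNK       n004                     0.9235     once
    8 motif8     15        WGHPAAFDPKWQHNK       n014                     0.9905     once
```

Reading the table: motifs 1–2 are the AEVP/REE tandem-repeat tracks —
low-complexity sequence present in every species, hence "gained" at the
root (`n001`) with probability 1. Motif 3 is the planted `alpha` motif
(a fragment of its consensus `WQHKCMFDYWIHECM`): a single confident gain
at node `n009`, exactly the clade stem the simulator used, with marginal
gain probability 0.97. Motif 7 is the planted `beta` motif, recovered at
its true stem `n004`. The remaining motifs are background coincidences
shared by closely related species — the kind of weak clade-restricted
signal a real analysis also reports. The `scaled_likelihood_of_gain`
column is the posterior probability of presence at the gain node; `call`
distinguishes single from multiple acquisitions.

The same stages are available from the shell:

```bash
motiftrace pipeline --config config.json --seed 1 --outdir run/
motiftrace simulate --config config.json      # or any single stage
```

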