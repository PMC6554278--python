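# codonopt

Codon optimization for recombinant protein expression in GC-rich
actinobacteria (and similar hosts), based on weakening mRNA secondary
structure at the translation-initiation region.

## The problem and the method

When a gene is expressed from a plasmid vector, translation efficiency —
and hence protein yield — depends strongly on the 5′ end of the mRNA. Two
sequence properties matter most:

* **ΔG_UH** — the predicted folding free energy (kcal/mol) of the RNA
  region formed by the vector's 5′ UTR plus the first 33 nucleotides
  (11 codons) of the coding sequence. Higher (less negative) ΔG_UH means
  weaker secondary structure around the ribosome-binding site and start
  codon, which correlates positively with expression.
* **CAI_H** — the codon adaptation index restricted to those 11 head
  codons: the geometric mean of relative-adaptiveness weights
  w_c = f_c / max_s f_s derived from the host's genomic codon usage.
  *Rare codons* are those with w_c < 0.1.

Because only the head is mutated (downstream nucleotides stay untouched,
so the designs are reachable by cheap primer-based mutagenesis), the
synonymous variant space stays small enough to fold **every** variant:

* **H-method** — enumerate all synonymous variants of the 11 head codons,
  fold each UTR+head region, and propose the variants with the highest
  ΔG_UH (H1, H2, H3, …).
* **C-method** — the same argmax, restricted to variants with CAI_H above
  a user threshold (typical operating points 0.60 / 0.75 / 0.90) and no
  rare codon in the head. This guards against the failure mode where the
  unconstrained optimum buys folding energy with AT-rich rare codons.
* **L-series** — the mirror argmin (deoptimized controls, useful for
  down-regulation).

The design rules are derived from data by **polyserial correlation**
between each continuous sequence feature (ΔG_UH, CAI, CAI_H, tAI, codon
and amino-acid repetition rates, head rare-codon count) and ordinal
expression scores y ∈ {1, 2, 3} assumed to discretize a latent Gaussian
liability: ρ = corr(x, liability), estimated either by the classical
two-step formula ρ = r_xy · s_y / Σ_k φ(τ_k) or by maximum likelihood,
with a window scan over (UTR suffix length, head length) to locate where
the folding-energy signal lives.

Folding is pluggable: a self-contained pair-energy model (exactly
verifiable against exhaustive structure enumeration) is the default;
ViennaRNA and RNAstructure's `EnsembleEnergy` are optional backends.

## Worked example

```python
from codonopt import (
    CodingSequence, HeadRegionSpec, BuiltinBackend, FIXTURE_UTR,
    synthetic_usage_table, cai_weights, rare_codons,
    h_method, c_method, deoptimize, dG_UH,
)

usage = synthetic_usage_table(seed=0, gc_bias=0.9)   # GC-rich host stand-in
cw = cai_weights(usage)
rare = rare_codons(usage, threshold=0.1)

seq = CodingSequence("example", "ATGAAACTGTTCGAAGACGGTGCCATCCTGGTTCGTGAA")
spec = HeadRegionSpec(utr=FIXTURE_UTR, head_nt=12)   # 4-codon head window
backend = BuiltinBackend()

print(round(dG_UH(seq, spec, backend), 3))           # wild-type energy
h = h_method(seq, spec, backend, k=3, cai_weights=cw)
c = c_method(seq, spec, backend, cw, rare, cai_h_min=0.75, k=1)
l = deoptimize(seq, spec, backend, k=1)
```

prints (wild type first, then the ranked designs):

```
wild-type dG_UH  = -67.873 kcal/mol
H1: head=ATGAAGTTATTT  dG_UH=-65.317  CAI_H=0.193
H2: head=ATGAAATTATTT  dG_UH=-65.437  CAI_H=0.108
H3: head=ATGAAGCTTTTT  dG_UH=-65.576  CAI_H=0.338
C1: head=ATGAAGCTCTTC  dG_UH=-66.227  CAI_H=1.000  rare=0
L1: head=ATGAAACTGTTC  dG_UH=-67.873
```

Reading this: the unconstrained H1 design gains ~2.6 kcal/mol of folding
energy over wild type but does it with the AT-rich rare codon TTA,
crashing CAI_H to 0.19 — precisely the failure mode the C-method exists
for. C1 gives up 0.9 kcal/mol of that gain but keeps CAI_H at 1.0 with
zero rare codons. The L1 deoptimized control coincides with the wild type
here because the wild-type head is already the energy minimum. Every
design translates to the same protein, and energies always satisfy
L1 ≤ wild type ≤ H1.

The same workflows are available from the shell:

```bash
codonopt fixtures study/ --seed 5 --n-genes 204
codonopt optimize study/genes.fasta designs.tsv --method c --cai-min 0.75 \
    --usage study/usage.tsv --utr study/utr.txt
codonopt analyze study/features.tsv study/scores.tsv analysis.tsv
codonopt scan study/genes.fasta study/scores.tsv scan.tsv --utr study/utr.txt
```

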