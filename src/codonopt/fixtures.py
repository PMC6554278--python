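"""Self-contained synthetic fixtures emulating the study's inputs.

The real study measured ordinal expression scores for 204 genes expressed
from one plasmid vector in a GC-rich actinobacterial host; its inputs (the
gene set, the vector's 5' UTR, the genomic codon-usage table, tRNA gene
copy numbers) are external data. This module generates statistically
analogous stand-ins so every analysis in the package runs offline:

* random proteins back-translated under a GC-biased synthetic usage table
  (with per-gene variation in codon optimality so CAI spreads out);
* a synthetic 60-nt UTR containing a purine-rich Shine-Dalgarno-like
  motif (the real vector UTR is not public);
* ordinal expression scores drawn from a latent-Gaussian liability built
  from the standardized *true* feature values of the generated sequences
  at configured latent correlations — so downstream feature-expression
  analysis can genuinely recover the planted structure end to end.

Identical configs yield bit-identical fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codon_data import (
    BASES,
    CODONS,
    CodonUsageTable,
    GeneticCode,
    TAIWeights,
    cai_weights,
    rare_codons,
    tai_weights,
)
from .folding import HeadRegionSpec
from .seq_features import CodingSequence, feature_table

__all__ = [
    "FIXTURE_UTR",
    "FixtureConfig",
    "SyntheticDataset",
    "random_protein",
    "random_cds",
    "synthetic_usage_table",
    "synthetic_trna_copy_numbers",
    "synthetic_tai_weights",
    "synthetic_expression_dataset",
]

#: fixed synthetic 60-nt vector UTR with an embedded SD-like AGGAGG motif
#: ~10 nt upstream of the start codon
FIXTURE_UTR = "GCTAGTTCACTGCCGATCGGTACTTGACAACCTTCGGGTATCAAGGAGGTGATCTACAAC"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_protein(length: int, seed=None, weights: Mapping[str, float] | None = None) -> str:
    """Random amino-acid string of ``length`` starting with M.

    Residues after the initiator are drawn uniformly over the 20 standard
    amino acids, or from ``weights`` when given.
    """
    if length < 2:
        raise ValueError("protein length must be >= 2")
    rng = _rng(seed)
    aas = list(AMINO_ACIDS)
    if weights is None:
        p = None
    else:
        p = np.array([weights.get(a, 0.0) for a in aas], dtype=float)
        p = p / p.sum()
    draws = rng.choice(aas, size=length - 1, p=p)
    return "M" + "".join(draws)


def random_cds(
    protein: str,
    usage: CodonUsageTable,
    seed=None,
    power: float = 1.0,
    gene_id: str = "synth",
) -> CodingSequence:
    """Back-translate a protein, sampling codons with probability
    proportional to usage counts raised to ``power`` (power 0 = family
    uniform, large power = always the most-used codon)."""
    rng = _rng(seed)
    code = usage.code
    codons = []
    for aa in protein:
        fam = sorted(code.families[aa])
        w = np.array([usage.counts[c] for c in fam], dtype=float)
        if w.sum() == 0:
            w = np.ones(len(fam))
        w = np.power(w, power) if power != 1.0 else w
        w = w / w.sum()
        codons.append(fam[int(rng.choice(len(fam), p=w))])
    return CodingSequence(id=gene_id, nt="".join(codons))


def synthetic_usage_table(seed=None, gc_bias: float = 0.9) -> CodonUsageTable:
    """A codon-usage table biased toward G/C-rich codons.

    Each codon's count is proportional to the product over its three
    positions of ``gc_bias`` (G or C) vs ``1 - gc_bias`` (A or T), times a
    modest lognormal noise term. At ``gc_bias=0.5`` families are
    near-uniform; at ``gc_bias >= 0.9`` strongly AT-rich codons in mixed
    families (e.g. TTA, ATA, AGA) fall below the 0.1 rare-codon cutoff,
    mirroring a GC-rich actinobacterial genome.
    """
    if not (0.0 < gc_bias < 1.0):
        raise ValueError("gc_bias must be in (0,1)")
    rng = _rng(seed)
    counts = {}
    for codon in CODONS:
        base = 1.0
        for b in codon:
            base *= gc_bias if b in "GC" else (1.0 - gc_bias)
        noise = math.exp(rng.normal(0.0, 0.25))
        counts[codon] = 1e4 * base * noise
    return CodonUsageTable(counts=counts, organism_label=f"synthetic(gc_bias={gc_bias})")


def synthetic_trna_copy_numbers(usage: CodonUsageTable, seed=None) -> dict:
    """Plausible tRNA gene copy numbers matched to a usage table.

    For each codon box (fixed first two bases) two anticodons are supplied
    — A34 (reads T/C/A-ending codons via wobble) and T34 (reads A/G-ending)
    — with copies scaled to the summed usage of the codons they serve, so
    every sense codon is decodable and abundant codons get more gene
    copies, as in real genomes.
    """
    rng = _rng(seed)
    copies: dict = {}
    sense = usage.code.sense_codons
    for b1 in BASES:
        for b2 in BASES:
            box = [b1 + b2 + b3 for b3 in BASES if (b1 + b2 + b3) in sense]
            if not box:
                continue
            stem = _COMPLEMENT[b2] + _COMPLEMENT[b1]
            total = sum(usage.counts[c] for c in box)
            scale = sum(usage.counts[c] for c in sense)
            mean = 1.0 + 12.0 * total / scale * len(box)
            for wobble34 in ("A", "T"):
                copies[wobble34 + stem] = max(1, int(rng.poisson(mean)))
    return copies


def synthetic_tai_weights(usage: CodonUsageTable, seed=None) -> TAIWeights:
    """tAI weights from synthetic copy numbers (zero weights geometric-mean
    filled so the index is defined for every sense codon)."""
    return tai_weights(synthetic_trna_copy_numbers(usage, seed), fill_zero="geomean")


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for the synthetic expression dataset.

    Defaults emulate the real study: 204 genes, three ordinal expression
    levels cut at latent -0.5 / 0.5, a strongly GC-biased usage table, and
    a dominant planted correlation of expression with dG_UH (0.6) plus a
    secondary one with CAI (0.25) and tAI (0.15) — the qualitative ranking
    the real analysis reported.
    """

    seed: int = 0
    n_genes: int = 204
    protein_len: tuple = (60, 250)
    gc_bias: float = 0.9
    latent_rhos: Mapping[str, float] = field(
        default_factory=lambda: {"dG_UH": 0.6, "cai": 0.25, "tai": 0.15}
    )
    cut_points: tuple = (-0.5, 0.5)
    utr: str = FIXTURE_UTR
    head_codons: int = 11

    def __post_init__(self) -> None:
        if list(self.cut_points) != sorted(self.cut_points):
            raise ValueError("cut_points must be increasing")
        ss = sum(r * r for r in self.latent_rhos.values())
        if ss >= 1.0:
            raise ValueError("sum of squared latent_rhos must be < 1")


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated genes, their true features, and latent-model scores."""

    sequences: tuple
    features: pd.DataFrame
    scores: pd.Series
    usage: CodonUsageTable
    tai_weights: TAIWeights
    utr: str
    config: FixtureConfig

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.scores.index, "score": self.scores.values})


def synthetic_expression_dataset(config: FixtureConfig, backend=None) -> SyntheticDataset:
    """Generate a full synthetic expression study.

    Genes are random proteins back-translated with per-gene codon
    optimality drawn lognormally (so CAI/tAI spread); the feature battery
    (including dG_UH under the supplied folding backend, default builtin
    ensemble) is computed on the generated sequences; the latent liability
    is sum_f rho_f * z_f + sigma * eps over the configured features with
    sigma chosen so the liability has unit variance under independence;
    scores are 1 + #(cut points below liability).
    """
    from .folding import BuiltinBackend

    backend = backend or BuiltinBackend()
    rng = np.random.default_rng(config.seed)
    usage = synthetic_usage_table(rng, config.gc_bias)
    cw = cai_weights(usage)
    tw = synthetic_tai_weights(usage, rng)
    rare = rare_codons(usage)
    lo, hi = config.protein_len
    seqs = []
    for g in range(config.n_genes):
        length = int(rng.integers(lo, hi + 1))
        prot = random_protein(length, rng)
        power = math.exp(rng.normal(0.0, 0.7))
        seqs.append(random_cds(prot, usage, rng, power=power, gene_id=f"gene{g:04d}"))
    spec = HeadRegionSpec(utr=config.utr, head_nt=3 * config.head_codons)
    feats = feature_table(
        seqs, cw, tw, rare, spec=spec, backend=backend, head_codons=config.head_codons
    )
    # latent liability from standardized true features
    liability = np.zeros(config.n_genes)
    ss = 0.0
    for name, rho in config.latent_rhos.items():
        x = feats[name].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0 or not np.all(np.isfinite(x)):
            continue
        liability += rho * (x - x.mean()) / sd
        ss += rho * rho
    sigma = math.sqrt(max(1.0 - ss, 0.0))
    liability += sigma * rng.standard_normal(config.n_genes)
    scores = np.ones(config.n_genes, dtype=int)
    for cut in config.cut_points:
        scores += liability > cut
    scores = pd.Series(scores, index=feats.index, name="score")
    return SyntheticDataset(
        sequences=tuple(seqs),
        features=feats,
        scores=scores,
        usage=usage,
        tai_weights=tw,
        utr=config.utr,
        config=config,
    )
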