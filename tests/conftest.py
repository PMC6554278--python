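"""Shared fixtures: small usage tables, a GC-biased synthetic table, the
fixture UTR/backend, and independent brute-force oracles used to check the
production implementations."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from codonopt.codon_data import (
    CODONS,
    CodonUsageTable,
    GeneticCode,
    cai_weights,
    rare_codons,
)
from codonopt.fixtures import FIXTURE_UTR, synthetic_usage_table
from codonopt.folding import BuiltinBackend, HeadRegionSpec, build_region, delta_g
from codonopt.seq_features import CodingSequence


def make_table(overrides: dict, default: float = 1.0, **kw) -> CodonUsageTable:
    """Usage table with every codon at ``default`` except the overrides."""
    counts = {c: default for c in CODONS}
    counts.update(overrides)
    return CodonUsageTable(counts=counts, **kw)


@pytest.fixture(scope="session")
def code() -> GeneticCode:
    return GeneticCode.standard()


@pytest.fixture(scope="session")
def ala_table() -> CodonUsageTable:
    return make_table({"GCA": 10, "GCC": 30, "GCG": 40, "GCT": 20})


@pytest.fixture(scope="session")
def gc_table() -> CodonUsageTable:
    return synthetic_usage_table(0, 0.9)


@pytest.fixture(scope="session")
def gc_cai(gc_table):
    return cai_weights(gc_table)


@pytest.fixture(scope="session")
def gc_rare(gc_table):
    return rare_codons(gc_table)


@pytest.fixture(scope="session")
def backend() -> BuiltinBackend:
    return BuiltinBackend()


@pytest.fixture(scope="session")
def short_spec() -> HeadRegionSpec:
    """A 24-nt UTR suffix + 12-nt head: small enough for exhaustive design
    oracles, long enough for real base pairing."""
    return HeadRegionSpec(utr=FIXTURE_UTR, head_nt=12, utr_take=24)


# --- independent oracles -------------------------------------------------


def brute_repetition_rate(items) -> float:
    """O(L^2) all-pairs scan for the repetition rate sum(1/d_i)/L."""
    L = len(items)
    if L == 0:
        return 0.0
    total = 0.0
    for i in range(L):
        for j in range(i + 1, L):
            if items[j] == items[i]:
                total += 1.0 / (j - i)
                break
    return total / L


def random_sense_cds(rng: np.random.Generator, n_codons: int, gene_id: str = "r") -> CodingSequence:
    """Random CDS over sense codons only, ATG first."""
    code = GeneticCode.standard()
    sense = sorted(code.sense_codons)
    cods = ["ATG"] + [sense[int(rng.integers(len(sense)))] for _ in range(n_codons - 1)]
    return CodingSequence(id=gene_id, nt="".join(cods))


def oracle_design(
    seq: CodingSequence,
    spec: HeadRegionSpec,
    backend,
    method: str,
    k: int,
    cai_w=None,
    rare: frozenset = frozenset(),
    cai_h_min: float | None = None,
) -> list:
    """Fold-everything reference: enumerate all synonymous heads directly
    from the genetic-code families, filter, fold each with delta_g, and
    sort with the same tie-break. Returns [(dG, head_nt), ...] top-k."""
    code = GeneticCode.standard()
    head_codons = spec.head_nt // 3
    head = seq.sense_codons[:head_codons]
    tail = seq.nt[3 * len(head):]
    options = [[head[0]]] + [sorted(code.synonyms(c) - rare) for c in head[1:]]
    scored = []
    for combo in itertools.product(*options):
        h = "".join(combo)
        if cai_h_min is not None:
            ch = math.exp(sum(math.log(cai_w[c]) for c in combo) / len(combo))
            if not (ch > cai_h_min - 1e-9):
                continue
        region = build_region(spec, CodingSequence("o", h + tail, require_start=False)).rna
        scored.append((delta_g(region, backend), h))
    reverse = method in ("H", "C")
    scored.sort(key=lambda t: ((-t[0]) if reverse else t[0], t[1]))
    return scored[:k]
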