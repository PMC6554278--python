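"""Head-region codon optimization: H-method, C-method, and deoptimization.

All three methods enumerate the synonymous variants of the first 11 codons
(33 head nucleotides) of a coding sequence, leaving the start codon and all
downstream nucleotides untouched, fold the UTR + head region of each
variant, and rank by the resulting dG_UH:

* H-method: highest dG_UH first (weakest 5' structure).
* C-method: same, restricted to variants whose head-region codon
  adaptation CAI_H exceeds a user threshold and that contain no rare codon.
* L-series deoptimization: lowest dG_UH first (controls / knock-down).

Constraint filtering is cheap and happens before the (expensive) folding;
ties on energy break toward the lexicographically smallest head sequence so
results are deterministic across platforms. Exhaustive enumeration is used
up to a variant cap, above which a seeded uniform sample is drawn.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

from .codon_data import CAIWeights, GeneticCode, normalize_codon
from .folding import HeadRegionSpec, build_region, delta_g
from .seq_features import CodingSequence, DEFAULT_HEAD_CODONS

__all__ = [
    "CapacityError",
    "InfeasibleDesignError",
    "VariantRecord",
    "DesignResult",
    "count_head_variants",
    "enumerate_head_variants",
    "h_method",
    "c_method",
    "deoptimize",
    "ENUMERATION_CAP",
    "SAMPLE_SIZE",
]

logger = logging.getLogger(__name__)

#: exhaustive enumeration up to this many variants ...
ENUMERATION_CAP = 1_000_000
#: ... above it, a seeded uniform sample of this size is drawn
SAMPLE_SIZE = 100_000

#: absolute tolerance on the strict CAI_H threshold comparison
CAI_H_TOL = 1e-9


class CapacityError(RuntimeError):
    """Variant space exceeds the enumeration cap and sampling is disabled."""


class InfeasibleDesignError(RuntimeError):
    """No synonymous variant satisfies the design constraints."""


@dataclass(frozen=True)
class VariantRecord:
    """One synonymous head variant with its design-relevant measurements."""

    head_nt: str
    full_cds: str
    dG_UH: float | None = None
    cai_h: float | None = None
    rare_count: int | None = None


@dataclass(frozen=True)
class DesignResult:
    """Ranked variants for one gene under one method (best first)."""

    gene_id: str
    method: str  # "H", "C", or "L"
    ranked: tuple
    params: Mapping
    n_variants_considered: int
    search_mode: str  # "exhaustive" | "sampled"

    def labels(self) -> tuple:
        """H1..Hk / C1..Ck / L1..Lk labels for the ranked variants."""
        return tuple(f"{self.method}{i + 1}" for i in range(len(self.ranked)))


def _head_codon_options(
    seq: CodingSequence,
    head_codons: int,
    code: GeneticCode,
    forbid: frozenset = frozenset(),
    keep_start: bool = True,
) -> list:
    """Per-position sorted synonymous-codon option lists for the head window."""
    head = seq.sense_codons[:head_codons]
    options = []
    for idx, codon in enumerate(head):
        if idx == 0 and keep_start:
            options.append([codon])
            continue
        syns = sorted(code.synonyms(codon))
        if forbid:
            kept = [c for c in syns if c not in forbid]
            if not kept:
                raise InfeasibleDesignError(
                    f"{seq.id}: every synonym of codon {codon} (position {idx}) is forbidden"
                )
            syns = kept
        options.append(syns)
    return options


def count_head_variants(
    seq: CodingSequence,
    head_codons: int = DEFAULT_HEAD_CODONS,
    code: GeneticCode | None = None,
) -> int:
    """Number of synonymous head variants: product of family sizes over the
    first min(head_codons, L) codons, with the start codon fixed."""
    code = code or GeneticCode.standard()
    options = _head_codon_options(seq, head_codons, code)
    return math.prod(len(o) for o in options)


def _iter_heads(
    options: list,
    seed: int | None,
    allow_sampling: bool,
    cap: int,
    sample_size: int,
) -> tuple:
    """(heads iterator, n_considered, search_mode); lexicographic when exhaustive."""
    total = math.prod(len(o) for o in options)
    if total <= cap:
        heads = ("".join(t) for t in itertools.product(*options))
        return heads, total, "exhaustive"
    if not allow_sampling:
        raise CapacityError(
            f"{total} synonymous variants exceed the cap of {cap}; enable sampling"
        )
    logger.warning(
        "variant space of %d exceeds cap %d; sampling %d variants", total, cap, sample_size
    )
    rng = np.random.default_rng(seed)
    sizes = [len(o) for o in options]
    seen = set()
    picks = []
    # oversample indices, dedupe, keep first sample_size distinct heads
    while len(picks) < min(sample_size, total):
        idx = tuple(int(rng.integers(0, s)) for s in sizes)
        if idx not in seen:
            seen.add(idx)
            picks.append("".join(o[i] for o, i in zip(options, idx)))
    return iter(picks), len(picks), "sampled"


def _cai_h_of_head(head_cods: tuple, weights: CAIWeights) -> float:
    return math.exp(sum(math.log(weights[c]) for c in head_cods) / len(head_cods))


def enumerate_head_variants(
    seq: CodingSequence,
    head_codons: int = DEFAULT_HEAD_CODONS,
    code: GeneticCode | None = None,
    cai_h_min: float | None = None,
    cai_weights: CAIWeights | None = None,
    forbid: Iterable[str] = (),
    keep_start: bool = True,
    allow_sampling: bool = True,
    seed: int | None = None,
    cap: int = ENUMERATION_CAP,
    sample_size: int = SAMPLE_SIZE,
) -> Iterator[VariantRecord]:
    """Stream synonymous head variants (energies unfilled).

    Every emitted variant translates identically to the wild type, differs
    from it only within the head window, and satisfies the constraints:
    CAI_H strictly above ``cai_h_min`` (within tolerance) and zero codons
    from ``forbid``. Emission order is lexicographic by head sequence in
    exhaustive mode.
    """
    code = code or GeneticCode.standard()
    forbid = frozenset(normalize_codon(c) for c in forbid)
    if cai_h_min is not None and cai_weights is None:
        raise ValueError("cai_h_min requires cai_weights")
    options = _head_codon_options(seq, head_codons, code, forbid, keep_start)
    n_head = len(options)
    tail = seq.nt[3 * n_head :]
    heads, _, _ = _iter_heads(options, seed, allow_sampling, cap, sample_size)
    for head in heads:
        head_cods = tuple(head[i : i + 3] for i in range(0, len(head), 3))
        cai_h = _cai_h_of_head(head_cods, cai_weights) if cai_weights is not None else None
        if cai_h_min is not None and not (cai_h > cai_h_min - CAI_H_TOL):
            continue
        rare_ct = sum(1 for c in head_cods if c in forbid) if forbid else 0
        yield VariantRecord(head_nt=head, full_cds=head + tail, cai_h=cai_h, rare_count=rare_ct)


def _fold_head(
    head: str, tail: str, seq_id: str, spec: HeadRegionSpec, backend, cache: dict | None
) -> float:
    region = build_region(spec, CodingSequence(seq_id, head + tail, require_start=False)).rna
    if cache is None:
        return delta_g(region, backend)
    if region not in cache:
        cache[region] = delta_g(region, backend)
    return cache[region]


def _design(
    seq: CodingSequence,
    spec: HeadRegionSpec,
    backend,
    method: str,
    k: int,
    code: GeneticCode,
    cai_weights: CAIWeights | None,
    rare: frozenset,
    cai_h_min: float | None,
    seed: int | None,
    allow_sampling: bool,
    cache: dict | None,
) -> DesignResult:
    head_codons = spec.head_nt // 3
    if k < 1:
        raise ValueError("k must be >= 1")
    options = _head_codon_options(seq, head_codons, code, rare, keep_start=True)
    heads, n_considered, search_mode = _iter_heads(
        options, seed, allow_sampling, ENUMERATION_CAP, SAMPLE_SIZE
    )
    n_head = len(options)
    tail = seq.nt[3 * n_head :]

    # cheap constraint filtering before any folding
    kept: list = []
    for head in heads:
        head_cods = tuple(head[i : i + 3] for i in range(0, len(head), 3))
        cai_h = _cai_h_of_head(head_cods, cai_weights) if cai_weights is not None else None
        if cai_h_min is not None and not (cai_h > cai_h_min - CAI_H_TOL):
            continue
        kept.append((head, cai_h))
    if not kept:
        # rare-codon filtering happens inside _head_codon_options, so if we
        # got here the CAI_H threshold is the binding constraint
        raise InfeasibleDesignError(
            f"{seq.id}: no synonymous head variant has CAI_H > {cai_h_min} "
            f"(rare-codon-free space of {n_considered} variants)"
        )

    scored = [
        (
            _fold_head(head, tail, seq.id, spec, backend, cache),
            head,
            cai_h,
        )
        for head, cai_h in kept
    ]
    reverse = method in ("H", "C")
    scored.sort(key=lambda t: ((-t[0]) if reverse else t[0], t[1]))
    if k > len(scored):
        warnings.warn(
            f"{seq.id}: requested k={k} but only {len(scored)} variants available",
            stacklevel=3,
        )
    top = scored[:k]
    ranked = tuple(
        VariantRecord(
            head_nt=head,
            full_cds=head + tail,
            dG_UH=dg,
            cai_h=cai_h,
            rare_count=sum(
                1 for i in range(0, len(head), 3) if head[i : i + 3] in rare
            ),
        )
        for dg, head, cai_h in top
    )
    params = {
        "head_codons": head_codons,
        "backend": getattr(backend, "name", "builtin") if backend else "builtin",
        "cai_h_min": cai_h_min,
        "rare": tuple(sorted(rare)),
        "k": k,
        "seed": seed,
        "utr_take": spec.utr_take,
    }
    return DesignResult(
        gene_id=seq.id,
        method=method,
        ranked=ranked,
        params=params,
        n_variants_considered=n_considered,
        search_mode=search_mode,
    )


def h_method(
    seq: CodingSequence,
    spec: HeadRegionSpec,
    backend=None,
    k: int = 3,
    code: GeneticCode | None = None,
    seed: int | None = None,
    allow_sampling: bool = True,
    cache: dict | None = None,
    cai_weights: CAIWeights | None = None,
) -> DesignResult:
    """Top-k synonymous head variants by descending dG_UH (H1..Hk).

    ``cai_weights`` is optional and only annotates each variant's CAI_H for
    reporting; it never constrains the H-method search.
    """
    code = code or GeneticCode.standard()
    return _design(
        seq, spec, backend, "H", k, code, cai_weights,
        frozenset(), None, seed, allow_sampling, cache,
    )


def c_method(
    seq: CodingSequence,
    spec: HeadRegionSpec,
    backend,
    cai_weights: CAIWeights,
    rare: Iterable[str],
    cai_h_min: float,
    k: int = 1,
    code: GeneticCode | None = None,
    seed: int | None = None,
    allow_sampling: bool = True,
    cache: dict | None = None,
) -> DesignResult:
    """Highest-dG_UH variant(s) with CAI_H above threshold and no rare codon
    in the head window (C-series)."""
    if not (0.0 <= cai_h_min <= 1.0):
        raise ValueError(f"cai_h_min must be in [0,1], got {cai_h_min}")
    code = code or GeneticCode.standard()
    rare = frozenset(normalize_codon(c) for c in rare)
    return _design(
        seq, spec, backend, "C", k, code, cai_weights,
        rare, cai_h_min, seed, allow_sampling, cache,
    )


def deoptimize(
    seq: CodingSequence,
    spec: HeadRegionSpec,
    backend=None,
    k: int = 3,
    code: GeneticCode | None = None,
    seed: int | None = None,
    allow_sampling: bool = True,
    cache: dict | None = None,
    cai_weights: CAIWeights | None = None,
) -> DesignResult:
    """Top-k variants by ascending dG_UH (L1..Lk): deoptimized controls with
    the strongest 5' structure."""
    code = code or GeneticCode.standard()
    return _design(
        seq, spec, backend, "L", k, code, cai_weights,
        frozenset(), None, seed, allow_sampling, cache,
    )
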