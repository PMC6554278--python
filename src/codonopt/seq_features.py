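"""Per-sequence features used for expression analysis and design.

Implements, for a validated coding sequence: CAI and its head-restricted
variant CAI_H (geometric mean of relative-adaptiveness weights over the
first 11 codons / 33 nt), tAI, the codon repetition rate
sum_i 1/d_i / L (d_i = codon-index distance to the next occurrence of the
same codon, positions with no later occurrence contributing 0), the amino
acid repetition rate (same formula on the encoded residues), and rare-codon
counts in the head window. Geometric means are computed in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .codon_data import CAIWeights, GeneticCode, TAIWeights, normalize_codon

__all__ = [
    "SequenceError",
    "CodingSequence",
    "FEATURE_COLUMNS",
    "translate",
    "cai",
    "cai_head",
    "tai",
    "codon_repetition_rate",
    "aa_repetition_rate",
    "rare_codon_count",
    "compute_features",
    "feature_table",
    "write_feature_tsv",
]

#: fixed column order of the batch feature table
FEATURE_COLUMNS = (
    "cai",
    "cai_h",
    "tai",
    "codon_rep_rate",
    "aa_rep_rate",
    "dG_UH",
    "rare_codon_count_head",
)

DEFAULT_HEAD_CODONS = 11


class SequenceError(ValueError):
    """Invalid coding sequence (frame, alphabet, start codon, internal stop)."""


@dataclass(frozen=True)
class CodingSequence:
    """A validated in-frame DNA coding sequence.

    Input is uppercased and U is mapped to T. The sequence must be a
    multiple of 3 over {A,C,G,T}, contain no internal stop codon, and end
    with at most one terminal stop. ``require_start`` (default True)
    additionally enforces an ATG first codon — relax it for feature-only
    use of natural genes with alternative starts.
    """

    id: str
    nt: str
    require_start: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        nt = self.nt.strip().upper().replace("U", "T")
        object.__setattr__(self, "nt", nt)
        if not nt:
            raise SequenceError(f"{self.id}: empty sequence")
        if len(nt) % 3 != 0:
            raise SequenceError(f"{self.id}: length {len(nt)} not divisible by 3")
        bad = set(nt) - set("ACGT")
        if bad:
            raise SequenceError(f"{self.id}: non-ACGT characters {sorted(bad)}")
        code = GeneticCode.standard()
        codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
        for idx, codon in enumerate(codons[:-1]):
            if codon in code.stop_codons:
                raise SequenceError(f"{self.id}: internal stop codon {codon} at codon {idx}")
        if self.require_start and codons[0] != "ATG":
            raise SequenceError(f"{self.id}: first codon is {codons[0]}, expected ATG")

    @property
    def codons(self) -> tuple:
        """All codons including a terminal stop if present."""
        return tuple(self.nt[i : i + 3] for i in range(0, len(self.nt), 3))

    @property
    def sense_codons(self) -> tuple:
        """Codons with any terminal stop stripped — the unit all features use."""
        cods = self.codons
        if cods and cods[-1] in GeneticCode.standard().stop_codons:
            return cods[:-1]
        return cods

    def __len__(self) -> int:
        return len(self.nt)


def translate(seq: CodingSequence, code: GeneticCode | None = None) -> str:
    """Amino-acid string of the sense codons (terminal stop dropped)."""
    code = code or GeneticCode.standard()
    return "".join(code.codon_to_aa[c] for c in seq.sense_codons)


def _geometric_mean_weights(
    codons: Sequence[str],
    weights: Mapping[str, float] | CAIWeights | TAIWeights,
    exclude_singletons: bool,
    what: str,
) -> float:
    code = GeneticCode.standard()
    logsum = 0.0
    n = 0
    for idx, codon in enumerate(codons):
        if exclude_singletons and len(code.synonyms(codon)) == 1:
            continue
        try:
            w = weights[codon]
        except KeyError:
            raise SequenceError(f"no {what} weight for codon {codon} (position {idx})")
        if w <= 0:
            raise SequenceError(f"{what} weight is 0 for codon {codon} (position {idx})")
        logsum += math.log(w)
        n += 1
    if n == 0:
        return 1.0  # e.g. 'M' alone with singletons excluded
    return math.exp(logsum / n)


def cai(seq: CodingSequence, weights: CAIWeights, exclude_singletons: bool = False) -> float:
    """Codon adaptation index: geometric mean of relative adaptiveness over
    all sense codons. Singleton families (Met, Trp) carry weight 1 and are
    included by default; ``exclude_singletons`` drops them from the mean."""
    return _geometric_mean_weights(seq.sense_codons, weights, exclude_singletons, "CAI")


def cai_head(
    seq: CodingSequence,
    weights: CAIWeights,
    head_codons: int = DEFAULT_HEAD_CODONS,
    exclude_singletons: bool = False,
) -> float:
    """CAI_H: CAI restricted to the first ``head_codons`` codons (default 11,
    i.e. 33 head nucleotides). Shorter sequences use all their codons."""
    if head_codons < 1:
        raise ValueError("head_codons must be >= 1")
    head = seq.sense_codons[: head_codons]
    return _geometric_mean_weights(head, weights, exclude_singletons, "CAI")


def tai(seq: CodingSequence, weights: TAIWeights) -> float:
    """tRNA adaptation index: geometric mean of tAI weights over sense codons."""
    return _geometric_mean_weights(seq.sense_codons, weights, False, "tAI")


def _repetition_rate(items: Sequence) -> float:
    """sum_i 1/d_i over positions divided by L, d_i the distance to the next
    occurrence of the same item; no later occurrence contributes 0."""
    L = len(items)
    if L == 0:
        return 0.0
    next_seen: dict = {}
    total = 0.0
    for i in range(L - 1, -1, -1):
        if items[i] in next_seen:
            total += 1.0 / (next_seen[items[i]] - i)
        next_seen[items[i]] = i
    return total / L


def codon_repetition_rate(seq: CodingSequence) -> float:
    """Repetition rate over codon identities (terminal stop excluded)."""
    return _repetition_rate(seq.sense_codons)


def aa_repetition_rate(seq: CodingSequence, code: GeneticCode | None = None) -> float:
    """Repetition rate over the encoded amino acids; always >= the codon
    repetition rate since identical codons encode identical residues."""
    code = code or GeneticCode.standard()
    return _repetition_rate([code.codon_to_aa[c] for c in seq.sense_codons])


def rare_codon_count(
    seq: CodingSequence,
    rare: Iterable[str],
    head_codons: int | None = DEFAULT_HEAD_CODONS,
) -> int:
    """Number of rare codons in the head window (``head_codons=None`` counts
    the whole sequence)."""
    rare = {normalize_codon(c) for c in rare}
    window = seq.sense_codons if head_codons is None else seq.sense_codons[:head_codons]
    return sum(1 for c in window if c in rare)


def compute_features(
    seq: CodingSequence,
    cai_w: CAIWeights,
    tai_w: TAIWeights | None = None,
    rare: Iterable[str] = (),
    spec=None,
    backend=None,
    head_codons: int = DEFAULT_HEAD_CODONS,
) -> dict:
    """The full feature vector of one sequence as a plain dict.

    dG_UH is filled only when a head-region spec and a folding backend are
    supplied (import kept local to avoid a hard module cycle); tai only when
    tAI weights are supplied — absent entries are NaN.
    """
    feats = {
        "cai": cai(seq, cai_w),
        "cai_h": cai_head(seq, cai_w, head_codons),
        "tai": tai(seq, tai_w) if tai_w is not None else float("nan"),
        "codon_rep_rate": codon_repetition_rate(seq),
        "aa_rep_rate": aa_repetition_rate(seq),
        "dG_UH": float("nan"),
        "rare_codon_count_head": rare_codon_count(seq, rare, head_codons),
    }
    if spec is not None and backend is not None:
        from .folding import dG_UH

        feats["dG_UH"] = dG_UH(seq, spec, backend)
    return feats


def feature_table(
    seqs: Iterable[CodingSequence],
    cai_w: CAIWeights,
    tai_w: TAIWeights | None = None,
    rare: Iterable[str] = (),
    spec=None,
    backend=None,
    head_codons: int = DEFAULT_HEAD_CODONS,
):
    """Batch feature computation: DataFrame indexed by sequence id with the
    fixed :data:`FEATURE_COLUMNS` order."""
    import pandas as pd

    rare = frozenset(normalize_codon(c) for c in rare)
    rows = {}
    for seq in seqs:
        rows[seq.id] = compute_features(seq, cai_w, tai_w, rare, spec, backend, head_codons)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_COLUMNS))
    df.index.name = "id"
    return df


def write_feature_tsv(df, path) -> None:
    """Write the batch feature table as TSV with 6 significant digits."""
    df.to_csv(path, sep="\t", float_format="%.6g")
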