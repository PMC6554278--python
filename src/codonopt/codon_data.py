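"""Genetic-code and codon-usage infrastructure.

This module holds the static knowledge every other part of the package
builds on: the standard genetic code and its synonymous-codon families,
genomic codon-usage tables (Kazusa-style block text or plain TSV), the
normalized codon frequencies w_c = f_c / max_s f_s derived from them,
rare-codon sets (w_c < threshold), CAI relative-adaptiveness weights, and
tRNA adaptation index (tAI) weights computed from tRNA gene copy numbers
under standard wobble-decoding penalties.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

from Bio.Data import CodonTable

__all__ = [
    "BASES",
    "CODONS",
    "GeneticCode",
    "CodonUsageTable",
    "CAIWeights",
    "TAIWeights",
    "UsageTableError",
    "UsageParseError",
    "parse_usage_table",
    "serialize_usage_table",
    "rare_codons",
    "cai_weights",
    "tai_weights",
    "load_tai_weights",
    "DEFAULT_WOBBLE_PENALTIES",
]

BASES = "ACGT"
#: all 64 DNA triplets in lexicographic order
CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class UsageTableError(ValueError):
    """Invalid codon-usage data (negative counts, zero families, ...)."""


class UsageParseError(UsageTableError):
    """Usage-table text could not be parsed into 64 codon counts."""


def normalize_codon(codon: str) -> str:
    """Uppercase a triplet and map RNA U to DNA T."""
    return codon.strip().upper().replace("U", "T")


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code: codon -> amino acid ('*' for stop) plus synonymous families."""

    codon_to_aa: Mapping[str, str]
    families: Mapping[str, frozenset]

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(f"genetic code must map all 64 codons, got {len(self.codon_to_aa)}")
        for aa, fam in self.families.items():
            if len(fam) not in (1, 2, 3, 4, 6):
                raise ValueError(f"family {aa} has invalid size {len(fam)}")

    @property
    def stop_codons(self) -> frozenset:
        return frozenset(c for c, aa in self.codon_to_aa.items() if aa == "*")

    @property
    def sense_codons(self) -> frozenset:
        return frozenset(c for c, aa in self.codon_to_aa.items() if aa != "*")

    def synonyms(self, codon: str) -> frozenset:
        """All codons encoding the same amino acid as ``codon`` (itself included)."""
        aa = self.codon_to_aa[codon]
        if aa == "*":
            return frozenset(self.stop_codons)
        return self.families[aa]

    @staticmethod
    @lru_cache(maxsize=None)
    def standard() -> "GeneticCode":
        """The standard genetic code (NCBI translation table 1)."""
        table = CodonTable.unambiguous_dna_by_id[1]
        codon_to_aa = dict(table.forward_table)
        for stop in table.stop_codons:
            codon_to_aa[stop] = "*"
        families: dict[str, set] = {}
        for codon, aa in codon_to_aa.items():
            if aa != "*":
                families.setdefault(aa, set()).add(codon)
        return GeneticCode(
            codon_to_aa=dict(sorted(codon_to_aa.items())),
            families={aa: frozenset(f) for aa, f in families.items()},
        )


@dataclass
class CodonUsageTable:
    """Per-codon genomic counts plus derived normalized frequencies.

    ``normalized`` maps each sense codon c to w_c = f_c / max_s f_s where s
    runs over the synonymous codons of c. Within every family the argmax
    codon(s) have w = 1 exactly. Stop codons are carried in ``counts`` but
    never normalized. A family whose counts are all zero has no defined
    normalization; its codons are absent from ``normalized`` and listed in
    ``zero_families`` — downstream weight derivation raises on them.
    """

    counts: dict
    organism_label: str = ""
    units: str = "count"
    code: GeneticCode = field(default_factory=GeneticCode.standard)
    normalized: dict = field(init=False, default_factory=dict)
    zero_families: tuple = field(init=False, default=())

    def __post_init__(self) -> None:
        self.counts = {normalize_codon(c): float(v) for c, v in self.counts.items()}
        missing = [c for c in CODONS if c not in self.counts]
        if missing:
            raise UsageParseError(f"usage table missing codons: {', '.join(missing)}")
        negative = sorted(c for c, v in self.counts.items() if v < 0)
        if negative:
            raise UsageTableError(f"negative counts for codons: {', '.join(negative)}")
        zero = []
        normalized: dict = {}
        for aa, fam in self.code.families.items():
            fmax = max(self.counts[c] for c in fam)
            if fmax == 0:
                zero.append(aa)
                continue
            for c in fam:
                normalized[c] = self.counts[c] / fmax
        self.normalized = normalized
        self.zero_families = tuple(sorted(zero))

    def _require_normalized(self) -> None:
        if self.zero_families:
            raise UsageTableError(
                "families with all-zero counts cannot be normalized: "
                + ", ".join(self.zero_families)
            )

    def w(self, codon: str) -> float:
        """Normalized frequency of a sense codon (undefined for stops)."""
        codon = normalize_codon(codon)
        if codon in self.code.stop_codons:
            raise UsageTableError(f"normalized frequency undefined for stop codon {codon}")
        if codon not in self.normalized:
            raise UsageTableError(
                f"codon {codon} belongs to an all-zero family; no normalized frequency"
            )
        return self.normalized[codon]


@dataclass(frozen=True)
class CAIWeights:
    """Relative-adaptiveness weights for the codon adaptation index.

    Same normalization contract as ``CodonUsageTable.normalized``; weights
    live in (0, 1], singleton families (Met, Trp) have w = 1.
    """

    w: Mapping[str, float]

    def __getitem__(self, codon: str) -> float:
        return self.w[normalize_codon(codon)]

    def __contains__(self, codon: str) -> bool:
        return normalize_codon(codon) in self.w


@dataclass(frozen=True)
class TAIWeights:
    """tAI weights per sense codon, max-normalized to [0, 1].

    provenance is "computed" (from tRNA gene copy numbers under wobble
    penalties) or "loaded" (an external weight matrix taken verbatim).
    """

    w: Mapping[str, float]
    provenance: str = "computed"

    def __post_init__(self) -> None:
        if not any(v > 0 for v in self.w.values()):
            raise ValueError("tAI weights must contain at least one positive weight")
        bad = [c for c, v in self.w.items() if not (0.0 <= v <= 1.0)]
        if bad:
            raise ValueError(f"tAI weights outside [0,1] for: {', '.join(sorted(bad))}")

    def __getitem__(self, codon: str) -> float:
        return self.w[normalize_codon(codon)]


# --- usage-table parsing -------------------------------------------------

_KAZUSA_FIELD = re.compile(r"([ACGTUacgtu]{3})\s+([0-9]+(?:\.[0-9]+)?)\s*(?:\(\s*([0-9]+)\s*\))?")
_TSV_LINE = re.compile(r"^([ACGTUacgtu]{3})\s+([0-9]+(?:\.[0-9]+)?)\s*$")


def parse_usage_table(
    text: str,
    dialect: str = "kazusa",
    organism_label: str = "",
    code: GeneticCode | None = None,
) -> CodonUsageTable:
    """Parse codon-usage text into a :class:`CodonUsageTable`.

    Two dialects are supported:

    ``kazusa``
        The Codon Usage Database "codon  per-mille (count)" block layout,
        e.g. ``UUU 17.6(714298)  UCU 15.2(618711) ...``. When counts are
        present in parentheses they are used; otherwise the per-mille
        frequencies are taken as counts (normalization is scale-invariant).
    ``tsv``
        One ``codon<TAB>count`` pair per line, optional header line.

    Codons are case-insensitive; U is mapped to T.
    """
    if not text or not text.strip():
        raise UsageParseError("empty usage-table text")
    code = code or GeneticCode.standard()
    counts: dict = {}
    if dialect == "kazusa":
        for m in _KAZUSA_FIELD.finditer(text):
            codon = normalize_codon(m.group(1))
            value = float(m.group(3)) if m.group(3) is not None else float(m.group(2))
            counts[codon] = value
    elif dialect == "tsv":
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            m = _TSV_LINE.match(line.replace("\t", " "))
            if m:
                counts[normalize_codon(m.group(1))] = float(m.group(2))
            elif line.lower().startswith(("codon", "#")):
                continue  # header / comment
            else:
                raise UsageParseError(f"unparseable TSV line: {line!r}")
    else:
        raise UsageParseError(f"unknown usage-table dialect: {dialect!r}")
    return CodonUsageTable(counts=counts, organism_label=organism_label, code=code)


def serialize_usage_table(table: CodonUsageTable) -> str:
    """Serialize counts as ``codon<TAB>count`` lines (TSV dialect round-trip)."""
    lines = ["codon\tcount"]
    for codon in CODONS:
        v = table.counts[codon]
        lines.append(f"{codon}\t{v:g}")
    return "\n".join(lines) + "\n"


# --- derived weights -----------------------------------------------------


def rare_codons(table: CodonUsageTable, threshold: float = 0.1) -> frozenset:
    """Codons whose normalized frequency w_c falls below ``threshold``.

    Stop codons are never included. The set is monotone in the threshold.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    table._require_normalized()
    return frozenset(c for c, w in table.normalized.items() if w < threshold)


def cai_weights(table: CodonUsageTable) -> CAIWeights:
    """CAI relative adaptiveness: w_c = f_c / max over synonyms — the
    normalized frequencies of the usage table, sense codons only."""
    table._require_normalized()
    return CAIWeights(w=dict(table.normalized))


# --- tAI -----------------------------------------------------------------

#: selective constraints s for the wobble channel, keyed by codon third base:
#: T read by G34 anticodons, C by A34 (inosine), A by A34 (inosine), G by U34.
DEFAULT_WOBBLE_PENALTIES: dict = {"T": 0.41, "C": 0.28, "A": 0.9999, "G": 0.68}

_WOBBLE34 = {"T": "G", "C": "A", "A": "A", "G": "T"}


def _anticodon(codon: str) -> str:
    """5'→3' anticodon perfectly complementary to a 5'→3' codon."""
    return "".join(_COMPLEMENT[b] for b in reversed(codon))


def tai_weights(
    copy_numbers: Mapping[str, int],
    wobble_penalties: Mapping[str, float] | None = None,
    code: GeneticCode | None = None,
    fill_zero: str = "none",
) -> TAIWeights:
    """tAI weights from tRNA gene copy numbers.

    For a sense codon the absolute weight combines the Watson–Crick
    anticodon and one wobble-decoding anticodon (G34 for codons ending T,
    inosine/A34 for C- and A-ending codons, U34 for G-ending codons), the
    latter discounted by a selective constraint s:

        W_c = n(WC anticodon) + (1 − s_b3) · n(wobble anticodon)

    Weights are then max-normalized. ``copy_numbers`` maps 5'→3' anticodon
    triplets (DNA alphabet, U accepted) to gene copy numbers.
    ``fill_zero="geomean"`` replaces zero weights by the geometric mean of
    the nonzero weights, the convention of the reference tAI tooling;
    the default leaves them at 0 (downstream tAI computation then errors
    on undecodable codons, which is usually what you want to notice).
    """
    code = code or GeneticCode.standard()
    cn = {normalize_codon(a): int(v) for a, v in copy_numbers.items()}
    if not any(v > 0 for v in cn.values()):
        raise ValueError("all tRNA gene copy numbers are zero")
    s = dict(DEFAULT_WOBBLE_PENALTIES)
    if wobble_penalties:
        s.update({normalize_codon(k)[0] if len(k) == 3 else k.upper(): v
                  for k, v in wobble_penalties.items()})
    raw: dict = {}
    for codon in sorted(code.sense_codons):
        b3 = codon[2]
        wc = _anticodon(codon)
        wobble = _WOBBLE34[b3] + wc[1:]
        raw[codon] = cn.get(wc, 0) + (1.0 - s[b3]) * cn.get(wobble, 0)
    wmax = max(raw.values())
    if wmax == 0:
        raise ValueError("no sense codon is decoded by the supplied tRNAs")
    w = {c: v / wmax for c, v in raw.items()}
    if fill_zero == "geomean":
        nz = [v for v in w.values() if v > 0]
        gm = math.exp(sum(math.log(v) for v in nz) / len(nz))
        w = {c: (v if v > 0 else gm) for c, v in w.items()}
    elif fill_zero != "none":
        raise ValueError(f"fill_zero must be 'none' or 'geomean', got {fill_zero!r}")
    return TAIWeights(w=w, provenance="computed")


def load_tai_weights(text: str, code: GeneticCode | None = None) -> TAIWeights:
    """Load a precomputed tAI weight matrix verbatim (``codon<TAB>weight``)."""
    code = code or GeneticCode.standard()
    w: dict = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.lower().startswith(("codon", "#")):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise UsageParseError(f"unparseable tAI matrix line: {line!r}")
        w[normalize_codon(parts[0])] = float(parts[1])
    missing = sorted(code.sense_codons - set(w))
    if missing:
        raise UsageParseError(f"tAI matrix missing sense codons: {', '.join(missing)}")
    w = {c: v for c, v in w.items() if c in code.sense_codons}
    return TAIWeights(w=w, provenance="loaded")


def serialize_tai_weights(weights: TAIWeights) -> str:
    lines = ["codon\tweight"]
    for codon in sorted(weights.w):
        lines.append(f"{codon}\t{weights.w[codon]:.10g}")
    return "\n".join(lines) + "\n"
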