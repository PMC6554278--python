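"""5'-region mRNA folding energy (dG_UH).

dG_UH is the predicted folding free energy of the RNA made of the
expression vector's 5' UTR (or a suffix of it) followed by the first 33
nucleotides of the coding sequence. Higher (less negative) values mean
weaker secondary structure at the translation-initiation region, which
associates with higher expression.

The energy engine is pluggable:

``builtin``
    A self-contained secondary-structure model over canonical pairs
    (GC, AU, GU) with a per-pair energy constant (GC −3.0, AU −2.0,
    GU −1.0 kcal/mol), minimum hairpin loop of 3 unpaired nt, and no
    pseudoknots. The minimum free energy is computed by a Nussinov-style
    dynamic program in min-plus algebra; the ensemble free energy
    −RT·ln Z by the McCaskill inside recursion at 37 °C. Every structure
    is counted exactly once, so for short sequences both quantities equal
    an exhaustive enumeration over all valid pair sets
    (:func:`reference_energies`). Absolute values are not thermodynamic
    predictions — all design contracts in this package depend only on the
    ordering of energies.
``vienna``
    ViennaRNA (``import RNA``): MFE or ensemble free energy from the
    partition function, Turner parameters.
``rnastructure``
    Shells out to the ``EnsembleEnergy`` executable of the RNAstructure
    package when it is on PATH.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .seq_features import CodingSequence

__all__ = [
    "FoldingError",
    "HeadRegionSpec",
    "Region",
    "build_region",
    "BuiltinBackend",
    "ViennaBackend",
    "RNAstructureBackend",
    "get_backend",
    "delta_g",
    "dG_UH",
    "enumerate_pair_sets",
    "reference_energies",
    "PAIR_ENERGY",
    "MIN_HAIRPIN",
    "RT_37",
]

#: per-pair energies of the built-in model, kcal/mol
PAIR_ENERGY = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}
#: minimum number of unpaired nucleotides enclosed by a hairpin-closing pair
MIN_HAIRPIN = 3
#: gas constant x 310.15 K, kcal/mol
RT_37 = 1.98720425864083e-3 * 310.15

# exp() of the largest |energy|/RT a double can hold; per-pair max 3.0 kcal/mol
_MAX_REGION_NT = 280


class FoldingError(RuntimeError):
    """Folding backend failure or invalid folding input."""


@dataclass(frozen=True)
class HeadRegionSpec:
    """Definition of the folded 5' region: UTR suffix + head nucleotides.

    ``utr_take=None`` uses the full UTR; integers select the 3'-most
    ``utr_take`` nt (the window-scan convention). ``head_nt`` must be a
    multiple of 3 (default 33 nt = 11 codons).
    """

    utr: str
    head_nt: int = 33
    utr_take: int | None = None

    def __post_init__(self) -> None:
        utr = self.utr.strip().upper().replace("U", "T")
        object.__setattr__(self, "utr", utr)
        if self.head_nt % 3 != 0 or self.head_nt < 0:
            raise ValueError(f"head_nt must be a non-negative multiple of 3, got {self.head_nt}")
        if self.utr_take is not None and not (0 <= self.utr_take <= len(utr)):
            raise ValueError(f"utr_take {self.utr_take} outside [0, {len(utr)}]")

    @property
    def utr_suffix(self) -> str:
        return self.utr if self.utr_take is None else self.utr[len(self.utr) - self.utr_take :]


class Region(NamedTuple):
    """A built 5' region: RNA string plus a flag for CDS shorter than head_nt."""

    rna: str
    truncated: bool

    def __str__(self) -> str:  # lets Region flow into delta_g directly
        return self.rna


def _transcribe(dna: str) -> str:
    return dna.upper().replace("T", "U")


def build_region(spec: HeadRegionSpec, seq: CodingSequence) -> Region:
    """Concatenate the chosen UTR suffix with the first ``head_nt`` coding
    nucleotides, transcribed to RNA. A CDS shorter than head_nt contributes
    all of its nucleotides and sets the ``truncated`` flag."""
    head = seq.nt[: spec.head_nt]
    truncated = len(head) < spec.head_nt
    rna = _transcribe(spec.utr_suffix + head)
    if not rna:
        raise FoldingError("empty folding region (no UTR suffix and no head nucleotides)")
    return Region(rna, truncated)


# --- built-in model ------------------------------------------------------


def _validate_rna(region: str) -> str:
    rna = str(region).strip().upper().replace("T", "U")
    if not rna:
        raise FoldingError("empty RNA region")
    bad = set(rna) - set("ACGU")
    if bad:
        raise FoldingError(f"non-ACGU characters in region: {sorted(bad)}")
    if len(rna) > _MAX_REGION_NT:
        raise FoldingError(
            f"region of {len(rna)} nt exceeds the built-in model's {_MAX_REGION_NT} nt "
            "limit (partition function overflows double precision)"
        )
    return rna


def _pair_energy_matrix(rna: str) -> np.ndarray:
    """E[i,k] = pair energy of (i,k) or +inf if unpairable / loop too short."""
    n = len(rna)
    E = np.full((n, n), np.inf)
    for i in range(n):
        for k in range(i + MIN_HAIRPIN + 1, n):
            e = PAIR_ENERGY.get((rna[i], rna[k]))
            if e is not None:
                E[i, k] = e
    return E


def _mfe(rna: str) -> float:
    """Minimum free energy over all non-crossing canonical-pair structures."""
    n = len(rna)
    E = _pair_energy_matrix(rna)
    # M[a, b] = MFE of rna[a:b] (half-open); empty interval = 0
    M = np.full((n + 1, n + 1), np.inf)
    np.fill_diagonal(M, 0.0)
    for i in range(n - 1, -1, -1):
        # eb[k] = E(i,k) + MFE(i+1 .. k-1 interior)  [interior = rna[i+1:k]]
        eb = np.full(n, np.inf)
        ks = np.arange(i + MIN_HAIRPIN + 1, n)
        if ks.size:
            eb[ks] = E[i, ks] + M[i + 1, ks]
        best = (eb[:, None] + M[1 : n + 1, :]).min(axis=0)  # over pairing partner k
        M[i, i + 1 :] = np.minimum(M[i + 1, i + 1 :], best[i + 1 :])
    return float(min(M[0, n], 0.0))


def _ensemble(rna: str) -> float:
    """Ensemble free energy −RT ln Z, Z summed over all valid structures
    (including the open chain), via the inside recursion."""
    n = len(rna)
    E = _pair_energy_matrix(rna)
    with np.errstate(over="raise"):
        B = np.where(np.isfinite(E), np.exp(-np.where(np.isfinite(E), E, 0.0) / RT_37), 0.0)
    # Z[a, b] = partition function of rna[a:b]; empty = 1, stored 0 off the
    # computed triangle so stray k >= j terms vanish in the dot product
    Z = np.zeros((n + 1, n + 1))
    np.fill_diagonal(Z, 1.0)
    for i in range(n - 1, -1, -1):
        qb = B[i, :] * Z[i + 1, :n]  # qb[k] = boltz(i,k) * Z(interior i+1..k-1)
        contrib = qb @ Z[1 : n + 1, :]  # contrib[j] = sum_k qb[k] * Z(k+1..j-1)
        Z[i, i + 1 :] = Z[i + 1, i + 1 :] + contrib[i + 1 :]
    return float(-RT_37 * math.log(Z[0, n]))


@dataclass(frozen=True)
class BuiltinBackend:
    """Self-contained folding backend; deterministic, dependency-free."""

    mode: str = "ensemble"
    temperature: float = 37.0
    name: str = "builtin"

    def __post_init__(self) -> None:
        if self.mode not in ("ensemble", "mfe"):
            raise FoldingError(f"unknown folding mode {self.mode!r}")
        if self.temperature != 37.0:
            raise FoldingError("the built-in model is parameterized at 37 °C only")

    def delta_g(self, region) -> float:
        rna = _validate_rna(region)
        return _ensemble(rna) if self.mode == "ensemble" else _mfe(rna)


@dataclass(frozen=True)
class ViennaBackend:
    """ViennaRNA adapter (Turner parameters); requires the RNA bindings."""

    mode: str = "ensemble"
    temperature: float = 37.0
    name: str = "vienna"

    def delta_g(self, region) -> float:
        try:
            import RNA
        except ImportError as exc:  # pragma: no cover - environment dependent
            raise FoldingError("ViennaRNA python bindings (RNA) are not installed") from exc
        rna = str(region).strip().upper().replace("T", "U")
        if not rna:
            raise FoldingError("empty RNA region")
        md = RNA.md()
        md.temperature = self.temperature
        fc = RNA.fold_compound(rna, md)
        _, mfe = fc.mfe()
        if self.mode == "mfe":
            return float(mfe)
        fc.exp_params_rescale(mfe)
        _, ens = fc.pf()
        return float(ens)


@dataclass(frozen=True)
class RNAstructureBackend:
    """Adapter for the RNAstructure ``EnsembleEnergy`` program (if on PATH)."""

    mode: str = "ensemble"
    temperature: float = 37.0
    name: str = "rnastructure"
    executable: str = "EnsembleEnergy"

    def delta_g(self, region) -> float:
        exe = shutil.which(self.executable)
        if exe is None:
            raise FoldingError(
                f"{self.executable} not found on PATH; install the RNAstructure package "
                "or select the 'builtin' or 'vienna' backend"
            )
        rna = str(region).strip().upper().replace("T", "U")
        with tempfile.TemporaryDirectory() as tmp:
            fasta = Path(tmp) / "region.fasta"
            fasta.write_text(f">region\n{rna}\n")
            try:
                out = subprocess.run(
                    [exe, "--sequence", str(fasta)],
                    capture_output=True, text=True, check=True,
                )
            except (OSError, subprocess.CalledProcessError) as exc:
                raise FoldingError(f"{self.executable} invocation failed: {exc}") from exc
        for line in out.stdout.splitlines():
            if "Ensemble energy" in line or "kcal/mol" in line:
                for tok in line.replace(":", " ").split():
                    try:
                        return float(tok)
                    except ValueError:
                        continue
        raise FoldingError(
            f"could not parse {self.executable} output:\n{out.stdout}"
        )


_BACKENDS = {
    "builtin": BuiltinBackend,
    "vienna": ViennaBackend,
    "rnastructure": RNAstructureBackend,
}


def get_backend(name: str = "builtin", mode: str = "ensemble", temperature: float = 37.0):
    """Construct a folding backend by config name."""
    try:
        cls = _BACKENDS[name]
    except KeyError:
        raise FoldingError(
            f"unknown folding backend {name!r}; choose from {sorted(_BACKENDS)}"
        )
    return cls(mode=mode, temperature=temperature)


def delta_g(region, backend=None) -> float:
    """Folding free energy of an RNA region in kcal/mol (<= 0; the open
    chain is the zero reference)."""
    backend = backend or BuiltinBackend()
    return backend.delta_g(region)


def dG_UH(seq: CodingSequence, spec: HeadRegionSpec, backend=None) -> float:
    """Fold the UTR-suffix + head region of a coding sequence."""
    region = build_region(spec, seq)
    if region.truncated:
        warnings.warn(
            f"{seq.id}: CDS shorter than head_nt={spec.head_nt}; folding whole CDS",
            stacklevel=2,
        )
    return delta_g(region.rna, backend)


# --- exhaustive reference (short sequences) ------------------------------


def enumerate_pair_sets(rna: str):
    """Yield every non-crossing set of canonical pairs with hairpin loops of
    at least MIN_HAIRPIN nt, as tuples of (i, j) index pairs.

    Recursive interval enumeration, independent of the dynamic programs;
    practical for sequences up to ~16 nt. The empty structure is included.
    """
    rna = _validate_rna(rna)
    n = len(rna)

    def _enum(i: int, j: int):  # structures of rna[i:j]
        if j - i <= MIN_HAIRPIN:
            yield ()
            return
        # position i unpaired
        for rest in _enum(i + 1, j):
            yield rest
        # position i paired with k
        for k in range(i + MIN_HAIRPIN + 1, j):
            if (rna[i], rna[k]) in PAIR_ENERGY:
                for inner in _enum(i + 1, k):
                    for outer in _enum(k + 1, j):
                        yield ((i, k),) + inner + outer

    yield from _enum(0, n)


def reference_energies(rna: str) -> tuple:
    """(mfe, ensemble) by brute-force enumeration of all structures."""
    rna = _validate_rna(rna)
    energies = [
        sum(PAIR_ENERGY[(rna[i], rna[j])] for i, j in struct)
        for struct in enumerate_pair_sets(rna)
    ]
    mfe = min(energies)
    # log-sum-exp for the partition function
    m = min(energies)
    z = sum(math.exp(-(e - m) / RT_37) for e in energies)
    ens = m - RT_37 * math.log(z)
    return mfe, ens
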