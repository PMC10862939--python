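"""Promoter sequences, energy matrices, and mutant-library generation.

This module holds the sequence-level plumbing of the MPRA simulator:

* :class:`PromoterSequence` — a promoter with a transcription start site
  (TSS), so positions can be addressed both by 0-based string index and by
  the TSS-relative "display" coordinate used on footprint axes.
* :class:`EnergyMatrix` — a position-by-base table of additive binding-energy
  contributions (kBT) for one DNA-binding factor, anchored on the promoter.
* :class:`MutationSpectrum` / :class:`MutantLibrary` / :func:`mutagenize` —
  random mutant-library construction with configurable mutational biases.
* engineered-promoter helpers (:func:`design_overlap_promoter`,
  :func:`insert_motif`) and plain-text I/O (FASTA via Biopython, TSV for
  matrices and mutation masks).

Conventions
-----------
Internal indexing is 0-based.  The display coordinate of index ``i`` is
``i - tss_index``; with the default 160-bp promoter and ``tss_index=115``
display coordinates span −115..+44, matching typical footprint axes.
Binding sites are half-open intervals in display coordinates.  All matrices
are given on the promoter's coding strand.  Wild-type-normalized matrices
(one zero entry per row, at the wild-type base) are the canonical form.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

#: Default promoter length (bp) and TSS index, so display coordinates span
#: −115..+44 — wide enough to place upstream activator sites and a −80 motif.
DEFAULT_LENGTH = 160
DEFAULT_TSS_INDEX = 115


class SequenceError(ValueError):
    """Invalid sequence content or out-of-bounds placement."""


class MatrixError(ValueError):
    """Invalid energy-matrix content or dimension mismatch."""


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def encode(seq: str) -> np.ndarray:
    """Map an ACGT string to an integer code array (A=0, C=1, G=2, T=3)."""
    try:
        return np.array([BASE_INDEX[b] for b in seq], dtype=np.uint8)
    except KeyError as exc:
        raise SequenceError(f"character {exc.args[0]!r} outside alphabet ACGT") from None


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in np.asarray(codes))


# ---------------------------------------------------------------------------
# Promoter sequences
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PromoterSequence:
    """A promoter sequence with a TSS anchoring display coordinates.

    Parameters
    ----------
    bases:
        Uppercase string over ``{A, C, G, T}``.
    tss_index:
        0-based index of the transcription start site; the display
        coordinate of index ``i`` is ``i - tss_index``.
    name:
        Optional identifier carried through FASTA I/O.
    """

    bases: str
    tss_index: int = DEFAULT_TSS_INDEX
    name: str = "promoter"

    def __post_init__(self) -> None:
        if not self.bases:
            raise SequenceError("empty promoter sequence")
        bad = set(self.bases) - set(ALPHABET)
        if bad:
            raise SequenceError(f"characters {sorted(bad)} outside alphabet ACGT")
        if not 0 <= self.tss_index < len(self.bases):
            raise SequenceError(
                f"tss_index {self.tss_index} outside sequence of length {len(self.bases)}"
            )

    @property
    def length(self) -> int:
        return len(self.bases)

    def to_index(self, display: int) -> int:
        """Convert a display (TSS-relative) coordinate to a string index."""
        idx = display + self.tss_index
        if not 0 <= idx < self.length:
            raise SequenceError(
                f"display coordinate {display} outside promoter span "
                f"[{-self.tss_index}, {self.length - self.tss_index})"
            )
        return idx

    def display_positions(self) -> np.ndarray:
        """Display coordinate of every position, −tss_index..length−tss_index−1."""
        return np.arange(self.length) - self.tss_index

    def window(self, display_start: int, length: int) -> str:
        """Subsequence of ``length`` bases starting at a display coordinate."""
        start = self.to_index(display_start)
        if start + length > self.length:
            raise SequenceError(
                f"window [{display_start}, {display_start + length}) runs off the promoter"
            )
        return self.bases[start : start + length]

    def codes(self) -> np.ndarray:
        return encode(self.bases)


def random_promoter(
    length: int = DEFAULT_LENGTH,
    tss_index: int = DEFAULT_TSS_INDEX,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    name: str = "promoter",
) -> PromoterSequence:
    """Uniformly random promoter sequence (seeded)."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    return PromoterSequence(decode(rng.integers(0, 4, size=length)), tss_index, name)


# ---------------------------------------------------------------------------
# Energy matrices
# ---------------------------------------------------------------------------

ROLES = ("polymerase", "repressor", "activator")


@dataclass(frozen=True)
class EnergyMatrix:
    """Additive binding-energy matrix for one factor, in kBT.

    ``energies[i, b]`` is the contribution of base ``b`` (A,C,G,T order) at
    site position ``i``.  ``offset`` is the display coordinate of the first
    site position on the promoter.  In wild-type-normalized form each row is
    zero at the wild-type base, so the matrix gives the *change* in binding
    energy relative to wild type.
    """

    energies: np.ndarray
    offset: int
    factor_name: str = ""
    factor_role: str = "polymerase"

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        if e.ndim != 2 or e.shape[1] != 4 or e.shape[0] < 1:
            raise MatrixError(f"energy matrix must be l x 4 with l >= 1, got {e.shape}")
        if not np.all(np.isfinite(e)):
            raise MatrixError("energy matrix contains non-finite values")
        if self.factor_role not in ROLES:
            raise MatrixError(f"factor_role must be one of {ROLES}, got {self.factor_role!r}")
        object.__setattr__(self, "energies", e)

    @property
    def site_length(self) -> int:
        return self.energies.shape[0]

    def is_normalized(self, atol: float = 1e-9) -> bool:
        """True when every row contains a (near-)zero entry.

        A wild-type-normalized matrix is zero at the wild-type base of each
        position; neutral mutations may contribute further zeros, so the
        check is for at least one zero per row.
        """
        zeros = np.isclose(self.energies, 0.0, atol=atol).sum(axis=1)
        return bool(np.all(zeros >= 1))

    def normalized(self, wild_type_window: str) -> "EnergyMatrix":
        """Re-anchor an arbitrary matrix so wild-type entries are zero."""
        codes = encode(wild_type_window)
        if codes.size != self.site_length:
            raise MatrixError(
                f"wild-type window length {codes.size} != site length {self.site_length}"
            )
        shifted = self.energies - self.energies[np.arange(self.site_length), codes][:, None]
        return replace(self, energies=shifted)

    def site_positions(self) -> np.ndarray:
        """Display coordinates covered by the site (half-open interval)."""
        return np.arange(self.offset, self.offset + self.site_length)


def synthetic_matrix(
    wild_type_window: str,
    offset: int,
    factor_role: str,
    factor_name: str = "",
    mutant_energy: float = 1.0,
) -> EnergyMatrix:
    """Synthetic matrix: 0 kBT at wild-type bases, ``mutant_energy`` elsewhere."""
    codes = encode(wild_type_window)
    e = np.full((codes.size, 4), float(mutant_energy))
    e[np.arange(codes.size), codes] = 0.0
    return EnergyMatrix(e, offset, factor_name or factor_role, factor_role)


def total_binding_energy(window: str | np.ndarray, matrix: EnergyMatrix) -> float:
    """Total additive binding energy of ``window`` under ``matrix`` (kBT).

    The window must match the matrix's site length exactly; the energy is the
    sum over positions of the entry for the observed base.
    """
    codes = window if isinstance(window, np.ndarray) else encode(window)
    if codes.size != matrix.site_length:
        raise MatrixError(
            f"window length {codes.size} != matrix site length {matrix.site_length}"
        )
    return float(matrix.energies[np.arange(matrix.site_length), codes].sum())


def average_mutation_effect(matrix: EnergyMatrix) -> float:
    """Mean energy cost of a single mutation in the site, ΔΔε (kBT).

    For a wild-type-normalized l x 4 matrix this is the sum of all (mutant)
    entries divided by 3l, since each position has three mutant bases.
    """
    if not matrix.is_normalized():
        raise MatrixError("average mutation effect requires a wild-type-normalized matrix")
    return float(matrix.energies.sum() / (3 * matrix.site_length))


# ---------------------------------------------------------------------------
# Mutation spectra and mutant libraries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationSpectrum:
    """Row-stochastic 4x4 substitution table with zero diagonal.

    ``substitution_probs[s, t]`` is the probability that a mutation at a base
    of identity ``s`` produces base ``t``.  A row of all zeros declares the
    source base immutable (it is silently never mutated).
    """

    substitution_probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.substitution_probs, dtype=float)
        if p.shape != (4, 4):
            raise SequenceError(f"spectrum must be 4x4, got {p.shape}")
        if np.any(p < 0) or np.any(np.abs(np.diag(p)) > 1e-12):
            raise SequenceError("spectrum must be non-negative with zero diagonal")
        rows = p.sum(axis=1)
        ok = np.isclose(rows, 1.0) | np.isclose(rows, 0.0)
        if not np.all(ok):
            raise SequenceError("each spectrum row must sum to 1 (or 0 for immutable bases)")
        object.__setattr__(self, "substitution_probs", p)

    @classmethod
    def uniform(cls) -> "MutationSpectrum":
        """Equal probability for each of the three mutant bases."""
        p = np.full((4, 4), 1.0 / 3.0)
        np.fill_diagonal(p, 0.0)
        return cls(p)

    @classmethod
    def transitions(cls) -> "MutationSpectrum":
        """Purine<->purine and pyrimidine<->pyrimidine swaps only (A<->G, C<->T)."""
        return cls.from_pairs({"A": "G", "G": "A", "C": "T", "T": "C"})

    @classmethod
    def from_pairs(cls, pairs: dict[str, str]) -> "MutationSpectrum":
        """Deterministic single-target spectrum; bases absent from ``pairs``
        are immutable (e.g. ``{"G": "A", "C": "T"}`` for a G→A / C→T bias)."""
        p = np.zeros((4, 4))
        for src, tgt in pairs.items():
            if src == tgt:
                raise SequenceError(f"self-substitution {src}->{tgt}")
            p[BASE_INDEX[src], BASE_INDEX[tgt]] = 1.0
        return cls(p)

    def immutable_bases(self) -> np.ndarray:
        """Boolean mask over A,C,G,T of bases that never mutate."""
        return np.isclose(self.substitution_probs.sum(axis=1), 0.0)


@dataclass
class MutantLibrary:
    """A library of promoter variants with per-position mutation indicators.

    ``codes`` is the (n, L) integer base array of all variants;
    ``mutation_mask[i, l]`` is 1 exactly when variant i differs from the wild
    type at position l.
    """

    wild_type: PromoterSequence
    codes: np.ndarray
    mutation_mask: np.ndarray
    rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        self.mutation_mask = np.asarray(self.mutation_mask, dtype=bool)
        if self.codes.ndim != 2 or self.codes.shape[0] < 1:
            raise SequenceError("library must contain at least one variant")
        if self.codes.shape[1] != self.wild_type.length:
            raise SequenceError("variant length differs from wild type")
        if self.mutation_mask.shape != self.codes.shape:
            raise SequenceError("mutation mask shape differs from variant array")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    def sequences(self) -> list[str]:
        return [decode(row) for row in self.codes]

    def variants(self) -> list[PromoterSequence]:
        tss = self.wild_type.tss_index
        return [
            PromoterSequence(decode(row), tss, f"{self.wild_type.name}_v{i}")
            for i, row in enumerate(self.codes)
        ]

    def site_codes(self, matrix: EnergyMatrix) -> np.ndarray:
        """(n, site_length) slice of variant codes under a matrix's site."""
        start = self.wild_type.to_index(matrix.offset)
        stop = start + matrix.site_length
        if stop > self.length:
            raise SequenceError("binding site runs off the promoter")
        return self.codes[:, start:stop]


def library_site_energies(library: MutantLibrary, matrix: EnergyMatrix) -> np.ndarray:
    """Per-variant total binding energy (kBT) of the matrix's site.

    Vectorized form of :func:`total_binding_energy` over the whole library.
    """
    sub = library.site_codes(matrix)
    return matrix.energies[np.arange(matrix.site_length)[None, :], sub].sum(axis=1)


def mutagenize(
    wild_type: PromoterSequence,
    n: int,
    rate: float,
    spectrum: MutationSpectrum | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    include_wild_type: bool = False,
) -> MutantLibrary:
    """Generate a random mutant library.

    Every position of every variant mutates independently with probability
    ``rate``; the target base of a mutation is drawn from the spectrum row of
    the source base.  Bases whose spectrum row is all-zero are immutable and
    are silently left at the wild type.  With ``include_wild_type`` the first
    variant is forced to the unmutated wild type.
    """
    if n < 1:
        raise SequenceError("library size must be >= 1")
    if not 0.0 <= rate <= 1.0:
        raise SequenceError("mutation rate must lie in [0, 1]")
    spectrum = spectrum if spectrum is not None else MutationSpectrum.uniform()
    rng = rng if rng is not None else np.random.default_rng(seed)

    wt = wild_type.codes()
    L = wt.size
    mask = rng.random((n, L)) < rate
    mask &= ~spectrum.immutable_bases()[wt][None, :]
    codes = np.tile(wt, (n, 1))
    # Draw targets per source base so each hit uses the right spectrum row.
    for src in range(4):
        hits = mask & (wt == src)[None, :]
        k = int(hits.sum())
        if k == 0:
            continue
        codes[hits] = rng.choice(4, size=k, p=spectrum.substitution_probs[src])
    if include_wild_type:
        codes[0] = wt
    mask = codes != wt[None, :]
    return MutantLibrary(wild_type, codes, mask, rate=rate, seed=seed)


# ---------------------------------------------------------------------------
# Engineered promoters
# ---------------------------------------------------------------------------


def insert_motif(promoter: PromoterSequence, motif: str, display_position: int) -> PromoterSequence:
    """Substitute ``motif`` into the promoter at a display coordinate.

    This is a replacement, not an insertion-with-shift: the promoter length
    is unchanged and only ``len(motif)`` positions can differ.
    """
    encode(motif)  # validate alphabet
    start = promoter.to_index(display_position)
    if start + len(motif) > promoter.length:
        raise SequenceError(
            f"motif of length {len(motif)} at {display_position} runs off the promoter"
        )
    bases = promoter.bases[:start] + motif + promoter.bases[start + len(motif):]
    return replace(promoter, bases=bases)


def design_overlap_promoter(
    rnap_matrix: EnergyMatrix,
    repressor_matrix: EnergyMatrix,
    overlap_offset: int,
    seed: int | None = None,
    length: int = DEFAULT_LENGTH,
    tss_index: int = DEFAULT_TSS_INDEX,
) -> PromoterSequence:
    """Design a promoter whose sites maximize binding of both factors.

    The repressor site is placed at display coordinate ``overlap_offset``
    (overriding the matrix's own offset), typically overlapping the
    polymerase site.  At positions covered by exactly one matrix the base
    minimizing that matrix's energy is chosen; at doubly covered positions
    the base minimizing the summed energy; elsewhere bases are random
    (seeded).
    """
    rng = np.random.default_rng(seed)
    codes = np.asarray(rng.integers(0, 4, size=length), dtype=np.uint8)
    total = np.zeros((length, 4))
    covered = np.zeros(length, dtype=bool)
    for matrix, offset in ((rnap_matrix, rnap_matrix.offset), (repressor_matrix, overlap_offset)):
        start = offset + tss_index
        stop = start + matrix.site_length
        if start < 0 or stop > length:
            raise SequenceError(
                f"site [{offset}, {offset + matrix.site_length}) falls off the promoter"
            )
        total[start:stop] += matrix.energies
        covered[start:stop] = True
    codes[covered] = np.argmin(total[covered], axis=1)
    return PromoterSequence(decode(codes), tss_index, "designed")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def write_fasta(path: str | Path, sequences: MutantLibrary | Iterable[PromoterSequence]) -> None:
    """Write a library or a collection of promoters as FASTA."""
    if isinstance(sequences, MutantLibrary):
        sequences = sequences.variants()
    records = [SeqRecord(Seq(p.bases), id=p.name, description="") for p in sequences]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path, tss_index: int = DEFAULT_TSS_INDEX) -> list[PromoterSequence]:
    """Read promoters from FASTA; all records share one ``tss_index``."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        try:
            out.append(PromoterSequence(seq, tss_index, rec.id))
        except SequenceError as exc:
            raise ParseError(f"{path}: record {rec.id!r}: {exc}") from None
    if not out:
        raise ParseError(f"{path}: no FASTA records found")
    return out


def library_from_sequences(
    wild_type: PromoterSequence, variants: Sequence[PromoterSequence]
) -> MutantLibrary:
    """Rebuild a :class:`MutantLibrary` from explicit variant sequences."""
    codes = np.stack([v.codes() for v in variants])
    mask = codes != wild_type.codes()[None, :]
    return MutantLibrary(wild_type, codes, mask)


_MATRIX_COLUMNS = ("pos", "A", "C", "G", "T")


def write_matrix(path: str | Path, matrix: EnergyMatrix) -> None:
    """Write an energy matrix as TSV with header metadata comments."""
    buf = io.StringIO()
    buf.write(f"# factor: {matrix.factor_name}\n")
    buf.write(f"# role: {matrix.factor_role}\n")
    buf.write(f"# offset: {matrix.offset}\n")
    buf.write("\t".join(_MATRIX_COLUMNS) + "\n")
    for i, row in enumerate(matrix.energies):
        buf.write("\t".join([str(matrix.offset + i)] + [repr(float(x)) for x in row]) + "\n")
    Path(path).write_text(buf.getvalue())


def read_matrix(path: str | Path, validate_normalized: bool = False) -> EnergyMatrix:
    """Read an energy matrix TSV written by :func:`write_matrix`.

    Malformed rows raise :class:`ParseError` naming the line number.  With
    ``validate_normalized`` the reader additionally checks the
    wild-type-normalization invariant (one zero entry per row).
    """
    meta = {"factor": "", "role": "polymerase", "offset": None}
    rows: list[list[float]] = []
    header_seen = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if ":" in line:
                key, _, value = line.lstrip("#").partition(":")
                meta[key.strip()] = value.strip()
            continue
        fields = line.split("\t")
        if not header_seen:
            if tuple(f.strip() for f in fields) != _MATRIX_COLUMNS:
                raise ParseError(
                    f"{path}:{lineno}: expected header {'	'.join(_MATRIX_COLUMNS)!r}, got {line!r}"
                )
            header_seen = True
            continue
        if len(fields) != 5:
            raise ParseError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
        try:
            rows.append([float(x) for x in fields[1:]])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric energy value") from None
    if not header_seen:
        raise ParseError(f"{path}: missing column header line")
    if not rows:
        raise ParseError(f"{path}: matrix has no data rows")
    offset = int(meta["offset"]) if meta["offset"] is not None else 0
    matrix = EnergyMatrix(np.array(rows), offset, str(meta["factor"]), str(meta["role"]))
    if validate_normalized and not matrix.is_normalized():
        raise MatrixError(f"{path}: matrix is not wild-type-normalized")
    return matrix


def write_mask(path: str | Path, library: MutantLibrary) -> None:
    """Write the n x L mutation mask as TSV (one row per variant)."""
    np.savetxt(path, library.mutation_mask.astype(int), fmt="%d", delimiter="\t")


def read_mask(path: str | Path) -> np.ndarray:
    try:
        mask = np.loadtxt(path, dtype=int, delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None
    return mask.astype(bool)
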