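"""Summary statistics of MPRA data: footprints, shifts, and signal-to-noise.

An *information footprint* is the per-position mutual information (bits)
between mutation status and binned expression across a mutant library;
positions inside functional binding sites carry high mutual information
because mutations there change expression.  The companion *expression
shift* statistics attach a direction: mutations at a repressor site raise
expression (positive shift) while mutations at RNAP or activator sites
lower it (negative shift).

Estimation conventions (fixed, documented):

* base identity is coarse-grained to wild-type vs mutant by default;
* expression is split into two bins at the mean count, with counts exactly
  equal to the mean assigned to the high bin; ``n_bins > 2`` switches to
  equal-count (quantile) bins;
* probabilities are plug-in empirical frequencies, 0*log(0) terms are 0,
  and no bias correction is applied;
* a position where the library carries no mutation has MI defined as 0 and
  is flagged, not an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .seqlib import ALPHABET, MutantLibrary, MutationSpectrum, PromoterSequence, mutagenize


class StatsError(ValueError):
    """Invalid input to a summary statistic."""


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------


@dataclass
class FootprintResult:
    """Per-position mutual information and expression-shift values.

    ``positions`` are display (TSS-relative) coordinates; ``mi`` is in bits;
    ``shift`` follows the absolute-shift definition (count units) and
    ``sign`` is its sign (+1 repressor-like, -1 activator/polymerase-like,
    0 for no shift).  ``unmutated`` flags positions the library never
    mutates (their MI is defined as 0).
    """

    positions: np.ndarray
    mi: np.ndarray
    shift: np.ndarray
    sign: np.ndarray
    unmutated: np.ndarray
    n_bins: int = 2
    coarse_base: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "mutual_information": self.mi,
                "expression_shift": self.shift,
                "shift_sign": self.sign,
                "unmutated": self.unmutated.astype(int),
            }
        )


@dataclass
class ExpressionShiftMatrix:
    """4 x L table of relative expression change per mutant base.

    ``values[b, l]`` is the mean relative deviation (c/<c> - 1) of variants
    carrying base b at position l, for mutant b; wild-type entries are
    exactly 0, as are bases never observed at a position.
    """

    positions: np.ndarray
    values: np.ndarray
    wild_type: str

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values.T, columns=list(ALPHABET))
        df.insert(0, "position", self.positions)
        df.insert(1, "wild_type_base", list(self.wild_type))
        return df


class SNRResult(NamedTuple):
    """Signal-to-noise ratio; ``infinite`` flags a zero off-site mean."""

    value: float
    infinite: bool


# ---------------------------------------------------------------------------
# Binning helpers
# ---------------------------------------------------------------------------


def _expression_bins(counts: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin labels for expression levels.

    Two bins split at the mean count (ties to the high bin); more bins use
    equal-count (rank quantile) binning.
    """
    if n_bins < 2:
        raise StatsError("need at least two expression bins")
    if n_bins == 2:
        return (counts >= counts.mean()).astype(np.int64)
    order = np.argsort(counts, kind="stable")
    labels = np.empty(counts.size, dtype=np.int64)
    labels[order] = (np.arange(counts.size) * n_bins) // counts.size
    return labels


def _as_counts(counts) -> np.ndarray:
    if isinstance(counts, pd.DataFrame):
        col = "sampled_count" if "sampled_count" in counts else "expected_count"
        counts = counts[col]
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise StatsError("counts must be one-dimensional")
    return c


def _mutual_information(labels_a: np.ndarray, labels_b: np.ndarray, ka: int, kb: int) -> float:
    """Plug-in MI (bits) between two small-alphabet label arrays."""
    n = labels_a.size
    joint = np.zeros((ka, kb))
    np.add.at(joint, (labels_a, labels_b), 1.0)
    joint /= n
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(joint > 0, joint / (pa * pb), 1.0)
        terms = np.where(joint > 0, joint * np.log2(ratio), 0.0)
    # plug-in MI is non-negative; clamp away float-rounding negatives
    return max(float(terms.sum()), 0.0)


# ---------------------------------------------------------------------------
# Footprint statistics
# ---------------------------------------------------------------------------


def information_footprint(
    library: MutantLibrary,
    counts,
    n_bins: int = 2,
    coarse_base: bool = True,
) -> FootprintResult:
    """Mutual information between mutation status and expression, per position.

    With the default 2x2 coarse-graining (wild-type/mutant base, low/high
    expression) each position's MI lies in [0, 1] bits.  Setting
    ``coarse_base=False`` uses the full 4-letter base identity.
    """
    c = _as_counts(counts)
    if c.size != library.n:
        raise StatsError(f"counts length {c.size} != library size {library.n}")
    if library.n < 2:
        raise StatsError("need at least two variants to estimate mutual information")
    mu = _expression_bins(c, n_bins)
    L = library.length
    mi = np.zeros(L)
    unmutated = ~library.mutation_mask.any(axis=0)
    for l in range(L):
        if unmutated[l]:
            continue
        if coarse_base:
            b = (~library.mutation_mask[:, l]).astype(np.int64)  # 1 = wild type
            mi[l] = _mutual_information(b, mu, 2, n_bins)
        else:
            b = library.codes[:, l].astype(np.int64)
            mi[l] = _mutual_information(b, mu, 4, n_bins)
    shift = expression_shift(library, c)
    return FootprintResult(
        positions=library.wild_type.display_positions(),
        mi=mi,
        shift=shift,
        sign=np.sign(shift).astype(int),
        unmutated=unmutated,
        n_bins=n_bins,
        coarse_base=coarse_base,
    )


def expression_shift(library: MutantLibrary, counts) -> np.ndarray:
    """Mask-weighted mean deviation from the mean count, per position.

    ds_l = (1/n) sum_i xi_{i,l} (c_i - <c>); positive values mark
    repressor-like positions, negative values polymerase/activator-like.
    """
    c = _as_counts(counts)
    if c.size != library.n:
        raise StatsError(f"counts length {c.size} != library size {library.n}")
    dev = c - c.mean()
    return library.mutation_mask.T.astype(float) @ dev / library.n


def expression_shift_matrix(library: MutantLibrary, counts) -> ExpressionShiftMatrix:
    """Per-base relative expression shifts.

    ds_{b,l} = (1/n) sum_i xi_{b,i,l} (c_i/<c> - 1) over variants carrying
    mutant base b at position l; wild-type entries are exactly 0.
    """
    c = _as_counts(counts)
    if c.size != library.n:
        raise StatsError(f"counts length {c.size} != library size {library.n}")
    mean = c.mean()
    if mean == 0:
        raise StatsError("relative shifts undefined for an all-zero expression table")
    rel = c / mean - 1.0
    L = library.length
    values = np.zeros((4, L))
    wt = library.wild_type.codes()
    for b in range(4):
        carrier = (library.codes == b) & library.mutation_mask
        values[b] = carrier.T.astype(float) @ rel / library.n
    values[wt, np.arange(L)] = 0.0
    return ExpressionShiftMatrix(
        positions=library.wild_type.display_positions(),
        values=values,
        wild_type=library.wild_type.bases,
    )


def avg_site_information(
    footprint: FootprintResult, site_positions: Sequence[int] | np.ndarray
) -> float:
    """Arithmetic mean of per-position MI over a binding site (display coords)."""
    pos = np.asarray(site_positions)
    if pos.size == 0:
        raise StatsError("binding site has no positions")
    idx = np.searchsorted(footprint.positions, pos)
    if np.any(idx >= footprint.positions.size) or np.any(
        footprint.positions[np.clip(idx, 0, footprint.positions.size - 1)] != pos
    ):
        raise StatsError("site positions outside the promoter")
    return float(footprint.mi[idx].mean())


def snr(
    footprint: FootprintResult, site_positions: Sequence[int] | np.ndarray
) -> SNRResult:
    """Ratio of mean MI inside declared binding sites to mean MI outside.

    A zero off-site mean (the noiseless limit) is reported as infinite with
    a flag rather than raising or silently dividing.
    """
    pos = np.asarray(site_positions)
    inside = np.isin(footprint.positions, pos)
    if not inside.any():
        raise StatsError("no footprint positions inside the declared sites")
    if inside.all():
        raise StatsError("no non-binding positions left to estimate noise")
    signal = float(footprint.mi[inside].mean())
    background = float(footprint.mi[~inside].mean())
    if background == 0.0:
        return SNRResult(math.inf, True)
    return SNRResult(signal / background, False)


# ---------------------------------------------------------------------------
# The two-letter minimal promoter (hitch-hiking fixture)
# ---------------------------------------------------------------------------


def minimal_promoter_dataset(
    reduced: bool = False, high: float = 100.0, low: float = 0.0
) -> tuple[MutantLibrary, np.ndarray]:
    """The 2-bp, two-letter constitutive promoter used to study hitch-hiking.

    Position 1 is a non-binding site and position 2 the RNAP-specific site;
    the two letters X (strong binding, wild type) and Y (weak) are encoded
    as A and C.  The full library holds all four sequences XX, YX, XY, YY
    with high expression whenever the specific site carries X; the reduced
    library holds only XX (high) and YY (low), which makes the two
    positions' mutation patterns perfectly correlated.
    Returns (library, counts).
    """
    wt = PromoterSequence("AA", tss_index=0, name="minimal")
    seqs = ["AA", "CA", "AC", "CC"] if not reduced else ["AA", "CC"]
    variants = [PromoterSequence(s, 0, f"minimal_{s}") for s in seqs]
    from .seqlib import library_from_sequences

    lib = library_from_sequences(wt, variants)
    counts = np.array([high if s[1] == "A" else low for s in seqs])
    return lib, counts


def write_footprint(path, footprint: FootprintResult) -> None:
    footprint.to_frame().to_csv(path, sep="\t", index=False)


def write_shift_matrix(path, matrix: ExpressionShiftMatrix) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False)


def read_footprint(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
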