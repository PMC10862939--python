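"""From occupancy probabilities to mRNA counts.

Under the occupancy hypothesis the steady-state mRNA count of a variant is
``m* = alpha * p_bound`` with ``alpha = r / gamma`` the ratio of the
transcription rate to the mRNA degradation rate; alpha defaults to 100 so
counts land on a realistic sequencing scale, and its value cancels from all
downstream footprint statistics.

The module also models two layers of measurement realism, both opt-in:

* extrinsic noise — per-variant RNAP and repressor copy numbers drawn from
  a log-normal distribution with a chosen mean and coefficient of variation
  (cell-to-cell variation in the transcription machinery);
* sequencing-style resampling — multinomial or Poisson resampling of the
  expected counts at a chosen read depth (PCR/sampling noise).

Expression tables are plain pandas DataFrames with one row per variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqlib import MutantLibrary
from .thermo import (
    ArchitectureModel,
    ConfigurationError,
    MWCParams,
    ThermoParams,
    pbound_induction_library,
    pbound_library,
    pbound_multicopy_library,
    pbound_nonspecific_library,
)

#: Columns of an expression table.
VARIANT, EXPECTED, SAMPLED = "variant", "expected_count", "sampled_count"


@dataclass
class NoiseSpec:
    """Extrinsic (copy-number) noise specification.

    ``means`` maps copy-number keys ('P', 'R', ...) to their mean copy
    numbers; the defaults are 5000 RNAPs and 100 repressors.  ``cv`` is the
    coefficient of variation shared by all factors; physiological values are
    below 2, but arbitrarily large values are accepted.
    """

    means: dict[str, float] = field(default_factory=lambda: {"P": 5000.0, "R": 100.0})
    cv: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ConfigurationError("coefficient of variation must be >= 0")
        if any(m <= 0 for m in self.means.values()):
            raise ConfigurationError("mean copy numbers must be positive")


def draw_copy_numbers(
    noise: NoiseSpec, n: int, rng: np.random.Generator | None = None
) -> dict[str, np.ndarray]:
    """One log-normal copy-number draw per variant per factor.

    The log-normal is parameterized by its *arithmetic* mean m and CV v:
    sigma^2 = ln(1 + v^2) and location mu = ln m - sigma^2/2, so
    E[X] = exp(mu + sigma^2/2) = m exactly and sd(X)/E[X] = v.
    With v = 0 every draw equals the mean.
    """
    if n < 1:
        raise ConfigurationError("need at least one variant")
    rng = rng if rng is not None else np.random.default_rng(noise.seed)
    draws: dict[str, np.ndarray] = {}
    for key, mean in noise.means.items():
        if noise.cv == 0:
            draws[key] = np.full(n, float(mean))
        else:
            sigma2 = np.log1p(noise.cv**2)
            mu = np.log(mean) - sigma2 / 2.0
            draws[key] = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)
    return draws


def expected_counts(
    library: MutantLibrary,
    architecture: ArchitectureModel,
    params: ThermoParams,
    mode: str = "equilibrium",
    noise: NoiseSpec | None = None,
    rng: np.random.Generator | None = None,
    mwc: MWCParams | None = None,
    inducer_c: float | None = None,
    n_sites: int = 1,
    **mode_kwargs,
) -> pd.DataFrame:
    """Expected mRNA count per variant: m* = alpha * p_bound.

    ``mode`` selects the occupancy model: ``equilibrium`` (generic
    states-and-weights engine), ``induction`` (MWC inducible repressor,
    requires ``mwc``), ``multicopy`` (repressor-site copy number
    ``n_sites`` via chemical potential) or ``nonspecific`` (RNAP binding at
    every promoter window).  With ``noise``, per-variant copy numbers are
    drawn first and fed into the equilibrium engine.
    """
    draws: dict[str, np.ndarray] = {}
    if noise is not None:
        if mode != "equilibrium":
            raise ConfigurationError("extrinsic noise is supported in equilibrium mode only")
        draws = draw_copy_numbers(noise, library.n, rng)
    if mode == "equilibrium":
        p = pbound_library(architecture, library, params, copies=draws or None)
    elif mode == "induction":
        if mwc is None:
            raise ConfigurationError("induction mode requires MWC parameters")
        p = pbound_induction_library(architecture, library, params, mwc, inducer_c)
    elif mode == "multicopy":
        p = pbound_multicopy_library(architecture, library, params, n_sites)
    elif mode == "nonspecific":
        p = pbound_nonspecific_library(architecture, library, params, **mode_kwargs)
    else:
        raise ConfigurationError(f"unknown expression mode {mode!r}")
    table = pd.DataFrame(
        {VARIANT: np.arange(library.n), EXPECTED: params.alpha * p}
    )
    for key, values in draws.items():
        table[f"{key}_draw"] = values
    return table


def resample_counts(
    table: pd.DataFrame,
    depth: float,
    mode: str = "multinomial",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sequencing-style resampling of expected counts at a read depth.

    ``multinomial`` draws exactly ``depth`` reads with probabilities
    proportional to m*; ``poisson`` draws independent Poisson counts with
    means scaled so the expected total is ``depth``.
    """
    if depth <= 0:
        raise ConfigurationError("sequencing depth must be positive")
    m = table[EXPECTED].to_numpy(dtype=float)
    total = m.sum()
    if total <= 0:
        raise ConfigurationError("cannot resample an all-zero expression table")
    rng = rng if rng is not None else np.random.default_rng(seed)
    if mode == "multinomial":
        sampled = rng.multinomial(int(depth), m / total)
    elif mode == "poisson":
        sampled = rng.poisson(m * (depth / total))
    else:
        raise ConfigurationError(f"unknown resampling mode {mode!r}")
    out = table.copy()
    out[SAMPLED] = sampled
    return out


def write_counts(path, table: pd.DataFrame, library: MutantLibrary | None = None) -> None:
    """Write an expression table as TSV, optionally with variant sequences."""
    out = table.copy()
    if library is not None:
        out.insert(1, "sequence", library.sequences())
    out.to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
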