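# mprasim

Simulated massively parallel reporter assays (MPRAs) from first principles.

Mutational-scanning MPRAs such as Sort-Seq and Reg-Seq infer the regulatory
architecture of a promoter by measuring expression for thousands of mutant
variants and asking, position by position, how strongly mutations and
expression co-vary.  `mprasim` closes that loop computationally: it maps
promoter sequence variants to expression through sequence-specific
thermodynamic (and optionally non-equilibrium graph-theoretic) models of
transcription, and then applies the same summary statistics used on real
MPRA data — information footprints, expression-shift matrices, and
signal-to-noise ratios.  Because the ground-truth architecture of a
synthetic dataset is known, the package is a test bench for MPRA design:
how mutation rate, library size, mutational bias, binding energies, factor
and binding-site copy numbers, inducers, non-specific binding, overlapping
sites, and broken detailed balance shape what a footprint can and cannot
reveal.  It is aimed at groups designing or interpreting bacterial MPRAs
and at anyone studying sequence-to-expression maps with statistical
mechanics.

## The model

The occupancy hypothesis links transcription to the equilibrium probability
that RNA polymerase (RNAP) occupies the promoter.  For a promoter under
simple repression,

    p_bound = (P/N_NS) e^{-β Δε_pd} / (1 + (P/N_NS) e^{-β Δε_pd} + (R/N_NS) e^{-β Δε_rd})

with `P`, `R` the RNAP and repressor copy numbers, `N_NS ≈ 4×10⁶` genomic
non-specific sites, and `Δε_pd`, `Δε_rd` the specific binding energies in
kBT.  The binding energies are *sequence specific*: each factor carries an
energy matrix `ε_{i,b}` (kBT per position and base, zero at the wild-type
base) and a variant's binding energy is the additive sum `Δε = Σ_i ε_{i,b_i}`.
A generic states-and-weights engine covers the six common architectures —
constitutive, simple repression, simple activation, repression–activation,
double repression (AND/OR/XOR logic), double activation — plus MWC
induction, chemical-potential titration of binding-site copies, genome-wide
non-specific RNAP binding, and a Matrix-Tree-Theorem solver for kinetic
state graphs with driven edges.

Expected counts are `m* = α · p_bound` (α = 100 by default).  The
information footprint is the per-position mutual information

    I_i = Σ_b Σ_μ Pr_i(b, μ) log₂ [ Pr_i(b, μ) / (Pr_i(b) Pr(μ)) ]

between mutation status `b` (wild-type vs mutant) and binned expression `μ`
(two bins split at the mean count), and the expression shift
`Δs_l = (1/n) Σ_i ξ_{i,l} (c_i − ⟨c⟩)` attaches a direction: positive means
repressor-like, negative RNAP/activator-like.

## Worked example

Simulate a 5,000-variant library of a 160-bp simple-repression promoter at
a 10% mutation rate and read the architecture back out of the footprint:

```python
import numpy as np
from mprasim import (ThermoParams, build_architecture, consensus_promoter,
                     mutagenize, expected_counts, information_footprint,
                     avg_site_information, snr)
from mprasim.thermo import binding_site_positions

promoter = consensus_promoter(seed=1)
params = ThermoParams()                      # P=1000, R=10, N_NS=4e6, alpha=100
arch = build_architecture("simple_repression", promoter)
library = mutagenize(promoter, n=5000, rate=0.1, seed=2)
counts = expected_counts(library, arch, params)
fp = information_footprint(library, counts)

sites = binding_site_positions(arch)
print("mean count:", round(counts["expected_count"].mean(), 3))
for name, pos in sites.items():
    shift = fp.shift[np.isin(fp.positions, pos)].mean()
    print(f"{name:10s} <I> = {avg_site_information(fp, pos):.4f} bits, "
          f"mean shift = {shift:+.4f}")
allpos = np.concatenate(list(sites.values()))
print("signal-to-noise ratio:", round(snr(fp, allpos).value, 1))
```

prints

```
mean count: 0.246
rnap       <I> = 0.0121 bits, mean shift = -0.0149
repressor  <I> = 0.0026 bits, mean shift = +0.0083
signal-to-noise ratio: 44.5
```

Both binding sites carry far more mutual information than the background
(SNR ≈ 45), and the shift signs identify them: mutations in the RNAP site
(display coordinates −36..−7) lower expression, mutations in the repressor
operator (+1..+20) raise it.  The low mean count reflects active repression
(p_bound ≈ 0.004 for the wild type, against ≈ 0.036 constitutive).

The same pipeline is scriptable from the shell:

```
mprasim simulate --config config.yaml --out results/
mprasim sweep --config config.yaml --parameter params.R --values 0,1,10,100 \
        --replicates 20 --out sweep.tsv
mprasim fixtures --out fixtures/
```

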