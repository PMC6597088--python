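"""Founder genotype simulation: 2 sire-breed (IB) + 5 dam-breed (LD) animals
by default, each with two haplotypes drawn from its breed's stratum frequency."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cross import CrossDesign


@dataclass
class FounderSet:
    variants: list            # list[TruthVariant], defines row order
    names: list               # founder sample names
    breeds: list              # breed label per founder ("IB"/"LD")
    haplotypes: np.ndarray    # (n_variants, n_founders, 2) in {0, 1}

    @property
    def genotypes(self) -> np.ndarray:
        """Alt-allele dosage matrix (n_variants x n_founders) in {0, 1, 2}."""
        return self.haplotypes.sum(axis=2)

    def genotype_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.genotypes,
            index=[str(v.key) for v in self.variants],
            columns=self.names,
        )


def simulate_founders(truth, design: CrossDesign, seed: int) -> FounderSet:
    """Draw two haplotypes per founder, Bernoulli at the breed's true frequency."""
    if design.n_founder_sires_IB < 1 or design.n_founder_dams_LD < 1:
        raise ValueError("design must include at least one founder per breed")
    rng = np.random.default_rng(seed)
    names = [f"IB_{i + 1}" for i in range(design.n_founder_sires_IB)] + [
        f"LD_{i + 1}" for i in range(design.n_founder_dams_LD)
    ]
    breeds = ["IB"] * design.n_founder_sires_IB + ["LD"] * design.n_founder_dams_LD
    n_var, n_f = len(truth), len(names)
    freqs = np.empty((n_var, n_f))
    for i, v in enumerate(truth):
        for j, b in enumerate(breeds):
            freqs[i, j] = v.true_freq_IB if b == "IB" else v.true_freq_LD
    haps = (rng.random((n_var, n_f, 2)) < freqs[:, :, None]).astype(np.int8)
    return FounderSet(variants=list(truth), names=names, breeds=breeds, haplotypes=haps)
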