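"""Gene-drop simulation of BC1 backcross populations.

F1 animals are produced from IB sire x LD dam gametes; each BC1 individual is
an F1 gamete plus a terminal-breed gamete.  Gametes carry a Poisson number of
crossovers per chromosome with uniform breakpoints (no interference).
Genotypes are emitted in the {-1, 0, +1} marker coding used downstream
(+1 = hom-ref, 0 = het, -1 = hom-alt).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .genome import SimulatedGenome

N_BATCHES = 14


@dataclass
class CrossDesign:
    n_founder_sires_IB: int = 2
    n_founder_dams_LD: int = 5
    backcrosses: list = field(
        default_factory=lambda: [
            ("BC1_LD", "LD", 160),
            ("BC1_DU", "DU", 143),
            ("BC1_PI", "PI", 138),
        ]
    )
    recombination_rate: float = 1.0  # expected crossovers per chromosome per meiosis

    def __post_init__(self) -> None:
        if self.n_founder_sires_IB < 0 or self.n_founder_dams_LD < 0:
            raise ValueError("founder counts must be non-negative")
        for name, breed, n in self.backcrosses:
            if n <= 0:
                raise ValueError(f"backcross {name} must have positive size")


@dataclass
class BackcrossResult:
    individuals: pd.DataFrame   # id, backcross, sex, batch
    markers: list               # list[TruthVariant] (column order)
    codes: np.ndarray           # (n_individuals, n_markers) in {-1, 0, +1}
    pedigree: pd.DataFrame      # id, f1_sire, f1_dam, terminal breed
    f1_gametes: np.ndarray      # (n, m) allele from the F1 parent, {0, 1}
    terminal_gametes: np.ndarray  # (n, m) allele from the terminal parent
    f1_origin: np.ndarray       # (n, m) True where the F1 gamete allele is of IB origin
    dosages: np.ndarray         # (n, m) alt-allele dosage in {0, 1, 2}

    @property
    def iberian_fraction(self) -> np.ndarray:
        """Per-individual fraction of marker alleles of Iberian origin."""
        return self.f1_origin.mean(axis=1) / 2.0


def _gamete(
    hapA: np.ndarray,
    hapB: np.ndarray,
    marker_chrom: np.ndarray,
    marker_pos: np.ndarray,
    chrom_lengths: dict,
    rate: float,
    rng: np.random.Generator,
):
    """One meiotic gamete over the marker map; returns (alleles, from_A mask)."""
    m = len(marker_pos)
    alleles = np.empty(m, dtype=np.int8)
    from_a = np.zeros(m, dtype=bool)
    for chrom, L in chrom_lengths.items():
        idx = np.where(marker_chrom == chrom)[0]
        current = bool(rng.integers(0, 2))  # True -> hapA
        if len(idx) == 0:
            continue
        k = int(rng.poisson(rate))
        breaks = np.sort(rng.uniform(0, L, size=k)) if k else np.empty(0)
        pos = marker_pos[idx]
        n_breaks_before = np.searchsorted(breaks, pos)
        use_a = (n_breaks_before % 2 == 0) == current
        alleles[idx] = np.where(use_a, hapA[idx], hapB[idx])
        from_a[idx] = use_a
    return alleles, from_a


def simulate_backcross(
    founders,
    genome: SimulatedGenome,
    design: CrossDesign,
    seed: int,
    terminal_freqs: Optional[dict] = None,
) -> BackcrossResult:
    """Drop founder haplotypes through F1s into the BC1 populations.

    ``terminal_freqs`` maps terminal-breed label -> per-marker alt frequency
    array; breeds without an entry default to the LD stratum frequency (the
    commercial breeds share a frequency pool unless told otherwise).
    """
    if design.n_founder_sires_IB < 1 or design.n_founder_dams_LD < 1:
        raise ValueError("cannot simulate a backcross without founders")
    rng = np.random.default_rng(seed)
    variants = founders.variants
    m = len(variants)
    marker_chrom = np.array([v.key.chrom for v in variants])
    marker_pos = np.array([v.key.pos for v in variants], dtype=float)
    chrom_lengths = genome.lengths()
    ld_freq = np.array([v.true_freq_LD for v in variants])
    terminal_freqs = terminal_freqs or {}

    ib_idx = [i for i, b in enumerate(founders.breeds) if b == "IB"]
    ld_idx = [i for i, b in enumerate(founders.breeds) if b == "LD"]
    haps = founders.haplotypes  # (m, n_founders, 2)

    # all sire x dam F1 combinations; BC1s draw an F1 parent uniformly
    f1s = []
    for si in ib_idx:
        for di in ld_idx:
            pat, _ = _gamete(haps[:, si, 0], haps[:, si, 1], marker_chrom, marker_pos,
                             chrom_lengths, design.recombination_rate, rng)
            mat, _ = _gamete(haps[:, di, 0], haps[:, di, 1], marker_chrom, marker_pos,
                             chrom_lengths, design.recombination_rate, rng)
            f1s.append((si, di, pat, mat))

    rows = []
    ped = []
    codes = []
    f1_gams = []
    term_gams = []
    origins = []
    counter = 0
    for bc_name, terminal, n_ind in design.backcrosses:
        tfreq = np.asarray(terminal_freqs.get(terminal, ld_freq), dtype=float)
        for _ in range(n_ind):
            counter += 1
            ind_id = f"{bc_name}_{counter:04d}"
            si, di, pat, mat = f1s[int(rng.integers(0, len(f1s)))]
            # F1 gamete: paternal haplotype (IB origin) vs maternal (LD origin)
            g, from_pat = _gamete(pat, mat, marker_chrom, marker_pos,
                                  chrom_lengths, design.recombination_rate, rng)
            t = (rng.random(m) < tfreq).astype(np.int8)
            dosage = g + t
            rows.append(
                {
                    "id": ind_id,
                    "backcross": bc_name,
                    # offset the sex alternation by one each batch cycle so sex
                    # and batch stay linearly independent in the design matrix
                    "sex": "M" if (counter + counter // N_BATCHES) % 2 else "F",
                    "batch": f"batch{(counter - 1) % N_BATCHES + 1}",
                }
            )
            ped.append(
                {
                    "id": ind_id,
                    "f1_sire": founders.names[si],
                    "f1_dam": founders.names[di],
                    "terminal_breed": terminal,
                }
            )
            codes.append(1 - dosage)
            f1_gams.append(g)
            term_gams.append(t)
            origins.append(from_pat)
    dosages = 1 - np.array(codes, dtype=np.int8)
    return BackcrossResult(
        individuals=pd.DataFrame(rows),
        markers=list(variants),
        codes=np.array(codes, dtype=np.int8),
        pedigree=pd.DataFrame(ped),
        f1_gametes=np.array(f1_gams, dtype=np.int8),
        terminal_gametes=np.array(term_gams, dtype=np.int8),
        f1_origin=np.array(origins, dtype=bool),
        dosages=dosages,
    )
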