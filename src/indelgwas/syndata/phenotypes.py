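"""Phenotype generation under the additive mixed model used for association:

``y = mean + sex + batch + backcross + beta * carcass + sum(planted a * code)
+ u + e`` with ``u ~ MVN(0, sigma_u^2 * K / mean(diag K))`` and
``sigma_u^2 = h2 * trait_sd^2``.  The kinship matrix is rescaled to unit mean
diagonal internally so that ``h2`` is interpretable as the share of
``trait_sd^2`` attributable to the polygenic term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cross import BackcrossResult, N_BATCHES


@dataclass
class PhenotypeModelConfig:
    trait_name: str = "C20_2_n6"
    trait_mean: float = 0.51      # merged-dataset calibration
    trait_sd: float = 0.14
    n_batches: int = N_BATCHES
    sex_effects: Sequence = (0.0, 0.0)            # M, F
    batch_effects: Sequence = tuple([0.0] * N_BATCHES)
    backcross_effects: Sequence = (0.0, 0.0, 0.0)
    carcass_weight_mean: float = 72.2
    carcass_weight_sd: float = 6.0
    beta_carcass: float = 0.0
    h2_polygenic: float = 0.0
    residual_sd: Optional[float] = None  # default: sqrt(1 - h2) * trait_sd
    log2_transform: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_polygenic <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if self.trait_sd < 0 or (self.residual_sd is not None and self.residual_sd < 0):
            raise ValueError("standard deviations must be non-negative")


def _mvn_polygenic(K: np.ndarray, sigma_u2: float, rng: np.random.Generator) -> np.ndarray:
    vals, vecs = np.linalg.eigh(K)
    if vals.min() < -1e-6 * max(1.0, abs(vals.max())):
        raise ValueError("kinship matrix K is not positive semi-definite")
    vals = np.clip(vals, 0.0, None)
    z = rng.standard_normal(len(vals))
    return vecs @ (np.sqrt(sigma_u2 * vals) * z)


def simulate_phenotypes(
    genotypes: BackcrossResult,
    kinship: np.ndarray,
    cfg: PhenotypeModelConfig,
    planted,
    seed: int,
) -> pd.DataFrame:
    """Return a phenotype table (id, trait, sex, batch, backcross, carcass_weight).

    ``planted`` is a sequence of ``(marker_index_or_key, effect)`` pairs, or
    ``(marker, effect, backcross_name)`` triples restricting the effect to one
    backcross; the effect is in trait units per unit of {-1, 0, +1} code.
    """
    n = len(genotypes.individuals)
    K = np.asarray(kinship, dtype=float)
    if K.shape != (n, n):
        raise ValueError("kinship dimension must equal the number of individuals")
    rng = np.random.default_rng(seed)

    ind = genotypes.individuals
    sex_levels = ["M", "F"]
    batch_levels = [f"batch{i + 1}" for i in range(cfg.n_batches)]
    bc_levels = [name for name, _, _ in _bc_order(ind)]

    y = np.full(n, cfg.trait_mean, dtype=float)
    y += np.array([cfg.sex_effects[sex_levels.index(s)] for s in ind["sex"]])
    y += np.array([cfg.batch_effects[batch_levels.index(b)] for b in ind["batch"]])
    y += np.array(
        [cfg.backcross_effects[bc_levels.index(b) % len(cfg.backcross_effects)]
         for b in ind["backcross"]]
    )
    carcass = rng.normal(cfg.carcass_weight_mean, cfg.carcass_weight_sd, size=n)
    y += cfg.beta_carcass * (carcass - cfg.carcass_weight_mean)

    key_index = {str(v.key): i for i, v in enumerate(genotypes.markers)}
    for entry in planted or ():
        marker, effect = entry[0], entry[1]
        target_bc = entry[2] if len(entry) > 2 else None
        j = marker if isinstance(marker, (int, np.integer)) else key_index[str(marker)]
        mask = (
            np.ones(n, dtype=bool)
            if target_bc is None
            else (ind["backcross"] == target_bc).to_numpy()
        )
        y += effect * genotypes.codes[:, j] * mask

    sigma_u2 = cfg.h2_polygenic * cfg.trait_sd**2
    if sigma_u2 > 0:
        scale = np.mean(np.diag(K))
        if scale <= 0:
            raise ValueError("kinship matrix K has non-positive mean diagonal")
        y += _mvn_polygenic(K / scale, sigma_u2, rng)
    residual_sd = (
        cfg.residual_sd
        if cfg.residual_sd is not None
        else np.sqrt(max(0.0, 1.0 - cfg.h2_polygenic)) * cfg.trait_sd
    )
    if residual_sd > 0:
        y += rng.normal(0.0, residual_sd, size=n)
    if cfg.log2_transform:
        if (y <= 0).any():
            raise ValueError("log2 transform requires strictly positive phenotypes")
        y = np.log2(y)

    out = ind.copy()
    out[cfg.trait_name] = y
    out["carcass_weight"] = carcass
    return out[["id", cfg.trait_name, "sex", "batch", "backcross", "carcass_weight"]]


def _bc_order(ind: pd.DataFrame):
    seen = []
    for b in ind["backcross"]:
        if b not in [x[0] for x in seen]:
            seen.append((b, None, None))
    return seen
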