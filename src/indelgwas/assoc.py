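"""Founder-frequency candidate selection, marker QC, genomic kinship, mixed
linear model association scan and Benjamini-Hochberg FDR classification.

The scan uses the common single-fit approximation: variance components are
estimated once by REML under the null (no marker) and the resulting
covariance ``V = sigma_u^2 K + sigma_e^2 I`` is reused for every marker's
generalized-least-squares test.  Genotypes are coded {-1, 0, +1}
(+1 hom-ref, 0 het, -1 hom-alt); missing codes are mean-imputed per marker
for both kinship and the scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

log = logging.getLogger(__name__)

SIGNIFICANT_FDR = 0.05
SUGGESTIVE_FDR = 0.10
_EPS = 1e-9


# ---------------------------------------------------------------------------
# founder frequencies & candidate selection
# ---------------------------------------------------------------------------


@dataclass
class FounderFrequencies:
    key: object
    freq_IB: Optional[float]
    freq_LD: Optional[float]
    n_alleles_IB: int
    n_alleles_LD: int


def founder_freqs(keys, genotypes: np.ndarray, breeds: Sequence[str]) -> list:
    """Alt-allele frequency per breed from founder dosage genotypes.

    ``genotypes`` is (n_variants x n_founders) with values {0, 1, 2} or NaN
    for missing; a breed with all alleles missing reports frequency None.
    """
    genotypes = np.asarray(genotypes, dtype=float)
    breeds = np.asarray(breeds)
    out = []
    for i, key in enumerate(keys):
        row = genotypes[i]
        freqs = {}
        counts = {}
        for breed in ("IB", "LD"):
            g = row[breeds == breed]
            g = g[~np.isnan(g)]
            counts[breed] = 2 * len(g)
            freqs[breed] = float(g.sum() / (2 * len(g))) if len(g) else None
        out.append(
            FounderFrequencies(
                key=key,
                freq_IB=freqs["IB"],
                freq_LD=freqs["LD"],
                n_alleles_IB=counts["IB"],
                n_alleles_LD=counts["LD"],
            )
        )
    return out


START_STOP_TERMS = {"start_lost", "stop_gained", "stop_lost"}


def select_candidates(freqs, annotations, lipid_genes: Iterable[str]) -> list:
    """Candidate indels by either selection criterion.

    (a) a start/stop consequence term in a lipid-metabolism gene;
    (b) High or Moderate severity at extreme founder frequencies
        (IB = 1 and LD <= 0.2, or IB = 0 and LD >= 0.8).

    Returns ``[(key, criteria, annotation)]`` with ``criteria`` a subset of
    {"a", "b"}.
    """
    lipid_genes = set(lipid_genes)
    by_key: dict = {}
    for ann in annotations:
        by_key.setdefault(ann.key, []).append(ann)
    out = []
    for f in freqs:
        anns = by_key.get(f.key, [])
        criteria = set()
        best = None
        for ann in anns:
            if ann.terms & START_STOP_TERMS and ann.gene_id in lipid_genes:
                criteria.add("a")
                best = best or ann
            if (
                ann.severity in ("High", "Moderate")
                and f.freq_IB is not None
                and f.freq_LD is not None
                and (
                    (abs(f.freq_IB - 1.0) < _EPS and f.freq_LD <= 0.2 + _EPS)
                    or (f.freq_IB < _EPS and f.freq_LD >= 0.8 - _EPS)
                )
            ):
                criteria.add("b")
                best = best or ann
        if criteria:
            out.append((f.key, criteria, best))
    return out


# ---------------------------------------------------------------------------
# genotype matrix, QC, genotype-frequency reporting
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    individuals: pd.DataFrame  # id, backcross, sex, batch columns
    markers: list              # marker identifiers, column order
    codes: np.ndarray          # (n, m) float with values {-1, 0, +1} or NaN

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        ok = np.isnan(self.codes) | np.isin(self.codes, (-1.0, 0.0, 1.0))
        if not ok.all():
            raise ValueError("codes must be in {-1, 0, +1} or missing")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def maf(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            f_alt = np.nanmean(1.0 - self.codes, axis=0) / 2.0
        return np.minimum(f_alt, 1.0 - f_alt)

    @property
    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.codes).mean(axis=0)


def marker_qc(G: GenotypeMatrix, maf_min: float = 0.05, missing_max: float = 0.05):
    """Drop markers with MAF < ``maf_min`` or missingness > ``missing_max``.

    Returns ``(filtered GenotypeMatrix, report dict)``.
    """
    maf = G.maf
    miss = G.missing_rate
    low_maf = np.isnan(maf) | (maf < maf_min)
    high_miss = miss > missing_max
    keep = ~(low_maf | high_miss)
    report = {
        "n_input": len(G.markers),
        "n_removed_maf": int(low_maf.sum()),
        "n_removed_missing": int((high_miss & ~low_maf).sum()),
        "n_kept": int(keep.sum()),
    }
    filtered = GenotypeMatrix(
        individuals=G.individuals,
        markers=[m for m, k in zip(G.markers, keep) if k],
        codes=G.codes[:, keep],
    )
    return filtered, report


def genotype_freq_table(G: GenotypeMatrix, markers: Optional[Sequence] = None) -> pd.DataFrame:
    """Per-backcross genotype-class fractions (hom-ref/het/hom-alt) per marker."""
    idx = (
        range(len(G.markers))
        if markers is None
        else [G.markers.index(m) for m in markers]
    )
    rows = []
    for j in idx:
        col = G.codes[:, j]
        for bc, sel in G.individuals.groupby("backcross", sort=False).groups.items():
            g = col[np.asarray(sel)]
            g = g[~np.isnan(g)]
            n = len(g)
            rows.append(
                {
                    "marker": str(G.markers[j]),
                    "backcross": bc,
                    "hom_ref": float((g == 1).sum() / n) if n else np.nan,
                    "het": float((g == 0).sum() / n) if n else np.nan,
                    "hom_alt": float((g == -1).sum() / n) if n else np.nan,
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


def impute_codes(codes: np.ndarray) -> np.ndarray:
    """Mean-impute missing codes per marker."""
    X = np.array(codes, dtype=float)
    means = np.nanmean(X, axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = means[nan_c]
    return X


def centered_kinship(codes: np.ndarray) -> np.ndarray:
    """Centred relatedness matrix K = (1/p) Xc Xc' from {-1,0,+1} codes."""
    X = impute_codes(codes)
    p = X.shape[1]
    if p == 0:
        raise ValueError("cannot compute kinship from zero markers")
    Xc = X - X.mean(axis=0, keepdims=True)
    K = Xc @ Xc.T / p
    return (K + K.T) / 2.0


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------


def design_matrix(
    pheno: pd.DataFrame, include_backcross: bool = True, carcass: bool = True
):
    """Fixed-effect design: intercept + sex + batch + (backcross) + carcass.

    Factor dummies drop the first observed level and any empty level; raises
    on a rank-deficient result, naming the collinear columns.
    """
    n = len(pheno)
    cols = [np.ones(n)]
    names = ["intercept"]
    factors = ["sex", "batch"] + (["backcross"] if include_backcross else [])
    for f in factors:
        levels = list(dict.fromkeys(pheno[f]))
        for lev in levels[1:]:
            cols.append((pheno[f] == lev).to_numpy(dtype=float))
            names.append(f"{f}[{lev}]")
    if carcass and "carcass_weight" in pheno:
        cols.append(pheno["carcass_weight"].to_numpy(dtype=float))
        names.append("carcass_weight")
    X = np.column_stack(cols)
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = [names[i] for i in range(X.shape[1]) if abs(R[i, i]) < 1e-8]
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")
    return X, names


# ---------------------------------------------------------------------------
# variance components (REML) and the scan
# ---------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    sigma_u2: float
    sigma_e2: float
    loglik: float

    def __post_init__(self) -> None:
        if self.sigma_u2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def h2(self) -> float:
        tot = self.sigma_u2 + self.sigma_e2
        return self.sigma_u2 / tot if tot > 0 else 0.0


def _reml_neg_loglik(log_delta, S, yt, Xt, logdet_xx):
    delta = np.exp(log_delta)
    w = delta * S + 1.0
    Xw = Xt / w[:, None]
    M = Xt.T @ Xw
    b = Xw.T @ yt
    beta = np.linalg.solve(M, b)
    r = yt - Xt @ beta
    n, q = Xt.shape
    rss = float(r @ (r / w))
    sigma_e2 = rss / (n - q)
    sign, logdet_m = np.linalg.slogdet(M)
    ll = -0.5 * (
        (n - q) * (np.log(2 * np.pi * sigma_e2) + 1.0)
        + np.log(w).sum()
        + logdet_m
        - logdet_xx
    )
    return -ll, sigma_e2, beta


def fit_null(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    n_grid: int = 80,
    bounds: tuple = (-10.0, 10.0),
) -> VarianceComponents:
    """REML variance components for ``y = X b + u + e`` with ``u ~ N(0, sigma_u^2 K)``.

    The ratio ``delta = sigma_u^2 / sigma_e^2`` is profiled on a log grid and
    refined with bounded scalar minimization; deterministic for fixed input.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    S, U = np.linalg.eigh((K + K.T) / 2.0)
    S = np.clip(S, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X
    sign, logdet_xx = np.linalg.slogdet(X.T @ X)

    grid = np.linspace(bounds[0], bounds[1], n_grid)
    vals = [_reml_neg_loglik(g, S, yt, Xt, logdet_xx)[0] for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    res = minimize_scalar(
        lambda g: _reml_neg_loglik(g, S, yt, Xt, logdet_xx)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    best = res.x if res.fun <= vals[i] else grid[i]
    neg_ll, sigma_e2, _ = _reml_neg_loglik(best, S, yt, Xt, logdet_xx)
    delta = float(np.exp(best))
    # boundary check: if delta = 0 (pure residual model) is at least as good,
    # snap to it so the scan reduces exactly to OLS
    neg_ll0, sigma_e2_0, _ = _reml_neg_loglik(-np.inf, S, yt, Xt, logdet_xx)
    if neg_ll0 <= neg_ll + 1e-6:
        delta, neg_ll, sigma_e2 = 0.0, neg_ll0, sigma_e2_0
    return VarianceComponents(
        sigma_u2=delta * sigma_e2, sigma_e2=sigma_e2, loglik=-neg_ll
    )


@dataclass
class AssociationResult:
    marker: object
    a_hat: float
    se: float
    statistic: float
    p_value: float
    q_value: float = np.nan
    cls: str = "ns"


def classify(q: float) -> str:
    if q <= SIGNIFICANT_FDR:
        return "significant"
    if q <= SUGGESTIVE_FDR:
        return "suggestive"
    return "ns"


def lmm_scan(
    y: np.ndarray,
    X: np.ndarray,
    G: GenotypeMatrix,
    K: np.ndarray,
    vc: VarianceComponents,
    apply_fdr: bool = True,
) -> list:
    """Per-marker GLS under the covariance *structure* fixed from the null fit
    (ratio sigma_u^2/sigma_e^2 held constant, overall scale re-estimated from
    each marker model's weighted residuals), Wald t test on the residual
    degrees of freedom.  With sigma_u^2 = 0 this is exactly ordinary least
    squares.  Constant markers are skipped with a log entry.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    S, U = np.linalg.eigh((K + K.T) / 2.0)
    S = np.clip(S, 0.0, None)
    if vc.sigma_e2 <= 0:
        raise ValueError("non-positive residual variance; check components")
    w = (vc.sigma_u2 / vc.sigma_e2) * S + 1.0
    yt = U.T @ y
    Xt = U.T @ X
    codes = impute_codes(G.codes)
    Gt = U.T @ codes  # rotate all markers at once
    n, q = X.shape
    df = n - q - 1
    results = []
    sw = 1.0 / w
    for j, marker in enumerate(G.markers):
        if np.ptp(codes[:, j]) == 0:
            log.info("lmm_scan: marker %s constant after imputation; skipped", marker)
            continue
        gt = Gt[:, j]
        A = np.column_stack([Xt, gt])
        Aw = A * sw[:, None]
        M = A.T @ Aw
        b = Aw.T @ yt
        try:
            Minv = np.linalg.inv(M)
        except np.linalg.LinAlgError:
            log.info("lmm_scan: singular system at marker %s; skipped", marker)
            continue
        beta = Minv @ b
        r = yt - A @ beta
        s2 = float(r @ (r * sw)) / df
        a = float(beta[-1])
        se = float(np.sqrt(s2 * Minv[-1, -1]))
        t = a / se
        p = float(2.0 * stats.t.sf(abs(t), df))
        results.append(AssociationResult(marker=marker, a_hat=a, se=se, statistic=t, p_value=p))
    if apply_fdr and results:
        qvals, classes = bh_fdr([r.p_value for r in results])
        for r, qv, c in zip(results, qvals, classes):
            r.q_value = qv
            r.cls = c
    return results


def bh_fdr(p_values):
    """Benjamini-Hochberg step-up q-values and significance classes.

    ``q(i) = min_{j >= i} (m / j) p_(j)`` on the sorted vector, mapped back to
    input order; significant iff q <= 0.05, suggestive iff 0.05 < q <= 0.1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    classes = [classify(v) for v in q]
    return q, classes


def scan_trait(
    pheno: pd.DataFrame,
    trait: str,
    G: GenotypeMatrix,
    K: Optional[np.ndarray] = None,
    include_backcross: bool = True,
    log2_transform: bool = False,
) -> tuple:
    """Convenience wrapper: design + null fit + scan + FDR for one trait.

    Returns ``(results, vc)``.
    """
    y = pheno[trait].to_numpy(dtype=float)
    if log2_transform:
        y = np.log2(y)
    X, _ = design_matrix(pheno, include_backcross=include_backcross)
    if K is None:
        K = centered_kinship(G.codes)
    vc = fit_null(y, X, K)
    return lmm_scan(y, X, G, K, vc), vc
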