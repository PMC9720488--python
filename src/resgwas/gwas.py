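"""Single-SNP mixed-model association with GRM correction.

Each SNP is added as a categorical fixed effect (one level per genotype
class, most frequent class as reference) to the trait's animal model. To
keep a genome scan tractable the polygenic-to-residual variance ratio is
fixed at the batch-level REML estimate, so every SNP model is a
generalised-least-squares fit under ``V0 = ratio * G + I`` (up to the
residual scale). The SNP term is judged by its conditional (incremental)
Wald F given all other fixed effects, with denominator df equal to the
residual df of the GLS fit.

Scan-level summaries: the genomic inflation factor (observed median
association chi-square over the 1-df null median, 0.45494) and Storey
q-values with suggestive/significant calls at FDR 10% and 5%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, linalg
from scipy.stats import chi2
from scipy.stats import f as f_dist

from .kinship import RelationshipMatrix
from .simulate import MISSING_CALL, GenotypePanel
from .varcomp import KinshipEig, ModelSpec, VarCompEstimate, build_design, eigendecompose

__all__ = [
    "SnpTestResult",
    "GwasSummary",
    "snp_association",
    "run_gwas",
    "genomic_inflation",
    "qvalues",
    "significance_calls",
]

CHI2_1_MEDIAN = chi2.ppf(0.5, df=1)  # 0.45494...
FDR_SUGGESTIVE = 0.10
FDR_SIGNIFICANT = 0.05


@dataclass
class SnpTestResult:
    snp_id: str
    chromosome: str
    position: int
    n_used: int
    ref_class: int
    effects: dict[int, float]  # genotype class -> effect vs reference
    F_statistic: float
    df_num: int
    df_den: float
    p_value: float
    q_value: float = math.nan
    testable: bool = True


@dataclass
class GwasSummary:
    lambda_gc: float
    n_snps_tested: int
    n_suggestive: int
    n_significant: int
    variance_ratio: float

    def to_dict(self) -> dict:
        return {
            "lambda_gc": self.lambda_gc,
            "n_snps_tested": self.n_snps_tested,
            "n_suggestive": self.n_suggestive,
            "n_significant": self.n_significant,
            "variance_ratio": self.variance_ratio,
        }


def _snp_dummies(calls: np.ndarray) -> tuple[np.ndarray, int, list[int]]:
    """Reference-coded dummies for the observed genotype classes of one
    SNP (missing rows excluded upstream). Reference = most frequent class,
    ties broken by lower genotype code."""
    classes, counts = np.unique(calls, return_counts=True)
    ref = int(classes[np.argmax(counts)])
    others = [int(c) for c in classes if c != ref]
    D = np.column_stack([(calls == c).astype(float) for c in others]) if others else np.empty((calls.size, 0))
    return D, ref, others


def _whitened_snp_test(
    yw: np.ndarray,
    Xbw: np.ndarray,
    Dw: np.ndarray,
    rss_base: float | None = None,
) -> tuple[np.ndarray, list[int], float, int, float, float] | None:
    """Conditional (incremental) F for the SNP block on whitened data.

    After whitening by V0^{-1/2}, the GLS conditional Wald F equals the
    ordinary incremental F between the base design and base-plus-SNP
    design. SNP dummy columns collinear with the base design are dropped
    (rank-revealing QR); returns None when none survive (no testable
    contrast). Returns (snp effects, kept column indices, F, df_num,
    df_den, p)."""
    n, p0 = Xbw.shape
    X = np.column_stack([Xbw, Dw])
    R = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(R))
    tol = 1e-9 * max(diag.max(), 1.0)
    kept = [j for j in range(Dw.shape[1]) if diag[p0 + j] > tol]
    if not kept:
        return None
    if len(kept) < Dw.shape[1]:
        Dw = Dw[:, kept]
        X = np.column_stack([Xbw, Dw])
    beta, *_ = np.linalg.lstsq(X, yw, rcond=None)
    rss_full = float(np.sum((yw - X @ beta) ** 2))
    if rss_base is None:
        beta0, *_ = np.linalg.lstsq(Xbw, yw, rcond=None)
        rss_base = float(np.sum((yw - Xbw @ beta0) ** 2))
    q = Dw.shape[1]
    df_den = n - X.shape[1]
    if df_den <= 0 or rss_full <= 0:
        return None
    F = max(((rss_base - rss_full) / q) / (rss_full / df_den), 0.0)
    pval = float(f_dist.sf(F, q, df_den))
    return beta[p0:], kept, F, q, float(df_den), min(max(pval, 1e-300), 1.0)


class _MixedGls:
    """Shared machinery for a scan: rotated base design for complete-call
    SNPs, and the raw V0 for per-SNP subsetting when calls are missing."""

    def __init__(
        self,
        y: np.ndarray,
        Xb: np.ndarray,
        G: np.ndarray,
        ratio: float,
        eig: KinshipEig | None = None,
    ) -> None:
        if ratio < 0:
            raise ValueError("variance ratio must be >= 0")
        self.y, self.Xb, self.ratio = y, Xb, ratio
        self.V0 = ratio * G + np.eye(len(y))
        if eig is None:
            d, U = linalg.eigh(G)
            d = np.clip(d, 0.0, None)
        else:
            U, d = eig.U, eig.d
        self.U = U
        sw = np.sqrt(ratio * d + 1.0)
        self.yw = (U.T @ y) / sw
        self.Xbw = (U.T @ Xb) / sw[:, None]
        self._sw = sw
        beta0, *_ = np.linalg.lstsq(self.Xbw, self.yw, rcond=None)
        self._rss_base = float(np.sum((self.yw - self.Xbw @ beta0) ** 2))

    @staticmethod
    def _package(out, others, ref):
        eff, kept, F, q, df_den, p = out
        classes = [others[j] for j in kept]
        return dict(zip(classes, eff.tolist())), ref, F, q, df_den, p

    def test_complete(self, calls: np.ndarray):
        D, ref, others = _snp_dummies(calls)
        Dw = (self.U.T @ D) / self._sw[:, None]
        out = _whitened_snp_test(self.yw, self.Xbw, Dw, rss_base=self._rss_base)
        return None if out is None else self._package(out, others, ref)

    def test_subset(self, calls: np.ndarray, keep: np.ndarray):
        D, ref, others = _snp_dummies(calls[keep])
        V = self.V0[np.ix_(keep, keep)]
        L = linalg.cholesky(V, lower=True)
        yw = linalg.solve_triangular(L, self.y[keep], lower=True)
        Xbw = linalg.solve_triangular(L, self.Xb[keep], lower=True)
        Dw = linalg.solve_triangular(L, D, lower=True)
        out = _whitened_snp_test(yw, Xbw, Dw)
        return None if out is None else self._package(out, others, ref)


def snp_association(
    df: pd.DataFrame,
    spec: ModelSpec,
    snp_calls: np.ndarray,
    G: RelationshipMatrix,
    ratio: float,
    snp_id: str = "snp",
    chromosome: str = "?",
    position: int = 0,
) -> SnpTestResult:
    """Test one SNP against one trait (standalone; ``run_gwas`` shares the
    rotation across SNPs). Rows of ``df`` must align with ``snp_calls``
    and with the order of ``G.ids``."""
    data = df.reset_index(drop=True)
    y = data[spec.response].to_numpy(dtype=float)
    Xb, _ = build_design(data, spec.fixed_factors)
    engine = _MixedGls(y, Xb, G.submatrix(data[spec.animal_col].tolist()).matrix, ratio)
    calls = np.asarray(snp_calls)
    keep = calls != MISSING_CALL
    classes = np.unique(calls[keep])
    if classes.size < 2:
        return SnpTestResult(
            snp_id, chromosome, position, int(keep.sum()),
            int(classes[0]) if classes.size else -1, {},
            math.nan, 0, math.nan, math.nan, testable=False,
        )
    out = engine.test_complete(calls) if keep.all() else engine.test_subset(calls, keep)
    if out is None:
        return SnpTestResult(
            snp_id, chromosome, position, int(keep.sum()), -1, {},
            math.nan, 0, math.nan, math.nan, testable=False,
        )
    effects, ref, F, q, df_den, p = out
    return SnpTestResult(
        snp_id, chromosome, position, int(keep.sum()), ref, effects, F, q, df_den, p
    )


def run_gwas(
    df: pd.DataFrame,
    spec: ModelSpec,
    panel: GenotypePanel,
    G: RelationshipMatrix,
    varcomp: VarCompEstimate | float,
    g_eig: KinshipEig | None = None,
    fdr_suggestive: float = FDR_SUGGESTIVE,
    fdr_significant: float = FDR_SIGNIFICANT,
) -> tuple[pd.DataFrame, GwasSummary]:
    """Scan every SNP of a QC'd panel against one trait.

    ``varcomp`` supplies the batch-level variance ratio (an estimate object
    or the ratio itself), fixed across all SNPs. Returns a per-SNP table
    sorted by chromosome/position (with -log10 p for plotting) and the
    scan summary (inflation factor, FDR calls).
    """
    if panel.n_snps == 0:
        raise ValueError("empty genotype panel")
    if isinstance(varcomp, VarCompEstimate):
        if not varcomp.converged:
            raise ValueError("variance-component fit did not converge")
        ratio = varcomp.sigma_a2 / varcomp.sigma_e2
    else:
        ratio = float(varcomp)

    data = df.dropna(subset=[spec.response]).reset_index(drop=True)
    hens = data[spec.animal_col].tolist()
    gpanel = panel.subset_individuals(hens)
    Gsub = G.submatrix(hens)
    y = data[spec.response].to_numpy(dtype=float)
    Xb, _ = build_design(data, spec.fixed_factors)
    if g_eig is not None and g_eig.ids == hens:
        engine = _MixedGls(y, Xb, Gsub.matrix, ratio, eig=g_eig)
    else:
        engine = _MixedGls(y, Xb, Gsub.matrix, ratio)

    results: list[SnpTestResult] = []
    smap = panel.snp_map
    for j in range(gpanel.n_snps):
        calls = gpanel.calls[:, j]
        keep = calls != MISSING_CALL
        meta = (str(smap.iloc[j]["snp_id"]), str(smap.iloc[j]["chromosome"]),
                int(smap.iloc[j]["position_bp"]))
        classes = np.unique(calls[keep])
        if classes.size < 2:
            results.append(SnpTestResult(
                *meta, int(keep.sum()), int(classes[0]) if classes.size else -1,
                {}, math.nan, 0, math.nan, math.nan, testable=False))
            continue
        out = engine.test_complete(calls) if keep.all() else engine.test_subset(calls, keep)
        if out is None:
            results.append(SnpTestResult(
                *meta, int(keep.sum()), -1, {}, math.nan, 0, math.nan,
                math.nan, testable=False))
            continue
        effects, ref, F, q, df_den, p = out
        results.append(SnpTestResult(*meta, int(keep.sum()), ref, effects,
                                     F, q, df_den, p))

    tested = [r for r in results if r.testable]
    pvals = np.array([r.p_value for r in tested])
    lam = genomic_inflation(pvals) if pvals.size else math.nan
    qvals = qvalues(pvals) if pvals.size else np.array([])
    for r, qv in zip(tested, qvals):
        r.q_value = float(qv)
    n_sug, n_sig = significance_calls(qvals, fdr_suggestive, fdr_significant)
    summary = GwasSummary(lam, len(tested), n_sug, n_sig, ratio)

    table = pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in results],
            "chromosome": [r.chromosome for r in results],
            "position_bp": [r.position for r in results],
            "n_used": [r.n_used for r in results],
            "ref_class": [r.ref_class for r in results],
            "effects": [
                ";".join(f"{c}:{v:.6g}" for c, v in sorted(r.effects.items()))
                for r in results
            ],
            "F": [r.F_statistic for r in results],
            "df_num": [r.df_num for r in results],
            "df_den": [r.df_den for r in results],
            "p": [r.p_value for r in results],
            "q": [r.q_value for r in results],
            "testable": [r.testable for r in results],
        }
    )
    table["neg_log10_p"] = -np.log10(table["p"])
    chrom_order = {c: i for i, c in enumerate(
        sorted(table["chromosome"].unique(), key=lambda c: (c == "Z", len(c), c)))}
    table = table.sort_values(
        ["chromosome", "position_bp"],
        key=lambda s: s.map(chrom_order) if s.name == "chromosome" else s,
    ).reset_index(drop=True)
    return table, summary


def genomic_inflation(p_values: np.ndarray) -> float:
    """lambda_GC = median(chi2_1 quantiles of the p-values) / 0.45494.

    The paper's convention converts every p to a 1-df chi-square quantile
    regardless of the test's numerator df.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    stats = chi2.isf(p, df=1)
    return float(np.median(stats) / CHI2_1_MEDIAN)


def _storey_pi0(p: np.ndarray) -> float:
    """Storey's pi0: the share of tests with p > lambda, extrapolated to
    lambda -> 1 with a smoothing spline over the grid 0.05..0.95."""
    lam = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([np.mean(p > l) / (1.0 - l) for l in lam])
    spline = interpolate.make_smoothing_spline(lam, pi0_lam)
    pi0 = float(spline(lam[-1]))
    return min(max(pi0, 1e-8), 1.0)


def qvalues(p_values: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey q-values: ``q_i = min_{p_j >= p_i} pi0 * m * p_j / rank_j``.

    With fewer than 100 p-values (too few to estimate pi0) — or with
    ``pi0=1`` forced — this reduces exactly to Benjamini-Hochberg.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = 1.0 if m < 100 else _storey_pi0(p)
    if not 0.0 < pi0 <= 1.0:
        raise ValueError("pi0 must lie in (0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def significance_calls(
    q_values: np.ndarray,
    fdr_suggestive: float = FDR_SUGGESTIVE,
    fdr_significant: float = FDR_SIGNIFICANT,
) -> tuple[int, int]:
    """Counts of SNPs below the suggestive and significant FDR thresholds."""
    q = np.asarray(q_values, dtype=float)
    return int(np.sum(q < fdr_suggestive)), int(np.sum(q < fdr_significant))
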