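"""Line-means association scan for transition phenotypes.

In a fully inbred panel every line is homozygous, so genotypes are coded as
dosages 0/2 (heterozygous calls are treated as missing by default, or as
dosage 1 if configured). For each variant the per-line phenotype mean is
regressed on dosage by ordinary least squares, optionally with user-supplied
per-line covariates (e.g. relatedness proxies, inversion or endosymbiont
status), and the genotype coefficient is tested two-sided. A
minor-line-count filter removes variants carried by too few lines to be
informative. Significance uses a strict Bonferroni threshold alpha/n_tests;
a configurable suggestive tier is also reported, and QQ points support
inflation diagnostics.

The scan is vectorized across variants: phenotype and genotypes are
residualized on the covariate design once, after which each variant's
effect, SE, t and P follow from closed-form simple regression. Variants
with missing calls fall back to a per-variant fit on their complete lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .heritability import bonferroni

__all__ = [
    "GenotypeMatrix",
    "read_genotypes",
    "filter_variants",
    "LineMeansScan",
    "ScanResults",
    "qq_points",
]


@dataclass
class GenotypeMatrix:
    """Variant x line dosage matrix for an inbred panel.

    ``dosages`` holds 0/2 (and optionally 1) with NaN for missing calls;
    ``variants`` carries id, chrom, pos (1-based), ref, alt per row.
    """

    variants: pd.DataFrame
    dosages: np.ndarray  # (n_variants, n_lines), float with NaN
    lines: list[str]

    def __post_init__(self):
        if self.dosages.shape != (len(self.variants), len(self.lines)):
            raise ValueError("dosage shape does not match variants x lines")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def minor_line_counts(self) -> np.ndarray:
        """Per variant, number of lines carrying the rarer genotype."""
        alt = np.nansum(self.dosages > 0, axis=1)
        ref = np.nansum(self.dosages == 0, axis=1)
        return np.minimum(alt, ref).astype(int)

    def call_rates(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=1)

    def subset(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.variants.loc[mask].reset_index(drop=True),
            self.dosages[np.asarray(mask)],
            self.lines,
        )


def _read_genotypes_tsv(path, sep: str = "\t") -> GenotypeMatrix:
    df = pd.read_csv(path, sep=sep)
    meta_cols = ["id", "chrom", "pos", "ref", "alt"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f"genotype TSV missing column(s): {missing}")
    lines = [c for c in df.columns if c not in meta_cols]
    dos = df[lines].to_numpy(dtype=float)
    return GenotypeMatrix(df[meta_cols].copy(), dos, lines)


def _read_genotypes_vcf(path, het_policy: str = "missing") -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    lines = list(vcf.samples)
    meta, rows = [], []
    for i, rec in enumerate(vcf):
        vid = rec.ID or f"{rec.CHROM}_{rec.POS}"
        meta.append((vid, rec.CHROM, rec.POS, rec.REF,
                     rec.ALT[0] if rec.ALT else "."))
        gt = rec.gt_types  # 0 hom-ref, 1 het, 2 missing, 3 hom-alt
        dos = np.full(len(lines), np.nan)
        dos[gt == 0] = 0.0
        dos[gt == 3] = 2.0
        if het_policy == "dosage1":
            dos[gt == 1] = 1.0
        rows.append(dos)
    variants = pd.DataFrame(meta, columns=["id", "chrom", "pos", "ref",
                                           "alt"])
    return GenotypeMatrix(variants, np.array(rows), lines)


def read_genotypes(path, fmt: str = "auto", sep: str = "\t",
                   het_policy: str = "missing") -> GenotypeMatrix:
    """Read genotypes from a wide TSV or a VCF.

    TSV layout: columns id, chrom, pos, ref, alt then one column per line
    with dosages in {0, 2} (NaN/blank = missing). VCF samples are lines;
    heterozygous calls become missing (default) or dosage 1.
    """
    fmt = fmt.lower()
    if fmt == "auto":
        fmt = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "tsv"
    if fmt == "vcf":
        return _read_genotypes_vcf(path, het_policy=het_policy)
    return _read_genotypes_tsv(path, sep=sep)


def filter_variants(gm: GenotypeMatrix,
                    min_minor_lines: int = 4) -> GenotypeMatrix:
    """Drop variants whose minor genotype is carried by too few lines."""
    keep = gm.minor_line_counts() >= min_minor_lines
    return gm.subset(keep)


def qq_points(pvalues) -> pd.DataFrame:
    """-log10 expected (uniform) vs observed quantiles for a QQ plot."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    if p.size == 0:
        raise ValueError("no P values")
    floor = np.finfo(float).tiny
    if (p <= 0).any():
        import warnings

        warnings.warn("P values of 0 clamped to machine floor")
        p = np.maximum(p, floor)
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(p)
    return pd.DataFrame({"expected": expected, "observed": observed})


class LineMeansScan:
    """Model: per-variant OLS of line-mean phenotype on genotype dosage.

    Parameters
    ----------
    phenotype : Series of per-line trait means indexed by line id.
    genotypes : GenotypeMatrix whose line ids intersect the phenotype's.
    covariates : optional DataFrame of per-line covariate columns
        (relatedness proxies, inversion status, endosymbiont infection ...),
        indexed by line; an intercept is always included.
    """

    def __init__(self, phenotype: pd.Series, genotypes: GenotypeMatrix,
                 covariates: pd.DataFrame | None = None):
        shared = [l for l in genotypes.lines if l in phenotype.index]
        if not shared:
            raise ValueError("no lines shared between phenotype and genotypes")
        if covariates is not None:
            shared = [l for l in shared if l in covariates.index]
        self.lines = shared
        cols = [genotypes.lines.index(l) for l in shared]
        self.genotypes = GenotypeMatrix(
            genotypes.variants, genotypes.dosages[:, cols], shared
        )
        self.y = phenotype.loc[shared].to_numpy(dtype=float)
        if covariates is not None:
            C = covariates.loc[shared].to_numpy(dtype=float)
            self.design = np.column_stack([np.ones(len(shared)), C])
        else:
            self.design = np.ones((len(shared), 1))
        if np.linalg.matrix_rank(self.design) < self.design.shape[1]:
            raise ValueError("covariate design is rank deficient")

    @staticmethod
    def _simple_ols(g: np.ndarray, y: np.ndarray, df_resid: int):
        """Effect/SE/t/P of y on residualized g (both centered)."""
        gg = float(g @ g)
        if gg <= 0 or df_resid < 1:
            return np.nan, np.nan, np.nan, np.nan
        beta = float(g @ y) / gg
        rss = float(y @ y) - beta**2 * gg
        rss = max(rss, 0.0)
        s2 = rss / df_resid
        if s2 == 0:
            return beta, 0.0, np.inf, 0.0
        se = np.sqrt(s2 / gg)
        t = beta / se
        p = 2.0 * float(stats.t.sf(abs(t), df_resid))
        return beta, se, t, p

    def fit(self, min_lines: int = 3) -> "ScanResults":
        X = self.design
        H = X @ np.linalg.solve(X.T @ X, X.T)
        n, c = X.shape
        y_r = self.y - H @ self.y
        G = self.genotypes.dosages
        complete = ~np.isnan(G).any(axis=1)
        out = np.full((self.genotypes.n_variants, 4), np.nan)
        n_used = np.full(self.genotypes.n_variants, n)
        df_resid = n - c - 1

        idx = np.flatnonzero(complete)
        if idx.size:
            Gc = G[idx]
            Gr = Gc - (H @ Gc.T).T
            gg = np.einsum("ij,ij->i", Gr, Gr)
            gy = Gr @ y_r
            ok = gg > 1e-12
            beta = np.where(ok, gy / np.maximum(gg, 1e-300), np.nan)
            rss = np.maximum(float(y_r @ y_r) - beta**2 * gg, 0.0)
            s2 = rss / df_resid
            se = np.sqrt(np.where(ok, s2 / np.maximum(gg, 1e-300), np.nan))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = beta / se
            p = 2.0 * stats.t.sf(np.abs(t), df_resid)
            out[idx, 0], out[idx, 1] = beta, se
            out[idx, 2], out[idx, 3] = t, p

        for i in np.flatnonzero(~complete):
            mask = ~np.isnan(G[i])
            if mask.sum() < max(min_lines, c + 2):
                continue
            Xi = X[mask]
            Hi = Xi @ np.linalg.solve(Xi.T @ Xi, Xi.T)
            yi = self.y[mask] - Hi @ self.y[mask]
            gi = G[i, mask] - Hi @ G[i, mask]
            out[i] = self._simple_ols(gi, yi, int(mask.sum()) - c - 1)
            n_used[i] = int(mask.sum())

        table = self.genotypes.variants.copy()
        table["n"] = n_used
        table["beta"] = out[:, 0]
        table["se"] = out[:, 1]
        table["t"] = out[:, 2]
        table["P"] = out[:, 3]
        return ScanResults(self, table)


@dataclass
class ScanResults:
    """Association scan output: per-variant effects and tests."""

    model: LineMeansScan
    table: pd.DataFrame

    def hits(self, alpha: float = 0.05, n_tests: int | None = None,
             suggestive: float | None = 1e-5) -> pd.DataFrame:
        """Variants passing the Bonferroni threshold, plus a suggestive tier.

        ``n_tests`` defaults to the number of variants actually tested.
        The returned frame has a ``tier`` column ('significant' or
        'suggestive'), sorted by P.
        """
        tested = self.table.dropna(subset=["P"])
        if n_tests is None:
            n_tests = len(tested)
        crit = bonferroni(alpha, max(n_tests, 1)) if len(tested) else 0.0
        sig = tested[tested["P"] <= crit].copy()
        sig["tier"] = "significant"
        frames = [sig]
        if suggestive is not None:
            sug = tested[
                (tested["P"] <= suggestive) & (tested["P"] > crit)
            ].copy()
            sug["tier"] = "suggestive"
            frames.append(sug)
        return pd.concat(frames).sort_values("P").reset_index(drop=True)

    def qq_points(self) -> pd.DataFrame:
        return qq_points(self.table["P"].dropna().to_numpy())

    def lambda_gc(self) -> float:
        """Genomic-control inflation factor (median chi2 ratio)."""
        p = self.table["P"].dropna().to_numpy()
        chi2 = stats.chi2.isf(p, df=1)
        return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))

    def summary(self) -> str:
        tested = self.table.dropna(subset=["P"])
        top = tested.nsmallest(1, "P")
        lines = [
            f"Line-means scan: {len(tested)} variants tested on "
            f"{len(self.model.lines)} lines",
            f"  lambda_GC = {self.lambda_gc():.3f}",
        ]
        if len(top):
            r = top.iloc[0]
            lines.append(
                f"  top hit: {r['id']} ({r['chrom']}:{r['pos']}) "
                f"beta={r['beta']:.4g} P={r['P']:.3g}"
            )
        return "\n".join(lines)
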