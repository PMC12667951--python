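"""Quantitative assessment of imputation quality.

Covers: feature-wise and sample-wise Pearson r distributions; distribution
comparisons (Mann-Whitney U, paired win-rate binomial test, Levene variance
test, Wilcoxon signed-rank); per-probe mean/variance summaries and PCA
diagnostics; phenotype-association preservation (sex/age adjustment, BH FDR
at 5%, effect-estimate concordance); and the pseudo-cohort meta-analysis
comparing 'classic' z-score combination against 'imputation-separate' and
'imputation-combined' workflows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

# --------------------------------------------------------------------------
# correlations
# --------------------------------------------------------------------------


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation; NaN when either vector is constant."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_r needs two equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _columnwise_r(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorised per-column Pearson r (NaN for constant columns)."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    denom = np.sqrt((a**2).sum(axis=0) * (b**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=0) / denom
    r[denom == 0] = np.nan
    return r


@dataclass
class CorrelationReport:
    feature_r: np.ndarray
    sample_r: np.ndarray
    n_undefined_features: int
    n_undefined_samples: int
    method: str = ""
    direction: str = ""

    @property
    def median_feature_r(self) -> float:
        return float(np.nanmedian(self.feature_r)) if np.any(~np.isnan(self.feature_r)) else np.nan

    @property
    def mean_feature_r(self) -> float:
        return float(np.nanmean(self.feature_r)) if np.any(~np.isnan(self.feature_r)) else np.nan

    @property
    def median_sample_r(self) -> float:
        return float(np.nanmedian(self.sample_r)) if np.any(~np.isnan(self.sample_r)) else np.nan

    @property
    def mean_sample_r(self) -> float:
        return float(np.nanmean(self.sample_r)) if np.any(~np.isnan(self.sample_r)) else np.nan


def correlation_report(
    imputed: np.ndarray, truth: np.ndarray, method: str = "", direction: str = ""
) -> CorrelationReport:
    """Per-probe r (across samples) and per-sample r (across probes).

    Undefined correlations (constant vectors) are excluded from the
    distributions and counted, not set to zero.
    """
    imputed = np.asarray(imputed, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if imputed.shape != truth.shape:
        raise ValueError("imputed and truth must have identical shapes")
    feat = _columnwise_r(imputed, truth)
    samp = _columnwise_r(imputed.T, truth.T)
    return CorrelationReport(
        feature_r=feat,
        sample_r=samp,
        n_undefined_features=int(np.isnan(feat).sum()),
        n_undefined_samples=int(np.isnan(samp).sum()),
        method=method,
        direction=direction,
    )


def distribution_tests(r1: np.ndarray, r2: np.ndarray, paired: bool = True) -> dict:
    """Compare two r distributions (e.g. two methods on the same probes).

    Returns Mann-Whitney U, Levene, and for paired inputs the per-item
    win-rate with a two-tailed binomial test plus a Wilcoxon signed-rank
    test.
    """
    r1 = np.asarray(r1, dtype=np.float64)
    r2 = np.asarray(r2, dtype=np.float64)
    r1c, r2c = r1[~np.isnan(r1)], r2[~np.isnan(r2)]
    mwu = stats.mannwhitneyu(r1c, r2c, alternative="two-sided")
    lev = stats.levene(r1c, r2c)
    out = {
        "mannwhitney_u": float(mwu.statistic),
        "mannwhitney_p": float(mwu.pvalue),
        "levene_stat": float(lev.statistic),
        "levene_p": float(lev.pvalue),
    }
    if paired and r1.size == r2.size:
        ok = ~np.isnan(r1) & ~np.isnan(r2)
        diff = r1[ok] - r2[ok]
        wins = int((diff > 0).sum())
        ties = int((diff == 0).sum())
        n_eff = int(ok.sum()) - ties
        if n_eff > 0:
            out["win_rate"] = wins / n_eff
            out["binomial_p"] = float(stats.binomtest(wins, n_eff, 0.5).pvalue)
        if np.any(diff != 0):
            w = stats.wilcoxon(r1[ok], r2[ok])
            out["wilcoxon_stat"] = float(w.statistic)
            out["wilcoxon_p"] = float(w.pvalue)
    return out


def mean_variance_summary(x: np.ndarray, probes: Optional[Sequence[str]] = None) -> pd.DataFrame:
    x = np.asarray(x, dtype=np.float64)
    idx = list(probes) if probes is not None else list(range(x.shape[1]))
    return pd.DataFrame({"mean": x.mean(axis=0), "variance": x.var(axis=0, ddof=1)}, index=idx)


def pca_diagnostics(
    truth: np.ndarray,
    imputed: dict[str, np.ndarray],
    axis: str = "features",
    n_components: int = 2,
    k_clusters: int = 6,
    seed: int = 0,
) -> dict:
    """PCA fit on the measured data only; imputed matrices are projected
    onto the measured PCs. k-means (seeded) on the measured points supplies
    cluster colours for plotting. ``axis='features'`` treats probes as
    points (samples as variables); ``axis='samples'`` the reverse.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    def as_points(m: np.ndarray) -> np.ndarray:
        m = np.asarray(m, dtype=np.float64)
        return m.T if axis == "features" else m

    if axis not in ("features", "samples"):
        raise ValueError("axis must be 'features' or 'samples'")
    pts_truth = as_points(truth)
    pca = PCA(n_components=n_components, svd_solver="full").fit(pts_truth)
    proj = {"truth": pca.transform(pts_truth)}
    for name, m in imputed.items():
        proj[name] = pca.transform(as_points(m))
    km = KMeans(n_clusters=k_clusters, random_state=seed, n_init=10).fit(pts_truth)
    return {
        "projections": proj,
        "clusters": km.labels_,
        "explained_variance_ratio": pca.explained_variance_ratio_,
    }


# --------------------------------------------------------------------------
# phenotype associations
# --------------------------------------------------------------------------


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=np.float64)
    ok = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _continuous_assoc(x: np.ndarray, y: np.ndarray, covariates: np.ndarray) -> pd.DataFrame:
    """Residualise the phenotype on [1, covariates], then per-probe simple
    regression of the residual on each standardized protein (vectorised OLS)."""
    n, d = x.shape
    c = np.column_stack([np.ones(n), covariates])
    beta_cov, *_ = np.linalg.lstsq(c, y, rcond=None)
    resid = y - c @ beta_cov
    xc = x - x.mean(axis=0)
    yc = resid - resid.mean()
    sxx = (xc**2).sum(axis=0)
    beta = (xc * yc[:, None]).sum(axis=0) / np.where(sxx > 0, sxx, np.nan)
    fitted = xc * beta
    rss = ((yc[:, None] - fitted) ** 2).sum(axis=0)
    dof = n - 2
    se = np.sqrt(rss / dof / np.where(sxx > 0, sxx, np.nan))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    return pd.DataFrame({"beta": beta, "se": se, "z": t, "p": p})


def _binary_assoc(x: np.ndarray, y: np.ndarray, covariates: np.ndarray) -> pd.DataFrame:
    """Per-probe logistic regression of the binary phenotype on the protein
    with sex/age covariates; the reported effect is the protein log-odds."""
    import statsmodels.api as sm

    n, d = x.shape
    rows = []
    base = np.column_stack([np.ones(n), covariates])
    for j in range(d):
        design = np.column_stack([base[:, :1], x[:, j], base[:, 1:]])
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=100)
            rows.append((fit.params[1], fit.bse[1], fit.tvalues[1], fit.pvalues[1]))
        except Exception:
            rows.append((np.nan, np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["beta", "se", "z", "p"])


def phenotype_associations(
    x: np.ndarray,
    probes: Sequence[str],
    phenotypes: pd.DataFrame,
    types: dict[str, str],
    covariate_cols: Sequence[str] = ("sex", "age"),
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per (probe, phenotype) association tests with sex/age adjustment.

    Continuous phenotypes are residualised on sex+age before a per-protein
    linear fit; binary phenotypes keep sex+age as covariates in a logistic
    model. q-values are BH-adjusted within each phenotype across probes.
    Returns a tidy frame with columns probe, phenotype, beta, se, z, p, q,
    significant.
    """
    x = np.asarray(x, dtype=np.float64)
    covariates = phenotypes[list(covariate_cols)].to_numpy(dtype=np.float64)
    frames = []
    for name, kind in types.items():
        y = phenotypes[name].to_numpy(dtype=np.float64)
        if kind == "continuous":
            if len(np.unique(y)) < 3:
                raise ValueError(f"phenotype {name!r} has <3 distinct values; not continuous")
            res = _continuous_assoc(x, y, covariates)
        elif kind == "binary":
            res = _binary_assoc(x, y, covariates)
        else:
            raise ValueError(f"unknown phenotype type {kind!r} for {name!r}")
        res.insert(0, "probe", list(probes))
        res.insert(1, "phenotype", name)
        res["q"] = bh_adjust(res["p"].to_numpy())
        res["significant"] = res["q"] <= fdr
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def association_concordance(truth: pd.DataFrame, imputed: pd.DataFrame) -> dict:
    """Concordance of effect estimates and recovery of significant hits.

    MAE and Pearson r of coefficients are computed over truth-significant
    (probe, phenotype) pairs; recovery = |truth-sig AND imputed-sig| /
    |truth-sig|, overall and per phenotype.
    """
    merged = truth.merge(
        imputed, on=["probe", "phenotype"], suffixes=("_truth", "_imp"), how="inner"
    )
    sig = merged[merged["significant_truth"]]
    out: dict = {"n_truth_significant": int(len(sig))}
    if len(sig):
        diff = (sig["beta_truth"] - sig["beta_imp"]).abs()
        out["coef_mae"] = float(diff.mean())
        if len(sig) >= 3 and sig["beta_truth"].std() > 0 and sig["beta_imp"].std() > 0:
            out["coef_r"] = pearson_r(sig["beta_truth"].to_numpy(), sig["beta_imp"].to_numpy())
        out["recovery"] = float((sig["significant_truth"] & sig["significant_imp"]).sum() / len(sig))
        per = (
            sig.groupby("phenotype")
            .apply(lambda g: (g["significant_imp"]).mean(), include_groups=False)
            .to_dict()
        )
        out["recovery_by_phenotype"] = per
        out["truth_hits_by_phenotype"] = sig.groupby("phenotype").size().to_dict()
    return out


# --------------------------------------------------------------------------
# meta-analysis
# --------------------------------------------------------------------------


def stouffer_z(z1: np.ndarray, z2: np.ndarray, w1: float = 1.0, w2: float = 1.0) -> np.ndarray:
    """Stouffer combination (w1*z1 + w2*z2) / sqrt(w1^2 + w2^2); default
    unweighted (equal pseudo-cohort sizes)."""
    return (w1 * np.asarray(z1) + w2 * np.asarray(z2)) / np.sqrt(w1**2 + w2**2)


@dataclass
class MetaResult:
    workflow: str
    replicate: int
    recovery_by_phenotype: dict[str, float]
    truth_hits_by_phenotype: dict[str, int]

    @property
    def mean_recovery(self) -> float:
        vals = list(self.recovery_by_phenotype.values())
        return float(np.mean(vals)) if vals else np.nan

    def mean_recovery_min_hits(self, min_hits: int) -> float:
        vals = [
            v
            for k, v in self.recovery_by_phenotype.items()
            if self.truth_hits_by_phenotype.get(k, 0) >= min_hits
        ]
        return float(np.mean(vals)) if vals else np.nan


def _sig_sets(assoc: pd.DataFrame) -> dict[str, set]:
    return {
        ph: set(g.loc[g["significant"], "probe"])
        for ph, g in assoc.groupby("phenotype")
    }


def _assoc_from_z(probes, phenotype_names, z_by_pheno, fdr) -> pd.DataFrame:
    frames = []
    for ph in phenotype_names:
        z = z_by_pheno[ph]
        p = 2 * stats.norm.sf(np.abs(z))
        q = bh_adjust(p)
        frames.append(
            pd.DataFrame(
                {"probe": probes, "phenotype": ph, "z": z, "p": p, "q": q, "significant": q <= fdr}
            )
        )
    return pd.concat(frames, ignore_index=True)


def meta_analysis(
    x_source: np.ndarray,
    x_target: np.ndarray,
    source_probes: Sequence[str],
    target_probes: Sequence[str],
    probe_map: Sequence[tuple[str, str]],
    phenotypes: pd.DataFrame,
    types: dict[str, str],
    imputer: Callable[[np.ndarray], np.ndarray],
    n_replicates: int = 20,
    seed: int = 0,
    fdr: float = 0.05,
) -> list[MetaResult]:
    """Pseudo-cohort meta-analysis over repeated random half-splits.

    Samples are split into two pseudo-cohorts: cohort 1 keeps native
    target-platform data, cohort 2 only source-platform data. Per replicate:

    * ``classic``              — per-cohort tests on the probes shared across
      platforms (cohort 2 uses its native source measurements for the mapped
      probes), combined by unweighted Stouffer z;
    * ``imputation_separate``  — cohort 2 is imputed into the target
      platform, tested separately, then z-combined with cohort 1;
    * ``imputation_combined``  — imputed cohort 2 is concatenated with
      cohort 1 into one table and tested once.

    Truth = associations on the full native target data. Recovery rates are
    per phenotype at the given FDR, stratified by truth-hit counts.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    x_source = np.asarray(x_source, dtype=np.float64)
    x_target = np.asarray(x_target, dtype=np.float64)
    n = x_source.shape[0]
    src_pos = {p: i for i, p in enumerate(source_probes)}
    tgt_pos = {p: i for i, p in enumerate(target_probes)}
    shared_src_idx = np.array([src_pos[a] for a, b in probe_map], dtype=np.intp)
    shared_tgt_idx = np.array([tgt_pos[b] for a, b in probe_map], dtype=np.intp)
    shared_tgt_names = [b for a, b in probe_map]

    truth_assoc = phenotype_associations(x_target, target_probes, phenotypes, types, fdr=fdr)
    truth_sig = _sig_sets(truth_assoc)
    truth_hits = {ph: len(s) for ph, s in truth_sig.items()}
    pheno_names = list(types)

    def z_table(x, probes, pheno_rows) -> dict[str, np.ndarray]:
        assoc = phenotype_associations(x, probes, pheno_rows, types, fdr=fdr)
        return {ph: g["z"].to_numpy() for ph, g in assoc.groupby("phenotype", sort=False)}, assoc

    rng = np.random.default_rng(seed)
    results: list[MetaResult] = []
    for rep in range(n_replicates):
        perm = rng.permutation(n)
        half = n // 2
        c1, c2 = perm[:half], perm[half:]
        ph1, ph2 = phenotypes.iloc[c1], phenotypes.iloc[c2]
        imputed2 = imputer(x_source[c2])

        # classic: shared probes only, native data in each cohort
        z1, _ = z_table(x_target[c1][:, shared_tgt_idx], shared_tgt_names, ph1)
        z2, _ = z_table(x_source[c2][:, shared_src_idx], shared_tgt_names, ph2)
        z_classic = {ph: stouffer_z(z1[ph], z2[ph]) for ph in pheno_names}
        classic = _assoc_from_z(shared_tgt_names, pheno_names, z_classic, fdr)

        # imputation-separate: all target probes
        z1f, _ = z_table(x_target[c1], target_probes, ph1)
        z2i, _ = z_table(imputed2, target_probes, ph2)
        z_sep = {ph: stouffer_z(z1f[ph], z2i[ph]) for ph in pheno_names}
        separate = _assoc_from_z(list(target_probes), pheno_names, z_sep, fdr)

        # imputation-combined: one harmonised table
        x_comb = np.vstack([x_target[c1], imputed2])
        ph_comb = pd.concat([ph1, ph2], ignore_index=True)
        combined = phenotype_associations(x_comb, target_probes, ph_comb, types, fdr=fdr)

        for name, assoc in (
            ("classic", classic),
            ("imputation_separate", separate),
            ("imputation_combined", combined),
        ):
            sig = _sig_sets(assoc)
            recovery = {
                ph: (len(sig.get(ph, set()) & truth_sig[ph]) / truth_hits[ph])
                for ph in pheno_names
                if truth_hits.get(ph, 0) > 0
            }
            results.append(
                MetaResult(
                    workflow=name,
                    replicate=rep,
                    recovery_by_phenotype=recovery,
                    truth_hits_by_phenotype=truth_hits,
                )
            )
    return results


def summarize_meta(results: list[MetaResult], min_hits: int = 0) -> pd.DataFrame:
    """Mean and SD of recovery per workflow across replicates."""
    rows = []
    for wf in sorted({r.workflow for r in results}):
        vals = [r.mean_recovery_min_hits(min_hits) for r in results if r.workflow == wf]
        vals = [v for v in vals if not np.isnan(v)]
        rows.append({"workflow": wf, "mean_recovery": np.mean(vals), "sd_recovery": np.std(vals)})
    return pd.DataFrame(rows)
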