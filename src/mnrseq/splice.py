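"""Splice-variant diversity: detected-isoform counts, Poisson regression,
inverse-variance meta-analysis, and the global distribution-shift test.

For every gene and sample the statistic is the number of distinct
transcripts of the gene with at least ``presence_threshold`` reads —
computed on the *unfiltered* transcript matrix so low-abundance isoforms,
the plausible carriers of a diversity change, are not pre-removed.  At
each gestational day a log-link Poisson regression models that count on
group (MNR vs CON) adjusting for sex; the 120/140 dG estimates are then
combined per gene by fixed-effect inverse-variance meta-analysis.  A
positive shift of the meta Z distribution indicates globally increased
isoform diversity in the MNR group, summarised by the mean, the moment
skewness, and a one-sample t-test of the mean against zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    ConfigError,
    PipelineConfig,
    StudyDesign,
    TranscriptCountMatrix,
)
from .de import bh_fdr

logger = logging.getLogger("mnrseq")

#: |beta| above which a Poisson fit is treated as separated/unbounded.
_BETA_BOUND = 20.0


@dataclass
class SpliceCountMatrix:
    """Gene x sample detected-isoform counts."""

    gene_symbols: list[str]
    sample_ids: list[str]
    iso_counts: np.ndarray  # nonnegative integers


def count_expressed_isoforms(
    matrix: TranscriptCountMatrix, presence_threshold: int = 1
) -> SpliceCountMatrix:
    """Number of isoforms of each gene with >= threshold reads per sample."""
    if presence_threshold < 1:
        raise ValueError("presence_threshold must be >= 1")
    present = (matrix.counts >= presence_threshold).astype(np.int64)
    df = pd.DataFrame(present, index=matrix.gene_symbols)
    grouped = df.groupby(level=0, sort=True).sum()
    return SpliceCountMatrix(
        gene_symbols=[str(g) for g in grouped.index],
        sample_ids=list(matrix.sample_ids),
        iso_counts=grouped.to_numpy(),
    )


# ---------------------------------------------------------------------------
# Poisson regression (vectorised IRLS across genes)

def poisson_irls(
    Y: np.ndarray, X: np.ndarray, tol: float = 1e-8, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit log-link Poisson GLMs for many response vectors sharing one
    design matrix, by iteratively reweighted least squares.

    Parameters
    ----------
    Y : (G, n) nonnegative counts, one row per gene.
    X : (n, p) design matrix.

    Returns
    -------
    beta : (G, p) coefficients; se : (G, p) Wald standard errors from the
    inverse Fisher information; converged : (G,) boolean.  Unbounded fits
    (e.g. a group with all-zero counts) are reported non-converged.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    G, n = Y.shape
    p = X.shape[1]
    # standard GLM starting values: mu halfway between y and its mean
    mu = (Y + Y.mean(axis=1, keepdims=True)) / 2.0 + 0.1
    eta = np.log(mu)
    beta = np.zeros((G, p))
    converged = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)
    se = np.full((G, p), np.nan)
    A_last = np.zeros((G, p, p))
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        mu_a = np.exp(np.clip(eta[idx], -30.0, 30.0))
        z = eta[idx] + (Y[idx] - mu_a) / mu_a
        A = np.einsum("gn,np,nq->gpq", mu_a, X, X)
        rhs = np.einsum("gn,np->gp", mu_a * z, X)
        try:
            new_beta = np.linalg.solve(A, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            new_beta = np.full((idx.size, p), np.nan)
            for k in range(idx.size):
                try:
                    new_beta[k] = np.linalg.solve(A[k], rhs[k])
                except np.linalg.LinAlgError:
                    pass
        A_last[idx] = A
        step = np.abs(new_beta - beta[idx]).max(axis=1)
        bad = ~np.isfinite(new_beta).all(axis=1)
        beta[idx] = np.where(np.isfinite(new_beta), new_beta, beta[idx])
        eta[idx] = beta[idx] @ X.T
        done = (step < tol) & ~bad
        converged[idx[done]] = True
        active[idx[done | bad]] = False
    # Wald SEs from the Fisher information evaluated at the final estimates
    fit_idx = np.flatnonzero(converged)
    if fit_idx.size:
        mu_f = np.exp(np.clip(eta[fit_idx], -30.0, 30.0))
        A_last[fit_idx] = np.einsum("gn,np,nq->gpq", mu_f, X, X)
        try:
            cov = np.linalg.inv(A_last[fit_idx])
            se[fit_idx] = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))
        except np.linalg.LinAlgError:
            for k in fit_idx:
                try:
                    se[k] = np.sqrt(np.diag(np.linalg.inv(A_last[k])))
                except np.linalg.LinAlgError:
                    converged[k] = False
    # unbounded estimates are not valid Wald fits
    unbounded = np.abs(beta).max(axis=1) > _BETA_BOUND
    converged &= ~unbounded
    converged &= np.isfinite(se).all(axis=1) & (se > 0).all(axis=1)
    return beta, se, converged


def poisson_glm(
    counts: np.ndarray, group: np.ndarray, sex: np.ndarray | None = None
) -> tuple[float, float, bool]:
    """Single-gene convenience wrapper: returns (beta_MNR, SE, converged).

    ``group`` and ``sex`` are 0/1 vectors (MNR=1, M=1); ``sex`` may be
    omitted or constant, in which case only intercept + group are fitted.
    """
    counts = np.asarray(counts, dtype=float)
    cols = [np.ones_like(counts), np.asarray(group, dtype=float)]
    if sex is not None:
        sex = np.asarray(sex, dtype=float)
        if np.ptp(sex) > 0:
            cols.append(sex)
    X = np.column_stack(cols)
    if np.ptp(cols[1]) == 0:
        raise ValueError("both groups must be present")
    beta, se, conv = poisson_irls(counts[None, :], X)
    return float(beta[0, 1]), float(se[0, 1]), bool(conv[0])


# ---------------------------------------------------------------------------
# meta-analysis and global shift

def inverse_variance_meta(effects) -> tuple[float, float, float, float]:
    """Fixed-effect inverse-variance combination of (beta, SE) pairs.

    Returns (combined beta, combined SE, Z, two-sided normal p).
    """
    effects = list(effects)
    if not effects:
        raise ValueError("no effects to combine")
    betas = np.array([e[0] for e in effects], dtype=float)
    ses = np.array([e[1] for e in effects], dtype=float)
    if not np.all(np.isfinite(ses)) or (ses <= 0).any():
        raise ValueError("SEs must be finite and positive")
    w = ses ** -2
    beta_hat = float((w * betas).sum() / w.sum())
    se_hat = float(w.sum() ** -0.5)
    z = beta_hat / se_hat
    p = 2.0 * stats.norm.sf(abs(z))
    return beta_hat, se_hat, float(z), float(p)


def global_shift_test(zscores) -> dict[str, float]:
    """Location and asymmetry of a Z-score distribution.

    Returns the mean, the moment skewness g1 = m3 / m2^(3/2), and the
    two-sided one-sample t statistic and p-value for mean zero.
    """
    z = np.asarray(zscores, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < 3:
        raise ValueError("need >= 3 finite Z-scores")
    if np.ptp(z) == 0:
        raise ValueError("zero variance in Z-scores")
    t_stat, p = stats.ttest_1samp(z, 0.0)
    return {
        "n": int(z.size),
        "mean": float(z.mean()),
        "skewness": float(stats.skew(z, bias=True)),
        "t": float(t_stat),
        "p": float(p),
    }


# ---------------------------------------------------------------------------
# pipeline facade

class SpliceDiversity:
    """Per-gene isoform-diversity model across gestational timepoints.

    ``fit()`` runs the per-timepoint Poisson regressions for every
    gestational day in the design, the fixed-effect meta-analysis across
    ``config.meta_timepoints``, and the global shift test on the meta
    Z-scores.
    """

    def __init__(self, counts: TranscriptCountMatrix, design: StudyDesign,
                 config: PipelineConfig | None = None):
        if counts.sample_ids != list(design.sample_ids):
            raise ConfigError("count matrix and design describe different samples")
        self.counts = counts
        self.design = design
        self.config = config or PipelineConfig()

    def fit(self) -> "SpliceResults":
        cfg = self.config
        missing = [d for d in cfg.meta_timepoints if d not in self.design.timepoints]
        if missing:
            raise ConfigError(f"meta timepoints absent from design: {missing}")
        iso = count_expressed_isoforms(self.counts, cfg.presence_threshold)
        genes = iso.gene_symbols
        per_tp: dict[int, pd.DataFrame] = {}
        for day in self.design.timepoints:
            mask = self.design.timepoint_mask(day)
            grp = (self.design.group[mask] == "MNR").astype(float)
            sex = (self.design.sex[mask] == "M").astype(float)
            if np.ptp(grp) == 0:
                logger.warning("splice: timepoint %d has a single group; skipped", day)
                continue
            cols = [np.ones(mask.sum()), grp]
            if np.ptp(sex) > 0:
                cols.append(sex)
            X = np.column_stack(cols)
            beta, se, conv = poisson_irls(iso.iso_counts[:, mask], X)
            p = np.where(conv, 2.0 * stats.norm.sf(np.abs(beta[:, 1] / se[:, 1])), np.nan)
            tab = pd.DataFrame(
                {
                    "gene_symbol": genes,
                    "gestational_day": day,
                    "beta_MNR": beta[:, 1],
                    "se": se[:, 1],
                    "converged": conv,
                    "p": p,
                }
            )
            fdr = np.full(len(tab), np.nan)
            ok = conv & np.isfinite(p)
            if ok.any():
                fdr[ok] = bh_fdr(p[ok])
            tab["fdr"] = fdr
            per_tp[day] = tab
            logger.info("splice: %d dG, %d/%d genes converged", day, conv.sum(), len(genes))
        meta = self._meta(per_tp, genes)
        return SpliceResults(model=self, iso=iso, per_timepoint=per_tp, meta=meta)

    def _meta(self, per_tp: dict[int, pd.DataFrame], genes: list[str]) -> pd.DataFrame:
        cfg = self.config
        days = [d for d in cfg.meta_timepoints if d in per_tp]
        n = len(genes)
        betas = np.full((len(days), n), np.nan)
        ses = np.full((len(days), n), np.nan)
        for k, day in enumerate(days):
            t = per_tp[day]
            usable = t["converged"].to_numpy() & np.isfinite(t["se"].to_numpy()) \
                & (t["se"].to_numpy() > 0)
            betas[k, usable] = t["beta_MNR"].to_numpy()[usable]
            ses[k, usable] = t["se"].to_numpy()[usable]
        w = np.where(np.isfinite(ses), ses ** -2, 0.0)
        n_used = (w > 0).sum(axis=0)
        wsum = w.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            beta_hat = np.where(n_used > 0,
                                np.nansum(np.where(w > 0, w * betas, 0.0), axis=0) / wsum,
                                np.nan)
            se_hat = np.where(n_used > 0, wsum ** -0.5, np.nan)
            z = beta_hat / se_hat
        p = np.where(np.isfinite(z), 2.0 * stats.norm.sf(np.abs(z)), np.nan)
        meta = pd.DataFrame(
            {
                "gene_symbol": genes,
                "n_timepoints": n_used,
                "beta": beta_hat,
                "se": se_hat,
                "z": z,
                "p": p,
                "excluded_reason": np.where(n_used > 0, "", "no converged timepoint fit"),
            }
        )
        fdr = np.full(len(meta), np.nan)
        ok = meta["p"].notna().to_numpy()
        if ok.any():
            fdr[ok] = bh_fdr(meta.loc[ok, "p"].to_numpy())
        meta["fdr"] = fdr
        return meta


class SpliceResults:
    """Per-timepoint, meta-analytic and global splice-diversity results."""

    def __init__(self, model, iso, per_timepoint, meta):
        self.model = model
        self.iso = iso
        self.per_timepoint = per_timepoint
        self.meta = meta

    @property
    def meta_z(self) -> np.ndarray:
        z = self.meta["z"].to_numpy(dtype=float)
        return z[np.isfinite(z)]

    def global_shift(self) -> dict[str, dict[str, float]]:
        """Shift summary on all meta Z-scores and on the p<0.05 subset."""
        out = {"all": global_shift_test(self.meta_z)}
        sub = self.meta[self.meta["p"] < 0.05]["z"].to_numpy(dtype=float)
        sub = sub[np.isfinite(sub)]
        if sub.size >= 3 and np.ptp(sub) > 0:
            out["p_lt_0.05"] = global_shift_test(sub)
        return out

    def significant_per_timepoint(self) -> dict[int, pd.DataFrame]:
        cfg = self.model.config
        return {
            d: t[t["fdr"] < cfg.fdr_timepoint].reset_index(drop=True)
            for d, t in self.per_timepoint.items()
        }

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Splice-variant diversity summary",
            f"  genes: {len(self.iso.gene_symbols)}; "
            f"meta timepoints: {list(cfg.meta_timepoints)}",
        ]
        for d, t in self.significant_per_timepoint().items():
            lines.append(f"  {d} dG: {len(t)} genes at FDR<{cfg.fdr_timepoint}")
        n_meta = int((self.meta["fdr"] < cfg.fdr_timepoint).sum())
        lines.append(f"  meta: {n_meta} genes at FDR<{cfg.fdr_timepoint}")
        g = self.global_shift()["all"]
        lines.append(
            f"  global shift: mean Z = {g['mean']:.3f}, skewness = {g['skewness']:.2f}, "
            f"t-test p = {g['p']:.3g} (n={g['n']})"
        )
        return "\n".join(lines)

    def plot_z_histogram(self, ax=None):
        """Histogram of meta Z-scores (all genes and the p<0.05 subset)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.meta_z, bins=40, alpha=0.6, label="all genes")
        sub = self.meta[self.meta["p"] < 0.05]["z"].dropna()
        if len(sub):
            ax.hist(sub, bins=40, alpha=0.6, label="p < 0.05")
        ax.axvline(0, color="k", lw=1)
        ax.set_xlabel("meta-analysis Z")
        ax.set_ylabel("genes")
        ax.legend()
        return ax

    def to_tsv(self, out_prefix: str, seed: int | None = None) -> list[str]:
        from .io import write_result_table

        written = []
        for d, tab in self.per_timepoint.items():
            path = f"{out_prefix}_tp{d}.tsv"
            write_result_table(tab, path, self.model.config, seed)
            written.append(path)
        path = f"{out_prefix}_meta.tsv"
        write_result_table(self.meta, path, self.model.config, seed)
        written.append(path)
        rows = []
        for panel, g in self.global_shift().items():
            rows.append({"panel": panel, **g})
        path = f"{out_prefix}_global.tsv"
        write_result_table(pd.DataFrame(rows), path, self.model.config, seed)
        written.append(path)
        return written
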