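"""Differential expression of gestational trajectories.

The model is a weighted linear model per transcript on log2
counts-per-million with observation-level precision weights estimated from
the mean–variance trend (the voom approach), followed by empirical-Bayes
moderation of the residual variances.  Three contrasts are tested for each
transcript: the group main effect (MNR), the linear group-by-time
interaction (MNR x t), and the quadratic interaction (MNR x t^2), which
captures expression differences that peak mid-gestation and vanish at the
design endpoints.  Each contrast is corrected with a Benjamini–Hochberg
FDR separately, transcripts are deduplicated to one per gene symbol, and
candidate sets are selected by FDR and unadjusted-p thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    CONTRAST_COLUMNS,
    DesignError,
    PipelineConfig,
    StudyDesign,
    TranscriptCountMatrix,
)

logger = logging.getLogger("mnrseq")


# ---------------------------------------------------------------------------
# filtering and weighting

def filter_low_counts(
    matrix: TranscriptCountMatrix, min_max_count: int = 15
) -> TranscriptCountMatrix:
    """Drop transcripts whose maximum count across samples is below
    ``min_max_count`` (keep max >= threshold).  Low-count transcripts
    destabilise the mean–variance trend the weights are built from."""
    if min_max_count < 1:
        raise ValueError("min_max_count must be >= 1")
    keep = matrix.counts.max(axis=1) >= min_max_count
    n_removed = int((~keep).sum())
    logger.info(
        "filter_low_counts: removed %d of %d transcripts (max count < %d)",
        n_removed, matrix.n_transcripts, min_max_count,
    )
    if not keep.any():
        logger.warning("filter_low_counts: no transcripts retained")
        return matrix.subset_transcripts(keep)
    return matrix.subset_transcripts(keep)


@dataclass
class WeightedExpression:
    """Log2-CPM expression with per-observation precision weights."""

    logcpm: np.ndarray            # transcripts x samples
    weights: np.ndarray           # same shape, strictly positive
    lib_sizes: np.ndarray         # per sample
    trend_x: np.ndarray = field(repr=False, default=None)  # mean log2 count
    trend_y: np.ndarray = field(repr=False, default=None)  # sqrt residual sd

    def plot_trend(self, ax=None):
        """Mean–variance trend diagnostic (sqrt residual sd vs mean log2 count)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.trend_x, self.trend_y, "r-", lw=2)
        ax.set_xlabel("mean log2 count")
        ax.set_ylabel("sqrt(residual sd)")
        ax.set_title("mean-variance trend")
        return ax


def _log2_cpm(counts: np.ndarray, lib_sizes: np.ndarray) -> np.ndarray:
    return np.log2((counts + 0.5) / (lib_sizes + 1.0)[None, :] * 1e6)


def voom_weights(
    matrix: TranscriptCountMatrix,
    design: StudyDesign,
    lowess_frac: float = 0.5,
) -> WeightedExpression:
    """Observation-level precision weights from the mean–variance trend.

    Per transcript an unweighted least-squares fit of log2-CPM on the model
    matrix yields a residual standard deviation; a lowess curve of
    sqrt(sd) against mean log2 count is interpolated at each observation's
    fitted log2 count and the weight is the curve value to the power -4
    (inverse predicted variance of the log-count observation).
    """
    X = design.model_matrix
    n, p = X.shape
    if matrix.n_samples != n:
        raise DesignError("design rows do not match matrix columns")
    if n - p < 2:
        raise DesignError(f"need >= 2 residual df, have {n - p}")
    lib_sizes = matrix.counts.sum(axis=0).astype(float)
    y = _log2_cpm(matrix.counts.astype(float), lib_sizes)

    # per-transcript OLS via one shared pseudoinverse
    pinv = np.linalg.pinv(X)
    beta = y @ pinv.T
    fitted = beta @ X.T
    resid = y - fitted
    sigma = np.sqrt((resid ** 2).sum(axis=1) / (n - p))

    mean_log_count = y.mean(axis=1) + np.mean(np.log2(lib_sizes + 1.0)) - np.log2(1e6)
    sqrt_sd = np.sqrt(sigma)

    fit = lowess(sqrt_sd, mean_log_count, frac=lowess_frac, return_sorted=True)
    tx, ty = fit[:, 0], fit[:, 1]
    tx, uniq = np.unique(tx, return_index=True)
    ty = ty[uniq]
    if tx.size < 2:  # degenerate trend (all means equal): flat curve
        tx = np.array([mean_log_count.min() - 1, mean_log_count.max() + 1])
        ty = np.array([sqrt_sd.mean(), sqrt_sd.mean()])

    fitted_log_count = fitted + (np.log2(lib_sizes + 1.0) - np.log2(1e6))[None, :]
    curve = np.interp(fitted_log_count, tx, ty)  # clips to trend range at extremes
    curve = np.maximum(curve, 1e-6)
    w = curve ** -4
    logger.info("voom_weights: %d transcripts, weight range [%.3g, %.3g]",
                matrix.n_transcripts, w.min(), w.max())
    return WeightedExpression(logcpm=y, weights=w, lib_sizes=lib_sizes,
                              trend_x=tx, trend_y=ty)


# ---------------------------------------------------------------------------
# weighted least squares and moderation

@dataclass
class LinearFits:
    """Per-transcript weighted least-squares results."""

    beta: np.ndarray              # transcripts x p
    sigma2: np.ndarray            # residual variance, weighted RSS / (n - p)
    df_residual: float
    stdev_unscaled: np.ndarray    # sqrt diag (X' W X)^-1, transcripts x p
    ok: np.ndarray                # finite, non-singular fits


def fit_weighted_lm(expr: WeightedExpression, design: StudyDesign) -> LinearFits:
    """Weighted least squares per transcript: beta = (X'WX)^-1 X'Wy."""
    X = design.model_matrix
    n, p = X.shape
    y = expr.logcpm
    w = expr.weights
    if y.shape[1] != n:
        raise DesignError("expression columns do not match design rows")
    if not np.all(np.isfinite(w)) or (w <= 0).any():
        raise ValueError("weights must be strictly positive and finite")

    Xw = w[:, :, None] * X[None, :, :]              # t x n x p
    A = np.einsum("tnp,nq->tpq", Xw, X)             # X'WX
    rhs = np.einsum("tnp,tn->tp", Xw, y)
    beta = np.empty((y.shape[0], p))
    cov = np.empty((y.shape[0], p, p))
    ok = np.ones(y.shape[0], dtype=bool)
    try:
        beta[:] = np.linalg.solve(A, rhs[..., None])[..., 0]
        cov[:] = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        for t in range(y.shape[0]):
            try:
                beta[t] = np.linalg.solve(A[t], rhs[t])
                cov[t] = np.linalg.inv(A[t])
            except np.linalg.LinAlgError:
                beta[t] = np.nan
                cov[t] = np.nan
                ok[t] = False

    resid = y - beta @ X.T
    rss = (w * resid ** 2).sum(axis=1)
    sigma2 = rss / (n - p)
    stdev_unscaled = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))
    ok &= np.isfinite(sigma2)
    return LinearFits(beta=beta, sigma2=sigma2, df_residual=float(n - p),
                      stdev_unscaled=stdev_unscaled, ok=ok)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x (Newton iteration on 1/trigamma)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif / x) < 1e-10:
            break
    return float(x)


def fit_scaled_f_prior(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match log sample variances to a scaled F distribution.

    Returns (prior df d0, prior variance s0^2); d0 is ``inf`` when the
    variances show no excess spread beyond the chi-square sampling noise.
    """
    s2 = np.asarray(sigma2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise ValueError("need >= 2 positive variances to fit the prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        df_prior = 2.0 * _trigamma_inverse(evar)
        s2_prior = np.exp(emean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0))
    else:
        df_prior = np.inf
        s2_prior = np.exp(emean)
    return float(df_prior), float(s2_prior)


@dataclass
class ModeratedStats:
    """Empirical-Bayes moderated statistics for the three contrasts."""

    df_prior: float
    s2_prior: float
    s2_post: np.ndarray                           # moderated variances
    t: dict[str, np.ndarray]                      # contrast -> moderated t
    p: dict[str, np.ndarray]
    coef: dict[str, np.ndarray]
    zero_variance_flag: np.ndarray


def ebayes_moderate(
    fits: LinearFits,
    contrasts: dict[str, int] = CONTRAST_COLUMNS,
    df_prior_override: float | None = None,
) -> ModeratedStats:
    """Shrink residual variances toward a common prior and compute
    moderated t statistics on augmented degrees of freedom.

    s2_post = (d0 s0^2 + d s^2) / (d0 + d); t = beta_c / (u_c sqrt(s2_post))
    on d0 + d df.  ``df_prior_override`` forces d0 (0 recovers the
    ordinary t).  Transcripts with exactly zero residual variance are
    assigned the smallest positive variance observed and flagged.
    """
    s2 = fits.sigma2.copy()
    finite = np.isfinite(s2)
    if finite.sum() < 10:
        raise ValueError("need >= 10 transcripts with finite residual variance")
    zero_flag = finite & (s2 <= 0)
    if zero_flag.any():
        smallest = s2[finite & (s2 > 0)].min()
        s2[zero_flag] = smallest
        logger.warning("ebayes_moderate: %d zero-variance transcripts floored", zero_flag.sum())

    d = fits.df_residual
    if df_prior_override is not None:
        d0 = float(df_prior_override)
        if d0 > 0:
            _, s02 = fit_scaled_f_prior(s2[finite], d)
        else:
            s02 = 0.0
    else:
        d0, s02 = fit_scaled_f_prior(s2[finite], d)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = 1e6  # effectively normal reference
    else:
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
        df_total = d0 + d

    t_out, p_out, c_out = {}, {}, {}
    for name, col in contrasts.items():
        u = fits.stdev_unscaled[:, col]
        tval = fits.beta[:, col] / (u * np.sqrt(s2_post))
        pval = 2.0 * stats.t.sf(np.abs(tval), df_total)
        t_out[name] = tval
        p_out[name] = pval
        c_out[name] = fits.beta[:, col]
    logger.info("ebayes_moderate: d0=%.3g s0^2=%.3g", d0, s02)
    return ModeratedStats(df_prior=d0, s2_prior=s02, s2_post=s2_post,
                          t=t_out, p=p_out, coef=c_out, zero_variance_flag=zero_flag)


# ---------------------------------------------------------------------------
# multiplicity, dedup, candidate selection

def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-value")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compute_contrasts(
    matrix: TranscriptCountMatrix, mod: ModeratedStats
) -> dict[str, pd.DataFrame]:
    """One table per contrast with coefficient, moderated t, p and BH FDR
    (FDR computed within each contrast separately)."""
    tables = {}
    for name in mod.t:
        tables[name] = pd.DataFrame(
            {
                "transcript_id": matrix.transcript_ids,
                "gene_symbol": matrix.gene_symbols,
                "contrast": name,
                "coefficient": mod.coef[name],
                "t_mod": mod.t[name],
                "p": mod.p[name],
                "fdr": bh_fdr(mod.p[name]),
            }
        )
    return tables


def dedupe_gene_symbols(table: pd.DataFrame) -> pd.DataFrame:
    """Keep one transcript per gene symbol: smallest p, ties broken by
    larger |moderated t| then lexicographic transcript_id."""
    df = table.copy()
    df["_abs_t"] = -df["t_mod"].abs()
    df = df.sort_values(["p", "_abs_t", "transcript_id"], kind="mergesort")
    df = df.drop_duplicates("gene_symbol", keep="first").drop(columns="_abs_t")
    return df.reset_index(drop=True)


def select_candidates(
    tables: dict[str, pd.DataFrame], config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Primary set (FDR < fdr_primary in any contrast) and network set
    (unadjusted p < p_network), each annotated with its qualifying contrast."""
    prim_rows, net_rows = [], []
    for name, tab in tables.items():
        hit = tab[tab["fdr"] < config.fdr_primary]
        prim_rows.append(hit.assign(criterion=f"fdr<{config.fdr_primary}"))
        hit = tab[tab["p"] < config.p_network]
        net_rows.append(hit.assign(criterion=f"p<{config.p_network}"))
    cols = ["gene_symbol", "transcript_id", "contrast", "coefficient", "t_mod", "p", "fdr", "criterion"]
    primary = (pd.concat(prim_rows)[cols] if prim_rows else pd.DataFrame(columns=cols))
    network = (pd.concat(net_rows)[cols] if net_rows else pd.DataFrame(columns=cols))
    return (primary.sort_values(["p", "gene_symbol"]).reset_index(drop=True),
            network.sort_values(["p", "gene_symbol"]).reset_index(drop=True))


# ---------------------------------------------------------------------------
# model / results facade

class DifferentialExpression:
    """Weighted linear model of transcript trajectories across gestation.

    Parameters
    ----------
    counts : TranscriptCountMatrix
        Raw (unfiltered) transcript counts.
    design : StudyDesign
        Sample covariates; rows must match the count columns.
    config : PipelineConfig, optional
        Thresholds; defaults follow the pipeline's standard settings.
    """

    def __init__(self, counts: TranscriptCountMatrix, design: StudyDesign,
                 config: PipelineConfig | None = None):
        if counts.sample_ids != list(design.sample_ids):
            raise DesignError("count matrix and design describe different samples")
        self.counts = counts
        self.design = design
        self.config = config or PipelineConfig()

    def fit(self, df_prior_override: float | None = None) -> "DEResults":
        cfg = self.config
        filtered = filter_low_counts(self.counts, cfg.min_max_count)
        if filtered.n_transcripts == 0:
            raise ValueError("no transcripts pass the count filter")
        expr = voom_weights(filtered, self.design, lowess_frac=cfg.lowess_frac)
        fits = fit_weighted_lm(expr, self.design)
        mod = ebayes_moderate(fits, df_prior_override=df_prior_override)
        tables = compute_contrasts(filtered, mod)
        return DEResults(model=self, filtered=filtered, expression=expr,
                         fits=fits, moderated=mod, tables=tables)


class DEResults:
    """Fitted differential-expression results for the three contrasts."""

    def __init__(self, model, filtered, expression, fits, moderated, tables):
        self.model = model
        self.filtered = filtered
        self.expression = expression
        self.fits = fits
        self.moderated = moderated
        self.tables = tables
        self._deduped: dict[str, pd.DataFrame] | None = None

    @property
    def contrast_names(self) -> list[str]:
        return list(self.tables)

    def deduped_tables(self) -> dict[str, pd.DataFrame]:
        """Per-contrast tables with one transcript per gene symbol
        (deduplication after FDR, preserving the adjusted values)."""
        if self._deduped is None:
            self._deduped = {k: dedupe_gene_symbols(v) for k, v in self.tables.items()}
        return self._deduped

    def candidates(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        return select_candidates(self.deduped_tables(), self.model.config)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Differential expression summary",
            f"  transcripts tested: {self.filtered.n_transcripts} "
            f"(of {self.model.counts.n_transcripts} input)",
            f"  residual df: {self.fits.df_residual:.0f}; "
            f"prior df d0={self.moderated.df_prior:.3g}, s0^2={self.moderated.s2_prior:.3g}",
        ]
        for name, tab in self.deduped_tables().items():
            n_fdr = int((tab["fdr"] < cfg.fdr_primary).sum())
            n_p = int((tab["p"] < cfg.p_network).sum())
            lines.append(
                f"  {name}: {n_fdr} genes at FDR<{cfg.fdr_primary}, "
                f"{n_p} at p<{cfg.p_network}"
            )
        return "\n".join(lines)

    def to_tsv(self, out_prefix: str, seed: int | None = None) -> list[str]:
        from .io import write_result_table

        written = []
        for name, tab in self.tables.items():
            path = f"{out_prefix}_{name}.tsv"
            write_result_table(tab, path, self.model.config, seed)
            written.append(path)
        combined = pd.concat(self.deduped_tables().values())
        primary, network = self.candidates()
        combined = combined.assign(
            primary_candidate=combined["gene_symbol"].isin(primary["gene_symbol"])
            & (combined["fdr"] < self.model.config.fdr_primary),
            network_candidate=combined["gene_symbol"].isin(network["gene_symbol"])
            & (combined["p"] < self.model.config.p_network),
        )
        path = f"{out_prefix}_deduped.tsv"
        write_result_table(combined.reset_index(drop=True), path, self.model.config, seed)
        written.append(path)
        return written
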