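"""Synthetic transcript-count generator with the study's statistical structure.

Each gene carries one *major* isoform (well expressed) and a number of
*minor* isoforms at low abundance, mirroring the real situation where most
annotated transcripts sit near the detection limit.  Counts are
negative-binomial with a shared per-gene-per-sample biological log-effect
and a log-normal library-size factor per sample.  Two kinds of signal can
be injected:

* a *quadratic group-by-time* expression effect on a fraction of major
  isoforms — the MNR group's log2 mean is shifted by an inverted parabola
  that is zero at the first and last gestational day and peaks
  mid-gestation (127.5 dG for the 90–165 dG design);
* an *isoform-diversity* effect on a fraction of genes — extra latent
  isoforms that are silent everywhere except in MNR samples at the
  affected timepoints, raising the expected number of detected isoforms
  by a factor of roughly ``exp(splice_effect)``.

Both signals are recorded in a truth table so recovery can be scored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import StudyDesign, TranscriptCountMatrix, mnr_study_design
from . import io as _io


class SimulationError(ValueError):
    """Infeasible simulation specification."""


@dataclass
class SimulationSpec:
    """Parameters of the synthetic study.

    Defaults emulate the study conditions: the 56-sample four-timepoint
    design (8 CON + 8 MNR at 90 and 165 dG, 6 + 6 at 120 and 140 dG), about
    4 isoforms per gene, mid-gestation-peaked expression effects on 5% of
    major isoforms, and a 0.5 log-rate isoform-diversity effect on 10% of
    genes at 120/140 dG.
    """

    n_genes: int = 2000
    mean_extra_isoforms: float = 3.0   # isoforms per gene = 1 + Poisson(this)
    major_log_mean: float = 5.0        # log2 abundance of the expressed isoform
    major_log_sd: float = 1.2
    minor_log_mean: float = 1.0        # log2 abundance of minor isoforms
    minor_log_sd: float = 1.8
    nb_dispersion: float = 0.3
    bio_log_sd: float = 0.7            # shared gene-by-sample log2 effect
    frac_de: float = 0.05
    de_effect: float = 1.0             # peak log2 group difference
    frac_splice: float = 0.10
    splice_effect: float = 0.5         # log increase of expected detected isoforms
    affected_timepoints: tuple[int, ...] = (120, 140)
    sex_effect: float = 0.1
    lib_size_log_sd: float = 0.1
    latent_log_mean: float = 3.0       # log2 mean of a switched-on latent isoform
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_de", "frac_splice"):
            if not 0 <= getattr(self, name) <= 1:
                raise SimulationError(f"{name} must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise SimulationError("nb_dispersion must be > 0")
        if self.splice_effect < 0:
            raise SimulationError("splice_effect must be >= 0")
        if self.n_genes < 1:
            raise SimulationError("n_genes must be >= 1")
        self.affected_timepoints = tuple(int(d) for d in self.affected_timepoints)

    def to_file(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["affected_timepoints"] = list(self.affected_timepoints)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationSpec":
        data = yaml.safe_load(Path(path).read_text())
        if "affected_timepoints" in data:
            data["affected_timepoints"] = tuple(data["affected_timepoints"])
        return cls(**data)


def quadratic_effect(days: np.ndarray, peak: float, lo: float = 90.0, hi: float = 165.0) -> np.ndarray:
    """Inverted-parabola effect: zero at ``lo`` and ``hi``, ``peak`` at the midpoint."""
    days = np.asarray(days, dtype=float)
    return peak * 4.0 * (days - lo) * (hi - days) / (hi - lo) ** 2


def nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws parameterised by mean and dispersion phi
    (var = mu + phi mu^2).  Zero-mean entries yield exact zeros."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        n = 1.0 / dispersion
        p = n / (n + mean[pos])
        out[pos] = rng.negative_binomial(n, p)
    return out


def detect_prob(mean, dispersion: float):
    """P(count >= 1) under NB(mean, dispersion) — the chance an isoform is seen."""
    mean = np.asarray(mean, dtype=float)
    n = 1.0 / dispersion
    p0 = (n / (n + mean)) ** n
    return 1.0 - p0


def simulate_counts(
    spec: SimulationSpec, design: StudyDesign | None = None
) -> tuple[TranscriptCountMatrix, StudyDesign, pd.DataFrame]:
    """Draw a synthetic dataset.

    Returns the count matrix, the design actually used, and a truth table
    with one row per transcript and one per gene (``level`` column)
    recording the injected effects.
    """
    if design is None:
        design = mnr_study_design()
    rng_master = np.random.default_rng(spec.seed)
    # independent child streams so changing one stage never reshuffles another
    r_struct, r_assign, r_counts, r_lib = rng_master.spawn(4)

    G = spec.n_genes
    n_iso = 1 + r_struct.poisson(spec.mean_extra_isoforms, size=G)
    n_samples = design.n_samples

    lo, hi = min(design.timepoints), max(design.timepoints)
    days = design.gestational_day.astype(float)
    is_mnr = (design.group == "MNR").astype(float)
    is_male = (design.sex == "M").astype(float)
    affected_mask = np.isin(design.gestational_day, spec.affected_timepoints)
    if spec.frac_splice > 0 and not affected_mask.any():
        raise SimulationError("affected_timepoints absent from the design")

    # disjoint gene sets carry the two signals, keeping them orthogonal
    perm = r_assign.permutation(G)
    n_splice = int(round(spec.frac_splice * G))
    splice_genes = np.zeros(G, dtype=bool)
    splice_genes[perm[:n_splice]] = True
    n_de = int(round(spec.frac_de * G))
    de_pool = perm[n_splice:]
    if n_de > de_pool.size:
        raise SimulationError("frac_de + frac_splice exceed the gene pool")
    de_genes = np.zeros(G, dtype=bool)
    de_genes[de_pool[:n_de]] = True

    gene_names = [f"GENE{g:05d}" for g in range(G)]
    tx_gene_idx = np.repeat(np.arange(G), n_iso)
    first_of_gene = np.r_[0, np.cumsum(n_iso)][:-1]
    is_major = np.zeros(tx_gene_idx.size, dtype=bool)
    is_major[first_of_gene] = True

    base_log2 = np.where(
        is_major,
        r_struct.normal(spec.major_log_mean, spec.major_log_sd, size=tx_gene_idx.size),
        r_struct.normal(spec.minor_log_mean, spec.minor_log_sd, size=tx_gene_idx.size),
    )

    # DE effect lives on the major (expressed) isoform of DE genes
    is_de_tx = is_major & de_genes[tx_gene_idx]

    effect_t = quadratic_effect(days, 1.0, lo, hi)  # per-sample unit parabola
    lib_factor = np.exp(r_lib.normal(0.0, spec.lib_size_log_sd, size=n_samples))
    bio = r_counts.normal(0.0, spec.bio_log_sd, size=(G, n_samples))

    log2_mu = (
        base_log2[:, None]
        + bio[tx_gene_idx, :]
        + spec.sex_effect * is_male[None, :]
        + np.where(is_de_tx[:, None],
                   spec.de_effect * effect_t[None, :] * is_mnr[None, :], 0.0)
    )
    mu = (2.0 ** log2_mu) * lib_factor[None, :]
    counts_main = nb_draw(r_counts, mu, spec.nb_dispersion)

    tx_ids, tx_genes = [], []
    for g in range(G):
        for j in range(n_iso[g]):
            tx_ids.append(f"{gene_names[g]}.T{j + 1:02d}")
            tx_genes.append(gene_names[g])

    # latent isoforms: silent except MNR samples at affected timepoints;
    # their number is sized so the expected detected-isoform count rises
    # by about exp(splice_effect)
    p_on = float(detect_prob(2.0 ** spec.latent_log_mean, spec.nb_dispersion))
    on_cols = is_mnr.astype(bool) & affected_mask
    n_latent = np.zeros(G, dtype=int)
    latent_rows, latent_ids, latent_genes = [], [], []
    for g in np.flatnonzero(splice_genes):
        tx_of_g = np.flatnonzero(tx_gene_idx == g)
        e0 = float(detect_prob(2.0 ** base_log2[tx_of_g], spec.nb_dispersion).sum())
        if spec.splice_effect == 0:
            continue
        m = max(1, int(round(e0 * np.expm1(spec.splice_effect) / p_on)))
        n_latent[g] = m
        for j in range(m):
            mean_row = np.zeros(n_samples)
            mean_row[on_cols] = (2.0 ** (spec.latent_log_mean + bio[g, on_cols])) \
                * lib_factor[on_cols]
            latent_rows.append(nb_draw(r_counts, mean_row, spec.nb_dispersion))
            latent_ids.append(f"{gene_names[g]}.L{j + 1:02d}")
            latent_genes.append(gene_names[g])

    if latent_rows:
        counts = np.vstack([counts_main, np.array(latent_rows)])
        tx_ids += latent_ids
        tx_genes += latent_genes
        is_de_all = np.r_[is_de_tx, np.zeros(len(latent_ids), dtype=bool)]
    else:
        counts = counts_main
        is_de_all = is_de_tx

    matrix = TranscriptCountMatrix(tx_ids, tx_genes, list(design.sample_ids), counts)

    truth = pd.DataFrame(
        {
            "level": ["transcript"] * len(tx_ids) + ["gene"] * G,
            "id": tx_ids + gene_names,
            "gene_symbol": tx_genes + gene_names,
            "is_de": np.r_[is_de_all, de_genes],
            "de_peak_log2": np.where(np.r_[is_de_all, de_genes], spec.de_effect, 0.0),
            "is_splice": np.r_[np.zeros(len(tx_ids), dtype=bool), splice_genes],
            "n_latent_isoforms": np.r_[np.zeros(len(tx_ids), dtype=int), n_latent],
        }
    )
    return matrix, design, truth


def write_fixture(spec: SimulationSpec, outdir: str | Path,
                  design: StudyDesign | None = None) -> dict[str, Path]:
    """Write counts/design/truth TSVs plus the simulation-spec snapshot to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, used_design, truth = simulate_counts(spec, design)
    paths = {
        "counts": outdir / "counts.tsv",
        "design": outdir / "design.tsv",
        "truth": outdir / "truth.tsv",
        "spec": outdir / "sim_spec.yaml",
    }
    _io.write_counts(matrix, paths["counts"], [f"simulated; seed {spec.seed}"])
    _io.write_design(used_design, paths["design"])
    _io._write_tsv(truth, paths["truth"], [f"simulation truth table; seed {spec.seed}"])
    spec.to_file(paths["spec"])
    return paths
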