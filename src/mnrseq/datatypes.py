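"""Core domain types shared by every analysis stage.

The pipeline operates on transcript-level RNA-seq counts from a two-group
(control vs. maternal nutrient reduction, "CON"/"MNR") longitudinal design
sampled at a handful of gestational days.  The types here hold the raw
count matrix, the per-sample covariates with the derived regression design
matrix, and the run configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

GROUPS = ("CON", "MNR")
SEXES = ("F", "M")

#: Column order of the full design matrix: intercept, sex (M=1), centered
#: time t, t^2, group (MNR=1), group*t, group*t^2.
MODEL_COLUMNS = (
    "intercept",
    "sex_M",
    "time",
    "time_sq",
    "group_MNR",
    "group_MNR_time",
    "group_MNR_time_sq",
)

#: Indices of the three primary contrasts within MODEL_COLUMNS.
CONTRAST_COLUMNS = {"MNR": 4, "MNR_x_time": 5, "MNR_x_time_sq": 6}


class FormatError(ValueError):
    """Malformed input file or in-memory container."""


class ConsistencyError(ValueError):
    """Two inputs that must describe the same samples disagree."""


class DesignError(ValueError):
    """Study design cannot support the requested model."""


class ConfigError(ValueError):
    """Invalid configuration value."""


@dataclass
class TranscriptCountMatrix:
    """Raw transcript x sample integer read counts.

    ``gene_symbols`` is aligned with ``transcript_ids`` (many transcripts
    may map to one gene symbol).
    """

    transcript_ids: list[str]
    gene_symbols: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n_t, n_s = self.counts.shape
        if len(self.transcript_ids) != n_t or len(self.gene_symbols) != n_t:
            raise FormatError("transcript annotation length does not match count rows")
        if len(self.sample_ids) != n_s:
            raise FormatError("sample id count does not match count columns")
        if len(set(self.transcript_ids)) != n_t:
            raise FormatError("duplicate transcript_id")
        if len(set(self.sample_ids)) != n_s:
            raise FormatError("duplicate sample_id")
        if n_t == 0 or n_s == 0:
            raise FormatError("empty count matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.issubdtype(self.counts.dtype, np.floating) and np.all(
                self.counts == np.floor(self.counts)
            ):
                self.counts = self.counts.astype(np.int64)
            else:
                raise FormatError("counts must be integers")
        if (self.counts < 0).any():
            raise FormatError("counts must be nonnegative")
        if any(not g for g in self.gene_symbols):
            raise FormatError("every transcript needs a non-empty gene_symbol")

    @property
    def n_transcripts(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_transcripts(self, mask: np.ndarray) -> "TranscriptCountMatrix":
        """Row-subset by boolean mask, keeping order."""
        idx = np.flatnonzero(np.asarray(mask))
        return TranscriptCountMatrix(
            transcript_ids=[self.transcript_ids[i] for i in idx],
            gene_symbols=[self.gene_symbols[i] for i in idx],
            sample_ids=list(self.sample_ids),
            counts=self.counts[idx],
        )


def _center_scale_time(days: np.ndarray) -> np.ndarray:
    """Affine map of gestational day onto [-1, 1] via the midrange.

    For the 90/120/140/165 dG design this is t = (dG - 127.5) / 37.5.
    A single-timepoint design maps to all-zero t (caught later as rank
    deficiency).
    """
    lo, hi = float(days.min()), float(days.max())
    if hi == lo:
        return np.zeros_like(days, dtype=float)
    center = (lo + hi) / 2.0
    half = (hi - lo) / 2.0
    return (days - center) / half


def build_model_matrix(design: "StudyDesign") -> np.ndarray:
    """Full-model design matrix with quadratic group-by-time interactions.

    Columns follow :data:`MODEL_COLUMNS`; sex is coded F=0/M=1 and group
    CON=0/MNR=1 (reference levels female control).  Raises
    :class:`DesignError` naming the collinear columns when the matrix is
    rank deficient (e.g. a single-timepoint design, where t and t^2
    collapse into the intercept).
    """
    t = _center_scale_time(design.gestational_day.astype(float))
    sex = (design.sex == "M").astype(float)
    grp = (design.group == "MNR").astype(float)
    X = np.column_stack(
        [np.ones_like(t), sex, t, t * t, grp, grp * t, grp * t * t]
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X)
        raise DesignError(
            f"design matrix rank {rank} < {X.shape[1]}; "
            f"collinear columns: {', '.join(bad) or 'unknown'}"
        )
    return X


def _collinear_columns(X: np.ndarray) -> list[str]:
    """Name columns lying in the span of the preceding ones."""
    bad = []
    for j in range(1, X.shape[1]):
        prev = X[:, :j]
        resid = X[:, j] - prev @ np.linalg.lstsq(prev, X[:, j], rcond=None)[0]
        scale = max(np.linalg.norm(X[:, j]), 1.0)
        if np.linalg.norm(resid) < 1e-10 * scale:
            bad.append(MODEL_COLUMNS[j])
    return bad


@dataclass
class StudyDesign:
    """Per-sample covariates plus the derived full-model matrix."""

    sample_ids: list[str]
    group: np.ndarray
    sex: np.ndarray
    gestational_day: np.ndarray
    model_matrix: np.ndarray = field(init=False, repr=False)
    time_centered: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=object)
        self.sex = np.asarray(self.sex, dtype=object)
        self.gestational_day = np.asarray(self.gestational_day, dtype=int)
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise FormatError("duplicate sample_id in design")
        for arr, name in ((self.group, "group"), (self.sex, "sex"), (self.gestational_day, "gestational_day")):
            if len(arr) != n:
                raise FormatError(f"{name} length does not match sample_ids")
        bad_group = set(self.group) - set(GROUPS)
        if bad_group:
            raise FormatError(f"unknown group level(s): {sorted(bad_group)}")
        bad_sex = set(self.sex) - set(SEXES)
        if bad_sex:
            raise FormatError(f"unknown sex level(s): {sorted(bad_sex)}")
        if (self.gestational_day <= 0).any():
            raise FormatError("gestational_day must be positive")
        self.time_centered = _center_scale_time(self.gestational_day.astype(float))
        self.model_matrix = build_model_matrix(self)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def timepoints(self) -> list[int]:
        return sorted(set(int(d) for d in self.gestational_day))

    def reorder(self, sample_ids: list[str]) -> "StudyDesign":
        """Return a design whose rows follow ``sample_ids``."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing or len(sample_ids) != len(self.sample_ids):
            raise ConsistencyError(
                f"sample mismatch between design and count matrix: {missing[:5]}"
            )
        idx = [pos[s] for s in sample_ids]
        return StudyDesign(
            sample_ids=list(sample_ids),
            group=self.group[idx],
            sex=self.sex[idx],
            gestational_day=self.gestational_day[idx],
        )

    def timepoint_mask(self, day: int) -> np.ndarray:
        return self.gestational_day == day


def mnr_study_design(
    days: tuple[int, ...] = (90, 120, 140, 165),
    group_sizes: dict[int, int] | None = None,
) -> StudyDesign:
    """The study's sampling layout: per gestational day, 8 CON + 8 MNR at
    90 and 165 dG and 6 + 6 at 120 and 140 dG, sexes balanced within group.
    """
    if group_sizes is None:
        group_sizes = {90: 8, 120: 6, 140: 6, 165: 8}
    ids, grp, sex, day_col = [], [], [], []
    for d in days:
        n = group_sizes.get(d, 6)
        for g in GROUPS:
            for i in range(n):
                ids.append(f"{g}_{d}_{i + 1:02d}")
                grp.append(g)
                sex.append(SEXES[i % 2])
                day_col.append(d)
    return StudyDesign(ids, np.array(grp, dtype=object), np.array(sex, dtype=object), np.array(day_col))


@dataclass
class PipelineConfig:
    """Run configuration with the pipeline's thresholds.

    min_max_count:   transcripts whose maximum count across samples falls
                     below this are dropped before expression modelling.
    presence_threshold: minimum reads for an isoform to count as expressed
                     in the splice-diversity statistic.
    fdr_primary:     FDR cut for the prioritized gene set (and for the
                     MCODE qualifying-gene rule).
    p_network:       unadjusted-p cut admitting genes to network analysis.
    fdr_timepoint:   FDR cut for the per-timepoint differential-splicing lists.
    meta_timepoints: gestational days combined by the splice meta-analysis.
    mcode_vwp:       MCODE vertex weight percentage (boundary looseness).
    mcode_min_score / mcode_min_nodes: cluster admission rules
                     (score strictly greater; node count at least).
    """

    min_max_count: int = 15
    presence_threshold: int = 1
    fdr_primary: float = 0.1
    p_network: float = 0.001
    fdr_timepoint: float = 0.05
    meta_timepoints: tuple[int, ...] = (120, 140)
    mcode_vwp: float = 0.2
    mcode_min_score: float = 4.0
    mcode_min_nodes: int = 7
    mcode_haircut: bool = True
    use_scaling_factors: bool = False
    lowess_frac: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_max_count < 1 or self.presence_threshold < 1:
            raise ConfigError("count thresholds must be >= 1")
        for name in ("fdr_primary", "p_network", "fdr_timepoint"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must be in (0, 1)")
        if not 0 <= self.mcode_vwp < 1:
            raise ConfigError("mcode_vwp must be in [0, 1)")
        if self.mcode_min_score <= 0 or self.mcode_min_nodes <= 0:
            raise ConfigError("MCODE admission thresholds must be positive")
        if not 0 < self.lowess_frac <= 1:
            raise ConfigError("lowess_frac must be in (0, 1]")
        self.meta_timepoints = tuple(int(d) for d in self.meta_timepoints)

    def to_file(self, path: str | Path) -> None:
        """Write as flat ``key: value`` text (lists comma-joined)."""
        lines = ["# mnrseq pipeline configuration"]
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name}: {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise ConfigError(f"malformed config line: {raw!r}")
            key, val = (s.strip() for s in line.split(":", 1))
            if key not in known:
                raise ConfigError(f"unknown config key: {key}")
            kwargs[key] = _parse_config_value(known[key].type, val)
        return cls(**kwargs)

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["meta_timepoints"] = list(self.meta_timepoints)
        return d


def _parse_config_value(typ: object, val: str):
    typ = str(typ)
    if "tuple" in typ:
        return tuple(int(x) for x in val.split(",") if x.strip())
    if typ == "bool":
        return val.lower() in ("1", "true", "yes", "on")
    if typ == "int":
        return int(val)
    if typ == "float":
        return float(val)
    return val
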