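"""Synthetic trust-level survey data with a prescribed moment structure.

The generator emulates an aggregated maternity patient-experience survey:
122 organizational units ("trusts"), eight section scores S1..S8 on a 0-10
scale with known means, standard deviations and inter-section Pearson
correlations, optional item-level blocks whose internal consistency
(Cronbach's alpha) hits a per-section target, and a small fraction of
missing-completely-at-random cells.

Section scores are multivariate Gaussian (clipped to the scale bounds;
at the default parameters the bounds sit more than five standard deviations
from every mean, so the clipped mass is negligible).  Item blocks use a
compound-symmetry construction whose inter-item correlation is obtained by
inverting the Spearman-Brown relation for the target alpha, with the extra
constraint that each row's item mean equals the row's section score exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.correlation_tools import corr_nearest
from statsmodels.tools.sm_exceptions import IterationLimitWarning

SECTIONS = ["S1", "S2", "S3", "S4", "S5", "S6", "S7", "S8"]

SECTION_NAMES = {
    "S1": "The start of the care during pregnancy",
    "S2": "Antenatal check-ups",
    "S3": "During the pregnancy",
    "S4": "The labour and birth",
    "S5": "Staff caring",
    "S6": "Care in the hospital",
    "S7": "Feeding the baby",
    "S8": "Care after birth",
}

# Published trust-level moments of the eight section scores.
DEFAULT_MEANS = np.array([5.10, 7.95, 8.26, 8.13, 8.35, 7.03, 8.28, 7.51])
DEFAULT_SDS = np.array([0.51, 0.36, 0.35, 0.36, 0.31, 0.53, 0.32, 0.36])

DEFAULT_CORRELATION = np.array(
    [
        [1.00, 0.63, 0.61, 0.49, 0.41, 0.33, 0.32, 0.42],
        [0.63, 1.00, 0.80, 0.50, 0.43, 0.34, 0.43, 0.66],
        [0.61, 0.80, 1.00, 0.63, 0.61, 0.43, 0.60, 0.67],
        [0.49, 0.50, 0.63, 1.00, 0.77, 0.50, 0.50, 0.50],
        [0.41, 0.43, 0.61, 0.77, 1.00, 0.57, 0.61, 0.57],
        [0.33, 0.34, 0.43, 0.50, 0.57, 1.00, 0.65, 0.50],
        [0.32, 0.43, 0.60, 0.50, 0.61, 0.65, 1.00, 0.61],
        [0.42, 0.66, 0.67, 0.50, 0.57, 0.50, 0.61, 1.00],
    ]
)

# Published per-section internal-consistency targets.
DEFAULT_ALPHAS = np.array([0.83, 0.75, 0.79, 0.74, 0.92, 0.53, 0.70, 0.92])

# 50 questions split over 8 sections; the per-section split is not published,
# so an (almost) even split is used, keeping the staff-caring block at 6 items.
DEFAULT_ITEMS_PER_SECTION = (7, 6, 6, 6, 6, 6, 6, 7)

DEFAULT_MISSING_RATE = 0.07
DEFAULT_N_ROWS = 122
SCALE = (0.0, 10.0)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic survey generator.

    Defaults reproduce the published study conditions: n = 122 trusts,
    the printed section means/SDs/correlations, the printed per-section
    alphas, 50 items, and a 7% MCAR missing rate.
    """

    n_rows: int = DEFAULT_N_ROWS
    section_means: np.ndarray = field(default_factory=lambda: DEFAULT_MEANS.copy())
    section_sds: np.ndarray = field(default_factory=lambda: DEFAULT_SDS.copy())
    correlation: np.ndarray = field(default_factory=lambda: DEFAULT_CORRELATION.copy())
    items_per_section: tuple[int, ...] = DEFAULT_ITEMS_PER_SECTION
    target_alphas: np.ndarray = field(default_factory=lambda: DEFAULT_ALPHAS.copy())
    missing_rate: float = DEFAULT_MISSING_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        self.section_means = np.asarray(self.section_means, dtype=float)
        self.section_sds = np.asarray(self.section_sds, dtype=float)
        self.correlation = np.asarray(self.correlation, dtype=float)
        self.target_alphas = np.asarray(self.target_alphas, dtype=float)
        self.validate()

    @property
    def n_sections(self) -> int:
        return len(self.section_means)

    def validate(self) -> None:
        p = self.n_sections
        if self.n_rows < 1:
            raise ValueError("n_rows must be positive")
        if self.section_sds.shape != (p,) or np.any(self.section_sds <= 0):
            raise ValueError("section_sds must be positive and match section_means")
        if self.correlation.shape != (p, p):
            raise ValueError("correlation must be square and match section count")
        if not np.allclose(self.correlation, self.correlation.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.correlation), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(self.correlation) > 1 + 1e-12):
            raise ValueError("correlation entries must lie in [-1, 1]")
        if len(self.items_per_section) != p:
            raise ValueError("items_per_section must match section count")
        if self.target_alphas.shape != (p,):
            raise ValueError("target_alphas must match section count")
        if np.any(self.target_alphas < 0) or np.any(self.target_alphas >= 1):
            raise ValueError("target alphas must lie in [0, 1)")
        for m, a in zip(self.items_per_section, self.target_alphas):
            if a > 0 and m < 2:
                raise ValueError("sections with a target alpha need >= 2 items")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class SurveyDataset:
    """Numeric trust x variable matrix with optional missing cells.

    ``values`` is a DataFrame whose NaNs mark missing cells; ``section_of``
    maps every column to its section id; ``level`` is "section" for the
    eight aggregate scores or "item" for question-level columns.
    """

    values: pd.DataFrame
    section_of: dict[str, str]
    level: str = "section"
    scale: tuple[float, float] = SCALE

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.section_of)
        if missing:
            raise ValueError(f"columns without a section assignment: {sorted(missing)}")
        if self.level not in ("section", "item"):
            raise ValueError("level must be 'section' or 'item'")

    @property
    def n_rows(self) -> int:
        return len(self.values)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def to_csv(self, path) -> None:
        """Write as comma-separated text with an 'NA' missing marker."""
        self.values.to_csv(path, index=False, na_rep="NA")

    @classmethod
    def from_csv(cls, path, section_of: dict[str, str] | None = None,
                 level: str = "section") -> "SurveyDataset":
        df = pd.read_csv(path, na_values=["NA"])
        if section_of is None:
            section_of = {c: c for c in df.columns}
        return cls(values=df, section_of=section_of, level=level)


def repair_correlation(matrix: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Project a symmetric unit-diagonal matrix onto the correlation cone.

    Printed correlation tables are rounded and can fail positive
    semidefiniteness; this returns the nearest (Frobenius) valid correlation
    matrix by Higham's alternating projections, and the input unchanged when
    it is already PSD.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if np.linalg.eigvalsh(matrix)[0] >= -tol:
        return matrix
    # corr_nearest warns whenever eigenvalue clipping is still active at its
    # iteration cap, even when the output already meets the PSD tolerance;
    # silence it and verify the property that actually matters
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", IterationLimitWarning)
        repaired = corr_nearest(matrix, threshold=1e-12)
    if np.linalg.eigvalsh(repaired)[0] < -tol:
        raise ValueError("nearest-correlation repair failed to reach PSD")
    return repaired


def generate_sections(config: GeneratorConfig,
                      rng: np.random.Generator | None = None) -> SurveyDataset:
    """Draw section-level scores from the configured Gaussian model.

    Rows come from N(mean, D R D) with R the PSD-repaired correlation and
    D = diag(section_sds), then clip to the score scale.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    corr = repair_correlation(config.correlation)
    cov = corr * np.outer(config.section_sds, config.section_sds)
    x = rng.multivariate_normal(config.section_means, cov, size=config.n_rows,
                                method="cholesky")
    x = np.clip(x, SCALE[0], SCALE[1])
    cols = SECTIONS[: config.n_sections]
    df = pd.DataFrame(x, columns=cols)
    return SurveyDataset(values=df, section_of={c: c for c in cols}, level="section")


def invert_spearman_brown(alpha: float, m: int) -> float:
    """Inter-item correlation of m equicorrelated items with Cronbach alpha
    equal to ``alpha``: rho = alpha / (m - alpha (m - 1))."""
    if not 0 <= alpha < 1:
        raise ValueError("alpha must lie in [0, 1)")
    if m < 2:
        raise ValueError("need at least two items")
    return alpha / (m - alpha * (m - 1))


def generate_items(config: GeneratorConfig, section_scores: SurveyDataset,
                   rng: np.random.Generator | None = None) -> SurveyDataset:
    """Expand section scores into equicorrelated item blocks.

    For a section with sample variance v and target alpha, items are
    x_j = s + sqrt(g) (z_j - mean(z)) with g = v m (1 - rho) / (1 + (m-1) rho)
    and rho from the Spearman-Brown inversion.  The centering makes each
    row's item mean equal its section score exactly while keeping the block
    compound-symmetric at correlation rho, hence population alpha = target.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    blocks: dict[str, np.ndarray] = {}
    section_of: dict[str, str] = {}
    n = section_scores.n_rows
    for j, sec in enumerate(section_scores.columns):
        m = config.items_per_section[j]
        alpha = float(config.target_alphas[j])
        if alpha > 0 and m < 2:
            raise ValueError(f"section {sec}: alpha target needs >= 2 items")
        s = section_scores.values[sec].to_numpy()
        rho = invert_spearman_brown(alpha, m) if m >= 2 else 1.0
        v = float(np.var(s, ddof=1))
        g = v * m * (1.0 - rho) / (1.0 + (m - 1) * rho)
        z = rng.standard_normal((n, m))
        dev = np.sqrt(g) * (z - z.mean(axis=1, keepdims=True))
        block = s[:, None] + dev
        for i in range(m):
            name = f"{sec}_Q{i + 1}"
            blocks[name] = block[:, i]
            section_of[name] = sec
    df = pd.DataFrame(blocks)
    return SurveyDataset(values=df, section_of=section_of, level="item")


def inject_missing(dataset: SurveyDataset, rate: float,
                   seed: int) -> SurveyDataset:
    """Blank exactly round(rate * n_cells) cells, uniformly at random (MCAR).

    Cells are drawn without replacement; a draw that would leave a column
    fully missing is redrawn so downstream mean imputation stays defined.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    n, p = dataset.values.shape
    n_cells = n * p
    k = int(round(rate * n_cells))
    if k == 0:
        return dataset
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        idx = rng.choice(n_cells, size=k, replace=False)
        rows, cols = np.divmod(idx, p)
        if np.all(np.bincount(cols, minlength=p) < n):
            break
    else:  # pragma: no cover - needs rate extremely close to 1
        raise RuntimeError("could not place missing cells without emptying a column")
    values = dataset.values.copy()
    arr = values.to_numpy(dtype=float)
    arr[rows, cols] = np.nan
    values.iloc[:, :] = arr
    return replace(dataset, values=values)


def generate_survey(config: GeneratorConfig,
                    with_items: bool = False) -> SurveyDataset:
    """One-call generator: sections (optionally items) plus MCAR missingness.

    All randomness derives from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    sections = generate_sections(config, rng=rng)
    data = generate_items(config, sections, rng=rng) if with_items else sections
    # derive the missingness seed from the master seed, keeping it below 2^31
    miss_seed = int(np.random.default_rng(config.seed + 2).integers(2**31))
    return inject_missing(data, config.missing_rate, seed=miss_seed)
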