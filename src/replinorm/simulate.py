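"""Synthetic single- and multi-laboratory experiments.

The generative model for one animal in lab *j*, genotype *g*, arm *a*
(0 = control, 1 = treatment) is

    y = h_g(x_j) + u_j + a * (delta0 + delta1 * x_j) + eps,

where ``x_j`` is the lab's value of a dominating environmental factor
(drawn from the environment distribution, or fixed at its mean under
standardization), ``u_j ~ N(0, small_effect_sd)`` is the Gaussian aggregate
of the many small-effect factors shared by all animals in the lab, and
``eps ~ N(0, within_noise_sd)`` is independent per animal.  The treatment
effect ``delta0 + delta1 * x_j`` may depend linearly on the dominating
factor: that dependence (``delta1 != 0``), or genotype-specific norms, is
what makes the *effect* vary between labs — the additive lab offsets
``h_g(x_j)`` and ``u_j`` cancel in a within-lab treatment-minus-control
contrast.

All randomness flows from a single integer seed through a hierarchical
substream scheme (one child stream per lab; within a lab, draws are made in
a fixed order: dominating factor, small-effect aggregate, then per-animal
noise by genotype, arm, animal index), so identical seeds reproduce
identical datasets record for record.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateSEError, StructuralError
from .norms import EnvironmentDistribution, ReactionNorm

__all__ = [
    "StudyDesign",
    "MultiLabDataset",
    "StudyResult",
    "simulate_multilab",
    "summarize_labs",
    "make_gradient_fixture",
    "results_to_frame",
    "results_from_frame",
]

DATASET_COLUMNS = ["lab_id", "genotype", "arm", "x", "u", "y"]
RESULT_COLUMNS = ["lab_id", "genotype", "mean_effect", "se", "n1", "n2", "x", "s2"]


@dataclass(frozen=True)
class StudyDesign:
    """Design of a (multi-)laboratory two-arm experiment.

    Parameters
    ----------
    n_labs, n_per_arm : int
        Number of laboratories and animals per arm per genotype per lab.
    genotypes : sequence of ReactionNorm
        One reaction norm per genotype in the study.
    standardization : {"standardized", "heterogenized"}
        Standardized designs fix the dominating factor at the environment
        mean in every lab; heterogenized designs let each lab draw its own
        value.
    within_noise_sd : float
        SD of per-animal residual noise (test variation, measurement error).
    small_effect_sd : float
        SD of the per-lab Gaussian aggregate of small-effect factors.
    delta0, delta1 : float
        Treatment effect at x = 0 and its slope per unit of the dominating
        factor.
    """

    n_labs: int
    n_per_arm: int
    genotypes: tuple[ReactionNorm, ...]
    standardization: str = "heterogenized"
    within_noise_sd: float = 1.0
    small_effect_sd: float = 0.0
    delta0: float = 0.0
    delta1: float = 0.0

    def __post_init__(self) -> None:
        if self.n_labs < 1:
            raise ValueError("n_labs must be >= 1")
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be >= 2")
        if self.within_noise_sd < 0 or self.small_effect_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.standardization not in ("standardized", "heterogenized"):
            raise ValueError("standardization must be 'standardized' or 'heterogenized'")
        if not self.genotypes:
            raise ValueError("need at least one genotype")
        object.__setattr__(self, "genotypes", tuple(self.genotypes))

    def describe(self) -> dict:
        return {
            "n_labs": self.n_labs,
            "n_per_arm": self.n_per_arm,
            "genotypes": [g.genotype_label for g in self.genotypes],
            "standardization": self.standardization,
            "within_noise_sd": self.within_noise_sd,
            "small_effect_sd": self.small_effect_sd,
            "delta0": self.delta0,
            "delta1": self.delta1,
        }


@dataclass(frozen=True)
class MultiLabDataset:
    """Per-animal records from a simulated multi-lab experiment."""

    frame: pd.DataFrame
    seed: int | None = None
    design: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in DATASET_COLUMNS if c not in self.frame.columns]
        if missing:
            raise StructuralError(f"dataset frame missing columns {missing}")

    def to_csv(self, path: str | Path | None = None) -> str | None:
        """Write (or return) the tidy per-animal table as CSV."""
        if path is None:
            buf = io.StringIO()
            self.frame[DATASET_COLUMNS].to_csv(buf, index=False)
            return buf.getvalue()
        self.frame[DATASET_COLUMNS].to_csv(path, index=False)
        return None

    @classmethod
    def from_csv(cls, path: str | Path) -> "MultiLabDataset":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class StudyResult:
    """Summary of one lab-by-genotype two-arm contrast.

    ``mean_effect`` is the treatment-minus-control difference in means,
    ``se`` its pooled-variance standard error, ``s2`` the pooled
    within-group variance, and ``x`` the lab's dominating-factor value
    (``None`` when unrecorded).
    """

    lab_id: str
    genotype_label: str
    mean_effect: float
    se: float
    n1: int
    n2: int
    x: float | None = None
    s2: float | None = None

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("need n >= 2 in each arm")
        if not self.se > 0:
            raise DegenerateSEError(
                f"study ({self.lab_id}, {self.genotype_label}) has "
                f"standard error {self.se}; all observations identical?"
            )

    @property
    def x_known(self) -> bool:
        return self.x is not None and math.isfinite(self.x)


def simulate_multilab(
    design: StudyDesign,
    env: EnvironmentDistribution,
    seed: int,
) -> MultiLabDataset:
    """Simulate per-animal data under the lab/genotype/arm generative model.

    Each lab gets its own random substream; within it the dominating-factor
    value, the small-effect aggregate and per-animal noise are drawn in a
    fixed order, so the dataset is bit-for-bit reproducible from
    ``(design, env, seed)``.
    """
    root = np.random.SeedSequence(seed)
    lab_streams = root.spawn(design.n_labs)
    records: list[tuple] = []
    pad = max(2, len(str(design.n_labs)))
    for j, stream in enumerate(lab_streams):
        rng = np.random.default_rng(stream)
        if design.standardization == "standardized":
            if env.mean is None:
                raise ValueError("standardized design needs an environment with a known mean")
            x_lab = float(env.mean)
        else:
            x_lab = float(env.sample(1, rng)[0])
        u_lab = float(rng.normal(0.0, design.small_effect_sd)) if design.small_effect_sd > 0 else 0.0
        lab_id = f"lab{j + 1:0{pad}d}"
        effect = design.delta0 + design.delta1 * x_lab
        for norm in design.genotypes:
            baseline = float(norm(x_lab)) + u_lab
            for arm_name, arm_ind in (("control", 0), ("treatment", 1)):
                eps = rng.normal(0.0, design.within_noise_sd, size=design.n_per_arm)
                y = baseline + arm_ind * effect + eps
                for yi in y:
                    records.append((lab_id, norm.genotype_label, arm_name,
                                    x_lab, u_lab, float(yi)))
    frame = pd.DataFrame.from_records(records, columns=DATASET_COLUMNS)
    return MultiLabDataset(frame=frame, seed=seed, design=design.describe())


def summarize_labs(data: MultiLabDataset) -> list[StudyResult]:
    """Collapse per-animal records to per-(lab, genotype) contrast summaries.

    ``mean_effect = mean(treatment) - mean(control)``; ``se`` uses the
    pooled within-cell variance, ``sqrt(s2 * (1/n1 + 1/n2))``.  An empty
    arm or a zero pooled variance is an error, not a silent NaN.
    """
    results: list[StudyResult] = []
    for (lab, genotype), cell in data.frame.groupby(["lab_id", "genotype"], sort=True):
        arms = {}
        for arm in ("treatment", "control"):
            vals = cell.loc[cell["arm"] == arm, "y"].to_numpy()
            if vals.size < 2:
                raise StructuralError(
                    f"cell (lab={lab}, genotype={genotype}, arm={arm}) has "
                    f"{vals.size} observations; need >= 2"
                )
            arms[arm] = vals
        t, c = arms["treatment"], arms["control"]
        n1, n2 = t.size, c.size
        s2 = ((n1 - 1) * t.var(ddof=1) + (n2 - 1) * c.var(ddof=1)) / (n1 + n2 - 2)
        se = math.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
        xs = cell["x"].unique()
        x = float(xs[0]) if len(xs) == 1 else None
        results.append(StudyResult(
            lab_id=str(lab), genotype_label=str(genotype),
            mean_effect=float(t.mean() - c.mean()), se=se,
            n1=int(n1), n2=int(n2), x=x, s2=float(s2),
        ))
    return results


def make_gradient_fixture(
    n_studies: int = 25,
    x_range: tuple[float, float] = (18.0, 30.0),
    delta0: float = 0.0,
    delta1: float = 0.25,
    se_per_study: float = 0.5,
    seed: int = 0,
    n_per_arm: int = 10,
) -> list[StudyResult]:
    """Studies whose effect sizes vary linearly along an environmental gradient.

    Emulates a body of studies sorted by a recorded environmental covariate
    (canonically ambient temperature over 18-30 degrees C): study *i* sits at
    an evenly spaced gradient value ``x_i``, its true effect is
    ``delta0 + delta1 * x_i``, and its observed mean effect is drawn Gaussian
    around the truth with sd ``se_per_study``.  Results are returned sorted
    by ``x``.  ``n_per_arm`` and ``s2`` are nominal bookkeeping values,
    back-computed so that ``se = sqrt(s2 * (1/n1 + 1/n2))`` holds.
    """
    if n_studies < 3:
        raise ValueError("need n_studies >= 3")
    if not se_per_study > 0:
        raise ValueError("se_per_study must be positive")
    xs = np.linspace(x_range[0], x_range[1], n_studies)
    rng = np.random.default_rng(seed)
    true_effects = delta0 + delta1 * xs
    observed = true_effects + rng.normal(0.0, se_per_study, size=n_studies)
    s2 = se_per_study ** 2 / (2.0 / n_per_arm)
    pad = max(2, len(str(n_studies)))
    return [
        StudyResult(
            lab_id=f"study{i + 1:0{pad}d}", genotype_label="g1",
            mean_effect=float(observed[i]), se=float(se_per_study),
            n1=n_per_arm, n2=n_per_arm, x=float(xs[i]), s2=float(s2),
        )
        for i in range(n_studies)
    ]


def results_to_frame(results: Sequence[StudyResult]) -> pd.DataFrame:
    """Tidy table of study summaries (fixed column order)."""
    return pd.DataFrame(
        [
            {
                "lab_id": r.lab_id, "genotype": r.genotype_label,
                "mean_effect": r.mean_effect, "se": r.se,
                "n1": r.n1, "n2": r.n2,
                "x": r.x if r.x is not None else np.nan,
                "s2": r.s2 if r.s2 is not None else np.nan,
            }
            for r in results
        ],
        columns=RESULT_COLUMNS,
    )


def results_from_frame(frame: pd.DataFrame) -> list[StudyResult]:
    """Inverse of :func:`results_to_frame`."""
    out = []
    for row in frame.itertuples(index=False):
        x = getattr(row, "x", np.nan)
        s2 = getattr(row, "s2", np.nan)
        out.append(StudyResult(
            lab_id=str(row.lab_id), genotype_label=str(row.genotype),
            mean_effect=float(row.mean_effect), se=float(row.se),
            n1=int(row.n1), n2=int(row.n2),
            x=None if pd.isna(x) else float(x),
            s2=None if pd.isna(s2) else float(s2),
        ))
    return out
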